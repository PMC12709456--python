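"""Linearised Hopf (Stuart-Landau) whole-brain model.

Each region follows the normal form of a supercritical Hopf bifurcation,
``dz_j = (a_j + i w_j) z_j - |z_j|^2 z_j + sum_m C[m, j] (z_m - z_j) + noise``,
operated in the noisy subcritical regime (``a_j < 0``) where the dynamics
linearise around the stable fixed point ``z = 0``.  Writing ``z = x + i y``
the linearisation is a 2N-dimensional Ornstein-Uhlenbeck process with
Jacobian ``J = [[A, -Omega], [Omega, A]]`` where ``A[n, m] = C[m, n]`` for
``m != n``, ``A[n, n] = a_n - sum_m C[m, n]`` and ``Omega = diag(omega)``.

The stationary covariance ``K`` solves the continuous Lyapunov equation
``J K + K J' + Q = 0`` and the lagged model covariance derives from
``expm(tau J) K``; throughout the package the index convention is that the
row indexes the *earlier* sample, ``KS_forward(tau)[i, j] =
cov(x_i(t), x_j(t + tau))``, matching the empirical estimators.  The
time-reversed counterpart of a stationary linear process is the transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov
from scipy.signal import welch

__all__ = [
    "HopfParameters",
    "build_jacobian",
    "solve_stationary_covariance",
    "lagged_model_covariance",
    "normalize_shifted",
    "estimate_node_frequencies",
    "model_statistics",
]

#: Standard resting-state frequency band (Hz) for node-frequency estimation.
DEFAULT_BAND_HZ = (0.008, 0.08)


@dataclass
class HopfParameters:
    """Parameters of the linearised Hopf model.

    Parameters
    ----------
    a : array-like or float
        Bifurcation parameter per region (1/s); must be negative so the
        fixed point is stable and the linearisation valid.
    omega : array-like or float
        Intrinsic angular frequency per region (rad/s).
    sigma : float
        Additive noise amplitude (signal units / sqrt(s)); equal independent
        noise on both oscillator components, ``Q = sigma^2 I``.
    tau : float
        Lag for the time-shifted covariances, in units of TR.
    """

    a: np.ndarray | float = -0.02
    omega: np.ndarray | float = 2 * np.pi * 0.05
    sigma: float = 0.01
    tau: float = 1.0

    def broadcast(self, n_regions: int) -> "HopfParameters":
        a = np.broadcast_to(np.asarray(self.a, dtype=float), (n_regions,)).copy()
        omega = np.broadcast_to(np.asarray(self.omega, dtype=float), (n_regions,)).copy()
        if np.any(a >= 0):
            raise ValueError("bifurcation parameter a must be < 0 (stable fixed point)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        return HopfParameters(a=a, omega=omega, sigma=float(self.sigma), tau=float(self.tau))


def build_jacobian(coupling: np.ndarray, params: HopfParameters) -> np.ndarray:
    """Jacobian of the linearised coupled Hopf system at the fixed point.

    Returns the 2N x 2N block matrix ``[[A, -Omega], [Omega, A]]``.  With the
    diffusive coupling convention the A-block rows satisfy the Gershgorin
    bound ``Re(lambda) <= a_n < 0``; stability is still verified and a
    violation raises.
    """
    C = np.asarray(coupling, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n):
        raise ValueError("coupling must be square")
    if np.any(C < 0):
        raise ValueError("coupling must be nonnegative")
    if np.any(np.diag(C) != 0):
        raise ValueError("coupling diagonal must be zero")
    p = params.broadcast(n)
    # A[n, m] = C[m, n]: input to region n from region m
    A = C.T.copy()
    np.fill_diagonal(A, p.a - C.sum(axis=0))
    Om = np.diag(p.omega)
    J = np.block([[A, -Om], [Om, A]])
    if np.max(np.linalg.eigvals(A + 1j * Om).real) >= 0:
        raise ValueError("Jacobian is not stable; linearisation invalid "
                         "for this coupling/parameter combination")
    return J


def solve_stationary_covariance(J: np.ndarray, sigma: float) -> np.ndarray:
    """Stationary covariance of the linear SDE ``dx = J x dt + sigma dW``.

    Solves ``J K + K J' + sigma^2 I = 0`` (Bartels-Stewart) and symmetrises
    the result to suppress round-off.
    """
    J = np.asarray(J, dtype=float)
    if np.max(np.linalg.eigvals(J).real) >= 0:
        raise ValueError("cannot solve the Lyapunov equation for an unstable Jacobian")
    Q = sigma**2 * np.eye(J.shape[0])
    K = solve_continuous_lyapunov(J, -Q)
    K = 0.5 * (K + K.T)
    resid = np.max(np.abs(J @ K + K @ J.T + Q))
    if resid > 1e-8 * np.max(np.abs(Q)):
        raise ArithmeticError(f"Lyapunov residual too large: {resid:g}")
    return K


def lagged_model_covariance(
    J: np.ndarray, K0: np.ndarray, tau_seconds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward and time-reversed lagged covariances of the stationary process.

    ``KS_forward[i, j] = cov(x_i(t), x_j(t + tau)) = (K0 expm(tau J'))_ij``,
    the transpose of ``expm(tau J) K0`` (same object, row = earlier sample);
    for the time-reversed stationary process the lagged covariance is
    exactly the transpose of the forward one.
    """
    if tau_seconds < 0:
        raise ValueError("tau must be nonnegative")
    KS_forward = (expm(tau_seconds * np.asarray(J, float)) @ np.asarray(K0, float)).T
    return KS_forward, KS_forward.T


def normalize_shifted(KS: np.ndarray, K0: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Normalise a (possibly lagged) covariance into correlation units.

    Divides entry ``(i, j)`` by ``sqrt(K0[i, i] K0[j, j])`` and restricts to
    the first N rows/columns (the observable x-components of the oscillators).
    """
    KS = np.asarray(KS, dtype=float)
    K0 = np.asarray(K0, dtype=float)
    d = np.diag(K0)
    if np.any(d <= 0):
        raise ValueError("zero variance on the diagonal; cannot normalise")
    FS = KS / np.sqrt(np.outer(d, d))
    if n_regions is None:
        n_regions = KS.shape[0] // 2 if KS.shape[0] % 2 == 0 else KS.shape[0]
    return FS[:n_regions, :n_regions]


def model_statistics(
    coupling: np.ndarray, params: HopfParameters, tr_seconds: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic (FC, FS_forward, FS_reversal) of the linearised model.

    Convenience wrapper chaining Jacobian -> Lyapunov -> lagged covariance ->
    normalisation, at lag ``params.tau`` TRs.  All three outputs are N x N.
    """
    n = coupling.shape[0]
    p = params.broadcast(n)
    J = build_jacobian(coupling, p)
    K0 = solve_stationary_covariance(J, p.sigma)
    KSf, KSr = lagged_model_covariance(J, K0, p.tau * tr_seconds)
    fc = normalize_shifted(K0, K0, n)
    return fc, normalize_shifted(KSf, K0, n), normalize_shifted(KSr, K0, n)


def estimate_node_frequencies(
    ts: np.ndarray,
    tr_seconds: float,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> np.ndarray:
    """Per-region intrinsic angular frequencies from the Welch periodogram.

    ``omega_j = 2 pi f_j`` with ``f_j`` the peak of region *j*'s power
    spectral density within ``band_hz``.  A peak pinned at a band edge
    triggers a warning (flat or out-of-band spectrum).
    """
    import warnings

    X = np.asarray(ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("time series must be regions x timepoints")
    if X.shape[1] < 64:
        raise ValueError("need at least 64 timepoints to estimate spectra")
    fs = 1.0 / tr_seconds
    lo, hi = band_hz
    if not (0 < lo < hi):
        raise ValueError("invalid frequency band")
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    nperseg = min(X.shape[1], 128)
    freqs, psd = welch(X, fs=fs, nperseg=nperseg, axis=1)
    in_band = (freqs >= lo) & (freqs <= hi)
    if in_band.sum() < 2:
        raise ValueError("band too narrow for the available spectral resolution")
    fb = freqs[in_band]
    peak = fb[np.argmax(psd[:, in_band], axis=1)]
    if np.any(np.isclose(peak, fb[0])) or np.any(np.isclose(peak, fb[-1])):
        warnings.warn("spectral peak at band edge for some regions "
                      "(flat or out-of-band spectrum)", stacklevel=2)
    return 2 * np.pi * peak
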