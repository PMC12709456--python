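"""Trophic hierarchy of directed weighted networks.

A directed coupling matrix ``C`` (entry ``C[m, n]`` = influence of region *m*
over region *n*) induces a hierarchy: each node receives a *trophic level*
``h`` solving the Laplacian system ``(diag(u) - C - C.T) h = v`` driven by the
node's flow imbalance ``v = d_out - d_in``.  Sources of causal influence sit
high, sinks low.  The weight-normalised squared deviation of edge-wise level
increments from the ideal unit drop is the *trophic incoherence* ``F0``;
``1 - F0`` is the *trophic directedness* (1 on a perfectly layered graph, 0 on
a fully symmetric one).  The levels solving the linear system are exactly the
minimisers of the incoherence energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TrophicResult",
    "flow_degrees",
    "trophic_levels",
    "trophic_incoherence",
    "directedness",
    "asymmetry_index",
    "classify_regimes",
    "network_average",
    "trophic_analysis",
]


def _validate_coupling(weights: np.ndarray) -> np.ndarray:
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"coupling must be square, got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("coupling contains non-finite entries")
    if np.any(W < 0):
        raise ValueError("coupling must be nonnegative")
    if np.any(np.diag(W) != 0):
        raise ValueError("coupling must have a zero diagonal")
    return W


def flow_degrees(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """In-/out-weights and their sum/imbalance for each node.

    Returns ``(d_in, d_out, u, v)`` with ``d_in[n] = sum_m C[m, n]``,
    ``d_out[n] = sum_m C[n, m]``, ``u = d_in + d_out`` and
    ``v = d_out - d_in`` (positive for sources, negative for sinks).
    """
    W = _validate_coupling(weights)
    d_in = W.sum(axis=0)
    d_out = W.sum(axis=1)
    return d_in, d_out, d_in + d_out, d_out - d_in


def graph_laplacian(weights: np.ndarray) -> np.ndarray:
    """Symmetrised weighted Laplacian ``diag(u) - C - C.T``."""
    W = _validate_coupling(weights)
    _, _, u, _ = flow_degrees(W)
    return np.diag(u) - W - W.T


def trophic_levels(weights: np.ndarray) -> np.ndarray:
    """Solve the trophic-level linear system and shift the minimum to zero.

    The Laplacian is exactly singular (constant nullspace on each weakly
    connected component), so the minimum-norm least-squares solution is taken
    and each component is shifted so its lowest node sits at level 0.
    Isolated nodes get level 0 with a warning; multiple components are solved
    independently with a warning.
    """
    W = _validate_coupling(weights)
    n = W.shape[0]
    _, _, u, v = flow_degrees(W)
    lap = np.diag(u) - W - W.T

    n_comp, labels = connected_components(W != 0, directed=True, connection="weak")
    h = np.zeros(n)
    if n_comp > 1:
        sizes = np.bincount(labels)
        if np.any(sizes == 1):
            warnings.warn(
                f"{int((sizes == 1).sum())} isolated node(s) assigned trophic level 0",
                stacklevel=2,
            )
        if np.any(sizes > 1) and (sizes > 1).sum() + (sizes == 1).sum() > 1:
            warnings.warn(
                f"network has {n_comp} weakly connected components; "
                "levels solved and shifted per component",
                stacklevel=2,
            )
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        if idx.size == 1:
            continue
        sub = np.ix_(idx, idx)
        h_c = np.linalg.lstsq(lap[sub], v[idx], rcond=None)[0]
        h[idx] = h_c - h_c.min()
    return h


def trophic_incoherence(weights: np.ndarray, h: np.ndarray | None = None) -> float:
    """Weight-normalised incoherence ``F0 = sum_e w_e (h_tail - h_head - 1)^2 / sum_e w_e``.

    Zero iff every edge drops exactly one level from its tail (source of the
    edge) to its head.  Invariant to uniform weight rescaling.
    """
    W = _validate_coupling(weights)
    if h is None:
        h = trophic_levels(W)
    h = np.asarray(h, dtype=float)
    total = W.sum()
    if total <= 0:
        raise ValueError("trophic incoherence undefined for a zero-weight network")
    # edge tail->head carries weight W[tail, head]; residual h_tail - h_head - 1
    resid = h[:, None] - h[None, :] - 1.0
    return float((W * resid**2).sum() / total)


def directedness(weights: np.ndarray) -> float:
    """Trophic directedness ``1 - F0``: 1 = perfectly layered, 0 = flat."""
    return 1.0 - trophic_incoherence(weights)


def asymmetry_index(A: np.ndarray) -> float:
    """Frobenius asymmetry ``||(A - A.T)/2||_F / ||A||_F`` in [0, 1]."""
    A = np.asarray(A, dtype=float)
    norm = np.linalg.norm(A)
    if norm == 0:
        raise ValueError("asymmetry index undefined for the zero matrix")
    return float(np.linalg.norm(0.5 * (A - A.T)) / norm)


def classify_regimes(h_group_mean: np.ndarray) -> np.ndarray:
    """Label regions as sink / mediator / source.

    Z-scores the group-mean regional levels (population s.d.) and splits
    ``[min(z), max(z)]`` into three equal-width intervals: lowest = sink,
    middle = mediator, highest = source.  Boundary ties go to the lower
    interval.  Constant input degenerates to all-mediator with a warning.
    """
    h = np.asarray(h_group_mean, dtype=float)
    if h.size < 3:
        raise ValueError("regime classification needs at least 3 regions")
    sd = h.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance in trophic levels; all regions labelled mediator",
                      stacklevel=2)
        return np.full(h.size, "mediator", dtype=object)
    z = (h - h.mean()) / sd
    lo, hi = z.min(), z.max()
    step = (hi - lo) / 3.0
    bins = np.digitize(z, [lo + step, lo + 2 * step], right=True)
    return np.array(["sink", "mediator", "source"], dtype=object)[bins]


def network_average(regional_values, mapping) -> "pd.Series":
    """Mean of a regional measure within each functional network.

    ``mapping`` maps each region label (or index) to one of the functional
    networks.  The mean rather than the sum is used so that networks with
    more parcels are not disproportionately weighted.
    """
    import pandas as pd

    values = pd.Series(regional_values) if not isinstance(regional_values, pd.Series) \
        else regional_values
    mapping = pd.Series(mapping) if not isinstance(mapping, pd.Series) else mapping
    missing = values.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"regions without a network assignment: {list(missing)}")
    return values.groupby(mapping.reindex(values.index)).mean()


@dataclass
class TrophicResult:
    """Per-region trophic levels plus the global hierarchy summaries."""

    h: np.ndarray
    d_in: np.ndarray
    d_out: np.ndarray
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    F0: float = 0.0
    directedness: float = 0.0
    asymmetry: float = 0.0
    region_ids: list | None = None

    def summary(self) -> str:
        lines = [
            "Trophic hierarchy",
            "-" * 40,
            f"regions            : {self.h.size}",
            f"incoherence F0     : {self.F0:.6f}",
            f"directedness (1-F0): {self.directedness:.6f}",
            f"asymmetry index    : {self.asymmetry:.6f}",
            f"level range        : [{self.h.min():.4f}, {self.h.max():.4f}]",
        ]
        return "\n".join(lines)


def trophic_analysis(weights: np.ndarray, region_ids=None) -> TrophicResult:
    """Full hierarchy characterisation of one directed coupling matrix."""
    W = _validate_coupling(weights)
    d_in, d_out, u, v = flow_degrees(W)
    h = trophic_levels(W)
    F0 = trophic_incoherence(W, h)
    return TrophicResult(
        h=h, d_in=d_in, d_out=d_out, u=u, v=v,
        F0=F0, directedness=1.0 - F0, asymmetry=asymmetry_index(W),
        region_ids=list(region_ids) if region_ids is not None else None,
    )
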