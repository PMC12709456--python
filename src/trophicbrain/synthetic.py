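"""Synthetic multi-site cohorts with planted hierarchy.

The controlled-access cohort the pipeline was designed around cannot ship
with the package, so every downstream stage is exercised on synthetic data
with known ground truth: a layered directed network with planted trophic
structure, per-subject BOLD-like signals simulated from coupled
Stuart-Landau oscillators, a group effect that flattens the hierarchy by
symmetrising the coupling, multi-site additive/multiplicative feature
effects, and biomarker/cognition variables linearly tied to the hierarchy.

Group effect: for group *g* with flattening ``lam`` in [0, 1], subject
couplings are drawn around ``(1 - lam) C + lam (C + C.T) / 2`` — ``lam = 0``
preserves the planted hierarchy, ``lam = 1`` symmetrises it completely
(directedness 0).  This manipulates exactly the quantity (asymmetry of
causal interactions) that trophic directedness measures, emulating the
flattened, less stratified architecture expected with disease progression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import directedness, trophic_levels

__all__ = [
    "GroundTruthNetwork",
    "CohortConfig",
    "CohortBundle",
    "SiteEffects",
    "generate_hierarchical_coupling",
    "simulate_hopf_bold",
    "simulate_linear_sde",
    "plant_site_effects",
    "generate_cohort",
]

GROUPS = ("HC-", "HC+", "MCI+", "AD+")

# Demographic profiles per group (age mean/sd in years, education mean/sd in
# years, probability female, probability APOE-e4 carrier) emulating a typical
# amyloid-stratified ageing cohort.
_DEMOGRAPHICS = {
    "HC-": dict(age=(72.4, 5.1), edu=(16.8, 2.3), p_female=0.50, p_apoe=0.17),
    "HC+": dict(age=(75.2, 5.8), edu=(16.9, 2.4), p_female=0.58, p_apoe=0.53),
    "MCI+": dict(age=(73.6, 6.4), edu=(16.0, 2.4), p_female=0.58, p_apoe=0.65),
    "AD+": dict(age=(75.4, 8.0), edu=(15.0, 2.3), p_female=0.43, p_apoe=0.62),
}


@dataclass
class GroundTruthNetwork:
    """Directed coupling with known layered hierarchy."""

    coupling: np.ndarray
    planted_levels: np.ndarray
    layer_assignment: np.ndarray


def generate_hierarchical_coupling(
    n_regions: int,
    n_layers: int,
    feedforward_weight: float,
    feedback_weight: float = 0.0,
    density: float = 1.0,
    seed: int | None = None,
) -> GroundTruthNetwork:
    """Layered directed network with predominantly feedforward edges.

    Regions are split as evenly as possible into ``n_layers`` ordered layers;
    each ordered pair spanning consecutive layers receives a feedforward edge
    (higher layer -> lower layer, weight ``feedforward_weight``) with
    probability ``density`` and a reversed edge (weight ``feedback_weight``)
    with the same probability when ``feedback_weight > 0``.  A deterministic
    spine of one feedforward edge per layer boundary guarantees weak
    connectivity.  ``planted_levels`` are the layer ranks, strictly
    decreasing with layer index (layer 0 = top of the hierarchy).
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_layers > n_regions or n_layers < 2:
        raise ValueError("n_layers must be in [2, n_regions]")
    if feedforward_weight < 0 or feedback_weight < 0:
        raise ValueError("weights must be nonnegative")
    if feedforward_weight == 0 and feedback_weight == 0:
        raise ValueError("all-zero weights define no graph")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")

    rng = np.random.default_rng(seed)
    layers = np.sort(np.arange(n_regions) % n_layers)
    C = np.zeros((n_regions, n_regions))
    members = [np.flatnonzero(layers == k) for k in range(n_layers)]
    for k in range(n_layers - 1):
        upper, lower = members[k], members[k + 1]
        for i in upper:
            for j in lower:
                if rng.random() < density:
                    C[i, j] = feedforward_weight
                if feedback_weight > 0 and rng.random() < density:
                    C[j, i] = feedback_weight
        # guarantee weak connectivity: every node touches the adjacent layer
        w, reverse = (feedforward_weight, False) if feedforward_weight > 0 \
            else (feedback_weight, True)
        for i in upper:
            if C[i, lower].sum() == 0 and C[lower, i].sum() == 0:
                j = lower[int(rng.integers(len(lower)))]
                C[(j, i) if reverse else (i, j)] = w
        for j in lower:
            if C[upper, j].sum() == 0 and C[j, upper].sum() == 0:
                i = upper[int(rng.integers(len(upper)))]
                C[(j, i) if reverse else (i, j)] = w
    planted = (n_layers - 1 - layers).astype(float)
    return GroundTruthNetwork(coupling=C, planted_levels=planted, layer_assignment=layers)


def simulate_hopf_bold(
    coupling: np.ndarray,
    a=-0.02,
    omega=2 * np.pi * 0.05,
    sigma: float = 0.01,
    n_timepoints: int = 197,
    tr_seconds: float = 3.0,
    dt: float = 0.1,
    burn_in_seconds: float = 60.0,
    seed: int | None = None,
    linear: bool = False,
) -> np.ndarray:
    """Euler-Maruyama simulation of coupled Stuart-Landau oscillators.

    Integrates ``dz_j = (a_j + i w_j) z_j - |z_j|^2 z_j
    + sum_m C[m, j] (z_m - z_j) dt + sigma dW`` from ``z(0) = 0``, discards
    ``burn_in_seconds`` of transient and records the real part every TR.
    With ``linear=True`` the cubic term is dropped (the Ornstein-Uhlenbeck
    regime the analytic covariances describe).

    Returns a ``n_regions x n_timepoints`` array.  Raises if the trajectory
    diverges (``dt`` too large or ``a >= 0`` misuse).
    """
    C = np.asarray(coupling, dtype=float)
    n = C.shape[0]
    if dt > tr_seconds / 10:
        raise ValueError("dt must be at most TR/10")
    a = np.broadcast_to(np.asarray(a, float), (n,))
    omega = np.broadcast_to(np.asarray(omega, float), (n,))
    if np.any(a >= 0):
        raise ValueError("a must be negative (noisy fixed-point regime)")
    rng = np.random.default_rng(seed)

    in_strength = C.sum(axis=0)  # total input to each region
    steps_per_tr = int(round(tr_seconds / dt))
    n_burn = int(round(burn_in_seconds / dt))
    total_steps = n_burn + n_timepoints * steps_per_tr
    sq_dt = np.sqrt(dt)

    x = np.zeros(n)
    y = np.zeros(n)
    out = np.empty((n, n_timepoints))
    rec = 0
    for step in range(1, total_steps + 1):
        if linear:
            gx = a * x
            gy = a * y
        else:
            r2 = x * x + y * y
            gx = (a - r2) * x
            gy = (a - r2) * y
        cx = C.T @ x - in_strength * x
        cy = C.T @ y - in_strength * y
        noise = rng.standard_normal((2, n))
        x_new = x + dt * (gx - omega * y + cx) + sigma * sq_dt * noise[0]
        y_new = y + dt * (gy + omega * x + cy) + sigma * sq_dt * noise[1]
        x, y = x_new, y_new
        if step > n_burn and (step - n_burn) % steps_per_tr == 0:
            out[:, rec] = x
            rec += 1
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("trajectory diverged; reduce dt or check that a < 0")
    return out


def simulate_linear_sde(
    J: np.ndarray,
    sigma: float,
    n_steps: int,
    dt: float,
    n_replicas: int = 1,
    burn_in_steps: int = 0,
    seed: int | None = None,
) -> np.ndarray:
    """Euler-Maruyama trajectories of ``dx = J x dt + sigma dW``.

    Brute-force oracle for the analytic covariance machinery: integrates
    ``n_replicas`` independent trajectories in parallel and returns an array
    of shape ``(n_replicas, dim, n_steps)`` (burn-in discarded).
    """
    J = np.asarray(J, dtype=float)
    dim = J.shape[0]
    rng = np.random.default_rng(seed)
    x = np.zeros((dim, n_replicas))
    sq_dt = np.sqrt(dt)
    out = np.empty((n_replicas, dim, n_steps))
    for step in range(burn_in_steps + n_steps):
        x = x + dt * (J @ x) + sigma * sq_dt * rng.standard_normal((dim, n_replicas))
        if step >= burn_in_steps:
            out[:, :, step - burn_in_steps] = x.T
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("linear SDE trajectory diverged; reduce dt")
    return out


@dataclass
class SiteEffects:
    """Planted ground-truth site effects: ``x -> gamma + delta * x``."""

    gamma: pd.DataFrame  # sites x features, additive
    delta: pd.DataFrame  # sites x features, multiplicative


def plant_site_effects(
    feature_table: pd.DataFrame,
    site_labels,
    shift_sd: float,
    scale_range: tuple[float, float],
    seed: int | None = None,
) -> tuple[pd.DataFrame, SiteEffects]:
    """Inject additive and multiplicative site effects into a feature table.

    Per site *i* and feature *v*, values become ``gamma_iv + delta_iv * x``
    with ``gamma ~ Normal(0, shift_sd)`` and ``delta ~ Uniform(scale_range)``.
    The drawn ground truth is returned for recovery tests.
    """
    lo, hi = scale_range
    if lo <= 0 or hi < lo:
        raise ValueError("scale_range must be positive and ordered (exclude 0)")
    site = pd.Series(site_labels, index=feature_table.index)
    sites = sorted(site.unique())
    rng = np.random.default_rng(seed)
    gamma = pd.DataFrame(
        rng.normal(0.0, shift_sd, (len(sites), feature_table.shape[1])),
        index=sites, columns=feature_table.columns,
    )
    delta = pd.DataFrame(
        rng.uniform(lo, hi, (len(sites), feature_table.shape[1])),
        index=sites, columns=feature_table.columns,
    )
    out = feature_table.mul(delta.loc[site].to_numpy(), axis=0) \
        + gamma.loc[site].to_numpy()
    return out, SiteEffects(gamma=gamma, delta=delta)


@dataclass
class CohortConfig:
    """Conditions of the emulated multi-site cohort.

    Defaults emulate the full study geometry (80 regions, 197 volumes at
    TR = 3 s, four amyloid-stratified groups of 46/36/31/21); tests and the
    worked examples scale ``n_regions`` and the group sizes down.
    """

    n_regions: int = 80
    n_subjects_per_group: tuple[int, int, int, int] = (46, 36, 31, 21)
    n_sites: int = 6
    flattening_per_group: tuple[float, float, float, float] = (0.0, 0.2, 0.4, 0.7)
    tr_seconds: float = 3.0
    n_timepoints: int = 197
    noise_sd: float = 0.05  # multiplicative jitter on subject coupling edges
    seed: int = 0
    # Hopf simulation regime
    a: float = -0.02
    omega_band_hz: tuple[float, float] = (0.01, 0.08)
    sigma: float = 0.01
    dt: float = 0.1
    # network geometry
    n_layers: int = 4
    feedforward_weight: float = 0.12
    feedback_weight: float = 0.03
    density: float = 0.6
    # linear couplings of biomarkers / cognition to the hierarchy deficit
    biomarker_effect_sizes: dict = field(default_factory=lambda: dict(
        amyloid=1.2, tau=0.8, gmv=0.4, cognition=1.0))
    biomarker_noise_sd: float = 0.05
    site_shift_sd: float = 0.1
    site_scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if len(self.n_subjects_per_group) != 4 or len(self.flattening_per_group) != 4:
            raise ValueError("expect exactly 4 groups")
        if any(not 0 <= f <= 1 for f in self.flattening_per_group):
            raise ValueError("flattening must be in [0, 1]")
        if min(self.n_subjects_per_group) < 1:
            raise ValueError("every group must have at least one subject")
        if self.n_timepoints < 150:
            raise ValueError("n_timepoints must be >= 150 (inclusion rule)")


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the generative ground truth."""

    timeseries: dict  # subject -> regions x timepoints
    metadata: pd.DataFrame  # group, age, gender, education, site, apoe
    biomarkers: dict  # modality -> subjects x regions DataFrame
    cognition: pd.DataFrame
    couplings: dict  # subject -> ground-truth coupling used for simulation
    truth: dict  # network, per-subject directedness, site effects, slopes
    config: CohortConfig
    region_ids: list
    network_mapping: pd.Series  # region -> functional network

    @property
    def subjects(self) -> list:
        return list(self.metadata.index)

    def save(self, out_dir) -> None:
        """Write the cohort as delimited text (one TSV per table/subject)."""
        out = Path(out_dir)
        (out / "timeseries").mkdir(parents=True, exist_ok=True)
        (out / "coupling_true").mkdir(exist_ok=True)
        for s, ts in self.timeseries.items():
            pd.DataFrame(ts.T, columns=self.region_ids).to_csv(
                out / "timeseries" / f"{s}.tsv", sep="\t", index=False)
        for s, c in self.couplings.items():
            pd.DataFrame(c, index=self.region_ids, columns=self.region_ids).to_csv(
                out / "coupling_true" / f"{s}.tsv", sep="\t")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t")
        for modality, table in self.biomarkers.items():
            table.to_csv(out / f"biomarkers_{modality}.tsv", sep="\t")
        self.cognition.to_csv(out / "cognition.tsv", sep="\t")
        self.network_mapping.rename("network").to_csv(out / "network_mapping.tsv", sep="\t")
        cfg = asdict(self.config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=list))


_NETWORKS = ("VN", "SMN", "DAN", "SAN", "LN", "CN", "DMN")


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate the full multi-site cohort from a single ground-truth network.

    Per group *g* with flattening ``lam_g``, subject couplings are
    ``(1 - lam_g) C + lam_g (C + C.T)/2`` with multiplicative edge jitter of
    s.d. ``noise_sd``; BOLD is simulated per subject from its coupling;
    biomarkers and cognition are linear in each subject's hierarchy deficit
    ``directedness(C_true) - directedness(C_subject)`` plus Gaussian noise;
    site effects are injected into the biomarker tables and their ground
    truth stored.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    net = generate_hierarchical_coupling(
        cfg.n_regions, cfg.n_layers, cfg.feedforward_weight,
        cfg.feedback_weight, cfg.density,
        seed=int(rng.integers(2**31)),
    )
    C = net.coupling
    C_sym = 0.5 * (C + C.T)
    d_ref = directedness(C)
    region_ids = [f"R{i:03d}" for i in range(cfg.n_regions)]
    network_mapping = pd.Series(
        [_NETWORKS[i % len(_NETWORKS)] for i in range(cfg.n_regions)],
        index=region_ids, name="network",
    )
    omega = 2 * np.pi * rng.uniform(*cfg.omega_band_hz, size=cfg.n_regions)

    timeseries, couplings, meta_rows, deficits = {}, {}, [], {}
    for g, (group, n_sub) in enumerate(zip(GROUPS, cfg.n_subjects_per_group)):
        lam = cfg.flattening_per_group[g]
        C_g = (1 - lam) * C + lam * C_sym
        demo = _DEMOGRAPHICS[group]
        for k in range(n_sub):
            subject = f"sub-{group.replace('+', 'p').replace('-', 'n')}{k:03d}"
            jitter = 1.0 + cfg.noise_sd * rng.standard_normal(C.shape)
            C_s = np.clip(C_g * jitter, 0.0, None)
            np.fill_diagonal(C_s, 0.0)
            couplings[subject] = C_s
            deficits[subject] = d_ref - directedness(C_s)
            timeseries[subject] = simulate_hopf_bold(
                C_s, a=cfg.a, omega=omega, sigma=cfg.sigma,
                n_timepoints=cfg.n_timepoints, tr_seconds=cfg.tr_seconds,
                dt=cfg.dt, seed=int(rng.integers(2**31)),
            )
            meta_rows.append(dict(
                subject=subject,
                group=group,
                age=rng.normal(*demo["age"]),
                gender="F" if rng.random() < demo["p_female"] else "M",
                education=rng.normal(*demo["edu"]),
                site=f"site{int(rng.integers(cfg.n_sites)):02d}",
                apoe4=int(rng.random() < demo["p_apoe"]),
            ))
    metadata = pd.DataFrame(meta_rows).set_index("subject")
    deficit = pd.Series(deficits).loc[metadata.index]

    eff = cfg.biomarker_effect_sizes
    n_sub_total = len(metadata)
    # fixed regional loading patterns (which regions carry the pathology)
    load_amy = rng.uniform(0.5, 1.5, cfg.n_regions)
    load_tau = rng.uniform(0.5, 1.5, cfg.n_regions)
    vol = rng.uniform(0.8, 1.2, cfg.n_regions)
    noise = cfg.biomarker_noise_sd

    def regional(base, slope, load, age_slope=0.0, scale=1.0):
        x = base + slope * np.outer(deficit.to_numpy(), load)
        x = x + age_slope * np.outer(metadata["age"].to_numpy() - 72.0, load)
        x = x * scale + noise * scale * rng.standard_normal((n_sub_total, cfg.n_regions))
        return pd.DataFrame(x, index=metadata.index, columns=region_ids)

    amyloid = regional(1.05, eff["amyloid"], load_amy)
    tau = regional(1.10, eff["tau"], load_tau)
    gmv = pd.DataFrame(
        5000 * vol * (1 - eff["gmv"] * deficit.to_numpy()[:, None])
        - 15.0 * (metadata["age"].to_numpy() - 72.0)[:, None] * vol
        + 5000 * noise * rng.standard_normal((n_sub_total, cfg.n_regions)),
        index=metadata.index, columns=region_ids,
    )
    site_truth = {}
    amyloid, site_truth["amyloid"] = plant_site_effects(
        amyloid, metadata["site"], cfg.site_shift_sd, cfg.site_scale_range,
        seed=int(rng.integers(2**31)))
    tau, site_truth["tau"] = plant_site_effects(
        tau, metadata["site"], cfg.site_shift_sd, cfg.site_scale_range,
        seed=int(rng.integers(2**31)))
    gmv, site_truth["gmv"] = plant_site_effects(
        gmv, metadata["site"], cfg.site_shift_sd * 100, cfg.site_scale_range,
        seed=int(rng.integers(2**31)))

    c = eff["cognition"]
    z = deficit.to_numpy()
    cognition = pd.DataFrame(dict(
        mmse=np.clip(29 - 25 * c * z + rng.normal(0, 1.0, n_sub_total), 0, 30),
        adas13=np.clip(10 + 60 * c * z + rng.normal(0, 3.0, n_sub_total), 0, 85),
        cdr_sb=np.clip(12 * c * z + rng.normal(0, 0.5, n_sub_total), 0, 18),
        moca=np.clip(28 - 25 * c * z + rng.normal(0, 1.2, n_sub_total), 0, 30),
    ), index=metadata.index)

    truth = dict(
        network=net,
        reference_directedness=d_ref,
        deficit=deficit,
        site_effects=site_truth,
        slopes=dict(amyloid=eff["amyloid"], tau=eff["tau"], gmv=eff["gmv"],
                    cognition=eff["cognition"]),
        planted_levels=pd.Series(net.planted_levels, index=region_ids),
        omega=omega,
    )
    return CohortBundle(
        timeseries=timeseries, metadata=metadata,
        biomarkers=dict(amyloid=amyloid, tau=tau, gmv=gmv),
        cognition=cognition, couplings=couplings, truth=truth,
        config=cfg, region_ids=region_ids, network_mapping=network_mapping,
    )
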