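"""Multi-site ComBat harmonization of regional / network measures.

Implements the canonical parametric empirical-Bayes ComBat model

    y_ijv = alpha_v + X_ij beta_v + gamma_iv + delta_iv eps_ijv

(site *i*, subject *j*, feature *v*): per-feature location/scale site
effects are estimated on covariate-adjusted, variance-standardised data,
shrunk toward site-level priors (normal prior on the additive effect,
inverse-gamma on the squared multiplicative effect), and removed while the
modelled biological covariate effects are reintroduced:

    y_combat = (y - alpha - X beta - gamma*) / delta* + alpha + X beta.

Subjects whose site contains no other subject carry no information about a
site distribution and are excluded up front.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "filter_unique_sites",
    "build_covariates",
    "fit_combat",
    "apply_combat",
    "check_harmonization",
    "CombatModel",
]


def filter_unique_sites(table: pd.DataFrame, site_col: str = "site"):
    """Drop subjects whose site has exactly one subject.

    Returns ``(kept_table, excluded_index)``.
    """
    if site_col not in table.columns:
        raise ValueError(f"no '{site_col}' column in the table")
    counts = table[site_col].value_counts()
    lonely = counts[counts == 1].index
    excluded = table.index[table[site_col].isin(lonely)]
    kept = table.drop(index=excluded)
    if kept.empty:
        raise ValueError("all sites are unique; nothing left to harmonize")
    return kept, excluded


def build_covariates(metadata: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric covariate design from a metadata table.

    Categorical columns (gender, diagnosis, ...) are one-hot encoded with
    the first level dropped; numeric columns pass through.
    """
    parts = []
    for col in columns:
        s = metadata[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float).to_frame(col))
        else:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


@dataclass
class CombatModel:
    """Fitted ComBat parameters (site effects on the standardised scale)."""

    alpha: np.ndarray  # per-feature grand mean
    beta: np.ndarray  # covariates x features
    sigma: np.ndarray  # per-feature pooled residual s.d.
    gamma_star: pd.DataFrame  # sites x features (EB additive)
    delta_star: pd.DataFrame  # sites x features (EB multiplicative, > 0)
    covariate_columns: list = field(default_factory=list)
    feature_columns: list = field(default_factory=list)


def _eb_site(z_site: np.ndarray, gamma_bar, tau2, lam, theta, tol=1e-6, max_iter=200):
    """Iterative parametric EB estimates for one site (standardised data)."""
    n = z_site.shape[0]
    gamma_hat = z_site.mean(axis=0)
    g_star = gamma_hat.copy()
    d_star = z_site.var(axis=0, ddof=1) if n > 1 else np.ones_like(gamma_hat)
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d_star * gamma_bar) / (n * tau2 + d_star)
        ss = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (theta + 0.5 * ss) / (n / 2.0 + lam - 1.0)
        if np.max(np.abs(g_new - g_star)) < tol and np.max(np.abs(d_new - d_star)) < tol:
            g_star, d_star = g_new, d_new
            break
        g_star, d_star = g_new, d_new
    return g_star, d_star


def fit_combat(Y: pd.DataFrame, site, covariates: pd.DataFrame | None = None) -> CombatModel:
    """Fit the parametric-EB ComBat model on subjects x features data.

    Requires every site to contribute at least two subjects (apply
    :func:`filter_unique_sites` first) and at least two sites overall.
    Zero-variance features are rejected.
    """
    Y = Y.astype(float)
    site = pd.Series(site, index=Y.index).astype(str)
    levels = sorted(site.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 sites to harmonize")
    counts = site.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise ValueError(f"site(s) with a single subject must be excluded first: {bad}")
    if (Y.std(ddof=0) == 0).any():
        raise ValueError("zero-variance feature(s) present")

    n, V = Y.shape
    D = pd.get_dummies(site, dtype=float)[levels].to_numpy()
    if covariates is not None:
        X_cov = covariates.loc[Y.index].to_numpy(dtype=float)
        if np.linalg.matrix_rank(X_cov) < X_cov.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        design = np.hstack([D, X_cov])
    else:
        X_cov = np.zeros((n, 0))
        design = D
    B = np.linalg.lstsq(design, Y.to_numpy(), rcond=None)[0]
    gamma_hat_raw = B[: len(levels)]  # sites x features, on the raw scale
    beta = B[len(levels):]
    frac = (counts[levels] / n).to_numpy()[:, None]
    alpha = (frac * gamma_hat_raw).sum(axis=0)
    resid = Y.to_numpy() - design @ B
    sigma = np.sqrt((resid**2).mean(axis=0))
    sigma = np.where(sigma > 0, sigma, 1.0)

    Z = (Y.to_numpy() - alpha - X_cov @ beta) / sigma

    g_rows, d_rows = [], []
    for i, lev in enumerate(levels):
        idx = (site == lev).to_numpy()
        z_site = Z[idx]
        gamma_hat = z_site.mean(axis=0)
        delta_hat = z_site.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if V > 1 else 1.0
        tau2 = max(tau2, 1e-12)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1) if V > 1 else 1.0
        s2 = max(s2, 1e-12)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        g_star, d2_star = _eb_site(z_site, gamma_bar, tau2, lam, theta)
        g_rows.append(g_star)
        d_rows.append(np.sqrt(np.clip(d2_star, 1e-12, None)))
    gamma_star = pd.DataFrame(g_rows, index=levels, columns=Y.columns)
    delta_star = pd.DataFrame(d_rows, index=levels, columns=Y.columns)

    return CombatModel(
        alpha=alpha, beta=beta, sigma=sigma,
        gamma_star=gamma_star, delta_star=delta_star,
        covariate_columns=list(covariates.columns) if covariates is not None else [],
        feature_columns=list(Y.columns),
    )


def apply_combat(model: CombatModel, Y: pd.DataFrame, site,
                 covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Harmonize data with a fitted model (sites must have been seen)."""
    Y = Y[model.feature_columns].astype(float)
    site = pd.Series(site, index=Y.index).astype(str)
    unseen = set(site.unique()) - set(model.gamma_star.index)
    if unseen:
        raise ValueError(f"site(s) not present at fit time: {sorted(unseen)}")
    if model.covariate_columns:
        if covariates is None:
            raise ValueError("model was fitted with covariates; provide them")
        X_cov = covariates.loc[Y.index, model.covariate_columns].to_numpy(dtype=float)
    else:
        X_cov = np.zeros((len(Y), 0))
    fitted = model.alpha + X_cov @ model.beta
    Z = (Y.to_numpy() - fitted) / model.sigma
    g = model.gamma_star.loc[site].to_numpy()
    d = model.delta_star.loc[site].to_numpy()
    adj = (Z - g) / d
    return pd.DataFrame(adj * model.sigma + fitted, index=Y.index, columns=Y.columns)


def harmonize(Y: pd.DataFrame, metadata: pd.DataFrame,
              covariate_cols=("age", "gender", "education", "group"),
              site_col: str = "site"):
    """One-call harmonization: unique-site filter, fit, apply.

    Returns ``(Y_harmonized, model, excluded_subjects)``; the harmonized
    table only contains the subjects that survived the unique-site filter.
    """
    kept_meta, excluded = filter_unique_sites(metadata, site_col)
    Yk = Y.loc[kept_meta.index]
    # constant features (e.g. the min-shifted bottom of the hierarchy) carry
    # no site information and pass through unchanged
    constant = Yk.columns[Yk.std(ddof=0) == 0]
    if len(constant):
        warnings.warn(f"{len(constant)} constant feature(s) passed through "
                      "unharmonized", stacklevel=2)
    variable = [c for c in Yk.columns if c not in set(constant)]
    cov = build_covariates(kept_meta, [c for c in covariate_cols if c in kept_meta])
    model = fit_combat(Yk[variable], kept_meta[site_col], cov)
    harmonized = apply_combat(model, Yk[variable], kept_meta[site_col], cov)
    out = Yk.copy()
    out[variable] = harmonized
    return out, model, excluded


def _perm_anova_p(values: np.ndarray, labels: np.ndarray, n_perm: int,
                  rng: np.random.Generator) -> float:
    """Permutation p-value of the one-way ANOVA F statistic."""
    def fstat(y, lab):
        groups = [y[lab == g] for g in np.unique(lab)]
        grand = y.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb = len(groups) - 1
        dfw = len(y) - len(groups)
        if dfb == 0 or dfw == 0 or ssw == 0:
            return 0.0
        return (ssb / dfb) / (ssw / dfw)

    obs = fstat(values, labels)
    hits = 1
    for _ in range(n_perm):
        if fstat(values, rng.permutation(labels)) >= obs:
            hits += 1
    return hits / (n_perm + 1)


def check_harmonization(Y_pre: pd.DataFrame, Y_post: pd.DataFrame,
                        site, group, age=None, n_perm: int = 499,
                        seed: int | None = None, q: float = 0.05) -> dict:
    """The two validation checks of a harmonization run.

    (1) within-group site effects: per-(feature, group) permutation-ANOVA
    p-values before and after harmonization; pass requires no
    post-harmonization site effect surviving BH-FDR at ``q``.
    (2) the age slope of each feature keeps its sign (biology preserved);
    evaluated on the feature-mean if ``age`` is given.
    """
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    site = pd.Series(site, index=Y_pre.index).astype(str)
    group = pd.Series(group, index=Y_pre.index)
    rows = []
    for g in group.unique():
        idx = group[group == g].index
        labs = site.loc[idx].to_numpy()
        if len(np.unique(labs)) < 2:
            continue
        for col in Y_pre.columns:
            rows.append(dict(
                feature=col, group=g,
                p_pre=_perm_anova_p(Y_pre.loc[idx, col].to_numpy(), labs, n_perm, rng),
                p_post=_perm_anova_p(Y_post.loc[idx, col].to_numpy(), labs, n_perm, rng),
            ))
    table = pd.DataFrame(rows)
    rejected_post = multipletests(table["p_post"], alpha=q, method="fdr_bh")[0]
    report = dict(
        site_effect_table=table,
        n_site_effects_pre=int((table["p_pre"] < 0.05).sum()),
        n_site_effects_post_fdr=int(rejected_post.sum()),
        site_effects_removed=not rejected_post.any(),
    )
    if age is not None:
        age = pd.Series(age, index=Y_pre.index).astype(float)
        slope_pre = np.polyfit(age, Y_pre.mean(axis=1), 1)[0]
        slope_post = np.polyfit(age, Y_post.mean(axis=1), 1)[0]
        report.update(age_slope_pre=float(slope_pre), age_slope_post=float(slope_post),
                      age_slope_sign_preserved=bool(np.sign(slope_pre) == np.sign(slope_post)))
    report["passed"] = report["site_effects_removed"] and report.get(
        "age_slope_sign_preserved", True)
    if not report["passed"]:
        warnings.warn("harmonization quality checks failed", stacklevel=2)
    return report
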