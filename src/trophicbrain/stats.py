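"""Inferential stages: covariate-adjusted permutation tests, FDR,
mixed-effects ridge regression, and cognition regressions.

Group contrasts use the Freedman-Lane scheme: the outcome is regressed on
the covariates alone, the residuals are permuted and added back to the
reduced-model fit, and the group coefficient's t statistic is recomputed on
each permuted outcome — respecting exchangeability under the null while
adjusting for age, gender and education.  Biomarker-to-hierarchy links are
fitted by ridge regression with an (unpenalised) random intercept per
subject, estimated by backfitting between a penalised fixed-effect solve
and a closed-form shrunken subject-intercept update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationTestResult",
    "permutation_group_test",
    "fdr_bh",
    "RidgeMixedResult",
    "ridge_mixed_fit",
    "cognition_regression",
]


@dataclass
class PermutationTestResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    coefficient: float = np.nan
    covariate_spec: list = field(default_factory=list)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residual of each column of M after OLS on Z (with intercept)."""
    beta = np.linalg.lstsq(Z, M, rcond=None)[0]
    return M - Z @ beta


def permutation_group_test(
    y, groups, covariates: pd.DataFrame | None = None,
    n_perm: int = 10_000, seed: int | None = None,
) -> PermutationTestResult:
    """Two-sided covariate-adjusted permutation test of a 2-group contrast.

    The statistic is the t value of the group indicator in the OLS of ``y``
    on [intercept, covariates, group]; the null distribution comes from
    Freedman-Lane residual permutation.  ``p`` is bounded below by
    ``1/(n_perm + 1)``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {list(levels)}")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value",
                      stacklevel=2)
    n = y.size
    g = (groups == levels[1]).astype(float)
    if covariates is not None:
        X_cov = np.asarray(covariates, dtype=float)
        if np.linalg.matrix_rank(X_cov) < X_cov.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        Z = np.column_stack([np.ones(n), X_cov])
    else:
        Z = np.ones((n, 1))
    cov_names = list(covariates.columns) if isinstance(covariates, pd.DataFrame) else []

    if np.all(y == y[0]):
        return PermutationTestResult(0.0, 1.0, n_perm, 0.0, cov_names)

    df = n - Z.shape[1] - 1
    if df < 1:
        raise ValueError("not enough observations for the model")

    g_t = _residualize(g[:, None], Z)[:, 0]
    g_ss = float(g_t @ g_t)
    if g_ss == 0:
        raise ValueError("group indicator collinear with covariates")

    def tstats(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Y_t = _residualize(Y, Z)
        beta = (g_t @ Y_t) / g_ss
        rss = (Y_t**2).sum(axis=0) - beta**2 * g_ss
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / df / g_ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        return t, beta

    t_obs, beta_obs = tstats(y[:, None])
    # Freedman-Lane: permute reduced-model residuals, add back fitted values
    fitted_red = y - _residualize(y[:, None], Z)[:, 0]
    resid_red = y - fitted_red
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n, n_perm)), axis=0)
    Y_perm = fitted_red[:, None] + resid_red[perm_idx]
    t_perm, _ = tstats(Y_perm)
    p = (1 + np.sum(np.abs(t_perm) >= np.abs(t_obs[0]))) / (n_perm + 1)
    return PermutationTestResult(
        observed_stat=float(t_obs[0]), p_value=float(p),
        n_permutations=n_perm, coefficient=float(beta_obs[0]),
        covariate_spec=cov_names,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR; returns (rejected, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rejected, p_adj


@dataclass
class RidgeMixedResult:
    """Penalised fixed effects with a random subject intercept."""

    betas: pd.Series
    permutation_p: pd.Series
    penalty: float
    random_intercept_variance: float
    residual_variance: float
    intercepts: pd.Series = field(repr=False, default=None)

    def summary(self) -> str:
        lines = ["Mixed-effects ridge regression", "-" * 42,
                 f"penalty (lambda)        : {self.penalty:g}",
                 f"random-intercept var    : {self.random_intercept_variance:.4g}",
                 f"residual var            : {self.residual_variance:.4g}"]
        for name, b in self.betas.items():
            p = self.permutation_p.get(name, np.nan)
            tag = f"  p_perm = {p:.4g}" if np.isfinite(p) else ""
            lines.append(f"  {name:<16} beta = {b:+.4f}{tag}")
        return "\n".join(lines)


def _ridge_backfit(X: np.ndarray, y: np.ndarray, subj_codes: np.ndarray,
                   lam: float, tol: float = 1e-8, max_iter: int = 500):
    """Alternate a ridge fixed-effect solve with a shrunken per-subject
    intercept update (intercept column unpenalised)."""
    n, p = X.shape
    n_subj = subj_codes.max() + 1
    counts = np.bincount(subj_codes, minlength=n_subj).astype(float)
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0  # intercept unpenalised
    XtX = X.T @ X + pen
    b = np.zeros(n_subj)
    beta = np.zeros(p)
    tau2 = sig2 = 1.0
    for _ in range(max_iter):
        beta_new = np.linalg.solve(XtX, X.T @ (y - b[subj_codes]))
        resid = y - X @ beta_new
        means = np.bincount(subj_codes, weights=resid, minlength=n_subj) / counts
        # variance components by moments, then BLUP shrinkage
        within = resid - means[subj_codes]
        sig2 = float((within**2).sum() / max(n - n_subj, 1))
        tau2 = max(float(np.var(means, ddof=1) - sig2 / counts.mean()), 0.0)
        shrink = (counts * tau2) / (counts * tau2 + sig2) if tau2 > 0 else np.zeros(n_subj)
        b_new = shrink * means
        delta = max(np.max(np.abs(beta_new - beta)), np.max(np.abs(b_new - b)))
        beta, b = beta_new, b_new
        if delta < tol:
            break
    return beta, b, tau2, sig2


def ridge_mixed_fit(
    long_table: pd.DataFrame,
    outcome: str,
    predictors,
    covariates=(),
    subject_col: str = "subject",
    penalty: float | None = None,
    n_perm: int = 500,
    seed: int | None = None,
    permute: tuple[str, ...] | None = None,
) -> RidgeMixedResult:
    """Ridge regression of a long (subject x unit) table with a random
    subject intercept.

    Continuous predictors and covariates are standardised internally (the
    outcome as well, so betas are on the standardised scale).  ``penalty``
    is chosen by generalized cross-validation over a log grid when not
    given.  Per-coefficient permutation p-values are obtained by permuting
    that predictor within subject and refitting.
    """
    cols = list(predictors) + list(covariates)
    df = long_table.dropna(subset=[outcome, subject_col, *cols]).copy()
    subj, _ = pd.factorize(df[subject_col])
    y = df[outcome].to_numpy(dtype=float)
    y = (y - y.mean()) / y.std(ddof=0)

    X_parts = [np.ones(len(df))]
    names = ["const"]
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"constant predictor {c!r}")
        if set(np.unique(v)).issubset({0.0, 1.0}):
            X_parts.append(v)  # binary indicators left on their natural scale
        else:
            X_parts.append((v - v.mean()) / sd)
        names.append(c)
    X = np.column_stack(X_parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix singular after standardisation")

    if penalty is None:
        grid = np.logspace(-3, 3, 13)
        best = (np.inf, grid[0])
        for lam in grid:
            beta, b, _, _ = _ridge_backfit(X, y, subj, lam)
            resid = y - X @ beta - b[subj]
            pen = lam * np.eye(X.shape[1]); pen[0, 0] = 0.0
            H_trace = np.trace(np.linalg.solve(X.T @ X + pen, X.T @ X))
            gcv = (resid**2).mean() / (1 - H_trace / len(y)) ** 2
            if gcv < best[0]:
                best = (gcv, lam)
        penalty = best[1]

    beta, b, tau2, sig2 = _ridge_backfit(X, y, subj, penalty)
    betas = pd.Series(beta[1:], index=names[1:])

    rng = np.random.default_rng(seed)
    targets = list(permute) if permute is not None else list(predictors)
    pvals = {}
    for name in targets:
        j = names.index(name)
        obs = abs(beta[j])
        hits = 1
        Xp = X.copy()
        col = X[:, j].copy()
        order = np.arange(len(y))
        groups = [np.flatnonzero(subj == s) for s in range(subj.max() + 1)]
        for _ in range(n_perm):
            for idx in groups:  # permute within subject
                order[idx] = rng.permutation(idx)
            Xp[:, j] = col[order]
            beta_p, _, _, _ = _ridge_backfit(Xp, y, subj, penalty, tol=1e-6,
                                             max_iter=100)
            if abs(beta_p[j]) >= obs:
                hits += 1
        pvals[name] = hits / (n_perm + 1)
    return RidgeMixedResult(
        betas=betas, permutation_p=pd.Series(pvals, dtype=float),
        penalty=float(penalty), random_intercept_variance=tau2,
        residual_variance=sig2,
        intercepts=pd.Series(b, index=pd.unique(df[subject_col])),
    )


def cognition_regression(
    scores: pd.DataFrame,
    network_levels: pd.DataFrame,
    covariates: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Multiple linear regressions of each score on each network level.

    One OLS per (score, network) pair with the covariates included;
    BH-FDR across the whole family.  Complete cases only (dropped rows are
    counted in the output attributes).
    """
    import statsmodels.api as sm

    rows = []
    for score in scores.columns:
        for net in network_levels.columns:
            df = pd.concat(
                [scores[score], network_levels[net], covariates], axis=1
            ).dropna()
            if len(df) <= covariates.shape[1] + 2:
                raise ValueError(
                    f"not enough complete cases for {score} ~ {net}")
            y = df[score].astype(float)
            X = sm.add_constant(df.drop(columns=[score]).astype(float))
            fit = sm.OLS(y, X).fit()
            rows.append(dict(
                score=score, network=net,
                beta=float(fit.params[net]), p=float(fit.pvalues[net]),
                n=int(len(df)),
            ))
    out = pd.DataFrame(rows)
    out["rejected"], out["p_fdr"] = fdr_bh(out["p"], q=q)
    return out
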