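"""Binary disease-staging classifier on hierarchy features.

Logistic regression over mRMR-selected features, tuned by a nested
leave-one-out grid search (number of features NF, inverse regularisation C,
L1/L2 penalty), evaluated over stratified 75/25 Monte Carlo splits with a
Youden-threshold decision rule, test-label permutation significance,
vertically averaged ROC curves, averaged confusion proportions, and exact
linear-model SHAP feature importances (unselected features scored 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "mrmr_select",
    "loocv_grid_search",
    "youden_threshold",
    "monte_carlo_evaluate",
    "linear_shap",
]

_PERFECT_CORR = 1.0 - 1e-12


@dataclass
class ClassifierConfig:
    """Staging-pipeline hyperparameters (grids follow the study protocol)."""

    nf_grid: tuple = tuple(range(5, 16))
    c_grid: tuple = (0.01, 0.1, 1, 5, 10, 50, 100, 500, 1000)
    penalty_grid: tuple = ("l1", "l2")
    n_monte_carlo: int = 20
    train_fraction: float = 0.75
    n_label_perms: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (self.nf_grid and self.c_grid and self.penalty_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy mRMR (FCQ variant) feature selection.

    Relevance = class-wise ANOVA F statistic; redundancy = mean absolute
    Pearson correlation with the already-selected set; the next feature
    maximises relevance / redundancy.  A candidate perfectly correlated
    with a selected feature carries infinite redundancy and is only taken
    when nothing else remains; constant features are never selectable.
    Both ingredients are scale invariant.
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    usable = np.flatnonzero(X.std(axis=0) > 0)
    if k > usable.size:
        raise ValueError(f"cannot select {k} of {usable.size} non-constant "
                         f"features ({n_features} total)")
    with np.errstate(divide="ignore", invalid="ignore"):
        relevance, _ = f_classif(X, y)
        relevance = np.nan_to_num(relevance, nan=0.0)
        corr = np.abs(np.nan_to_num(np.corrcoef(X, rowvar=False), nan=1.0))

    rel_usable = np.where(np.isin(np.arange(n_features), usable),
                          relevance, -np.inf)
    selected = [int(np.argmax(rel_usable))]
    remaining = set(usable.tolist()) - set(selected)
    while len(selected) < k:
        best_j, best_score = None, -np.inf
        dup_j = None
        for j in remaining:
            red = corr[j, selected].mean()
            if corr[j, selected].max() >= _PERFECT_CORR:
                dup_j = j  # effectively a duplicate of a selected feature
                continue
            score = relevance[j] / max(red, 1e-12)
            if score > best_score:
                best_j, best_score = j, score
        if best_j is None:
            best_j = dup_j  # only duplicates left
        selected.append(best_j)
        remaining.discard(best_j)
    return selected


def youden_threshold(probs: np.ndarray, y: np.ndarray) -> float:
    """Probability threshold maximising Youden's J = sens + spec - 1.

    The decision rule is ``predict positive iff P(x) >= threshold``;
    candidates are the observed probabilities, ties resolved toward the
    lowest threshold.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to compute Youden's J")
    pos = y == np.max(y)
    best_t, best_j = None, -np.inf
    for t in np.sort(np.unique(probs)):
        pred = probs >= t
        sens = np.mean(pred[pos])
        spec = np.mean(~pred[~pos])
        j = sens + spec - 1
        if j > best_j:  # strict: earliest (lowest) threshold wins ties
            best_t, best_j = t, j
    return float(best_t)


def _make_clf(C: float, penalty: str) -> LogisticRegression:
    # l1_ratio supersedes the deprecated penalty= keyword
    return LogisticRegression(C=C, l1_ratio=1.0 if penalty == "l1" else 0.0,
                              solver="liblinear", max_iter=2000)


def loocv_grid_search(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig):
    """Nested LOOCV grid search over (NF, C, penalty).

    For each grid cell the out-of-fold probabilities over all leave-one-out
    folds are pooled into a single ROC-AUC (per-fold AUC is undefined for a
    single held-out sample); feature selection is re-run inside every
    training fold so no test information leaks.  Ties break toward the
    smallest NF, then the strongest regularisation (smallest C), then L2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    nf_grid = [nf for nf in cfg.nf_grid if nf <= X.shape[1]]
    if not nf_grid:
        raise ValueError("every NF in the grid exceeds the feature count")
    max_nf = max(nf_grid)

    # per fold: one greedy mRMR ordering reused for every NF prefix
    fold_order = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_order.append(mrmr_select(X[mask], y[mask], max_nf))

    oof = {(nf, C, pen): np.full(n, np.nan)
           for nf in nf_grid for C in cfg.c_grid for pen in cfg.penalty_grid}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            continue  # degenerate fold: leave the cell entry undefined
        order = fold_order[i]
        for nf in nf_grid:
            feats = order[:nf]
            Xtr, Xte = X[np.ix_(mask, feats)], X[i, feats][None, :]
            for C in cfg.c_grid:
                for pen in cfg.penalty_grid:
                    clf = _make_clf(C, pen).fit(Xtr, y[mask])
                    oof[(nf, C, pen)][i] = clf.predict_proba(Xte)[0, 1]

    def tie_key(cell):
        nf, C, pen = cell
        return (nf, C, 0 if pen == "l2" else 1)

    best_cell, best_auc = None, -np.inf
    for cell in sorted(oof, key=tie_key):
        probs = oof[cell]
        ok = ~np.isnan(probs)
        if len(np.unique(y[ok])) < 2:
            continue
        auc = roc_auc_score(y[ok] == classes[1], probs[ok])
        if auc > best_auc:
            best_cell, best_auc = cell, auc
    if best_cell is None:
        raise RuntimeError("no grid cell produced a defined AUC")
    return best_cell, float(best_auc)


def linear_shap(coef: np.ndarray, X: np.ndarray, X_background: np.ndarray) -> np.ndarray:
    """Exact SHAP values of a linear (logit-scale) model under feature
    independence: ``phi_j(x) = w_j (x_j - mean(background_j))``.

    Returns an array of per-sample, per-feature contributions; summing over
    features recovers the logit deviation from the background mean.
    """
    coef = np.asarray(coef, dtype=float).ravel()
    mu = np.asarray(X_background, dtype=float).mean(axis=0)
    return (np.asarray(X, dtype=float) - mu) * coef


@dataclass
class ClassifierReport:
    """Aggregated Monte Carlo staging-classifier evaluation."""

    metrics: pd.DataFrame  # per-iteration metrics
    metrics_mean: pd.Series
    metrics_sd: pd.Series
    permutation_p_median: float
    permutation_p_iqr: tuple
    roc_fpr_grid: np.ndarray = field(repr=False)
    roc_tpr_mean: np.ndarray = field(repr=False)
    confusion_proportions: pd.DataFrame = field(repr=False)
    shap_importance: pd.Series = field(repr=False)
    selected_per_iteration: list = field(repr=False, default_factory=list)
    n_failed_iterations: int = 0
    classes: tuple = ("neg", "pos")

    def summary(self) -> str:
        m, s = self.metrics_mean, self.metrics_sd
        lines = [
            f"Staging classifier ({self.classes[0]} vs {self.classes[1]}, "
            f"{len(self.metrics)} Monte Carlo splits)",
            "-" * 58,
        ]
        for k in ("balanced_accuracy", "roc_auc", "sensitivity", "specificity", "f1"):
            lines.append(f"  {k:<18}: {m[k]:.3f} +/- {s[k]:.3f}")
        lines.append(f"  permutation p     : median {self.permutation_p_median:.4g} "
                     f"(IQR {self.permutation_p_iqr[0]:.4g}-{self.permutation_p_iqr[1]:.4g})")
        lines.append(f"  mean NF selected  : {np.mean([len(s) for s in self.selected_per_iteration]):.2f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_fpr_grid, self.roc_tpr_mean, label="vertical mean ROC")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax


def monte_carlo_evaluate(
    X, y, cfg: ClassifierConfig | None = None, feature_names=None,
) -> ClassifierReport:
    """Full Monte Carlo staging evaluation.

    Per iteration: stratified 75/25 split, inner LOOCV grid search on the
    training split, refit with the chosen cell on the full training split,
    Youden threshold from the training-refit probabilities, evaluation on
    the untouched test split, and a test-label permutation p-value of the
    balanced accuracy.  Failed iterations are logged and excluded.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary contrast required")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    y_bin = (y == classes[1]).astype(int)
    rng = np.random.default_rng(cfg.seed)

    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_monte_carlo, train_size=cfg.train_fraction,
        random_state=int(rng.integers(2**31)),
    )
    fpr_grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    rows, perm_ps, tprs, confusions, shap_rows, selections = [], [], [], [], [], []
    n_failed = 0
    for train_idx, test_idx in splitter.split(X, y_bin):
        try:
            Xtr, ytr = X[train_idx], y_bin[train_idx]
            Xte, yte = X[test_idx], y_bin[test_idx]
            # features constant in the training split are uninformative and
            # keep an importance of exactly zero
            usable = np.flatnonzero(Xtr.std(axis=0) > 0)
            (nf, C, pen), _ = loocv_grid_search(Xtr[:, usable], ytr, cfg)
            feats = usable[mrmr_select(Xtr[:, usable], ytr, nf)]
            clf = _make_clf(C, pen).fit(Xtr[:, feats], ytr)
            thr = youden_threshold(clf.predict_proba(Xtr[:, feats])[:, 1], ytr)
            probs = clf.predict_proba(Xte[:, feats])[:, 1]
            pred = (probs >= thr).astype(int)

            sens = float(np.mean(pred[yte == 1])) if np.any(yte == 1) else np.nan
            spec = float(np.mean(1 - pred[yte == 0])) if np.any(yte == 0) else np.nan
            row = dict(
                balanced_accuracy=balanced_accuracy_score(yte, pred),
                roc_auc=roc_auc_score(yte, probs),
                sensitivity=sens, specificity=spec,
                f1=f1_score(yte, pred, zero_division=0),
                nf=nf, C=C, penalty=pen, threshold=thr,
            )

            obs = row["balanced_accuracy"]
            hits = 1
            for _ in range(cfg.n_label_perms):
                if balanced_accuracy_score(rng.permutation(yte), pred) >= obs:
                    hits += 1
            perm_ps.append(hits / (cfg.n_label_perms + 1))

            fpr, tpr, _ = roc_curve(yte, probs)
            tprs.append(np.interp(fpr_grid, fpr, tpr))

            cm = np.zeros((2, 2))
            for t, p_ in zip(yte, pred):
                cm[t, p_] += 1
            confusions.append(cm / cm.sum(axis=1, keepdims=True))

            phi = np.zeros((len(test_idx), X.shape[1]))
            phi[:, feats] = linear_shap(clf.coef_, Xte[:, feats], Xtr[:, feats])
            shap_rows.append(np.abs(phi).mean(axis=0))
            selections.append([feature_names[j] for j in feats])
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - iteration-level resilience
            n_failed += 1
            warnings.warn(f"Monte Carlo iteration failed and was excluded: {exc}",
                          stacklevel=2)
    if not rows:
        raise RuntimeError("every Monte Carlo iteration failed")

    metrics = pd.DataFrame(rows)
    numeric = metrics[["balanced_accuracy", "roc_auc", "sensitivity",
                       "specificity", "f1"]]
    perm = np.asarray(perm_ps)
    label_names = (str(classes[0]), str(classes[1]))
    return ClassifierReport(
        metrics=metrics,
        metrics_mean=numeric.mean(), metrics_sd=numeric.std(ddof=1),
        permutation_p_median=float(np.median(perm)),
        permutation_p_iqr=(float(np.percentile(perm, 25)),
                           float(np.percentile(perm, 75))),
        roc_fpr_grid=fpr_grid, roc_tpr_mean=np.mean(tprs, axis=0),
        confusion_proportions=pd.DataFrame(
            np.mean(confusions, axis=0),
            index=[f"true_{c}" for c in label_names],
            columns=[f"pred_{c}" for c in label_names]),
        shap_importance=pd.Series(np.mean(shap_rows, axis=0), index=feature_names),
        selected_per_iteration=selections,
        n_failed_iterations=n_failed,
        classes=label_names,
    )
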