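"""Classifier evaluation: stratified CV, AUROC/AUPRC/F1, bootstrap CIs
and DeLong's test for correlated AUROCs.

AUROC is computed in Mann-Whitney form (probability that a random
positive outscores a random negative, ties counting one half) and the
DeLong machinery uses midrank placement values, so both agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from netmediator.io_formats import CASE, ExpressionMatrix

__all__ = [
    "auroc",
    "auprc",
    "f1_score",
    "bootstrap_ci",
    "delong_test",
    "delong_auc_variance",
    "cross_validate",
    "EvalReport",
]

MODEL_KINDS = ("svm", "rf", "adaboost", "gradboost", "extratrees")

# small documented per-model grids, searched inside each training fold only
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"C": [0.1, 1.0, 10.0]},
    "rf": {"max_depth": [None, 5]},
    "adaboost": {"learning_rate": [0.5, 1.0]},
    "gradboost": {"learning_rate": [0.05, 0.1]},
    "extratrees": {"max_depth": [None, 5]},
}


@dataclass
class EvalReport:
    model: str
    auroc: float
    auprc: float
    f1: float
    auroc_ci: tuple[float, float] | None = None
    delong_p: float | None = None


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s, method="average")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision (area under the precision-recall curve)."""
    from sklearn.metrics import average_precision_score

    y = _check_labels(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def f1_score(scores, labels, threshold: float = 0.5) -> float:
    from sklearn.metrics import f1_score as _f1

    y = _check_labels(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float(_f1(y, pred, zero_division=0))


def bootstrap_ci(
    scores,
    labels,
    metric=auroc,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a score metric.

    Resamples (score, label) pairs with replacement; resamples missing a
    class are redrawn.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n = y.size
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        vals[b] = metric(s[idx], y[idx])
    lo = (1.0 - level) / 2.0
    return float(np.quantile(vals, lo)), float(np.quantile(vals, 1.0 - lo))


def _placement_values(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values (V10 for positives, V01 for negatives)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    tz = stats.rankdata(np.concatenate([pos, neg]), method="average")
    tx = stats.rankdata(pos, method="average")
    ty = stats.rankdata(neg, method="average")
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUROC and its DeLong variance estimate."""
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    v10, v01, auc = _placement_values(s, y)
    m, n = v10.size, v01.size
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's two-sided test comparing two correlated AUROCs.

    Scores must be paired on identical samples. Returns (z, p); identical
    scores give (0, 1).
    """
    y = _check_labels(labels)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    va10, va01, auc_a = _placement_values(sa, y)
    vb10, vb01, auc_b = _placement_values(sb, y)
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _make_model(kind: str, seed: int):
    from sklearn.ensemble import (
        AdaBoostClassifier,
        ExtraTreesClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if kind == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)), "svc"
    if kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed), None
    if kind == "adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed), None
    if kind == "gradboost":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed), None
    if kind == "extratrees":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed), None
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def cross_validate(
    expr: ExpressionMatrix,
    genes: list[str] | None,
    model_kind: str,
    folds: int = 5,
    seed: int = 0,
    grid: dict | None = None,
) -> dict:
    """Stratified k-fold CV of a classifier on a fixed gene panel.

    The gene panel is fixed before CV (never tuned on outcome labels);
    hyperparameters are grid-searched inside each training fold. Returns
    out-of-fold scores, fold assignment and summary metrics; positive
    class is "case".
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    if genes is None:
        genes = list(expr.genes)
    missing = [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise ValueError(f"panel genes missing from matrix: {missing[:5]}")
    rows = [expr.gene_index(g) for g in genes]
    X = expr.values[rows].T  # samples x genes
    y = np.array([1 if expr.group_of[s] == CASE else 0 for s in expr.samples])
    if min(np.bincount(y)) < folds:
        raise ValueError("a class would be absent from some fold; reduce folds")

    if grid is None:
        grid = DEFAULT_GRIDS[model_kind]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(y.size, np.nan)
    fold_of = np.full(y.size, -1)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model, prefix = _make_model(model_kind, seed)
        param_grid = {f"{prefix}__{k}" if prefix else k: v for k, v in grid.items()}
        inner = min(3, int(min(np.bincount(y[tr]))))
        if param_grid and inner >= 2:
            search = GridSearchCV(model, param_grid, cv=inner, scoring="roc_auc")
            search.fit(X[tr], y[tr])
            fitted = search.best_estimator_
        else:
            model.fit(X[tr], y[tr])
            fitted = model
        if hasattr(fitted, "decision_function"):
            oof[te] = fitted.decision_function(X[te])
        else:
            oof[te] = fitted.predict_proba(X[te])[:, 1]
        fold_of[te] = fold

    # F1 needs a class boundary; decision_function scores cut at 0, probabilities at 0.5
    threshold = 0.0 if model_kind == "svm" else 0.5
    return {
        "model": model_kind,
        "scores": pd.Series(oof, index=expr.samples, name="score"),
        "labels": pd.Series(y, index=expr.samples, name="label"),
        "fold": pd.Series(fold_of, index=expr.samples, name="fold"),
        "auroc": auroc(oof, y),
        "auprc": auprc(oof, y),
        "f1": f1_score(oof, y, threshold=threshold),
    }
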