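"""Cell-type specificity of gene sets in a labelled cell x gene matrix.

Per-gene one-way ANOVA across cell types, z-scoring of type means, and
the log observed/expected fraction of "expressed" genes per type (a gene
counts as expressed in a type when its z-score there exceeds a
threshold, 0 by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["celltype_stats", "zscore_across_types", "obs_exp_fraction"]

DELTA = 1e-6


def celltype_stats(
    matrix: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-(gene, type) mean and variance plus per-gene one-way ANOVA.

    ``matrix`` is cells x genes; ``labels`` maps cell -> type. Returns
    (means, variances, anova) where means/variances are gene x type and
    anova has columns F and p (F=0, p=1 for zero-variance genes).
    """
    labels = labels.reindex(matrix.index)
    if labels.isna().any():
        raise ValueError("every cell needs a type label")
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("each cell type needs >= 2 cells")

    X = matrix.to_numpy(dtype=float)
    n, _ = X.shape
    k = len(types)
    group_idx = [np.flatnonzero((labels == t).to_numpy()) for t in types]

    means = np.column_stack([X[idx].mean(axis=0) for idx in group_idx])
    variances = np.column_stack([X[idx].var(axis=0, ddof=1) for idx in group_idx])
    sizes = np.array([len(idx) for idx in group_idx])

    grand = X.mean(axis=0)
    ssb = (sizes[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((sizes - 1)[None, :] * variances).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    total_var = X.var(axis=0)
    F = np.where(total_var == 0, 0.0, F)
    F = np.where(np.isfinite(F), F, np.inf)
    p = stats.f.sf(F, df_b, df_w)
    p = np.where(total_var == 0, 1.0, p)

    genes = matrix.columns
    means_df = pd.DataFrame(means, index=genes, columns=types)
    var_df = pd.DataFrame(variances, index=genes, columns=types)
    anova_df = pd.DataFrame({"F": F, "p": p}, index=genes)
    return means_df, var_df, anova_df


def zscore_across_types(type_means: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene's type means across types (sample sd, ddof=1).

    Rows with zero sd become all-zero.
    """
    if type_means.shape[1] < 2:
        raise ValueError("need >= 2 types")
    m = type_means.to_numpy(dtype=float)
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mu) / sd
    z = np.where(sd == 0, 0.0, z)
    return pd.DataFrame(z, index=type_means.index, columns=type_means.columns)


def obs_exp_fraction(
    geneset: list[str],
    z: pd.DataFrame,
    expressed_threshold: float = 0.0,
    delta: float = DELTA,
    expected_over: str = "all",
) -> pd.DataFrame:
    """Observed vs expected fraction of geneset genes expressed per type.

    A gene is "expressed" in a type when its z-score there exceeds
    ``expressed_threshold``. obs = fraction of geneset genes expressed in
    the type; exp = fraction over ``expected_over`` ("all" matrix genes,
    or "tested" = geneset complement excluded);
    log2_ratio = log2((obs+delta)/(exp+delta)).
    """
    members = [g for g in dict.fromkeys(geneset) if g in z.index]
    if not members:
        raise ValueError("geneset has no gene in the matrix")
    expressed = z.to_numpy() > expressed_threshold
    in_set = z.index.isin(members)

    obs = expressed[in_set].mean(axis=0)
    if expected_over == "all":
        exp = expressed.mean(axis=0)
    elif expected_over == "tested":
        if (~in_set).sum() == 0:
            exp = expressed.mean(axis=0)
        else:
            exp = expressed[~in_set].mean(axis=0)
    else:
        raise ValueError(f"unknown expected_over {expected_over!r}")

    log2_ratio = np.log2((obs + delta) / (exp + delta))
    return pd.DataFrame(
        {"obs_frac": obs, "exp_frac": exp, "log2_ratio": log2_ratio},
        index=pd.Index(z.columns, name="cell_type"),
    )
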