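"""Cohort-level differential expression and top-k selection.

Two tests are provided: Welch's unequal-variance t and a moderated t
whose per-gene variance is shrunk toward the median gene variance with a
prior of d0 = 4 degrees of freedom. Multiple testing uses
Benjamini-Hochberg step-up FDR over all genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from netmediator._stats import bh_adjust
from netmediator.io_formats import CASE, CONTROL, ExpressionMatrix

__all__ = ["differential_expression", "select_top_degs"]

MODERATED_PRIOR_DF = 4.0


def differential_expression(expr: ExpressionMatrix, method: str = "moderated") -> pd.DataFrame:
    """Two-group test per gene.

    Returns a DataFrame indexed by gene with columns ``log2FC`` (case mean
    minus control mean), ``t_stat``, ``p_value`` and ``fdr``.
    """
    if method not in ("welch", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    case = expr.group_values(CASE)
    ctrl = expr.group_values(CONTROL)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")

    m1 = case.mean(axis=1)
    m2 = ctrl.mean(axis=1)
    log2fc = m1 - m2

    if method == "welch":
        v1 = case.var(axis=1, ddof=1)
        v2 = ctrl.var(axis=1, ddof=1)
        denom2 = v1 / n1 + v2 / n2
        zero = denom2 == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(denom2)
            df = denom2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = np.ones_like(t)
        ok = ~zero
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} gene(s) with zero within-group variance; "
                "p set to 0 where means differ, 1 otherwise"
            )
            differs = zero & (log2fc != 0)
            p[differs] = 0.0
            t[zero] = 0.0
            t[differs] = np.inf * np.sign(log2fc[differs])
            p[zero & ~differs] = 1.0
    else:
        v1 = case.var(axis=1, ddof=1)
        v2 = ctrl.var(axis=1, ddof=1)
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        prior = float(np.median(s2))
        d0 = MODERATED_PRIOR_DF
        s2_mod = (d0 * prior + df_resid * s2) / (d0 + df_resid)
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, np.where(log2fc != 0, np.inf, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), df_resid + d0)
        p = np.where(np.isfinite(t), p, np.where(t == 0, 1.0, 0.0))

    fdr = bh_adjust(p)
    return pd.DataFrame(
        {"log2FC": log2fc, "t_stat": t, "p_value": p, "fdr": fdr},
        index=pd.Index(expr.genes, name="gene"),
    )


def select_top_degs(
    table: pd.DataFrame,
    k: int = 100,
    fdr_max: float = 0.05,
    absolute: bool = False,
) -> list[str]:
    """Top-k genes by log2FC among FDR survivors.

    Filters ``fdr <= fdr_max`` then sorts by log2FC descending (or |log2FC|
    when ``absolute``); ties broken by smaller p then gene ID. Returns all
    survivors with a warning when fewer than k remain.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    surv = table[table["fdr"] <= fdr_max].copy()
    if surv.empty:
        warnings.warn("no genes pass the FDR threshold")
        return []
    surv = surv.assign(_key=surv["log2FC"].abs() if absolute else surv["log2FC"])
    surv = surv.reset_index().sort_values(
        by=["_key", "p_value", "gene"], ascending=[False, True, True], kind="mergesort"
    )
    if len(surv) < k:
        warnings.warn(f"only {len(surv)} genes pass the filter (requested {k})")
    return surv["gene"].head(k).tolist()
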