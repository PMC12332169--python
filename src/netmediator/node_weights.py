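"""Per-sample node weights from fold-change residuals.

For one case sample, the signed log2 fold change of every gene against a
control reference (median by default) is computed, the expected |log2FC|
at that gene's control expression level is estimated by a local-linear
tricube (loess-style) fit, and the node weight is the positive part of
the residual plus a small floor epsilon. Genes whose fold change has the
wrong sign for the requested mode get the floor only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from netmediator.io_formats import CASE, CONTROL, ExpressionMatrix

__all__ = [
    "NodeWeightVector",
    "per_sample_logfc",
    "loess_expected",
    "residual_weights",
    "sample_node_weights",
]

DEFAULT_EPS = 1e-4
DEFAULT_SPAN = 0.75


@dataclass
class NodeWeightVector:
    """Nonnegative per-gene weights for one sample."""

    sample: str
    weights: pd.Series  # gene -> weight, strictly positive
    logfc: pd.Series  # gene -> signed log2FC
    expected: pd.Series  # gene -> expected |log2FC|
    mode: str = "activated"

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("node weights must be strictly positive")


def per_sample_logfc(
    expr: ExpressionMatrix, sample: str, reference: str = "median"
) -> pd.Series:
    """Signed per-gene log2FC of a case sample against the control reference."""
    if expr.group_of.get(sample) != CASE:
        raise ValueError(f"sample {sample!r} is not a case sample")
    ctrl = expr.group_values(CONTROL)
    if ctrl.shape[1] < 2:
        raise ValueError("need >= 2 control samples")
    if reference == "median":
        ref = np.median(ctrl, axis=1)
    elif reference == "mean":
        ref = ctrl.mean(axis=1)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    vals = expr.sample_column(sample) - ref
    return pd.Series(vals, index=pd.Index(expr.genes, name="gene"), name=sample)


def control_reference(expr: ExpressionMatrix, reference: str = "median") -> pd.Series:
    """Per-gene control reference expression (the loess abscissa)."""
    ctrl = expr.group_values(CONTROL)
    ref = np.median(ctrl, axis=1) if reference == "median" else ctrl.mean(axis=1)
    return pd.Series(ref, index=pd.Index(expr.genes, name="gene"))


def loess_expected(
    abs_logfc: pd.Series,
    control_ref_expr: pd.Series,
    span: float = DEFAULT_SPAN,
) -> pd.Series:
    """Expected |log2FC| as a local-linear tricube fit against expression.

    For each gene, the nearest ``ceil(span * n)`` points by control
    expression are fit with a weighted straight line (tricube weights on
    scaled distance) and evaluated at the gene's expression. Predictions
    are clipped at zero. If every control expression is identical the
    global mean of |log2FC| is returned with a warning.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    y = abs_logfc.reindex(control_ref_expr.index).to_numpy(dtype=float)
    x = control_ref_expr.to_numpy(dtype=float)
    n = x.size
    if n < 30:
        raise ValueError("need >= 30 genes for a stable loess fit")
    if np.allclose(x, x[0]):
        warnings.warn("constant control expression; falling back to global mean |log2FC|")
        return pd.Series(np.full(n, float(np.mean(y))), index=control_ref_expr.index)

    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]

    fitted = np.empty(n)
    lo = 0
    for pos in range(n):
        x0 = xs[pos]
        # slide the k-window so it holds the k nearest neighbours of x0
        while lo + k < n and (xs[lo + k] - x0) < (x0 - xs[lo]):
            lo += 1
        xw = xs[lo : lo + k]
        yw = ys[lo : lo + k]
        d = np.abs(xw - x0)
        dmax = d.max()
        if dmax == 0:
            w = np.ones_like(d)
        else:
            w = (1.0 - (d / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        sw = w.sum()
        if sw <= 0 or np.count_nonzero(w) < 2:
            fitted[pos] = yw[d == 0].mean() if (d == 0).any() else yw.mean()
            continue
        xm = np.dot(w, xw) / sw
        ym = np.dot(w, yw) / sw
        sxx = np.dot(w, (xw - xm) ** 2)
        if sxx <= 1e-12:
            fitted[pos] = ym
        else:
            beta = np.dot(w, (xw - xm) * (yw - ym)) / sxx
            fitted[pos] = ym + beta * (x0 - xm)

    out = np.empty(n)
    out[order] = np.clip(fitted, 0.0, None)
    return pd.Series(out, index=control_ref_expr.index)


def residual_weights(
    signed_logfc: pd.Series,
    expected: pd.Series,
    mode: str = "activated",
    eps: float = DEFAULT_EPS,
    sample: str = "",
) -> NodeWeightVector:
    """Positive residual of observed over expected |log2FC|, sign-gated.

    ``activated``: genes with positive log2FC get
    ``max(|log2FC| - expected, 0) + eps``; others get ``eps``.
    ``repressed`` mirrors for negative log2FC.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0 (zero weights break path costs)")
    if mode not in ("activated", "repressed"):
        raise ValueError(f"unknown mode {mode!r}")
    lfc = signed_logfc
    exp = expected.reindex(lfc.index)
    residual = np.clip(lfc.abs() - exp, 0.0, None)
    gate = lfc > 0 if mode == "activated" else lfc < 0
    w = residual.where(gate, 0.0) + eps
    return NodeWeightVector(
        sample=sample or str(lfc.name or ""),
        weights=w,
        logfc=lfc,
        expected=exp,
        mode=mode,
    )


def sample_node_weights(
    expr: ExpressionMatrix,
    sample: str,
    mode: str = "activated",
    span: float = DEFAULT_SPAN,
    eps: float = DEFAULT_EPS,
    reference: str = "median",
) -> NodeWeightVector:
    """Convenience chain: log2FC -> loess expected -> residual weights."""
    lfc = per_sample_logfc(expr, sample, reference=reference)
    ref = control_reference(expr, reference=reference)
    exp = loess_expected(lfc.abs(), ref, span=span)
    return residual_weights(lfc, exp, mode=mode, eps=eps, sample=sample)
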