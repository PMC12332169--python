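"""Aggregate per-sample TopNets into a cohort-level central-gene table."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from netmediator.pathext_core import TopNet, ripple_centrality

__all__ = ["top_k_per_sample", "frequency_rank"]


def top_k_per_sample(topnet: TopNet, k: int = 100) -> pd.Series:
    """Top-k TopNet genes by ripple centrality for one sample.

    Returns a Series gene -> centrality ordered by centrality descending,
    ties by gene ID; empty for an empty TopNet (the sample then counts as
    non-significant). Fewer than k nodes means all are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if topnet.is_empty():
        return pd.Series(dtype=float, name="ripple").rename_axis("gene")
    r = ripple_centrality(topnet)
    ordered = r.sort_index().sort_values(ascending=False, kind="mergesort")
    return ordered.head(k)


def frequency_rank(
    per_sample_lists: Mapping[str, pd.Series] | Sequence[pd.Series],
    k_final: int = 100,
) -> pd.DataFrame:
    """Rank genes by how many per-sample top-k lists they appear in.

    ``per_sample_lists`` maps sample -> (gene -> centrality) Series; empty
    series mark non-significant samples and are excluded from the
    denominator. Returns the top ``k_final`` rows of a table with columns
    ``frequency``, ``freq_fraction`` (over significant samples) and
    ``mean_centrality``, sorted by frequency desc, mean centrality desc,
    gene ID. The number of significant samples is stored in
    ``result.attrs["n_significant_samples"]``.
    """
    if isinstance(per_sample_lists, Mapping):
        lists = list(per_sample_lists.values())
    else:
        lists = list(per_sample_lists)
    if not lists:
        raise ValueError("no per-sample lists provided")
    non_empty = [s for s in lists if len(s) > 0]
    if not non_empty:
        raise ValueError("no significantly altered samples")
    n_sig = len(non_empty)

    freq: dict[str, int] = {}
    csum: dict[str, float] = {}
    for s in non_empty:
        for gene, r in s.items():
            freq[gene] = freq.get(gene, 0) + 1
            csum[gene] = csum.get(gene, 0.0) + float(r)

    table = pd.DataFrame(
        {
            "frequency": pd.Series(freq),
            "mean_centrality": pd.Series({g: csum[g] / freq[g] for g in freq}),
        }
    ).rename_axis("gene")
    table["freq_fraction"] = table["frequency"] / n_sig
    table = table.reset_index().sort_values(
        by=["frequency", "mean_centrality", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    out = table.head(k_final).set_index("gene")[
        ["frequency", "freq_fraction", "mean_centrality"]
    ]
    out.attrs["n_significant_samples"] = n_sig
    return out
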