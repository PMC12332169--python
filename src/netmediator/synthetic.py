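"""Synthetic cohorts, networks and single-cell matrices.

The generators plant three gene classes in a two-group expression cohort:

* ``deg``      — genes with a fixed case-mean log2 shift (half up, half down);
* ``mediator`` — hub genes with negligible shift that are wired so that
  paths between up-shifted genes pass through them;
* ``null``     — everything else.

All generators are pure functions of their arguments plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from netmediator.io_formats import CASE, CONTROL, ExpressionMatrix, InteractionNetwork

__all__ = [
    "SyntheticSpec",
    "generate_cohort",
    "generate_network",
    "generate_single_cell",
]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-group cohort.

    Baselines span 4 log2 units and within-group noise is larger for
    low-expression genes, so the expected-|log2FC| trend against control
    expression is decreasing rather than flat.
    """

    n_genes: int = 500
    n_case: int = 16
    n_control: int = 48
    deg_fraction: float = 0.1
    deg_effect: float = 2.0
    mediator_count: int = 5
    deg_noise: float = 0.1
    noise_sd: float = 0.5
    baseline_low: float = 4.0
    baseline_high: float = 8.0
    heteroscedastic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per group")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.mediator_count < 0:
            raise ValueError("mediator_count must be >= 0")
        n_deg = int(round(self.deg_fraction * self.n_genes))
        if n_deg + self.mediator_count > self.n_genes:
            raise ValueError("deg + mediator genes exceed n_genes")
        if self.noise_sd < 0 or self.deg_noise < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def n_deg(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a two-group log2 expression cohort.

    Returns the expression matrix and a truth table indexed by gene with
    columns ``role`` (mediator/deg/null), ``direction`` (up/down/none) and
    ``shift`` (planted case-mean log2 shift).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    n = spec.n_genes

    baseline = rng.uniform(spec.baseline_low, spec.baseline_high, size=n)
    if spec.heteroscedastic:
        # noisier at low expression: multiplier from 2.0 (lowest) to 0.75 (highest)
        rel = (baseline - spec.baseline_low) / max(spec.baseline_high - spec.baseline_low, 1e-12)
        sd = spec.noise_sd * (2.0 - 1.25 * rel)
    else:
        sd = np.full(n, spec.noise_sd)

    special = rng.choice(n, size=spec.n_deg + spec.mediator_count, replace=False)
    deg_idx = np.sort(special[: spec.n_deg])
    med_idx = np.sort(special[spec.n_deg :])

    shift = np.zeros(n)
    n_up = spec.n_deg - spec.n_deg // 2
    up_idx = deg_idx[:n_up]
    down_idx = deg_idx[n_up:]
    shift[up_idx] = spec.deg_effect
    shift[down_idx] = -spec.deg_effect
    shift[med_idx] = rng.uniform(-spec.deg_noise, spec.deg_noise, size=len(med_idx))

    n_samples = spec.n_case + spec.n_control
    noise = rng.normal(0.0, 1.0, size=(n, n_samples)) * sd[:, None]
    values = baseline[:, None] + noise
    values[:, : spec.n_case] += shift[:, None]

    samples = [f"case{i:03d}" for i in range(spec.n_case)] + [
        f"ctrl{i:03d}" for i in range(spec.n_control)
    ]
    groups = {s: (CASE if s.startswith("case") else CONTROL) for s in samples}
    expr = ExpressionMatrix(genes, samples, values, groups)

    role = np.array(["null"] * n, dtype=object)
    role[deg_idx] = "deg"
    role[med_idx] = "mediator"
    direction = np.array(["none"] * n, dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    truth = pd.DataFrame(
        {"role": role, "direction": direction, "shift": shift},
        index=pd.Index(genes, name="gene"),
    )
    return expr, truth


def generate_network(
    n_genes: int,
    mediator_ids: Sequence[str],
    attach_m: int = 2,
    seed: int = 0,
    deg_ids: Sequence[str] | None = None,
    mediator_links: int = 20,
    confidence: float = 0.95,
) -> InteractionNetwork:
    """Preferential-attachment backbone with mediator hubs.

    Each mediator is additionally wired to ``mediator_links`` planted
    up-shifted genes (``deg_ids``) so that shortest paths between those
    genes pass through it.
    """
    import networkx as nx

    if attach_m >= n_genes:
        raise ValueError("attach_m must be smaller than n_genes")
    genes = _gene_names(n_genes)
    gene_set = set(genes)
    for m in mediator_ids:
        if m not in gene_set:
            raise ValueError(f"mediator {m!r} not among generated gene names")

    g = nx.barabasi_albert_graph(n_genes, attach_m, seed=int(seed))
    mapping = {i: genes[i] for i in range(n_genes)}
    g = nx.relabel_nodes(g, mapping)

    rng = np.random.default_rng(seed)
    targets = list(deg_ids) if deg_ids else []
    for m in mediator_ids:
        if targets:
            k = min(mediator_links, len(targets))
            chosen = rng.choice(len(targets), size=k, replace=False)
            for j in sorted(chosen):
                if targets[j] != m:
                    g.add_edge(m, targets[j])

    edges = [(u, v, confidence) for u, v in g.edges()]
    return InteractionNetwork(edges, directed=False)


def generate_single_cell(
    n_cells_per_type: Mapping[str, int] | int,
    cell_types: Sequence[str] | None = None,
    marker_sets: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
    n_genes: int = 200,
    elevation: float = 3.0,
    dispersion: float = 0.3,
    base_mean: float = 5.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an over-dispersed cell x gene count matrix with labels.

    Marker genes have their mean multiplied by ``elevation`` in their own
    cell type; counts are gamma-Poisson (negative-binomial-like) with the
    given dispersion. Returns (log1p-normalized matrix, cell-type labels).
    """
    if marker_sets is None:
        marker_sets = {}
    if cell_types is None:
        cell_types = list(marker_sets) if marker_sets else ["typeA", "typeB"]
    if isinstance(n_cells_per_type, int):
        n_cells_per_type = {t: n_cells_per_type for t in cell_types}
    for t in cell_types:
        if n_cells_per_type.get(t, 0) <= 0:
            raise ValueError(f"cell type {t!r} has no cells")
    if elevation <= 0:
        raise ValueError("elevation must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"SC{i:04d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for t, members in marker_sets.items():
        for g in members:
            if g not in gene_index:
                raise ValueError(f"marker gene {g!r} outside the generated gene space")

    gene_mean = base_mean * rng.lognormal(mean=0.0, sigma=0.8, size=n_genes)

    rows: list[np.ndarray] = []
    labels: list[str] = []
    cells: list[str] = []
    cid = 0
    for t in cell_types:
        mu = gene_mean.copy()
        for g in marker_sets.get(t, ()):  # elevate markers in their own type
            mu[gene_index[g]] *= elevation
        n_cells = n_cells_per_type[t]
        shape = 1.0 / max(dispersion, 1e-9)
        lam = rng.gamma(shape, scale=mu / shape, size=(n_cells, n_genes))
        counts = rng.poisson(lam)
        rows.append(counts)
        labels.extend([t] * n_cells)
        cells.extend(f"cell{cid + i:05d}" for i in range(n_cells))
        cid += n_cells

    counts = np.vstack(rows).astype(float)
    matrix = pd.DataFrame(np.log1p(counts), index=cells, columns=genes)
    return matrix, pd.Series(labels, index=cells, name="cell_type")
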