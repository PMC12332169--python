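"""Readers and writers for the text formats the pipeline consumes.

All formats are plain TSV:

* expression: first column gene IDs, header row sample IDs, numeric body;
* GMT: per line ``name<TAB>description<TAB>member...``;
* network edge list: ``source<TAB>target[<TAB>confidence]`` with header.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "InteractionNetwork",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Log2-scale gene x sample expression with a two-group split."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), log2 units
    group_of: dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = {g for g in self.group_of.values()} - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not self.case_samples or not self.control_samples:
            raise ValueError("both case and control groups must be non-empty")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == CASE]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == CONTROL]

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def sample_column(self, sample: str) -> np.ndarray:
        return self.values[:, self._sample_index[sample]]

    def group_values(self, group: str) -> np.ndarray:
        cols = [self._sample_index[s] for s in self.samples if self.group_of[s] == group]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def swapped_groups(self) -> "ExpressionMatrix":
        """Return a copy with case/control labels exchanged."""
        flipped = {s: (CONTROL if g == CASE else CASE) for s, g in self.group_of.items()}
        return ExpressionMatrix(list(self.genes), list(self.samples), self.values.copy(), flipped)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class InteractionNetwork:
    """Interaction edge list with confidences in [0, 1].

    Undirected by default; self-loops are dropped and duplicate edges
    merged keeping the maximum confidence.
    """

    edges: list[tuple[str, str, float]]
    directed: bool = False

    def __post_init__(self) -> None:
        merged: dict[tuple[str, str], float] = {}
        for u, v, c in self.edges:
            if not u or not v:
                raise ValueError("edge references an empty gene symbol")
            if u == v:
                continue
            key = (u, v) if self.directed else (min(u, v), max(u, v))
            prev = merged.get(key)
            if prev is None or c > prev:
                merged[key] = float(c)
        self.edges = [(u, v, c) for (u, v), c in sorted(merged.items())]

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for u, v, _ in self.edges:
            seen.setdefault(u)
            seen.setdefault(v)
        return sorted(seen)

    def filtered(self, min_confidence: float) -> "InteractionNetwork":
        """Edges with confidence strictly greater than ``min_confidence``."""
        kept = [(u, v, c) for u, v, c in self.edges if c > min_confidence]
        return InteractionNetwork(kept, directed=self.directed)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        for u, v, c in self.edges:
            g.add_edge(u, v, confidence=c)
        return g


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path: str | Path,
    group_map: Mapping[str, str],
    pseudocount: float = 1.0,
    assume_log: bool = False,
) -> ExpressionMatrix:
    """Read a gene x sample TSV into an :class:`ExpressionMatrix`.

    Unless ``assume_log``, values are transformed to ``log2(x + pseudocount)``.
    Duplicate gene rows are collapsed keeping the row with the highest mean
    expression. Every sample in the header must appear in ``group_map``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicated sample header(s): {dupes}")
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    mat = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(f"non-numeric value at gene {gene!r}, sample {col!r}")
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy()][0]
            raise ValueError(f"missing value at gene {gene!r}, sample {col!r}")
        mat[:, j] = converted.to_numpy()

    if not assume_log:
        mat = np.log2(mat + pseudocount)

    genes = [str(g) for g in df.index]
    if len(set(genes)) != len(genes):
        frame = pd.DataFrame(mat, index=genes)
        means = frame.mean(axis=1)
        keep_pos = []
        seen: dict[str, int] = {}
        for i, g in enumerate(genes):
            if g not in seen:
                seen[g] = i
                keep_pos.append(i)
            elif means.iloc[i] > means.iloc[seen[g]]:
                keep_pos[keep_pos.index(seen[g])] = i
                seen[g] = i
        mat = mat[keep_pos]
        genes = [genes[i] for i in keep_pos]

    groups = {s: group_map[s] for s in samples}
    return ExpressionMatrix(genes, list(samples), mat, groups)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write log2 values as TSV (read back with ``assume_log=True``)."""
    expr.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-style GMT file.

    Each line: ``name<TAB>description<TAB>member...``; members are
    deduplicated preserving first occurrence; empty sets are skipped.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if members:
                sets[name] = (desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# network


def read_network(
    path: str | Path,
    min_confidence: float = 0.0,
    directed: bool = False,
) -> InteractionNetwork:
    """Read an edge-list TSV (source, target, optional confidence).

    Edges with confidence strictly greater than ``min_confidence`` are
    retained; missing confidence defaults to 1.0.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise ValueError("network file needs at least source and target columns")
    src = df.iloc[:, 0]
    tgt = df.iloc[:, 1]
    if src.isna().any() or tgt.isna().any():
        raise ValueError("edge references an empty gene symbol")
    src = src.astype(str)
    tgt = tgt.astype(str)
    if (src.str.strip().str.len() == 0).any() or (tgt.str.strip().str.len() == 0).any():
        raise ValueError("edge references an empty gene symbol")
    if df.shape[1] >= 3:
        conf = pd.to_numeric(df.iloc[:, 2], errors="raise").astype(float)
    else:
        conf = pd.Series(np.ones(len(df)))
    edges = [
        (u, v, c)
        for u, v, c in zip(src, tgt, conf)
        if c > min_confidence
    ]
    return InteractionNetwork(edges, directed=directed)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tconfidence\n")
        for u, v, c in network.edges:
            fh.write(f"{u}\t{v}\t{c:.10g}\n")
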