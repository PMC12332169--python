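"""Hub-gene selection by degree and drug-target annotation."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from netmediator.io_formats import InteractionNetwork

__all__ = ["degree_hubs", "map_drug_targets", "read_drug_table"]


def degree_hubs(
    genes: list[str],
    network: InteractionNetwork,
    min_confidence: float = 0.7,
    top_n: int = 10,
    induced: bool = True,
) -> pd.DataFrame:
    """Top-n genes by degree in the confidence-filtered subnetwork.

    Edges with confidence strictly greater than ``min_confidence`` are
    kept; by default the subnetwork is induced on the query gene list.
    Ties broken by gene ID. Returns a DataFrame gene -> degree.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    filtered = network.filtered(min_confidence)
    gene_set = set(genes)
    degree: dict[str, int] = {}
    for u, v, _ in filtered.edges:
        if induced:
            if u in gene_set and v in gene_set:
                degree[u] = degree.get(u, 0) + 1
                degree[v] = degree.get(v, 0) + 1
        else:
            if u in gene_set:
                degree[u] = degree.get(u, 0) + 1
            if v in gene_set:
                degree[v] = degree.get(v, 0) + 1
    if not degree:
        raise ValueError("induced subnetwork is empty")
    ordered = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(ordered, columns=["gene", "degree"]).set_index("gene")


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a (gene, drug, status) TSV; malformed rows raise with the line."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"drug table line {lineno}: expected gene<TAB>drug[<TAB>status]")
            rows.append((fields[0], fields[1], fields[2] if len(fields) > 2 else ""))
    return pd.DataFrame(rows, columns=["gene", "drug", "status"])


def map_drug_targets(
    hubs: pd.DataFrame,
    drug_table: pd.DataFrame,
    max_per_gene: int = 3,
) -> pd.DataFrame:
    """Annotate hubs with up to ``max_per_gene`` drugs (stable input order).

    Hubs without an entry in the table are flagged "no data".
    """
    if max_per_gene < 1:
        raise ValueError("max_per_gene must be >= 1")
    out = hubs.copy()
    drugs_col = []
    for gene in out.index:
        matches = drug_table[drug_table["gene"] == gene]["drug"].tolist()
        uniq = list(dict.fromkeys(matches))[:max_per_gene]
        drugs_col.append("; ".join(uniq) if uniq else "no data")
    out["drugs"] = drugs_col
    return out
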