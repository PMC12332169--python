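"""Differentially active paths on a node-weighted interactome.

Node weights are normalized to (0, 1] by the maximum weight and each
edge (u, v) is priced at ``1 / sqrt(w_u * w_v)``, so a path is cheap
exactly when it traverses consistently high-weight nodes. Shortest paths
between the top-weight terminal nodes are scored against a null that
shuffles the weight vector over nodes (topology preserved), and the
union of significant paths forms the TopNet on which a reachability
("ripple") centrality is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from netmediator._stats import bh_adjust
from netmediator.io_formats import InteractionNetwork
from netmediator.node_weights import DEFAULT_EPS, NodeWeightVector

__all__ = [
    "WeightedPathGraph",
    "PathRecord",
    "TopNet",
    "build_path_graph",
    "candidate_paths",
    "permutation_significance",
    "build_topnet",
    "ripple_centrality",
]


@dataclass
class WeightedPathGraph:
    """Interactome with per-node weights and derived edge costs.

    ``rows``/``cols`` hold directed arc endpoints (undirected inputs are
    expanded to symmetric arcs); the cost of arc (i, j) is
    ``1 / sqrt(what_i * what_j)`` with ``what = weights / max(weights)``.
    """

    nodes: list[str]
    weights: np.ndarray  # raw weights, strictly positive
    rows: np.ndarray
    cols: np.ndarray
    node_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.node_index:
            self.node_index = {g: i for i, g in enumerate(self.nodes)}
        if np.any(self.weights <= 0):
            raise ValueError("node weights must be strictly positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def normalized_weights(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.weights if weights is None else weights
        return w / w.max()

    def cost_matrix(self, weights: np.ndarray | None = None) -> csr_matrix:
        """Sparse arc-cost matrix for the given (or stored) weight vector."""
        what = self.normalized_weights(weights)
        a = 1.0 / np.sqrt(what)
        data = a[self.rows] * a[self.cols]
        n = self.n_nodes
        return csr_matrix((data, (self.rows, self.cols)), shape=(n, n))


@dataclass
class PathRecord:
    source: str
    target: str
    path: list[str]
    cost: float


@dataclass
class TopNet:
    """Union of significant differentially active paths (directed)."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    pair_pvalues: pd.DataFrame  # columns: source, target, p_value, adj_p, significant

    def is_empty(self) -> bool:
        return len(self.nodes) == 0

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def build_path_graph(
    network: InteractionNetwork,
    weights: NodeWeightVector | pd.Series,
    eps: float = DEFAULT_EPS,
) -> WeightedPathGraph:
    """Map node weights onto the interactome.

    Network genes absent from the weight vector get the floor ``eps``;
    weight genes absent from the network are ignored. Undirected networks
    are expanded to symmetric directed arcs.
    """
    wseries = weights.weights if isinstance(weights, NodeWeightVector) else weights
    nodes = network.nodes
    if not nodes:
        raise ValueError("network has no edges")
    overlap = set(nodes) & set(wseries.index)
    if not overlap:
        raise ValueError("no overlap between weight genes and network nodes")

    node_index = {g: i for i, g in enumerate(nodes)}
    w = np.full(len(nodes), eps, dtype=float)
    common = wseries.reindex(nodes)
    mask = common.notna().to_numpy()
    w[mask] = common.to_numpy(dtype=float)[mask]

    rows, cols = [], []
    for u, v, _ in network.edges:
        i, j = node_index[u], node_index[v]
        rows.append(i)
        cols.append(j)
        if not network.directed:
            rows.append(j)
            cols.append(i)
    return WeightedPathGraph(
        nodes=nodes,
        weights=w,
        rows=np.asarray(rows, dtype=np.int64),
        cols=np.asarray(cols, dtype=np.int64),
        node_index=node_index,
    )


def select_terminals(graph: WeightedPathGraph, terminal_fraction: float = 0.05) -> list[str]:
    """Top fraction of nodes by weight; ties by weight desc then gene ID."""
    if not 0.0 < terminal_fraction <= 1.0:
        raise ValueError("terminal_fraction must be in (0, 1]")
    k = int(np.ceil(terminal_fraction * graph.n_nodes))
    order = sorted(range(graph.n_nodes), key=lambda i: (-graph.weights[i], graph.nodes[i]))
    terminals = [graph.nodes[i] for i in order[:k]]
    if len(terminals) < 2:
        raise ValueError("fewer than 2 terminal nodes; increase terminal_fraction")
    return terminals


def candidate_paths(
    graph: WeightedPathGraph,
    terminal_fraction: float = 0.05,
    terminals: list[str] | None = None,
) -> list[PathRecord]:
    """Minimum-cost path for every ordered terminal pair (Dijkstra).

    Unreachable pairs are skipped.
    """
    if terminals is None:
        terminals = select_terminals(graph, terminal_fraction)
    if len(terminals) < 2:
        raise ValueError("need >= 2 terminals")
    idx = np.array([graph.node_index[t] for t in terminals])
    costs = graph.cost_matrix()
    dist, pred = dijkstra(costs, directed=True, indices=idx, return_predecessors=True)

    records: list[PathRecord] = []
    for a, s in enumerate(terminals):
        si = idx[a]
        for b, t in enumerate(terminals):
            if a == b:
                continue
            ti = idx[b]
            d = dist[a, ti]
            if not np.isfinite(d):
                continue
            path_idx = [ti]
            cur = ti
            while cur != si:
                cur = pred[a, cur]
                path_idx.append(cur)
            path = [graph.nodes[i] for i in reversed(path_idx)]
            records.append(PathRecord(source=s, target=t, path=path, cost=float(d)))
    return records


def permutation_significance(
    graph: WeightedPathGraph,
    paths: list[PathRecord],
    n_perm: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-value per terminal pair.

    Each permutation shuffles the node-weight vector uniformly over nodes,
    rebuilds edge costs and recomputes the same-pair shortest-path cost;
    ``p = (1 + #{C_perm <= C_obs}) / (1 + n_perm)`` (plus-one estimator,
    never zero).
    """
    if seed is None:
        raise ValueError("seed is required for the permutation null")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not paths:
        return pd.DataFrame(columns=["source", "target", "p_value"])

    rng = np.random.default_rng(seed)
    sources = sorted({p.source for p in paths})
    src_row = {s: i for i, s in enumerate(sources)}
    src_idx = np.array([graph.node_index[s] for s in sources])
    tgt_idx = np.array([graph.node_index[p.target] for p in paths])
    row_of = np.array([src_row[p.source] for p in paths])
    obs = np.array([p.cost for p in paths])

    hits = np.zeros(len(paths), dtype=np.int64)
    for _ in range(n_perm):
        perm_w = rng.permutation(graph.weights)
        costs = graph.cost_matrix(perm_w)
        dist = dijkstra(costs, directed=True, indices=src_idx)
        perm_cost = dist[row_of, tgt_idx]
        hits += (perm_cost <= obs + 1e-12).astype(np.int64)

    p = (1.0 + hits) / (1.0 + n_perm)
    return pd.DataFrame(
        {
            "source": [p_.source for p_ in paths],
            "target": [p_.target for p_ in paths],
            "p_value": p,
        }
    )


def build_topnet(
    paths: list[PathRecord],
    p_values: pd.DataFrame,
    alpha: float = 0.05,
) -> TopNet:
    """Union of edges of significant paths after BH adjustment across pairs."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not paths:
        warnings.warn("no candidate paths; TopNet is empty")
        return TopNet([], [], pd.DataFrame(columns=["source", "target", "p_value", "adj_p", "significant"]))

    pv = p_values.copy()
    pv["adj_p"] = bh_adjust(pv["p_value"].to_numpy())
    pv["significant"] = pv["adj_p"] <= alpha

    sig_pairs = {
        (r.source, r.target) for r in pv.itertuples() if r.significant
    }
    edge_set: set[tuple[str, str]] = set()
    node_set: set[str] = set()
    for rec in paths:
        if (rec.source, rec.target) not in sig_pairs:
            continue
        node_set.update(rec.path)
        edge_set.update(zip(rec.path[:-1], rec.path[1:]))
    if not node_set:
        warnings.warn("no significant path; TopNet is empty")
    return TopNet(sorted(node_set), sorted(edge_set), pv)


def ripple_centrality(topnet: TopNet) -> pd.Series:
    """Reachability centrality on the directed TopNet.

    ``r(v) = sqrt(R_out(v) * R_in(v)) / (n - 1)`` with R_out/R_in the
    number of nodes reachable from / reaching v (excluding v); zero for
    graphs with fewer than two nodes and for isolated nodes.
    """
    import networkx as nx

    n = len(topnet.nodes)
    if n <= 1:
        return pd.Series(0.0, index=pd.Index(topnet.nodes, name="gene"))
    g = topnet.to_networkx()
    r = {}
    for v in topnet.nodes:
        out_reach = len(nx.descendants(g, v))
        in_reach = len(nx.ancestors(g, v))
        r[v] = float(np.sqrt(out_reach * in_reach) / (n - 1))
    return pd.Series(r, name="ripple").rename_axis("gene")
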