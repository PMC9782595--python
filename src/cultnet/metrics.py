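"""Graph-theoretic characterization of effective connectivity networks.

All functions operate on directed, unweighted adjacency matrices (square
0/1 numpy arrays).  Distances are hop counts; global efficiency is the mean
inverse shortest-path length over ordered node pairs; modularity is the
standard undirected Newman-Girvan quantity evaluated on the symmetrized
graph; betweenness is the unnormalized directed variant with endpoints
excluded.  Communities come from the Louvain greedy modularity optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MetricReport",
    "degrees",
    "shortest_paths",
    "global_efficiency",
    "louvain_communities",
    "modularity",
    "betweenness",
    "metric_report",
]


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary (entries in {0, 1})")
    return a.astype(np.int8)


def _digraph(a: np.ndarray) -> nx.DiGraph:
    g: nx.DiGraph = nx.from_numpy_array(a, create_using=nx.DiGraph)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


@dataclass
class MetricReport:
    """Bundle of per-network metrics for one effective network."""

    k_in: np.ndarray
    k_out: np.ndarray
    k: np.ndarray
    geff: float
    q: float
    communities: np.ndarray  # community label per node, contiguous ints
    bc: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        ids = (
            self.node_ids
            if self.node_ids is not None
            else np.arange(len(self.k))
        )
        return {
            "geff": float(self.geff),
            "q": float(self.q),
            "n_communities": int(self.communities.max() + 1)
            if self.communities.size
            else 0,
            "nodes": [
                {
                    "id": int(i),
                    "k_in": int(ki),
                    "k_out": int(ko),
                    "k": int(kt),
                    "community": int(c),
                    "bc": float(b),
                }
                for i, ki, ko, kt, c, b in zip(
                    ids, self.k_in, self.k_out, self.k, self.communities, self.bc
                )
            ],
        }


def degrees(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node in/out/total degree of a directed binary adjacency.

    Returns ``(k_in, k_out, k)`` with ``k = k_in + k_out``.
    """
    a = _check_adjacency(adjacency)
    k_out = a.sum(axis=1).astype(int)
    k_in = a.sum(axis=0).astype(int)
    return k_in, k_out, k_in + k_out


def shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs directed hop-count distance matrix.

    Unreachable pairs get ``inf``; the diagonal is 0.  Uses breadth-first
    search, to which Dijkstra reduces on unweighted graphs.
    """
    a = _check_adjacency(adjacency)
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    g = _digraph(a)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, hops in lengths.items():
            d[src, dst] = hops
    return d


def global_efficiency(
    adjacency: np.ndarray, exclude: set[int] | None = None
) -> float:
    """Global efficiency Geff = mean of 1/d_ij over ordered pairs i != j.

    1/inf counts as 0, so Geff is 1 for a complete digraph and 0 for an
    edgeless one.  ``exclude`` drops nodes before the computation (the
    node-induced subgraph is used), which keeps pre/post-damage networks
    size-matched when a deleted node must be ignored.
    """
    a = _check_adjacency(adjacency)
    if exclude:
        keep = np.array(sorted(set(range(a.shape[0])) - set(exclude)))
        a = a[np.ix_(keep, keep)]
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    d = shortest_paths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def louvain_communities(
    adjacency: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Louvain community detection on the symmetrized graph.

    Returns an integer community label per node (contiguous, starting at
    0); deterministic for a fixed seed.  Isolated nodes get their own
    community.
    """
    a = _check_adjacency(adjacency)
    sym = ((a + a.T) > 0).astype(np.int8)
    g = nx.from_numpy_array(sym)
    g.remove_edges_from(nx.selfloop_edges(g))
    parts = nx.community.louvain_communities(g, seed=int(seed))
    labels = np.empty(a.shape[0], dtype=int)
    # relabel so community ids are ordered by their lowest member
    for lab, members in enumerate(sorted(parts, key=min)):
        for node in members:
            labels[node] = lab
    return labels


def modularity(adjacency: np.ndarray, partition: np.ndarray) -> float:
    """Newman-Girvan modularity Q of a partition, on the symmetrized graph.

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j), with A the
    undirected adjacency, k_i its degree and m its edge count.  Q is 0 when
    the whole network forms a single community.
    """
    a = _check_adjacency(adjacency)
    part = np.asarray(partition)
    if part.shape != (a.shape[0],):
        raise ValueError("partition must assign one community per node")
    sym = ((a + a.T) > 0).astype(float)
    np.fill_diagonal(sym, 0.0)
    k = sym.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    same = part[:, None] == part[None, :]
    b = sym - np.outer(k, k) / two_m
    return float(b[same].sum() / two_m)


def betweenness(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized directed betweenness centrality per node.

    BC_i = sum over ordered pairs (j, k), j != k, both != i, of the
    fraction of shortest directed paths from j to k passing through i.
    """
    a = _check_adjacency(adjacency)
    g = _digraph(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def metric_report(
    adjacency: np.ndarray,
    seed: int = 0,
    node_ids: np.ndarray | None = None,
) -> MetricReport:
    """Compute the full metric bundle for one adjacency matrix."""
    a = _check_adjacency(adjacency)
    k_in, k_out, k = degrees(a)
    comm = louvain_communities(a, seed=seed)
    try:
        q = modularity(a, comm)
    except ValueError:  # edgeless network
        q = float("nan")
    try:
        geff = global_efficiency(a)
    except ValueError:
        geff = float("nan")
    return MetricReport(
        k_in=k_in,
        k_out=k_out,
        k=k,
        geff=geff,
        q=q,
        communities=comm,
        bc=betweenness(a),
        node_ids=node_ids if node_ids is not None else np.arange(a.shape[0]),
    )
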