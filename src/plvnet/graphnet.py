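"""Threshold binarization of connectivity matrices and binary-graph
network properties: clustering coefficient, characteristic path length,
node degree.

Conventions (documented because degenerate graphs occur at sparse
thresholds):

* the binarization cut is ``fraction x max`` over the *off-diagonal*
  entries (the diagonal is identically 1 and would pin the cut), with a
  strict ``>`` at the cut, so ties are excluded;
* a node with fewer than 2 neighbours has clustering coefficient 0;
* characteristic path length averages, per node, the shortest-path
  distance to *reachable* partners only; isolated nodes contribute 0 and
  a warning is emitted; a graph with no edges has undefined CPL (NaN).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix


@dataclass
class BinaryGraph:
    """Undirected, loop-free graph over channels."""

    adjacency: np.ndarray           # channels x channels bool
    channel_labels: tuple[str, ...]
    threshold_used: float
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.channel_labels = tuple(self.channel_labels)
        n = len(self.channel_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square, matching labels")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class NetworkMetrics:
    """All network properties of one binary graph, kept for auditability."""

    mean_cc: float
    cpl: float
    degrees: np.ndarray
    n_nodes: int
    t_i: np.ndarray                 # per-node triangle counts
    d_ij: np.ndarray                # pairwise hop distances (inf = unreachable)


def binarize(matrix: ConnectivityMatrix, fraction: float = 0.8) -> BinaryGraph:
    """Edge (p, q) present iff PLV[p, q] > fraction x max off-diagonal PLV."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    values = matrix.values
    n = len(matrix.channel_labels)
    off = ~np.eye(n, dtype=bool)
    peak = values[off].max() if n > 1 else 0.0
    if peak <= 0.0:
        warnings.warn("all off-diagonal PLV values are zero; graph is empty")
    cut = fraction * peak
    adjacency = (values > cut) & off
    adjacency &= adjacency.T
    return BinaryGraph(
        adjacency, matrix.channel_labels, threshold_used=float(cut),
        source={"subject_id": matrix.subject_id, "condition": matrix.condition,
                "band": matrix.band, "group": matrix.group,
                "fraction": fraction},
    )


def node_degrees(graph: BinaryGraph) -> np.ndarray:
    """Number of neighbours per node, in channel-label order."""
    return graph.adjacency.sum(axis=1).astype(np.int64)


def clustering_coefficient(graph: BinaryGraph):
    """Mean clustering coefficient and the per-node vector.

    CC_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of edges among node
    i's neighbours; CC_i := 0 for k_i < 2. The network value is the plain
    mean over all n nodes.
    """
    a = graph.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    t = np.diag(a @ a @ a) // 2
    cc = np.zeros(graph.n_nodes, dtype=np.float64)
    ok = k >= 2
    cc[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return float(cc.mean()), cc


def shortest_path_matrix(graph: BinaryGraph) -> np.ndarray:
    """All-pairs hop distances by breadth-first search; inf if unreachable."""
    n = graph.n_nodes
    neighbours = [np.flatnonzero(graph.adjacency[i]) for i in range(n)]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0.0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in neighbours[u]:
                if np.isinf(d[s, v]):
                    d[s, v] = d[s, u] + 1.0
                    queue.append(v)
    return d


def characteristic_path_length(graph: BinaryGraph, d: np.ndarray | None = None) -> float:
    """Mean over nodes of the mean hop distance to reachable partners.

    Unreachable pairs are excluded from both numerator and pair count.
    Returns NaN (with a warning) for an edgeless graph.
    """
    if graph.n_edges == 0:
        warnings.warn("graph has no edges; characteristic path length undefined")
        return float("nan")
    if d is None:
        d = shortest_path_matrix(graph)
    n = graph.n_nodes
    per_node = np.zeros(n)
    isolated = []
    for i in range(n):
        finite = np.isfinite(d[i]) & (np.arange(n) != i)
        if not finite.any():
            isolated.append(graph.channel_labels[i])
            continue
        per_node[i] = d[i, finite].mean()
    if isolated:
        warnings.warn(
            f"{len(isolated)} isolated node(s) contribute 0 to CPL: {isolated}"
        )
    return float(per_node.mean())


def network_metrics(graph: BinaryGraph) -> NetworkMetrics:
    """Bundle of every property the analysis stage consumes."""
    mean_cc, cc = clustering_coefficient(graph)
    d = shortest_path_matrix(graph)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cpl = characteristic_path_length(graph, d)
    a = graph.adjacency.astype(np.int64)
    t = np.diag(a @ a @ a) // 2
    return NetworkMetrics(
        mean_cc=mean_cc, cpl=cpl, degrees=node_degrees(graph),
        n_nodes=graph.n_nodes, t_i=t, d_ij=d,
    )


# ---------------------------------------------------------------------------
# Exports

def write_edge_list(path, graph: BinaryGraph) -> None:
    """Edge-list TSV (label1, label2), lexicographic by index order."""
    with open(path, "w") as fh:
        fh.write("ch1\tch2\n")
        n = graph.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if graph.adjacency[i, j]:
                    fh.write(f"{graph.channel_labels[i]}\t"
                             f"{graph.channel_labels[j]}\n")


def write_adjacency_csv(path, graph: BinaryGraph) -> None:
    with open(path, "w") as fh:
        fh.write("," + ",".join(graph.channel_labels) + "\n")
        for label, row in zip(graph.channel_labels, graph.adjacency):
            fh.write(label + "," + ",".join(str(int(v)) for v in row) + "\n")
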