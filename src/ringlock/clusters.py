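"""Graph analysis of deadlock edges: clusters, populations, hub cutting.

Deadlocked pairs define a simple undirected graph over all rings; its
connected components are the deadlock clusters.  ``n_k`` counts clusters of
size ``k`` (isolated rings are size-1 clusters); "nontrivial" clusters are
those with k >= 2.  Cluster graphs may contain cycles — they are not trees —
so a per-component cycle flag is kept.  Population series over time yield
``t_max(k)``, the earliest time at which the size-k population peaks, the
signature of an aggregation cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DeadlockGraph",
    "ClusterStats",
    "PopulationSeries",
    "build_graph",
    "cluster_stats",
    "population_series",
    "hub_cut",
]


@dataclass
class DeadlockGraph:
    """Simple undirected graph on all ring ids with deadlock edges."""

    graph: nx.Graph
    time: float = 0.0

    @property
    def n_rings(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(min(u, v), max(u, v)) for u, v in self.graph.edges]


@dataclass(frozen=True)
class ClusterStats:
    n_k: dict[int, int]  # cluster size -> count
    largest_size: int
    n_components: int
    n_nontrivial: int  # components with k >= 2
    has_cycle: dict[int, bool]  # component index -> cycle flag
    components: list[frozenset[int]]

    @property
    def n_rings(self) -> int:
        return sum(k * c for k, c in self.n_k.items())


@dataclass(frozen=True)
class PopulationSeries:
    times: np.ndarray
    sizes: np.ndarray  # occupied cluster sizes, ascending
    n_k_t: np.ndarray  # (len(times), len(sizes)) population matrix
    t_max: dict[int, float]  # size -> earliest time of peak population


def build_graph(
    edges: list[tuple[int, int]] | np.ndarray, n_rings: int, time: float = 0.0
) -> DeadlockGraph:
    """Deduplicated simple graph; isolated nodes kept as size-1 clusters."""
    g = nx.Graph()
    g.add_nodes_from(range(n_rings))
    for a, b in np.asarray(edges, dtype=np.intp).reshape(-1, 2):
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-loop edge on ring {a}")
        if not (0 <= a < n_rings and 0 <= b < n_rings):
            raise ValueError(f"edge ({a}, {b}) outside 0..{n_rings - 1}")
        g.add_edge(a, b)
    return DeadlockGraph(graph=g, time=time)


def cluster_stats(dg: DeadlockGraph) -> ClusterStats:
    """Connected-component decomposition with exact n_k and cycle flags."""
    comps = [frozenset(c) for c in nx.connected_components(dg.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    n_k: dict[int, int] = {}
    has_cycle: dict[int, bool] = {}
    for idx, comp in enumerate(comps):
        k = len(comp)
        n_k[k] = n_k.get(k, 0) + 1
        sub_edges = dg.graph.subgraph(comp).number_of_edges()
        has_cycle[idx] = sub_edges >= k and k >= 3
    return ClusterStats(
        n_k=dict(sorted(n_k.items())),
        largest_size=max(n_k) if n_k else 0,
        n_components=len(comps),
        n_nontrivial=sum(c for k, c in n_k.items() if k >= 2),
        has_cycle=has_cycle,
        components=comps,
    )


def population_series(graphs: list[DeadlockGraph]) -> PopulationSeries:
    """Assemble n_k(t) and peak times from time-ordered deadlock graphs.

    ``t_max(k)`` is the earliest time achieving the maximum population of
    size-k clusters (plateaus resolve to the earliest time).
    """
    if not graphs:
        raise ValueError("need at least one graph")
    times = np.array([g.time for g in graphs])
    if (np.diff(times) <= 0).any():
        raise ValueError("duplicate or decreasing timestamps")
    stats = [cluster_stats(g) for g in graphs]
    sizes = sorted({k for s in stats for k in s.n_k})
    mat = np.zeros((len(graphs), len(sizes)), dtype=np.intp)
    for row, s in enumerate(stats):
        for col, k in enumerate(sizes):
            mat[row, col] = s.n_k.get(k, 0)
    t_max = {
        k: float(times[int(np.argmax(mat[:, col]))])
        for col, k in enumerate(sizes)
    }
    return PopulationSeries(
        times=times, sizes=np.array(sizes, dtype=np.intp), n_k_t=mat, t_max=t_max
    )


def hub_cut(dg: DeadlockGraph, n_cut: int) -> tuple[DeadlockGraph, list[int]]:
    """Remove the ``n_cut`` highest-degree rings (ties to lower ring id).

    Returns the reduced graph (removed rings stay as isolated nodes, since
    cutting a ring open does not delete it from the melt) and the removal
    list, ordered, for feeding the simulator's ``cut_ring``.
    """
    if n_cut > dg.n_rings:
        raise ValueError("cannot cut more rings than exist")
    ranked = sorted(dg.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    removed = [int(node) for node, _deg in ranked[:n_cut]]
    g = dg.graph.copy()
    for node in removed:
        g.remove_edges_from(list(g.edges(node)))
    return DeadlockGraph(graph=g, time=dg.time), removed
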