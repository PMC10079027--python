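"""Global integration, segregation and hierarchy measures.

* Integration — global efficiency
  E_glob = 1/(N(N-1)) * sum_{i != j} 1/s_ij, with s_ij the Dijkstra distance
  under inverse-weight edge lengths; unreachable pairs contribute 0.
* Segregation — modularity
  Q = 1/(2m) * sum_{ij} [a_ij - d_i d_j / (2m)] * delta(c_i, c_j),
  maximized over partitions with the Louvain heuristic ("ultimate
  modularity"); seeded restarts, best partition kept.
* Hierarchy — global reaching centrality
  GRC = sum_i [C_R^max - C_R(i)] / (N - 1), where the local reaching
  centrality C_R(i) averages, over reachable targets j, the mean edge weight
  along the selected geodesic i -> j.  Geodesics are selected by
  inverse-weight distance; ties are broken by fewest links, then by
  lexicographic next-hop, so the selection is deterministic.  Each
  undirected edge is treated as two directed links.

The four-variant comparison (extended/restricted x raw/volume-normalized)
summarizes each connectome by (E_glob, ultimate Q, GRC) and reports
per-variant centroids for integration-vs-segregation-vs-hierarchy scatter
plots.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .build import ConnectivityMatrix
from .centrality import ShortestPathCache, shortest_paths

__all__ = [
    "Partition",
    "TopologySummary",
    "global_efficiency",
    "modularity",
    "louvain_partition",
    "local_reaching_centrality",
    "global_reaching_centrality",
    "integration_segregation_summary",
]


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment with contiguous ids from 0."""

    community_of: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = self.community_of
        ids = np.unique(c)
        if len(c) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("community ids must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.community_of))


@dataclass(frozen=True)
class TopologySummary:
    """Global metrics of one connectome variant."""

    e_glob: float
    q_ultimate: float
    partition: Partition
    grc: float
    variant: str = ""


# ---------------------------------------------------------------------------


def global_efficiency(
    matrix: ConnectivityMatrix, cache: ShortestPathCache | None = None
) -> float:
    """Mean inverse geodesic distance over ordered node pairs."""
    n = matrix.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    cache = cache or shortest_paths(matrix)
    d = cache.dist.copy()
    np.fill_diagonal(d, np.inf)  # exclude i == j; 1/inf = 0 also covers disconnection
    with np.errstate(divide="ignore"):
        eff = 1.0 / d
    return float(eff[np.isfinite(eff)].sum() / (n * (n - 1)))


def modularity(matrix: ConnectivityMatrix, partition: Partition | np.ndarray) -> float:
    """Newman modularity Q of a partition on the weighted adjacency."""
    w = matrix.weights
    comm = partition.community_of if isinstance(partition, Partition) else np.asarray(partition)
    if len(comm) != matrix.n_nodes:
        raise ValueError("partition does not cover all nodes")
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for empty graph")
    d = w.sum(axis=1)
    same = comm[:, None] == comm[None, :]
    return float(((w - np.outer(d, d) / two_m)[same]).sum() / two_m)


def _contiguous(comm: np.ndarray) -> np.ndarray:
    """Renumber community ids to 0..k-1 in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty(len(comm), dtype=np.int64)
    for i, c in enumerate(comm):
        out[i] = seen.setdefault(int(c), len(seen))
    return out


def louvain_partition(
    matrix: ConnectivityMatrix, seed: int = 0, n_restarts: int = 10
) -> tuple[Partition, float]:
    """Best-of-``n_restarts`` Louvain maximization of modularity.

    Each restart shuffles node processing order through its seed.  The
    single-community partition (Q = 0) is always a candidate, so the
    returned Q is never negative.  The returned Q is recomputed from the
    returned partition with :func:`modularity`.
    """
    n = matrix.n_nodes
    if matrix.total_weight() <= 0:
        raise ValueError("Louvain undefined for empty graph")
    g = nx.from_numpy_array(matrix.weights)
    best_comm = np.zeros(n, dtype=np.int64)
    best_q = modularity(matrix, best_comm)
    for r in range(n_restarts):
        communities = louvain_communities(g, weight="weight", seed=int(seed) + r)
        comm = np.empty(n, dtype=np.int64)
        for cid, nodes in enumerate(communities):
            comm[list(nodes)] = cid
        comm = _contiguous(comm)
        q = modularity(matrix, comm)
        if q > best_q:
            best_q, best_comm = q, comm
    return Partition(community_of=best_comm), best_q


def _reaching_geodesics(
    weights: np.ndarray, source: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-target (sum of edge weights, number of links) along the selected
    geodesic from ``source``.

    Dijkstra keyed by (distance, links, path); the tuple comparison
    implements the fewest-links / lexicographic-next-hop tie-break.
    """
    n = weights.shape[0]
    neighbors = [np.nonzero(weights[u])[0] for u in range(n)]
    weight_sum = np.zeros(n)
    link_count = np.zeros(n, dtype=np.int64)
    settled = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int, tuple[int, ...], float]] = [(0.0, 0, (source,), 0.0)]
    while heap:
        dist, links, path, wsum = heapq.heappop(heap)
        u = path[-1]
        if settled[u]:
            continue
        settled[u] = True
        weight_sum[u] = wsum
        link_count[u] = links
        for v in neighbors[u]:
            if not settled[v]:
                w = weights[u, v]
                heapq.heappush(
                    heap, (dist + 1.0 / w, links + 1, path + (int(v),), wsum + w)
                )
    return weight_sum, link_count


def local_reaching_centrality(matrix: ConnectivityMatrix, node: int) -> float:
    """Mean-edge-weight reach of one node, averaged over N-1 targets.

    C_R(i) = 1/(N-1) * sum over reachable j != i of (mean weight of the
    links along the selected geodesic i -> j); unreachable targets
    contribute 0.  Isolated nodes score 0.
    """
    n = matrix.n_nodes
    if n < 2:
        raise ValueError("reaching centrality needs at least 2 nodes")
    wsum, links = _reaching_geodesics(matrix.weights, node)
    reached = links > 0
    if not reached.any():
        return 0.0
    return float((wsum[reached] / links[reached]).sum() / (n - 1))


def global_reaching_centrality(matrix: ConnectivityMatrix) -> tuple[float, np.ndarray]:
    """GRC and the per-node local reaching centralities it derives from."""
    n = matrix.n_nodes
    if n < 2:
        raise ValueError("GRC needs at least 2 nodes")
    local = np.array([local_reaching_centrality(matrix, i) for i in range(n)])
    grc = float((local.max() - local).sum() / (n - 1))
    return grc, local


def summarize(
    matrix: ConnectivityMatrix, variant: str = "", seed: int = 0, n_restarts: int = 10
) -> TopologySummary:
    """(E_glob, ultimate Q, GRC) for one connectome."""
    cache = shortest_paths(matrix)
    part, q = louvain_partition(matrix, seed=seed, n_restarts=n_restarts)
    grc, _ = global_reaching_centrality(matrix)
    return TopologySummary(
        e_glob=global_efficiency(matrix, cache),
        q_ultimate=q,
        partition=part,
        grc=grc,
        variant=variant,
    )


def integration_segregation_summary(
    variants: dict[str, list[ConnectivityMatrix]],
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-matrix metrics and per-variant centroids for the four-variant
    integration/segregation/hierarchy comparison.

    Returns (points, centroids): ``points`` has one row per matrix with
    columns (variant, subject, e_glob, q_ultimate, n_communities, grc);
    ``centroids`` averages each variant's points.
    """
    rows = []
    for variant, matrices in variants.items():
        if not matrices:
            raise ValueError(f"variant {variant!r} has no matrices")
        for subject, m in enumerate(matrices):
            s = summarize(m, variant=variant, seed=seed, n_restarts=n_restarts)
            rows.append(
                {
                    "variant": variant,
                    "subject": subject,
                    "e_glob": s.e_glob,
                    "q_ultimate": s.q_ultimate,
                    "n_communities": s.partition.n_communities,
                    "grc": s.grc,
                }
            )
    points = pd.DataFrame(rows)
    centroids = (
        points.groupby("variant", sort=False)[["e_glob", "q_ultimate", "grc"]]
        .mean()
        .reset_index()
    )
    return points, centroids
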