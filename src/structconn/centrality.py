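"""Node centrality measures for weighted structural connectomes.

Three measures are computed on the symmetric weighted adjacency A = (a_ij):

* degree centrality (node strength): d_i = sum_j a_ij — the total streamline
  count attached to a structure;
* eigenvector centrality: the components of the Perron eigenvector of A
  (largest eigenvalue), which rewards connections to well-connected nodes;
  computed by power iteration and rescaled to a maximum component of 1,
  since only relative values matter for ranking;
* betweenness centrality:
  b_i = 2 / ((N-1)(N-2)) * sum_{j<k, j!=i!=k} sigma_jk(i) / sigma_jk,
  where sigma_jk counts weighted shortest paths between j and k and
  sigma_jk(i) those passing through i.  Edge length is the reciprocal of
  the weight (strong connections are short), geodesics by Dijkstra; paths
  tied within a relative tolerance of the minimum are all counted.

Cross-subject hub tables: centralities are computed per subject, averaged
per structure with inter-subject sample SDs, max-normalized (the top
structure scores exactly 1), and ranked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .build import ConnectivityMatrix

__all__ = [
    "CentralityVector",
    "ShortestPathCache",
    "RankingTable",
    "degree_centrality",
    "eigenvector_centrality",
    "shortest_paths",
    "betweenness_centrality",
    "per_subject_centralities",
    "rank_structures",
    "MEASURES",
]

MEASURES = ("degree", "eigenvector", "betweenness")


@dataclass(frozen=True)
class CentralityVector:
    """Per-node values of one centrality measure, in node order."""

    values: np.ndarray = field(repr=False)
    measure: str = "degree"
    node_labels: np.ndarray = field(repr=False, default=None)
    node_names: tuple[str, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")


@dataclass(frozen=True)
class ShortestPathCache:
    """Pairwise geodesics under inverse-weight edge lengths.

    ``dist[j, k]`` is the Dijkstra distance (inf when disconnected),
    ``sigma[j, k]`` the number of shortest paths (paths within ``rel_tol``
    relative tolerance of the minimum all count; 0 when disconnected,
    1 on the diagonal).
    """

    dist: np.ndarray = field(repr=False)
    sigma: np.ndarray = field(repr=False)
    rel_tol: float = 1e-9

    def sigma_through(self, i: int) -> np.ndarray:
        """Counts sigma_jk(i) of shortest j-k paths with i interior.

        Uses the Bellman decomposition sigma_jk(i) = sigma_ji * sigma_ik
        when d(j,i) + d(i,k) equals d(j,k) (within tolerance), else 0.
        """
        d, s = self.dist, self.sigma
        on_path = np.isfinite(d[:, i][:, None] + d[i, :][None, :]) & (
            d[:, i][:, None] + d[i, :][None, :] <= d * (1.0 + self.rel_tol)
        )
        out = np.where(on_path, s[:, i][:, None] * s[i, :][None, :], 0.0)
        out[i, :] = 0.0
        out[:, i] = 0.0
        np.fill_diagonal(out, 0.0)
        return out


@dataclass(frozen=True)
class RankingTable:
    """Structures ranked by cross-subject mean centrality.

    Columns: measure, name, mean, sd, normalized_mean (mean / max mean, so
    the top row is exactly 1), sd_normalized, rank (1-based).  Rows sorted
    by mean descending, ties broken lexicographically by name.
    """

    rows: pd.DataFrame = field(repr=False)
    measure: str = "degree"
    n_nodes: int = 0

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.rows.head(k)

    @property
    def first_name(self) -> str:
        return str(self.rows.iloc[0]["name"])


# ---------------------------------------------------------------------------


def degree_centrality(matrix: ConnectivityMatrix) -> CentralityVector:
    """Node strength: row sums of the weight matrix."""
    return CentralityVector(
        values=matrix.weights.sum(axis=1),
        measure="degree",
        node_labels=matrix.node_labels,
        node_names=matrix.node_names,
    )


def eigenvector_centrality(
    matrix: ConnectivityMatrix, tol: float = 1e-12, max_iter: int = 10_000
) -> CentralityVector:
    """Perron eigenvector of the adjacency, max component rescaled to 1.

    Power iteration on the (largest) connected component; all components are
    non-negative by Perron–Frobenius.  Disconnected matrices trigger a
    warning and zeros outside the largest component.
    """
    w = matrix.weights
    n = w.shape[0]
    n_comp, comp = connected_components(csr_matrix(w), directed=False)
    values = np.zeros(n)
    if n_comp > 1:
        warnings.warn(
            "adjacency is disconnected; eigenvector centrality computed on "
            "the largest component, zeros elsewhere",
            stacklevel=2,
        )
    sizes = np.bincount(comp)
    main = np.nonzero(comp == sizes.argmax())[0]
    a = w[np.ix_(main, main)]
    if a.sum() == 0:
        raise ValueError("largest component has no edges; eigenvector undefined")

    # diagonal shift keeps the Perron vector but breaks the +/-lambda
    # degeneracy of bipartite graphs that stalls plain power iteration
    shift = a.sum(axis=1).max()
    a_shifted = a + shift * np.eye(len(main))
    x = np.full(len(main), 1.0 / np.sqrt(len(main)))
    for _ in range(max_iter):
        y = a_shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(f"eigenvector power iteration did not converge in {max_iter}")
    x = np.abs(x)
    values[main] = x / x.max()
    return CentralityVector(
        values=values,
        measure="eigenvector",
        node_labels=matrix.node_labels,
        node_names=matrix.node_names,
    )


def _length_graph(weights: np.ndarray) -> csr_matrix:
    """Sparse graph of edge lengths 1/weight; zero weight = absent edge."""
    n = weights.shape[0]
    ii, jj = np.nonzero(weights)
    lengths = 1.0 / weights[ii, jj]
    return csr_matrix((lengths, (ii, jj)), shape=(n, n))


def shortest_paths(matrix: ConnectivityMatrix, rel_tol: float = 1e-9) -> ShortestPathCache:
    """All-pairs Dijkstra distances and tolerance-aware shortest-path counts."""
    w = matrix.weights
    n = w.shape[0]
    graph = _length_graph(w)
    dist = dijkstra(graph, directed=False)

    lengths = np.full((n, n), np.inf)
    ii, jj = np.nonzero(w)
    lengths[ii, jj] = 1.0 / w[ii, jj]

    sigma = np.zeros((n, n))
    for s in range(n):
        ds = dist[s]
        # tight edges u->v lie on some shortest path from s
        reach = np.isfinite(ds)
        tight = (ds[:, None] + lengths) <= ds[None, :] * (1.0 + rel_tol)
        tight &= reach[:, None] & reach[None, :]
        tight[:, s] = False
        # count tight-edge paths from s by repeated propagation (the tight
        # graph is a DAG ordered by distance, so this terminates)
        x = np.zeros(n)
        x[s] = 1.0
        acc = x.copy()
        for _ in range(n):
            x = tight.T @ x
            if not x.any():
                break
            acc += x
        sigma[s] = acc
    return ShortestPathCache(dist=dist, sigma=sigma, rel_tol=rel_tol)


def betweenness_centrality(
    matrix: ConnectivityMatrix, cache: ShortestPathCache | None = None
) -> CentralityVector:
    """Fraction of weighted geodesics through each node, normalized so a
    star center scores exactly 1 (prefactor 2/((N-1)(N-2)), unordered
    pairs, endpoints excluded)."""
    n = matrix.n_nodes
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    cache = cache or shortest_paths(matrix)
    sigma = cache.sigma
    values = np.zeros(n)
    triu = np.triu(np.ones((n, n), dtype=bool), 1)
    connected = triu & (sigma > 0)
    for i in range(n):
        through = cache.sigma_through(i)
        mask = connected.copy()
        mask[i, :] = False
        mask[:, i] = False
        values[i] = np.sum(through[mask] / sigma[mask])
    values *= 2.0 / ((n - 1) * (n - 2))
    return CentralityVector(
        values=values,
        measure="betweenness",
        node_labels=matrix.node_labels,
        node_names=matrix.node_names,
    )


_DISPATCH = {
    "degree": degree_centrality,
    "eigenvector": eigenvector_centrality,
    "betweenness": betweenness_centrality,
}


def per_subject_centralities(
    matrices: list[ConnectivityMatrix], measure: str
) -> list[CentralityVector]:
    """Apply one measure independently to each subject's matrix."""
    if measure not in _DISPATCH:
        raise ValueError(f"unknown measure {measure!r}")
    out = []
    for k, m in enumerate(matrices):
        try:
            out.append(_DISPATCH[measure](m))
        except Exception as exc:
            raise RuntimeError(f"{measure} failed for subject {k}: {exc}") from exc
    return out


def rank_structures(per_subject: list[CentralityVector]) -> RankingTable:
    """Cross-subject mean/SD per structure, max-normalized and ranked."""
    if not per_subject:
        raise ValueError("need at least one subject")
    measure = per_subject[0].measure
    names = per_subject[0].node_names
    stack = np.array([v.values for v in per_subject])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(per_subject) >= 2 else np.zeros_like(mean)
    top = mean.max()
    if top <= 0:
        raise ValueError("all structures have zero mean centrality")
    df = pd.DataFrame(
        {
            "measure": measure,
            "name": list(names),
            "mean": mean,
            "sd": sd,
            "normalized_mean": mean / top,
            "sd_normalized": sd / top,
        }
    )
    df = df.sort_values(
        ["mean", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return RankingTable(rows=df, measure=measure, n_nodes=len(names))
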