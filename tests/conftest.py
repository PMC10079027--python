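"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use different machinery from the implementation:
dense eigendecomposition (numpy.linalg.eigh) instead of power iteration,
Floyd-Warshall (scipy) instead of Dijkstra, and exhaustive simple-path
enumeration instead of DAG counting, so agreement is a real cross-check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from structconn.build import ConnectivityMatrix

REL_TOL = 1e-9


def as_cm(weights, kind: str = "raw") -> ConnectivityMatrix:
    """Wrap a plain array as a ConnectivityMatrix with labels 1..n."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    return ConnectivityMatrix(
        weights=w,
        node_labels=np.arange(1, n + 1, dtype=np.int64),
        node_names=tuple(f"n{i:02d}" for i in range(n)),
        kind=kind,
    )


def random_weights(rng: np.random.Generator, n: int, p_edge: float = 0.6,
                   pool=None) -> np.ndarray:
    """Random symmetric non-negative weight matrix with zero diagonal.

    Drawing weights from a small dyadic pool makes tied shortest paths
    exactly representable, exercising the tie-counting logic without
    floating-point fragility.
    """
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                if pool is not None:
                    w[i, j] = pool[rng.integers(len(pool))]
                else:
                    w[i, j] = float(rng.uniform(0.2, 3.0))
                w[j, i] = w[i, j]
    return w


# -- oracles -----------------------------------------------------------------


def oracle_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs geodesic distances under 1/weight edge lengths."""
    n = weights.shape[0]
    ii, jj = np.nonzero(weights)
    lengths = csr_matrix((1.0 / weights[ii, jj], (ii, jj)), shape=(n, n))
    return floyd_warshall(lengths, directed=False)


def oracle_path_counts(weights: np.ndarray, rel_tol: float = REL_TOL):
    """Exhaustive simple-path enumeration: (dist, sigma, sigma_through).

    sigma_through[i][j, k] counts minimal paths j->k with i strictly
    interior.  Only sensible for n <= ~7.
    """
    n = weights.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    through = np.zeros((n, n, n))
    nodes = list(range(n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            paths = []
            others = [x for x in nodes if x not in (j, k)]
            for r in range(len(others) + 1):
                for mids in permutations(others, r):
                    seq = (j, *mids, k)
                    ws = [weights[a, b] for a, b in zip(seq, seq[1:])]
                    if all(w > 0 for w in ws):
                        paths.append((sum(1.0 / w for w in ws), seq))
            if not paths:
                continue
            best = min(p[0] for p in paths)
            minimal = [seq for d, seq in paths if d <= best * (1.0 + rel_tol)]
            dist[j, k] = best
            sigma[j, k] = len(minimal)
            for seq in minimal:
                for mid in seq[1:-1]:
                    through[mid, j, k] += 1
    return dist, sigma, through


def oracle_betweenness(weights: np.ndarray, rel_tol: float = REL_TOL) -> np.ndarray:
    """Eq-style betweenness from exhaustive path enumeration."""
    n = weights.shape[0]
    _, sigma, through = oracle_path_counts(weights, rel_tol)
    b = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or sigma[j, k] == 0:
                    continue
                b[i] += through[i, j, k] / sigma[j, k]
    return b * 2.0 / ((n - 1) * (n - 2))


def oracle_eigenvector(weights: np.ndarray) -> np.ndarray:
    """Dense symmetric eigensolve, Perron vector scaled to max 1."""
    vals, vecs = np.linalg.eigh(weights)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def is_connected(weights: np.ndarray) -> bool:
    return np.isfinite(oracle_distances(weights)).all()


# -- a small shared synthetic world -----------------------------------------


@pytest.fixture(scope="session")
def small_world():
    """One modest synthetic dataset shared by read-only tests."""
    import structconn as sc

    parc = sc.make_parcellation(12, 1, seed=11)
    vol = sc.make_label_volume(parc, (14, 14, 14), seed=12)
    gt = sc.make_ground_truth_matrix(parc)
    records = sc.generate_ensemble(gt, vol, 3, 2, 1500, 0.2, seed=13)
    return parc, vol, gt, records
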