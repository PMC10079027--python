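"""Build weighted connectivity matrices from streamline endpoint records.

Each streamline contributes one count to a_ij and one to a_ji, where i and j
are the parcellation labels its two endpoints fall into (a bi-directional
label map, so matrices are symmetric by construction).  Records are discarded
— and tallied by reason — when an endpoint lands in background, outside the
requested label subset, or when both endpoints share a label (self-loops are
excluded; the centrality definitions downstream assume a zero diagonal).

Run-level matrices are averaged per subject, subject-level matrices averaged
into an overarching connectome with elementwise inter-subject standard
deviations.  Restricted connectomes can be formed three ways: dropping
matrix rows/columns (``submatrix``), rebuilding from records whose endpoints
survive (``endpoint_filter``), or additionally discarding records that
traverse a removed structure (``traversal_filter`` — the analogue of
re-running tractography with an altered white-matter mask, which is how a
removed relay structure severs routes whose endpoints it does not touch).
Volume normalization divides each weight by the summed volumes of its two
endpoint structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .parcellation import Parcellation
from .synthetic import EndpointRecordSet, LabelVolume

__all__ = [
    "ConnectivityMatrix",
    "BuildResult",
    "EnsembleStats",
    "assign_endpoint_label",
    "assign_endpoint_labels",
    "build_matrix",
    "average_runs",
    "average_subjects",
    "restrict",
    "volume_normalize",
]

KINDS = ("raw", "run_mean", "subject_mean", "volume_normalized")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric non-negative weighted adjacency over a parcellation subset.

    ``node_labels`` fixes the node order (a subsequence of the generating
    parcellation's canonical order); ``kind`` records provenance.
    """

    weights: np.ndarray = field(repr=False)
    node_labels: np.ndarray = field(repr=False)
    node_names: tuple[str, ...] = field(repr=False)
    kind: str = "raw"

    def __post_init__(self) -> None:
        w = self.weights
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if len(self.node_names) != n:
            raise ValueError("node_names length mismatch")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not np.allclose(w, w.T, rtol=0.0, atol=1e-9 * max(1.0, np.abs(w).max())):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class BuildResult:
    """A built matrix plus the accounting of kept/discarded records."""

    matrix: ConnectivityMatrix
    kept: int
    discarded: dict[str, int]


@dataclass(frozen=True)
class EnsembleStats:
    """Cross-subject mean matrix and elementwise sample SD (ddof=1)."""

    mean_matrix: ConnectivityMatrix
    sd_matrix: np.ndarray | None = field(repr=False, default=None)
    n_subjects: int = 1
    n_runs: int = 1


# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def assign_endpoint_labels(points: np.ndarray, label_volume: LabelVolume) -> np.ndarray:
    """Map world-mm points to parcellation labels (0 = background).

    Points go through the inverse affine to continuous voxel coordinates,
    are rounded half-away-from-zero to the nearest 0-based voxel index, and
    looked up in the grid; out-of-bounds indices map to 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("endpoint coordinates must be finite")
    inv = np.linalg.inv(label_volume.affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    idx = _round_half_away(vox).astype(np.int64)
    shape = np.array(label_volume.grid.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    labels = np.zeros(len(points), dtype=np.int64)
    ii = idx[inside]
    labels[inside] = label_volume.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
    return labels


def assign_endpoint_label(point, label_volume: LabelVolume) -> int:
    """Single-point convenience wrapper around :func:`assign_endpoint_labels`."""
    return int(assign_endpoint_labels(np.asarray(point, dtype=float), label_volume)[0])


def build_matrix(
    endpoints: EndpointRecordSet,
    label_volume: LabelVolume,
    parcellation_subset: Parcellation,
    drop_traversing: set[int] | frozenset[int] | None = None,
) -> BuildResult:
    """Accumulate endpoint records into a symmetric streamline-count matrix.

    A record is discarded (and tallied) if either endpoint is background
    (``background``), falls outside the subset (``outside_subset``), if its
    traversed set intersects ``drop_traversing`` (``traversal``), or if both
    endpoints share a label (``self_pair``).  Every kept record adds 1 to
    both a_ij and a_ji.
    """
    labels = parcellation_subset.labels
    n = len(labels)
    w = np.zeros((n, n), dtype=float)
    tally = {"background": 0, "outside_subset": 0, "traversal": 0, "self_pair": 0}

    if len(endpoints) > 0:
        la = assign_endpoint_labels(endpoints.first_points, label_volume)
        lb = assign_endpoint_labels(endpoints.last_points, label_volume)
        background = (la == 0) | (lb == 0)
        in_subset = np.isin(la, labels) & np.isin(lb, labels)
        drop = frozenset(drop_traversing or ())
        if drop:
            traverses = np.fromiter(
                (bool(t & drop) for t in endpoints.traversed),
                dtype=bool, count=len(endpoints),
            )
        else:
            traverses = np.zeros(len(endpoints), dtype=bool)
        # discard reasons are checked in a fixed priority order
        d_bg = background
        d_out = ~d_bg & ~in_subset
        d_trav = ~d_bg & in_subset & traverses
        d_self = ~d_bg & in_subset & ~traverses & (la == lb)
        keep = ~(d_bg | d_out | d_trav | d_self)
        tally["background"] = int(d_bg.sum())
        tally["outside_subset"] = int(d_out.sum())
        tally["traversal"] = int(d_trav.sum())
        tally["self_pair"] = int(d_self.sum())

        if keep.any():
            order = np.argsort(labels)
            sorted_labels = labels[order]
            ia = order[np.searchsorted(sorted_labels, la[keep])]
            ib = order[np.searchsorted(sorted_labels, lb[keep])]
            np.add.at(w, (ia, ib), 1.0)
            np.add.at(w, (ib, ia), 1.0)

    kept = len(endpoints) - sum(tally.values())
    matrix = ConnectivityMatrix(
        weights=w,
        node_labels=labels.copy(),
        node_names=tuple(parcellation_subset.names),
        kind="raw",
    )
    return BuildResult(matrix=matrix, kept=kept, discarded=tally)


def _check_aligned(matrices: list[ConnectivityMatrix]) -> None:
    if not matrices:
        raise ValueError("need at least one matrix")
    ref = matrices[0].node_labels
    for m in matrices[1:]:
        if not np.array_equal(m.node_labels, ref):
            raise ValueError("matrices have mismatched node sets")


def average_runs(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise arithmetic mean over runs of one subject."""
    _check_aligned(matrices)
    mean = np.mean([m.weights for m in matrices], axis=0)
    return replace(matrices[0], weights=mean, kind="run_mean")


def average_subjects(per_subject: list[ConnectivityMatrix], n_runs: int = 1) -> EnsembleStats:
    """Cross-subject mean and elementwise sample SD (undefined for n=1)."""
    _check_aligned(per_subject)
    stack = np.array([m.weights for m in per_subject])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(per_subject) >= 2 else None
    mean_matrix = replace(per_subject[0], weights=mean, kind="subject_mean")
    return EnsembleStats(
        mean_matrix=mean_matrix, sd_matrix=sd,
        n_subjects=len(per_subject), n_runs=n_runs,
    )


def restrict(
    source,
    keep_labels,
    mode: str = "traversal_filter",
    *,
    label_volume: LabelVolume | None = None,
    parcellation: Parcellation | None = None,
):
    """Form a restricted connectome.

    ``submatrix`` takes ``source`` as a :class:`ConnectivityMatrix` and drops
    rows/columns.  ``endpoint_filter`` and ``traversal_filter`` take
    ``source`` as an :class:`EndpointRecordSet` (plus ``label_volume`` and
    the full ``parcellation``) and rebuild; the traversal variant also drops
    records whose traversed labels intersect the removed set, emulating
    tracking with an altered mask.  Returns a :class:`ConnectivityMatrix`
    for ``submatrix`` and a :class:`BuildResult` otherwise.
    """
    keep = sorted(int(x) for x in keep_labels)
    if not keep:
        raise ValueError("keep_labels must be non-empty")

    if mode == "submatrix":
        if not isinstance(source, ConnectivityMatrix):
            raise TypeError("submatrix mode needs a ConnectivityMatrix")
        current = source.node_labels.tolist()
        unknown = set(keep) - set(current)
        if unknown:
            raise ValueError(f"keep_labels not a subset: {sorted(unknown)}")
        sel = np.array([i for i, lab in enumerate(current) if lab in set(keep)])
        return replace(
            source,
            weights=source.weights[np.ix_(sel, sel)],
            node_labels=source.node_labels[sel],
            node_names=tuple(source.node_names[i] for i in sel),
        )

    if mode not in ("endpoint_filter", "traversal_filter"):
        raise ValueError(f"unknown restriction mode {mode!r}")
    if label_volume is None or parcellation is None:
        raise ValueError(f"{mode} needs label_volume and parcellation")
    sub = parcellation.subset(keep)
    removed = (
        frozenset(parcellation.labels.tolist()) - frozenset(keep)
        if mode == "traversal_filter"
        else None
    )
    return build_matrix(source, label_volume, sub, drop_traversing=removed)


def volume_normalize(matrix: ConnectivityMatrix, volumes: dict[int, float]) -> ConnectivityMatrix:
    """Divide each weight by the summed volumes (mm^3) of its two nodes."""
    vols = np.array(
        [volumes.get(int(lab), np.nan) for lab in matrix.node_labels], dtype=float
    )
    if np.any(~np.isfinite(vols)) or np.any(vols <= 0):
        bad = matrix.node_labels[~np.isfinite(vols) | (vols <= 0)]
        raise ValueError(f"missing or non-positive volume for labels {bad.tolist()}")
    denom = vols[:, None] + vols[None, :]
    w = matrix.weights / denom
    np.fill_diagonal(w, 0.0)
    return replace(matrix, weights=w, kind="volume_normalized")
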