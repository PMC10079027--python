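"""Synthetic multi-subject streamline-endpoint generator.

Real structural connectomes are built from diffusion-MRI tractography: a
fibre-tracking algorithm emits streamlines, and only the two endpoints of
each streamline (looked up in a parcellation label volume) enter the
connectivity matrix.  This module emulates the *output* of that process at
desk scale so every downstream stage can be exercised and tested without
non-redistributable subject data:

* a parcellation with two "hemisphere" community blocks and a "subcortical"
  block that contains one or more dominant hub structures (brainstem-like);
* a voxel label volume partitioning a brain-like ellipsoid by Voronoi
  assignment, voxel counts roughly proportional to structure volumes;
* a planted-hub block model over unordered region pairs: within-community
  pairs get weight ``w_in``, between-community pairs ``w_out``, any pair
  touching a hub is boosted by ``hub_boost``, and the whole matrix is
  normalized to unit mass over unordered pairs — this is the ground-truth
  connection-probability matrix;
* per-streamline endpoint records sampled from that matrix, with endpoint
  coordinates drawn uniformly over the region's voxels, plus a traversal
  label set (every between-community pair routes through one hub, emulating
  streamlines that pass over subcortical structures and are lost when the
  tracking mask removes them);
* multi-subject / multi-run ensembles with multiplicative lognormal
  inter-subject noise on the pair weights.

No diffusion signal, fibre-orientation distributions, or curved streamline
geometry is simulated: endpoints and traversal sets are all the downstream
analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .parcellation import Parcellation

__all__ = [
    "LabelVolume",
    "GroundTruth",
    "EndpointRecordSet",
    "VolumeSpec",
    "make_parcellation",
    "make_label_volume",
    "make_ground_truth_matrix",
    "sample_endpoints",
    "generate_ensemble",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class LabelVolume:
    """3-D integer label lattice plus a voxel-index -> world-mm affine."""

    grid: np.ndarray = field(repr=False)
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @cached_property
    def voxels_by_label(self) -> dict[int, np.ndarray]:
        """Map label_id -> (k, 3) array of voxel indices carrying it."""
        flat = self.grid.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_vals = flat[order]
        uniq, starts = np.unique(sorted_vals, return_index=True)
        coords = np.column_stack(np.unravel_index(order, self.grid.shape))
        out: dict[int, np.ndarray] = {}
        bounds = np.append(starts, len(flat))
        for v, a, b in zip(uniq, bounds[:-1], bounds[1:]):
            if v != 0:
                out[int(v)] = coords[a:b]
        return out

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Apply the affine to (n, 3) voxel indices."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class GroundTruth:
    """Planted-hub block model: the connection-probability matrix endpoint
    sampling draws from, plus the community/hub/traversal bookkeeping."""

    prob_matrix: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)       # node order, label ids
    community_of: np.ndarray = field(repr=False)  # per node, aligned to labels
    hub_labels: np.ndarray = field(repr=False)
    traversal_sets: dict[tuple[int, int], frozenset] = field(repr=False)

    def __post_init__(self) -> None:
        p = self.prob_matrix
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("prob_matrix must be symmetric")
        if np.any(np.diag(p) != 0):
            raise ValueError("prob_matrix must have zero diagonal")
        if np.any(p < 0):
            raise ValueError("prob_matrix entries must be non-negative")
        mass = np.triu(p, 1).sum()
        if abs(mass - 1.0) > 1e-12:
            raise ValueError(f"pair mass must be 1, got {mass}")


@dataclass(frozen=True)
class EndpointRecordSet:
    """First/last world-mm points of each streamline for one (subject, run),
    with optional traversed-label sets."""

    first_points: np.ndarray = field(repr=False)
    last_points: np.ndarray = field(repr=False)
    traversed: tuple[frozenset, ...] = field(repr=False)
    subject_id: int = 0
    run_id: int = 0

    def __post_init__(self) -> None:
        n = len(self.first_points)
        if self.last_points.shape != (n, 3) or self.first_points.shape != (n, 3):
            raise ValueError("endpoint arrays must be (n, 3)")
        if len(self.traversed) != n:
            raise ValueError("traversed must have one entry per record")

    def __len__(self) -> int:
        return len(self.first_points)


@dataclass(frozen=True)
class VolumeSpec:
    """Lognormal volume model: volumes = median * exp(sigma * z); hub
    structures get exactly ``hub_multiplier * median`` (largest in the table
    whenever the multiplier exceeds the dispersion-adjusted maximum)."""

    median_mm3: float = 3000.0
    sigma: float = 0.4
    hub_multiplier: float = 3.0


# ---------------------------------------------------------------------------
# generators


def make_parcellation(
    n_regions: int,
    n_hubs: int = 1,
    volume_spec: VolumeSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> Parcellation:
    """Generate a parcellation with hemisphere blocks and a subcortical block.

    Communities: two "hemisphere" blocks of cortical regions plus, when hubs
    or spare regions exist, a "subcortical" block containing all hubs.
    Volumes are lognormal; hubs get ``hub_multiplier * median``.
    Deterministic for a fixed seed.
    """
    if n_regions < 3:
        raise ValueError("n_regions must be >= 3")
    if not 0 <= n_hubs < n_regions:
        raise ValueError("need 0 <= n_hubs < n_regions")
    spec = volume_spec or VolumeSpec()
    rng = np.random.default_rng(seed)

    n_rest = n_regions - n_hubs
    n_subcort_extra = int(round(0.15 * n_rest)) if n_rest >= 8 else 0
    n_cortical = n_rest - n_subcort_extra
    n_left = (n_cortical + 1) // 2
    n_right = n_cortical - n_left

    names: list[str] = []
    communities: list[int] = []
    is_hub: list[bool] = []
    for k in range(n_left):
        names.append(f"ctx-lh-{k + 1:03d}")
        communities.append(0)
        is_hub.append(False)
    for k in range(n_right):
        names.append(f"ctx-rh-{k + 1:03d}")
        communities.append(1)
        is_hub.append(False)
    for k in range(n_subcort_extra):
        names.append(f"subcort-{k + 1:03d}")
        communities.append(2)
        is_hub.append(False)
    for k in range(n_hubs):
        names.append(f"hub-{k + 1:02d}")
        communities.append(2 if (n_subcort_extra or n_hubs) else 0)
        is_hub.append(True)

    volumes = spec.median_mm3 * np.exp(spec.sigma * rng.standard_normal(n_regions))
    hub_mask = np.array(is_hub)
    volumes[hub_mask] = spec.hub_multiplier * spec.median_mm3

    table = pd.DataFrame(
        {
            "label_id": np.arange(1, n_regions + 1, dtype=np.int64),
            "name": names,
            "volume_mm3": volumes,
            "is_hub": hub_mask,
            "community": np.array(communities, dtype=np.int64),
        }
    )
    return Parcellation(table)


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Brain-like mask: voxel centers inside the inscribed ellipsoid."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0 - 0.25, 0.5) for s in shape]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    return (ii / semi[0]) ** 2 + (jj / semi[1]) ** 2 + (kk / semi[2]) ** 2 <= 1.0


def make_label_volume(
    parcellation: Parcellation,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    affine: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> LabelVolume:
    """Partition a brain-like ellipsoid into regions by nearest-seed-point
    (Voronoi) assignment.

    Each region receives a number of seed points roughly proportional to its
    volume (at least one), so voxel counts track parcellation volumes.
    Voxels outside the ellipsoid are background (0).
    """
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(grid_shape)
    in_voxels = np.column_stack(np.nonzero(mask))
    n_regions = parcellation.n_regions
    if len(in_voxels) < n_regions:
        raise ValueError(
            f"grid {grid_shape} has only {len(in_voxels)} voxels inside the "
            f"mask for {n_regions} regions"
        )

    vols = parcellation.volumes
    budget = min(len(in_voxels), max(16 * n_regions, 256))
    raw = vols / vols.sum() * budget
    counts = np.maximum(1, np.floor(raw).astype(int))
    # largest-remainder top-up within budget
    short = budget - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - np.floor(raw)), kind="stable")
        counts[order[:short]] += 1
    n_seeds = counts.sum()

    pick = rng.choice(len(in_voxels), size=min(n_seeds, len(in_voxels)), replace=False)
    seed_voxels = in_voxels[pick]
    seed_region = np.repeat(np.arange(n_regions), counts)[: len(seed_voxels)]
    # every region keeps at least its first seed point even if truncated
    if len(np.unique(seed_region)) < n_regions:  # pragma: no cover - tiny grids
        firsts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        seed_voxels = in_voxels[rng.choice(len(in_voxels), n_regions, replace=False)]
        seed_region = np.arange(n_regions)

    tree = cKDTree(seed_voxels)
    _, nearest = tree.query(in_voxels)
    grid = np.zeros(grid_shape, dtype=np.int16)
    labels = parcellation.labels
    grid[tuple(in_voxels.T)] = labels[seed_region[nearest]].astype(np.int16)

    aff = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    return LabelVolume(grid=grid, affine=aff)


def make_ground_truth_matrix(
    parcellation: Parcellation,
    w_in: float = 2.0,
    w_out: float = 1.0,
    hub_boost: float = 3.0,
    seed: int | None = None,
) -> GroundTruth:
    """Planted-hub block-model connection probabilities.

    Pair weight is ``w_in`` within a community, ``w_out`` between, times
    ``hub_boost`` when either member is a hub; weights are normalized to unit
    total mass over unordered pairs.  Every between-community pair gets a
    traversal set holding one hub id, so removing that hub from the tracking
    mask severs all between-community routes.  The model is deterministic;
    ``seed`` is accepted for interface symmetry.
    """
    del seed
    if not (w_in > w_out > 0):
        raise ValueError("need w_in > w_out > 0")
    if hub_boost < 1:
        raise ValueError("hub_boost must be >= 1")
    n = parcellation.n_regions
    if n < 2:
        raise ValueError("need at least two regions")

    comm = parcellation.communities
    same = comm[:, None] == comm[None, :]
    w = np.where(same, w_in, w_out).astype(float)
    hubs = parcellation.hub_labels
    hub_idx = np.isin(parcellation.labels, hubs)
    touches_hub = hub_idx[:, None] | hub_idx[None, :]
    w[touches_hub] *= hub_boost
    np.fill_diagonal(w, 0.0)
    w /= np.triu(w, 1).sum()

    traversal: dict[tuple[int, int], frozenset] = {}
    labels = parcellation.labels
    route_hub = frozenset({int(hubs.min())}) if len(hubs) else frozenset()
    for a in range(n):
        for b in range(a + 1, n):
            key = (int(labels[a]), int(labels[b]))
            traversal[key] = route_hub if comm[a] != comm[b] else frozenset()

    return GroundTruth(
        prob_matrix=w,
        labels=labels.copy(),
        community_of=comm.copy(),
        hub_labels=hubs.copy(),
        traversal_sets=traversal,
    )


def sample_endpoints(
    ground_truth: GroundTruth,
    label_volume: LabelVolume,
    n_streamlines: int,
    seed: int | np.random.Generator = 0,
    subject_id: int = 0,
    run_id: int = 0,
) -> EndpointRecordSet:
    """Draw streamline endpoint records from the ground-truth pair law.

    Each record samples an unordered label pair from ``prob_matrix``, then an
    endpoint voxel uniformly within each label (mapped to world mm through
    the affine); endpoint orientation and record order are randomized.
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    rng = np.random.default_rng(seed)
    labels = ground_truth.labels
    n = len(labels)
    iu, ju = np.triu_indices(n, 1)
    p = ground_truth.prob_matrix[iu, ju]
    p = p / p.sum()

    pair_idx = rng.choice(len(p), size=n_streamlines, p=p)
    a_lab = labels[iu[pair_idx]]
    b_lab = labels[ju[pair_idx]]

    def draw_voxels(lab_arr: np.ndarray) -> np.ndarray:
        out = np.empty((len(lab_arr), 3), dtype=float)
        for lab in np.unique(lab_arr):
            vox = label_volume.voxels_by_label.get(int(lab))
            if vox is None or len(vox) == 0:
                raise ValueError(f"label {lab} has no voxels")
            where = np.nonzero(lab_arr == lab)[0]
            out[where] = vox[rng.integers(0, len(vox), size=len(where))]
        return out

    a_vox = draw_voxels(a_lab)
    b_vox = draw_voxels(b_lab)
    flip = rng.random(n_streamlines) < 0.5
    first_vox = np.where(flip[:, None], b_vox, a_vox)
    last_vox = np.where(flip[:, None], a_vox, b_vox)

    traversed = tuple(
        ground_truth.traversal_sets.get((int(a), int(b)), frozenset())
        for a, b in zip(a_lab, b_lab)
    )
    order = rng.permutation(n_streamlines)
    return EndpointRecordSet(
        first_points=label_volume.voxel_to_world(first_vox)[order],
        last_points=label_volume.voxel_to_world(last_vox)[order],
        traversed=tuple(traversed[i] for i in order),
        subject_id=subject_id,
        run_id=run_id,
    )


def generate_ensemble(
    ground_truth: GroundTruth,
    label_volume: LabelVolume,
    n_subjects: int,
    n_runs: int,
    n_streamlines: int,
    subject_noise_sd: float = 0.2,
    seed: int = 0,
) -> list[EndpointRecordSet]:
    """Multi-subject, multi-run endpoint ensembles.

    Each subject's pair weights are the ground-truth weights perturbed by
    independent multiplicative lognormal noise (sd of the log equal to
    ``subject_noise_sd``) and renormalized; each run then samples endpoints
    independently from the subject's matrix.  Returns ``n_subjects * n_runs``
    record sets tagged with (subject_id, run_id).
    """
    if n_subjects < 1 or n_runs < 1:
        raise ValueError("n_subjects and n_runs must be >= 1")
    if subject_noise_sd < 0:
        raise ValueError("subject_noise_sd must be non-negative")

    ss = np.random.SeedSequence(seed)
    out: list[EndpointRecordSet] = []
    for subj, subj_ss in enumerate(ss.spawn(n_subjects)):
        noise_ss, *run_ss = subj_ss.spawn(n_runs + 1)
        p = ground_truth.prob_matrix
        if subject_noise_sd > 0:
            rng = np.random.default_rng(noise_ss)
            n = p.shape[0]
            iu, ju = np.triu_indices(n, 1)
            factors = np.exp(subject_noise_sd * rng.standard_normal(len(iu)))
            w = np.zeros_like(p)
            w[iu, ju] = p[iu, ju] * factors
            w = w + w.T
            w /= np.triu(w, 1).sum()
            p = w
        subj_gt = GroundTruth(
            prob_matrix=p,
            labels=ground_truth.labels,
            community_of=ground_truth.community_of,
            hub_labels=ground_truth.hub_labels,
            traversal_sets=ground_truth.traversal_sets,
        )
        for run, r_ss in enumerate(run_ss):
            out.append(
                sample_endpoints(
                    subj_gt,
                    label_volume,
                    n_streamlines,
                    seed=np.random.default_rng(r_ss),
                    subject_id=subj,
                    run_id=run,
                )
            )
    return out
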