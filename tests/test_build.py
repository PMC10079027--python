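"""Matrix construction, averaging, restriction and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import structconn as sc
from structconn.build import ConnectivityMatrix
from structconn.synthetic import EndpointRecordSet, LabelVolume

from conftest import as_cm


def tiny_parcellation(n: int) -> sc.Parcellation:
    return sc.Parcellation(
        pd.DataFrame(
            {
                "label_id": range(1, n + 1),
                "name": [f"r{i}" for i in range(n)],
                "volume_mm3": [100.0] * n,
                "is_hub": [False] * n,
                "community": [0] * n,
            }
        )
    )


def tiny_volume() -> LabelVolume:
    # 3x1x1 grid: voxel (i,0,0) carries label i+1
    grid = np.array([[[1]], [[2]], [[3]]], dtype=np.int16)
    return LabelVolume(grid=grid, affine=np.eye(4))


def records_from_pairs(pairs, traversed=None) -> EndpointRecordSet:
    """Endpoint records whose endpoints sit exactly on voxels of the given
    label pairs (labels 1..3 in the tiny volume)."""
    first = np.array([[a - 1, 0, 0] for a, _ in pairs], dtype=float)
    last = np.array([[b - 1, 0, 0] for _, b in pairs], dtype=float)
    trav = tuple(traversed or [frozenset()] * len(pairs))
    return EndpointRecordSet(first_points=first, last_points=last, traversed=trav)


class TestAssignEndpointLabel:
    def test_rounding_half_away_from_zero(self):
        grid = np.zeros((4, 4, 4), dtype=np.int16)
        grid[2, 1, 2] = 7
        vol = LabelVolume(grid=grid, affine=np.eye(4))
        assert sc.assign_endpoint_label((1.5, 0.9, 2.0), vol) == 7

    def test_out_of_bounds_is_background(self):
        vol = tiny_volume()
        assert sc.assign_endpoint_label((5.0, 0.0, 0.0), vol) == 0
        assert sc.assign_endpoint_label((-1.0, 0.0, 0.0), vol) == 0

    def test_anisotropic_affine(self):
        vol = LabelVolume(grid=tiny_volume().grid, affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        assert sc.assign_endpoint_label((4.0, 0.0, 0.0), vol) == 3

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sc.assign_endpoint_label((np.nan, 0, 0), tiny_volume())


class TestBuildMatrix:
    def test_counting_and_symmetry(self):
        res = sc.build_matrix(
            records_from_pairs([(1, 2), (2, 1), (2, 3)]), tiny_volume(), tiny_parcellation(3)
        )
        w = res.matrix.weights
        assert w[0, 1] == w[1, 0] == 2
        assert w[1, 2] == w[2, 1] == 1
        assert res.kept == 3

    def test_background_discarded(self):
        rs = EndpointRecordSet(
            first_points=np.array([[10.0, 0, 0]]),
            last_points=np.array([[1.0, 0, 0]]),
            traversed=(frozenset(),),
        )
        res = sc.build_matrix(rs, tiny_volume(), tiny_parcellation(3))
        assert res.discarded["background"] == 1
        assert res.matrix.total_weight() == 0

    def test_self_pair_discarded(self):
        res = sc.build_matrix(records_from_pairs([(2, 2)]), tiny_volume(), tiny_parcellation(3))
        assert res.discarded["self_pair"] == 1
        assert np.all(np.diag(res.matrix.weights) == 0)

    def test_outside_subset_discarded(self):
        sub = tiny_parcellation(3).subset([1, 2])
        res = sc.build_matrix(records_from_pairs([(1, 3), (1, 2)]), tiny_volume(), sub)
        assert res.discarded["outside_subset"] == 1
        assert res.kept == 1

    def test_conservation(self, small_world):
        parc, vol, gt, records = small_world
        res = sc.build_matrix(records[0], vol, parc)
        assert res.kept + sum(res.discarded.values()) == len(records[0])
        assert res.matrix.total_weight() == 2 * res.kept


class TestAveraging:
    def test_run_mean(self):
        a = as_cm([[0, 2], [2, 0]])
        b = as_cm([[0, 4], [4, 0]])
        m = sc.average_runs([a, b])
        assert np.array_equal(m.weights, [[0, 3], [3, 0]])
        assert m.kind == "run_mean"

    def test_single_matrix_identity(self):
        a = as_cm([[0, 2], [2, 0]])
        assert np.array_equal(sc.average_runs([a]).weights, a.weights)

    def test_subject_mean_and_sd(self):
        a = as_cm([[0, 2], [2, 0]])
        b = as_cm([[0, 4], [4, 0]])
        stats = sc.average_subjects([a, b])
        assert stats.mean_matrix.weights[0, 1] == 3
        assert stats.sd_matrix[0, 1] == pytest.approx(np.sqrt(2))

    def test_single_subject_sd_undefined(self):
        stats = sc.average_subjects([as_cm([[0, 1], [1, 0]])])
        assert stats.sd_matrix is None

    def test_identical_subjects_zero_sd(self):
        a = as_cm([[0, 2], [2, 0]])
        stats = sc.average_subjects([a, a, a])
        assert np.all(stats.sd_matrix == 0)

    def test_mismatched_nodes_rejected(self):
        a = as_cm([[0, 1], [1, 0]])
        b = sc.restrict(as_cm(np.zeros((3, 3))), [1, 3], "submatrix")
        with pytest.raises(ValueError):
            sc.average_runs([a, b])

    def test_degree_commutes_with_averaging(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            w = rng.uniform(0, 5, (4, 4))
            w = np.triu(w, 1)
            mats.append(as_cm(w + w.T))
        mean_deg = np.mean([sc.degree_centrality(m).values for m in mats], axis=0)
        deg_mean = sc.degree_centrality(sc.average_runs(mats)).values
        assert np.allclose(mean_deg, deg_mean)


class TestRestrict:
    def test_submatrix_selection(self):
        m = as_cm([[0, 5, 1], [5, 0, 2], [1, 2, 0]])
        r = sc.restrict(m, [1, 2], "submatrix")
        assert np.array_equal(r.weights, [[0, 5], [5, 0]])
        assert r.node_labels.tolist() == [1, 2]

    def test_submatrix_not_subset_rejected(self):
        with pytest.raises(ValueError):
            sc.restrict(as_cm(np.zeros((2, 2))), [9], "submatrix")

    def test_endpoint_filter_drops_removed_endpoint(self):
        res = sc.restrict(
            records_from_pairs([(1, 3), (1, 2)]),
            [1, 2],
            "endpoint_filter",
            label_volume=tiny_volume(),
            parcellation=tiny_parcellation(3),
        )
        assert res.kept == 1
        assert res.discarded["outside_subset"] == 1

    def test_traversal_filter_vs_endpoint_filter(self):
        # record (1,2) traverses label 3: dropped only under traversal_filter
        rs = records_from_pairs([(1, 2)], traversed=[frozenset({3})])
        kw = dict(label_volume=tiny_volume(), parcellation=tiny_parcellation(3))
        kept_ep = sc.restrict(rs, [1, 2], "endpoint_filter", **kw)
        kept_tr = sc.restrict(rs, [1, 2], "traversal_filter", **kw)
        assert kept_ep.kept == 1
        assert kept_tr.kept == 0
        assert kept_tr.discarded["traversal"] == 1

    def test_submatrix_commutes_with_averaging(self, small_world):
        parc, vol, gt, records = small_world
        mats = [sc.build_matrix(r, vol, parc).matrix for r in records[:3]]
        keep = parc.labels[:5].tolist()
        a = sc.restrict(sc.average_runs(mats), keep, "submatrix")
        b = sc.average_runs([sc.restrict(m, keep, "submatrix") for m in mats])
        assert np.allclose(a.weights, b.weights, atol=1e-12)


class TestVolumeNormalize:
    def test_arithmetic(self):
        m = as_cm([[0, 10], [10, 0]])
        r = sc.volume_normalize(m, {1: 2.0, 2: 3.0})
        assert r.weights[0, 1] == pytest.approx(2.0)
        assert r.kind == "volume_normalized"

    def test_homogeneity_in_volumes(self):
        m = as_cm([[0, 10, 4], [10, 0, 0], [4, 0, 0]])
        vols = {1: 2.0, 2: 3.0, 3: 5.0}
        a = sc.volume_normalize(m, vols).weights
        b = sc.volume_normalize(m, {k: 10 * v for k, v in vols.items()}).weights
        assert np.allclose(b, a / 10)

    def test_missing_volume_rejected(self):
        with pytest.raises(ValueError):
            sc.volume_normalize(as_cm([[0, 1], [1, 0]]), {1: 2.0})

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            sc.volume_normalize(as_cm([[0, 1], [1, 0]]), {1: 2.0, 2: 0.0})


class TestMatrixInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_built_matrices_satisfy_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        w = np.triu(rng.uniform(0, 3, (n, n)), 1)
        m = as_cm(w + w.T)
        assert np.allclose(m.weights, m.weights.T)
        norm = sc.volume_normalize(m, {i: float(rng.uniform(1, 10)) for i in range(1, n + 1)})
        assert np.allclose(norm.weights, norm.weights.T)
        assert np.all(np.diag(norm.weights) == 0)

    def test_asymmetric_rejected(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityMatrix(
                weights=w, node_labels=np.array([1, 2]), node_names=("a", "b")
            )

    def test_negative_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityMatrix(
                weights=w, node_labels=np.array([1, 2]), node_names=("a", "b")
            )
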