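"""Generator contracts: sizes, determinism, planted structure, sampling law."""

import numpy as np
import pandas as pd
import pytest

import structconn as sc
from structconn.synthetic import VolumeSpec


class TestMakeParcellation:
    @pytest.mark.parametrize(
        "n, hubs", [(104, 1), (5, 0), (30, 2), (3, 0)]
    )
    def test_sizes_and_ids(self, n, hubs):
        parc = sc.make_parcellation(n, hubs, seed=7)
        assert parc.n_regions == n
        assert set(parc.labels.tolist()) == set(range(1, n + 1))
        assert len(parc.hub_labels) == hubs
        assert (parc.volumes > 0).all()

    def test_deterministic(self):
        a = sc.make_parcellation(20, 1, seed=42)
        b = sc.make_parcellation(20, 1, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_hubs_sit_with_largest_volumes(self):
        parc = sc.make_parcellation(30, 1, VolumeSpec(sigma=0.4, hub_multiplier=3.0), seed=1)
        hub_vol = parc.table.loc[parc.table.is_hub, "volume_mm3"].iloc[0]
        assert hub_vol == pytest.approx(3.0 * 3000.0)
        assert hub_vol >= parc.volumes.max() * 0.999

    def test_hub_in_subcortical_community(self):
        parc = sc.make_parcellation(30, 1, seed=5)
        hub_comm = parc.table.loc[parc.table.is_hub, "community"].iloc[0]
        assert hub_comm == 2
        assert len(np.unique(parc.communities)) == 3

    @pytest.mark.parametrize("n, hubs", [(2, 0), (5, 5), (5, -1)])
    def test_invalid_sizes_rejected(self, n, hubs):
        with pytest.raises(ValueError):
            sc.make_parcellation(n, hubs)


class TestMakeLabelVolume:
    def test_every_region_present(self):
        parc = sc.make_parcellation(5, 0, seed=1)
        vol = sc.make_label_volume(parc, (16, 16, 16), seed=2)
        present = set(np.unique(vol.grid).tolist()) - {0}
        assert present == set(parc.labels.tolist())

    def test_hub_gets_most_voxels(self):
        # multiplier 5 with sigma 0.3 exceeds the dispersion-adjusted max,
        # so the hub holds the largest volume and should get the most voxels
        parc = sc.make_parcellation(12, 1, VolumeSpec(sigma=0.3, hub_multiplier=5.0), seed=3)
        vol = sc.make_label_volume(parc, (20, 20, 20), seed=4)
        counts = {int(l): int((vol.grid == l).sum()) for l in parc.labels}
        hub = int(parc.hub_labels[0])
        assert counts[hub] >= max(c for l, c in counts.items() if l != hub)

    def test_identity_affine_roundtrip(self):
        parc = sc.make_parcellation(4, 0, seed=1)
        vol = sc.make_label_volume(parc, (10, 10, 10), seed=2)
        pts = vol.voxel_to_world(np.array([[1, 2, 3], [0, 0, 0]]))
        assert np.array_equal(pts, [[1, 2, 3], [0, 0, 0]])

    def test_background_only_outside_ellipsoid(self):
        parc = sc.make_parcellation(4, 0, seed=1)
        vol = sc.make_label_volume(parc, (12, 12, 12), seed=2)
        assert vol.grid[0, 0, 0] == 0  # corner is outside the ellipsoid

    def test_grid_too_small_rejected(self):
        parc = sc.make_parcellation(104, 1, seed=1)
        with pytest.raises(ValueError):
            sc.make_label_volume(parc, (4, 4, 4), seed=2)


class TestGroundTruthMatrix:
    def test_normalization_and_symmetry(self):
        parc = sc.make_parcellation(30, 1, seed=2)
        gt = sc.make_ground_truth_matrix(parc, 2.0, 1.0, 3.0)
        p = gt.prob_matrix
        assert np.allclose(p, p.T)
        assert np.all(np.diag(p) == 0)
        assert np.triu(p, 1).sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_community_no_hub_is_uniform(self):
        parc = sc.make_parcellation(6, 0, seed=3)
        table = parc.table.copy()
        table["community"] = 0
        gt = sc.make_ground_truth_matrix(sc.Parcellation(table), 2.0, 1.0, 1.0)
        off = gt.prob_matrix[np.triu_indices(6, 1)]
        assert np.allclose(off, off[0])

    def test_hub_row_mass_ratio(self):
        # all one community isolates the hub_boost effect on row sums
        parc = sc.make_parcellation(40, 1, seed=4)
        table = parc.table.copy()
        table["community"] = 0
        boost = 3.0
        gt = sc.make_ground_truth_matrix(sc.Parcellation(table), 2.0, 1.0, boost)
        row = gt.prob_matrix.sum(axis=1)
        hub_i = int(np.nonzero(table["is_hub"].to_numpy())[0][0])
        non_hub = np.delete(row, hub_i).mean()
        # ratio -> boost for large N (hub-adjacent terms inflate non-hub rows slightly)
        assert row[hub_i] / non_hub == pytest.approx(boost, rel=0.1)

    def test_planted_hub_has_largest_row_mass(self):
        parc = sc.make_parcellation(30, 1, seed=5)
        gt = sc.make_ground_truth_matrix(parc, 2.0, 1.0, 3.0)
        row = gt.prob_matrix.sum(axis=1)
        hub_i = np.nonzero(np.isin(gt.labels, gt.hub_labels))[0]
        assert row.argmax() == hub_i[0]

    def test_intercommunity_pairs_route_through_hub(self):
        parc = sc.make_parcellation(10, 1, seed=6)
        gt = sc.make_ground_truth_matrix(parc)
        hub = int(gt.hub_labels[0])
        comm = dict(zip(gt.labels.tolist(), gt.community_of.tolist()))
        for (a, b), t in gt.traversal_sets.items():
            if comm[a] != comm[b]:
                assert t == frozenset({hub})
            else:
                assert t == frozenset()

    def test_invalid_weights_rejected(self):
        parc = sc.make_parcellation(5, 0, seed=1)
        with pytest.raises(ValueError):
            sc.make_ground_truth_matrix(parc, 1.0, 2.0)
        with pytest.raises(ValueError):
            sc.make_ground_truth_matrix(parc, 2.0, 1.0, hub_boost=0.5)


class TestSampleEndpoints:
    def test_count_and_roundtrip_labels(self, small_world):
        parc, vol, gt, _ = small_world
        rs = sc.sample_endpoints(gt, vol, 100, seed=9)
        assert len(rs) == 100
        la = sc.assign_endpoint_labels(rs.first_points, vol)
        lb = sc.assign_endpoint_labels(rs.last_points, vol)
        assert set(la) | set(lb) <= set(parc.labels.tolist())
        assert (la != 0).all() and (lb != 0).all()

    def test_deterministic(self, small_world):
        _, vol, gt, _ = small_world
        a = sc.sample_endpoints(gt, vol, 500, seed=21)
        b = sc.sample_endpoints(gt, vol, 500, seed=21)
        assert np.array_equal(a.first_points, b.first_points)
        assert np.array_equal(a.last_points, b.last_points)
        assert a.traversed == b.traversed

    def test_empirical_frequencies_match_multinomial_bound(self):
        parc = sc.make_parcellation(20, 1, seed=3)
        vol = sc.make_label_volume(parc, (16, 16, 16), seed=4)
        gt = sc.make_ground_truth_matrix(parc)
        n = 50_000
        rs = sc.sample_endpoints(gt, vol, n, seed=5)
        res = sc.build_matrix(rs, vol, parc)
        emp = res.matrix.weights / res.kept
        iu, ju = np.triu_indices(parc.n_regions, 1)
        p = gt.prob_matrix[iu, ju]
        se = np.sqrt(p * (1 - p) / n)
        frac = float((np.abs(emp[iu, ju] - p) <= 4 * se).mean())
        assert frac >= 0.99


class TestGenerateEnsemble:
    def test_bookkeeping_tags(self, small_world):
        _, vol, gt, _ = small_world
        records = sc.generate_ensemble(gt, vol, 2, 3, 50, 0.1, seed=1)
        tags = [(r.subject_id, r.run_id) for r in records]
        assert tags == [(s, r) for s in range(2) for r in range(3)]

    def test_zero_noise_shares_ground_truth(self):
        parc = sc.make_parcellation(10, 1, seed=2)
        vol = sc.make_label_volume(parc, (12, 12, 12), seed=3)
        gt = sc.make_ground_truth_matrix(parc)
        records = sc.generate_ensemble(gt, vol, 3, 1, 30_000, 0.0, seed=4)
        mats = [sc.build_matrix(r, vol, parc) for r in records]
        freqs = [m.matrix.weights / m.kept for m in mats]
        # all subjects draw from the same matrix: frequencies agree within noise
        for f in freqs[1:]:
            assert np.abs(f - freqs[0]).max() < 0.02

    def test_subject_sd_monotone_in_noise(self):
        parc = sc.make_parcellation(10, 1, seed=2)
        vol = sc.make_label_volume(parc, (12, 12, 12), seed=3)
        gt = sc.make_ground_truth_matrix(parc)
        sds = []
        for noise in (0.0, 0.2, 0.5):
            records = sc.generate_ensemble(gt, vol, 8, 1, 20_000, noise, seed=7)
            mats = [sc.build_matrix(r, vol, parc).matrix for r in records]
            stats = sc.average_subjects(mats)
            sds.append(float(stats.sd_matrix.mean()))
        assert sds[0] < sds[1] < sds[2]

    def test_negative_noise_rejected(self, small_world):
        _, vol, gt, _ = small_world
        with pytest.raises(ValueError):
            sc.generate_ensemble(gt, vol, 1, 1, 10, -0.1, seed=0)

    def test_bitwise_deterministic(self, small_world):
        _, vol, gt, _ = small_world
        a = sc.generate_ensemble(gt, vol, 2, 2, 200, 0.3, seed=99)
        b = sc.generate_ensemble(gt, vol, 2, 2, 200, 0.3, seed=99)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.first_points, rb.first_points)
            assert np.array_equal(ra.last_points, rb.last_points)
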