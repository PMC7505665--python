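import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sharedrep as sr
from sharedrep import patstats
from sharedrep.simulate import plant_patterns, simulate_subjects

from oracles import bh_stepup, octant_by_angle


class TestGroupTTest:
    def test_hand_t_value(self):
        res = patstats.group_ttest(np.array([[1.0], [2.0], [3.0]]))
        assert res.stat[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))
        assert res.stat[0] == pytest.approx(3.4641016, abs=1e-6)

    def test_zero_variance_voxel_flagged(self):
        res = patstats.group_ttest(np.zeros((5, 2)))
        assert np.all(res.stat == 0.0) and np.all(res.p == 1.0)
        assert res.zero_variance.all()

    def test_sign_flip_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.5, 1.0, size=(10, 30))
        a = patstats.group_ttest(x)
        b = patstats.group_ttest(-x)
        assert np.allclose(a.stat, -b.stat)
        assert np.allclose(a.p, b.p)

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 20))
        res = patstats.group_ttest(x)
        t_ref, p_ref = stats.ttest_1samp(x, 0.0)
        assert np.allclose(res.stat, t_ref) and np.allclose(res.p, p_ref)


class TestFDR:
    def test_hand_stepup_example(self):
        rej = patstats.fdr_threshold(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        assert rej.sum() == 3 and not rej[3]

    def test_all_ones_rejects_nothing(self):
        assert not patstats.fdr_threshold(np.ones(10)).any()

    def test_empty_input(self):
        assert patstats.fdr_threshold(np.array([])).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
           st.floats(0.01, 0.2))
    def test_matches_brute_force_stepup(self, p, q):
        p = np.asarray(p)
        assert np.array_equal(patstats.fdr_threshold(p, q), bh_stepup(p, q))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_q(self, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1, size=30)
        tight = patstats.fdr_threshold(p, q=0.01)
        loose = patstats.fdr_threshold(p, q=0.10)
        assert np.all(loose[tight])  # every tight rejection survives loosening


class TestExtentFilter:
    @staticmethod
    def _grid(shape=(10, 10, 10)):
        return sr.make_grid(shape, voxel_size_mm=(2.0, 2.0, 2.0))

    def _cluster_mask(self, grid, n_voxels):
        # a compact 18-connected cluster of exactly n voxels
        mask = np.zeros(grid.shape, dtype=bool)
        coords = [(x, y, z) for z in range(3) for y in range(3) for x in range(3)]
        for x, y, z in coords[:n_voxels]:
            mask[x + 2, y + 2, z + 2] = True
        return mask

    def test_12_voxel_cluster_removed_at_2mm(self):
        g = self._grid()
        out = patstats.extent_filter(self._cluster_mask(g, 12), g, min_mm3=100.0)
        assert not out.any()  # 12 * 8 mm^3 = 96 < 100

    def test_13_voxel_cluster_kept_at_2mm(self):
        g = self._grid()
        mask = self._cluster_mask(g, 13)
        out = patstats.extent_filter(mask, g, min_mm3=100.0)
        assert np.array_equal(out, mask)  # 13 * 8 mm^3 = 104 >= 100

    def test_empty_mask(self):
        g = self._grid((4, 4, 4))
        out = patstats.extent_filter(np.zeros(g.shape, bool), g)
        assert not out.any()

    def test_masked_vector_form_roundtrips(self):
        g = self._grid()
        mask3d = self._cluster_mask(g, 20)
        vec = g.to_masked(mask3d.astype(float)).astype(bool)
        out = patstats.extent_filter(vec, g, min_mm3=100.0)
        assert out.ndim == 1 and out.sum() == 20


class TestConjunction:
    def test_self_and_empty(self):
        a = np.array([True, False, True])
        assert np.array_equal(patstats.conjunction(a, a), a)
        assert not patstats.conjunction(a, np.zeros(3, bool)).any()

    def test_hand_three_voxel_case(self):
        a = np.array([True, True, False])
        b = np.array([False, True, True])
        assert np.array_equal(patstats.conjunction(a, b), [False, True, False])

    def test_sign_consistency_option(self):
        a = np.array([True, True])
        stat_a = np.array([1.0, 1.0])
        stat_b = np.array([1.0, -1.0])
        out = patstats.conjunction(a, a, stat_a, stat_b, require_same_sign=True)
        assert np.array_equal(out, [True, False])


class TestSpatialCorrelation:
    def test_identity_and_negation(self):
        x = np.array([1.0, 2.0, 4.0, -1.0])
        assert patstats.spatial_correlation(x, x) == pytest.approx(1.0)
        assert patstats.spatial_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=100), rng.normal(size=100)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        assert patstats.spatial_correlation(a, b) == pytest.approx(np.mean(za * zb))


class TestPermutationSimilarity:
    @staticmethod
    def _null_pairs(seed, n=10, v=40):
        rng = np.random.default_rng(seed)
        return (
            (rng.normal(size=(n, v)), rng.normal(size=(n, v))),
            (rng.normal(size=(n, v)), rng.normal(size=(n, v))),
        )

    def test_add_one_formula_when_observed_beats_all(self):
        # a map builder whose output ignores the label shuffle entirely is
        # degenerate; instead plant a huge effect so r_obs tops the null
        rng = np.random.default_rng(3)
        signal = rng.normal(size=50)
        pa = (signal + 0.01 * rng.normal(size=(10, 50)), 0.01 * rng.normal(size=(10, 50)))
        pb = (signal + 0.01 * rng.normal(size=(10, 50)), 0.01 * rng.normal(size=(10, 50)))
        res = patstats.permutation_similarity(
            pa, pb, patstats.ttest_map_builder, n_perm=100, seed=0
        )
        assert res.p == pytest.approx(1.0 / 201.0)

    def test_null_p_is_moderate(self):
        pa, pb = self._null_pairs(4)
        res = patstats.permutation_similarity(
            pa, pb, patstats.ttest_map_builder, n_perm=150, seed=1
        )
        assert res.p > 0.05

    def test_seeded_determinism(self):
        pa, pb = self._null_pairs(5)
        r1 = patstats.permutation_similarity(pa, pb, patstats.ttest_map_builder,
                                             n_perm=120, seed=2)
        r2 = patstats.permutation_similarity(pa, pb, patstats.ttest_map_builder,
                                             n_perm=120, seed=2)
        assert r1.p == r2.p and np.array_equal(r1.null, r2.null)

    def test_voxel_order_invariance(self):
        pa, pb = self._null_pairs(6)
        perm = np.random.default_rng(0).permutation(40)
        r1 = patstats.permutation_similarity(pa, pb, patstats.ttest_map_builder,
                                             n_perm=120, seed=3)
        pa2 = (pa[0][:, perm], pa[1][:, perm])
        pb2 = (pb[0][:, perm], pb[1][:, perm])
        r2 = patstats.permutation_similarity(pa2, pb2, patstats.ttest_map_builder,
                                             n_perm=120, seed=3)
        assert r1.r_obs == pytest.approx(r2.r_obs)
        assert r1.p == pytest.approx(r2.p)


class TestBootstrapWeights:
    def test_seeded_determinism(self, small_dataset):
        _, pain, ctrl = small_dataset.paired("NS", "pain", "control")
        a = patstats.bootstrap_weights(pain, ctrl, n_boot=50, seed=1)
        b = patstats.bootstrap_weights(pain, ctrl, n_boot=50, seed=1)
        assert np.array_equal(a.stat, b.stat)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            patstats.bootstrap_weights(np.zeros((5, 4)), np.zeros((5, 4)), n_boot=10)

    def test_planted_voxels_get_larger_z(self, small_grid):
        truth = plant_patterns(small_grid, 30, 0, 0, 0, seed=1, noise_sd=0.3)
        ds = simulate_subjects(truth, 20, seed=3)
        _, pain, ctrl = ds.paired("NS", "pain", "control")
        rmap = patstats.bootstrap_weights(pain, ctrl, n_boot=200, seed=4)
        planted = truth.shared_pattern != 0
        assert np.abs(rmap.stat[planted]).mean() > 2 * np.abs(rmap.stat[~planted]).mean()


class TestOctants:
    def test_angle_examples(self):
        # two informative voxels steering the z-scores; verify via the
        # independent angle oracle on the z-transformed coordinates
        rng = np.random.default_rng(7)
        wx, wy = rng.normal(size=200), rng.normal(size=200)
        res = patstats.octant_analysis(wx, wy)
        zx = (wx - wx.mean()) / wx.std()
        zy = (wy - wy.mean()) / wy.std()
        expected = np.array([octant_by_angle(a, b) for a, b in zip(zx, zy)])
        assert np.array_equal(res.octant_of, expected)

    def test_brute_force_agreement_large(self):
        rng = np.random.default_rng(8)
        wx, wy = rng.normal(size=10000), rng.normal(size=10000)
        res = patstats.octant_analysis(wx, wy)
        zx = (wx - wx.mean()) / wx.std()
        zy = (wy - wy.mean()) / wy.std()
        expected = np.array([octant_by_angle(a, b) for a, b in zip(zx, zy)])
        assert np.array_equal(res.octant_of, expected)

    def test_counts_partition_voxels(self):
        rng = np.random.default_rng(9)
        res = patstats.octant_analysis(rng.normal(size=500), rng.normal(size=500))
        assert res.counts.sum() + res.excluded_zero == 500

    def test_ssd_hand_sum(self):
        # octant containing z-pairs (1,1) and (2,2) has SSD 2 + 8 = 10;
        # feed pre-z-scored values through a direct sector computation
        zx = np.array([1.0, 2.0])
        zy = np.array([1.0, 2.0])
        theta = np.degrees(np.arctan2(zy, zx))
        assert np.all((22.5 <= theta) & (theta < 67.5))  # both in the shared+ sector
        assert np.sum(zx**2 + zy**2) == pytest.approx(10.0)

    def test_swap_equivariance(self):
        # swapping the x and y inputs maps O1<->O3, O5<->O7, O4<->O8 and
        # fixes the shared octants O2, O6
        rng = np.random.default_rng(10)
        wx, wy = rng.normal(size=2000), rng.normal(size=2000)
        a = patstats.octant_analysis(wx, wy)
        b = patstats.octant_analysis(wy, wx)
        swap = {1: 3, 3: 1, 5: 7, 7: 5, 4: 8, 8: 4, 2: 2, 6: 6}
        for o in range(1, 9):
            assert a.counts[o - 1] == b.counts[swap[o] - 1]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            patstats.octant_analysis(np.ones(10), np.arange(10.0))
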