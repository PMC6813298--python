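"""Voxel/cluster inference: t-maps, BH-FDR, 26-connectivity, sign-flip
cluster FDR."""
import numpy as np
import pytest
from scipy import stats

from rsgica.errors import InvalidVolumeError
from rsgica.maps_stats import (
    connected_clusters,
    fdr_bh,
    null_max_extents,
    one_sample_tmap,
    threshold_component,
)


class TestOneSampleTMap:
    def test_all_zero_voxel(self):
        res = one_sample_tmap(np.zeros((5, 3)))
        np.testing.assert_array_equal(res.t_values, 0.0)
        np.testing.assert_array_equal(res.p_values, 1.0)
        assert res.df == 4

    def test_matches_reference_statistics(self):
        vals = np.array([[1.0], [2.0], [3.0], [4.0]])
        res = one_sample_tmap(vals)
        np.testing.assert_allclose(res.t_values[0], 2.5 / (1.29099445 / 2),
                                   rtol=1e-6)
        # independent oracle
        t_ref, p_ref = stats.ttest_1samp(vals[:, 0], 0.0)
        np.testing.assert_allclose(res.t_values[0], t_ref, rtol=1e-10)
        np.testing.assert_allclose(res.p_values[0], p_ref, rtol=1e-10)

    def test_constant_nonzero_voxel_flagged(self):
        res = one_sample_tmap(np.full((4, 2), 3.0))
        assert np.isinf(res.t_values).all()
        np.testing.assert_array_equal(res.p_values, 0.0)
        np.testing.assert_array_equal(res.infinite_t_voxels, [0, 1])

    def test_too_few_subjects(self):
        with pytest.raises(InvalidVolumeError):
            one_sample_tmap(np.zeros((2, 4)))


def _bh_oracle(p, q):
    """Exhaustive check of every sorted index."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = p.size
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= q * i / m:
            k = i
    reject = np.zeros(m, bool)
    if k:
        reject[order[:k]] = True
    return reject


class TestFdrBH:
    def test_spec_examples(self):
        reject, p_star = fdr_bh([0.001, 0.02, 0.03, 0.04], 0.05)
        assert reject.all() and p_star == 0.04
        reject, p_star = fdr_bh([1.0, 1.0, 1.0], 0.05)
        assert not reject.any() and p_star is None
        reject, p_star = fdr_bh([0.04], 0.05)
        assert reject.all() and p_star == 0.04

    def test_against_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.integers(1, 51)
            p = rng.uniform(size=n) ** rng.uniform(0.5, 3.0)
            q = rng.uniform(0.01, 0.2)
            reject, _ = fdr_bh(p, q)
            np.testing.assert_array_equal(reject, _bh_oracle(p, q))

    def test_monotone_in_q(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=200) ** 2
        r_low, _ = fdr_bh(p, 0.01)
        r_high, _ = fdr_bh(p, 0.05)
        assert np.all(~r_low | r_high)  # lowering q never adds rejections

    def test_empty_input(self):
        with pytest.raises(ValueError):
            fdr_bh([], 0.05)


class TestConnectedClusters:
    def test_two_disjoint_blobs(self):
        m = np.zeros((6, 6, 6), bool)
        m[0, 0, 0] = m[0, 0, 1] = True
        m[4, 4, 4] = m[4, 4, 5] = True
        clusters = connected_clusters(m)
        assert sorted(c.size for c in clusters) == [2, 2]

    def test_empty_mask(self):
        assert connected_clusters(np.zeros((3, 3, 3), bool)) == []

    @pytest.mark.parametrize("offset", [(1, 0, 0), (1, 1, 0), (1, 1, 1)])
    def test_face_edge_corner_connect(self, offset):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = True
        m[1 + offset[0], 1 + offset[1], 1 + offset[2]] = True
        clusters = connected_clusters(m)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_center_of_mass(self):
        m = np.zeros((5, 5, 5), bool)
        m[1, 2, 3] = m[2, 2, 3] = True
        (c,) = connected_clusters(m)
        assert c.center_of_mass == (1.5, 2.0, 3.0)


class TestClusterFDR:
    mask = np.ones((6, 6, 4), bool)

    def test_preconditions(self):
        maps = np.random.default_rng(0).normal(size=(4, self.mask.sum()))
        with pytest.raises(InvalidVolumeError):
            null_max_extents(maps, self.mask, 0.001, 100, 0)
        maps = np.random.default_rng(0).normal(size=(8, self.mask.sum()))
        with pytest.raises(ValueError):
            null_max_extents(maps, self.mask, 0.001, 50, 0)

    def test_planted_effect_survives(self):
        rng = np.random.default_rng(13)
        v = int(self.mask.sum())
        maps = rng.normal(size=(12, v))
        maps[:, :20] += 3.0  # consistent effect in a 20-voxel block
        comp = threshold_component(maps, self.mask, q_voxel=0.01,
                                   q_cluster=0.05, n_permutations=200, seed=0)
        assert comp.voxel_mask.sum() >= 10
        assert any(c.survives for c in comp.clusters)

    def test_pure_noise_rarely_survives(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(10):
            maps = rng.normal(size=(12, int(self.mask.sum())))
            comp = threshold_component(maps, self.mask, q_voxel=0.001,
                                       q_cluster=0.005, n_permutations=100,
                                       seed=1)
            hits += comp.voxel_mask.any()
        assert hits <= 1

    def test_voxel_threshold_monotonicity(self):
        rng = np.random.default_rng(15)
        maps = rng.normal(size=(12, int(self.mask.sum())))
        maps[:, :30] += 1.5
        res = one_sample_tmap(maps)
        r_strict, _ = fdr_bh(res.p_values, 0.0005)
        r_loose, _ = fdr_bh(res.p_values, 0.005)
        assert np.all(~r_strict | r_loose)


def test_type_one_control_on_exchangeable_null_maps():
    """Given genuinely exchangeable null subject maps (the sign-flip
    null's own assumption), the dual FDR thresholds admit clusters in at
    most 10% of components over 20 seeds.

    This isolates the thresholding machinery from the back-projection
    step, whose circular one-sample mean violates exchangeability.
    """
    mask = np.zeros((12, 12, 8), bool)
    mask[2:-2, 2:-2, 1:-1] = True
    v = int(mask.sum())
    hits = 0
    total = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        for comp in range(7):
            maps = rng.normal(size=(22, v))
            out = threshold_component(maps, mask, q_voxel=0.001,
                                      q_cluster=0.005, n_permutations=100,
                                      seed=seed * 10 + comp)
            hits += bool(out.voxel_mask.any())
            total += 1
    assert hits / total <= 0.10
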