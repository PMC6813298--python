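"""Group decomposition: normalization, concatenation, PCA, fastICA and
GICA1 back-projection."""
import itertools
import warnings

import numpy as np
import pytest

from rsgica.gica import (
    backproject_gica1,
    concat_temporal,
    fastica_spatial,
    group_pca_reduce,
    run_gica,
    variance_normalize,
)


class TestVarianceNormalize:
    def test_unit_variance_columns(self):
        rng = np.random.default_rng(0)
        X, zeros = variance_normalize(rng.normal(2.0, 3.0, size=(50, 40)))
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-8)
        assert zeros.size == 0

    def test_constant_column_recorded(self):
        X = np.random.default_rng(1).normal(size=(20, 5))
        X[:, 2] = 7.0
        out, zeros = variance_normalize(X)
        np.testing.assert_array_equal(zeros, [2])
        np.testing.assert_array_equal(out[:, 2], 0.0)

    def test_idempotent(self):
        X, _ = variance_normalize(np.random.default_rng(2).normal(size=(30, 8)))
        again, _ = variance_normalize(X)
        np.testing.assert_allclose(again, X, atol=1e-8)


class TestConcat:
    def test_provenance(self):
        runs = [np.zeros((10, 5)), np.zeros((7, 5))]
        Y, prov = concat_temporal(runs, run_ids=["a", "b"])
        assert Y.shape == (17, 5)
        assert len(prov) == 17
        assert (prov["run"] == "a").sum() == 10
        np.testing.assert_array_equal(prov["volume"][:10], np.arange(10))

    def test_single_run_identity(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        Y, _ = concat_temporal([X])
        np.testing.assert_array_equal(Y, X)

    def test_voxel_mismatch(self):
        with pytest.raises(ValueError):
            concat_temporal([np.zeros((5, 4)), np.zeros((5, 3))])


class TestGroupPCA:
    def test_exact_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 200))
        reduced, U, ev = group_pca_reduce(X, 3)
        recon = U @ reduced
        assert np.abs(recon - X).max() / np.abs(X).max() <= 1e-8

    def test_full_order_lossless(self):
        X = np.random.default_rng(4).normal(size=(8, 30))
        reduced, U, ev = group_pca_reduce(X, 8)
        np.testing.assert_allclose(U @ reduced, X, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 500))
        _, _, ev = group_pca_reduce(X, 10)
        # independent oracle: eigenvalues of the temporal Gram matrix
        eigs = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1]
        np.testing.assert_allclose(ev, eigs[:10], rtol=1e-6)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            group_pca_reduce(np.zeros((5, 10)), 6)


def _align_score(true_sources, est_sources):
    """Best |corr| assignment by brute force over permutations and signs."""
    k = true_sources.shape[0]
    c = np.corrcoef(np.vstack([true_sources, est_sources]))[:k, k:]
    best = -1.0
    for perm in itertools.permutations(range(k)):
        score = min(abs(c[i, perm[i]]) for i in range(k))
        best = max(best, score)
    return best


class TestFastICA:
    def test_recovers_mixed_uniform_sources(self):
        rng = np.random.default_rng(6)
        S = rng.uniform(-np.sqrt(3), np.sqrt(3), size=(2, 5000))
        A = np.array([[1.0, 0.4], [0.3, 1.0]])
        _, est = fastica_spatial(A @ S, seed=3)
        assert _align_score(S, est) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(3, 2000))
        _, a = fastica_spatial(X, seed=1, allow_unconverged=True)
        _, b = fastica_spatial(X, seed=1, allow_unconverged=True)
        np.testing.assert_array_equal(a, b)

    def test_gaussian_sources_do_not_crash(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2, 3000))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, est = fastica_spatial(X, seed=2, allow_unconverged=True)
        assert est.shape == (2, 3000)


class TestBackprojection:
    def test_single_run_maps_equal_group_maps(self, tiny_study):
        from rsgica.preprocess import preprocess_study

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = preprocess_study(tiny_study)[:1]
            decomp = run_gica(pre, 4, seed=0)
        rid = (pre[0].subject_id, pre[0].run_index)
        run_maps = decomp.run_maps[rid]
        for ci in range(4):
            r = np.corrcoef(run_maps[ci], decomp.group_maps[ci])[0, 1]
            assert abs(r) >= 0.999

    def test_zero_data_gives_zero_maps(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        maps = rng.normal(size=(2, 300))
        mixing = rng.normal(size=(20, 2))
        prov = pd.DataFrame(
            {"run": ["a"] * 10 + ["b"] * 10, "volume": list(range(10)) * 2}
        )
        _, run_maps = backproject_gica1(
            maps, mixing, prov,
            {"a": rng.normal(size=(10, 300)), "b": np.zeros((10, 300))},
        )
        np.testing.assert_allclose(run_maps["b"], 0.0, atol=1e-12)


class TestDecomposition:
    def test_bit_identical_rerun(self, small_decomposition):
        study, pre, decomp = small_decomposition
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = run_gica(pre, 7, seed=5)
        np.testing.assert_array_equal(decomp.group_maps, again.group_maps)
        np.testing.assert_array_equal(decomp.mixing, again.mixing)

    def test_canonical_form(self, small_decomposition):
        from scipy.stats import skew

        _, _, decomp = small_decomposition
        np.testing.assert_allclose(decomp.group_maps.std(axis=1), 1.0,
                                   atol=1e-8)
        assert np.all(skew(decomp.group_maps, axis=1) >= -1e-9)
        ev = decomp.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)

    def test_subject_maps_average_runs(self, small_decomposition):
        _, _, decomp = small_decomposition
        sid = sorted(decomp.subject_maps)[0]
        pair = [m for (s, _), m in decomp.run_maps.items() if s == sid]
        np.testing.assert_allclose(decomp.subject_maps[sid],
                                   np.mean(pair, axis=0), atol=1e-10)


def test_model_order_probe_retains_networks(recovery_suite):
    """At model order 10 (> n_networks + 3) every planted network still has
    a matching component with |corr| >= 0.7 in at least 9 of 10 seeds."""
    ok = sum(
        all(v >= 0.7 for v in ev.probe_corrs.values())
        for ev in recovery_suite
    )
    assert ok >= 9
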