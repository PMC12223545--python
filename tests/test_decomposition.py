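"""PCA/whitening, elbow selection, infomax ICA, mCCA and mCCA+jICA."""

import numpy as np
import pytest

import deltafuse as df
from deltafuse.decomposition import PCAModel, reconstruct
from conftest import amari_index, greedy_match


def closed_form_cca(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """SVD-of-whitened-cross-covariance oracle for canonical correlations."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    ua, *_ = np.linalg.svd(a, full_matrices=False)
    ub, *_ = np.linalg.svd(b, full_matrices=False)
    return np.linalg.svd(ua.T @ ub, compute_uv=False)[:k]


class TestElbow:
    def test_override_short_circuits(self):
        assert df.select_components_elbow(np.array([9.0, 5.0, 1.0]), override=5) == 5

    def test_linear_spectrum_degenerates_to_one_with_warning(self):
        with pytest.warns(UserWarning, match="elbow undefined"):
            assert df.select_components_elbow(np.linspace(10, 1, 8)) == 1

    def test_matches_brute_force_distance_evaluation(self):
        ev = np.array([10.0, 5.0, 2.5, 1.2, 1.1, 1.05, 1.0])
        # oracle: exhaustive point-to-chord distance on the normalized curve
        x = np.linspace(0, 1, ev.size)
        y = (ev - ev[-1]) / (ev[0] - ev[-1])
        p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
        chord = (p1 - p0) / np.linalg.norm(p1 - p0)
        dists = [
            np.linalg.norm((np.array([xi, yi]) - p0) - ((np.array([xi, yi]) - p0) @ chord) * chord)
            for xi, yi in zip(x, y)
        ]
        assert df.select_components_elbow(ev) == int(np.argmax(dists)) + 1

    def test_non_descending_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            df.select_components_elbow(np.array([1.0, 2.0, 3.0]))


class TestPCAModel:
    def test_whitened_covariance_is_identity(self, rng):
        x = rng.standard_normal((20, 500)) * rng.gamma(2, size=(20, 1))
        pca = PCAModel.fit(x, 6)
        z = pca.project(x)
        assert np.allclose(z @ z.T / z.shape[1], np.eye(6), atol=1e-8)

    def test_back_projection_inverts_on_retained_subspace(self, rng):
        a = rng.standard_normal((30, 4))
        s = rng.standard_normal((4, 300))
        x = a @ s
        pca = PCAModel.fit(x, 4)
        assert np.allclose(pca.back_project(pca.project(x)), x, atol=1e-8)


class TestInfomax:
    def test_amari_index_on_noiseless_supergaussian_mixtures(self, rng):
        # sparse (Bernoulli-Gaussian) sources: strongly supergaussian, like
        # the localized connectivity / blob patterns the pipeline targets
        s_true = rng.standard_normal((3, 500)) * (rng.random((3, 500)) < 0.1)
        a_true = rng.standard_normal((20, 3))
        res = df.infomax_ica(a_true @ s_true, 3, seed=0)
        gain = np.linalg.pinv(res.A_F) @ a_true  # estimated unmixing × true mixing
        assert amari_index(gain) < 0.01

    def test_source_recovery_on_synthetic_cohort(self, small_cohort):
        res = df.infomax_ica(small_cohort.delta_fnc, 5, seed=0)
        _, vals = greedy_match(res.S_F, small_cohort.truth.S_F_true)
        assert np.all(vals > 0.95)

    def test_single_component_is_principal_axis(self, rng):
        x = rng.standard_normal((40, 6)) @ rng.standard_normal((6, 200))
        res = df.infomax_ica(x, 1, seed=0)
        xc = x - x.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(xc, full_matrices=False)
        cos = abs(res.S_F[0] @ vt[0]) / np.linalg.norm(res.S_F[0])
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_feature_permutation_equivariance(self, rng):
        x = rng.standard_normal((30, 4)) @ np.abs(rng.laplace(size=(4, 300)))
        perm = rng.permutation(x.shape[1])
        res = df.infomax_ica(x, 3, seed=1)
        res_p = df.infomax_ica(x[:, perm], 3, seed=1)
        assert np.allclose(res.S_F[:, perm], res_p.S_F, atol=1e-6)
        assert np.allclose(res.A_F, res_p.A_F, atol=1e-6)

    def test_positive_scaling_equivariance(self, rng):
        x = rng.standard_normal((30, 4)) @ rng.laplace(size=(4, 300))
        res = df.infomax_ica(x, 3, seed=1)
        res_c = df.infomax_ica(3.0 * x, 3, seed=1)
        assert np.allclose(res_c.S_F, res.S_F, atol=1e-6)  # unit-norm sources
        assert np.allclose(res_c.A_F, 3.0 * res.A_F, atol=1e-5)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            df.infomax_ica(rng.standard_normal((4, 50)), 5, seed=0)


class TestMcca:
    def test_identical_sets_fully_correlated(self, rng):
        y = rng.standard_normal((40, 6))
        res = df.mcca([y, y.copy()], 3)
        assert np.allclose(res.canonical_correlations, 1.0, atol=1e-10)

    def test_two_set_solution_matches_closed_form_cca(self, rng):
        for _ in range(20):
            y1 = rng.standard_normal((50, 10))
            y2 = rng.standard_normal((50, 10))
            res = df.mcca([y1, y2], 3)
            assert np.allclose(
                res.canonical_correlations, closed_form_cca(y1, y2, 3), atol=1e-8
            )

    def test_correlations_nonincreasing(self, rng):
        res = df.mcca([rng.standard_normal((60, 8)) for _ in range(3)], 4)
        assert np.all(np.diff(res.canonical_correlations) <= 1e-10)

    def test_independent_sets_within_permutation_null(self, rng):
        y1 = rng.standard_normal((5000, 5))
        y2 = rng.standard_normal((5000, 5))
        observed = df.mcca([y1, y2], 5).canonical_correlations
        null_top = []
        for _ in range(60):
            null_top.append(
                df.mcca([y1[rng.permutation(5000)], y2], 5).canonical_correlations[0]
            )
        assert observed[0] <= np.quantile(null_top, 0.95)

    def test_variates_orthogonal_within_set(self, rng):
        y1 = rng.standard_normal((80, 6))
        y2 = rng.standard_normal((80, 6))
        res = df.mcca([y1, y2], 4)
        for d in res.variates:
            gram = d.T @ d / d.shape[0]
            assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_rank_deficient_set_rejected(self, rng):
        low = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 8))
        with pytest.raises(ValueError, match="rank"):
            df.mcca([low, rng.standard_normal((40, 8))], 5)


class TestMccaJica:
    def test_source_recovery_both_modalities(self, small_cohort):
        res = df.mcca_jica(small_cohort.delta_fnc, small_cohort.delta_gmv, 5, seed=0)
        _, vals_f = greedy_match(res.S_F, small_cohort.truth.S_F_true)
        _, vals_g = greedy_match(res.S_G, small_cohort.truth.S_G_true)
        assert np.all(vals_f > 0.9)
        assert np.all(vals_g > 0.9)

    def test_noiseless_reconstruction_exact(self):
        c = df.simulate_cohort(n_subjects=100, seed=6, noise_sd=0.0)
        res = df.mcca_jica(c.delta_fnc, c.delta_gmv, 5, seed=0)
        for modality, x in (("fnc", c.delta_fnc), ("gmv", c.delta_gmv)):
            rel = np.linalg.norm(x - reconstruct(res, modality)) / np.linalg.norm(x)
            assert rel < 1e-6

    def test_planted_loading_correlation_estimated(self):
        c = df.simulate_cohort(n_subjects=2000, seed=11)
        res = df.mcca_jica(c.delta_fnc, c.delta_gmv, 5, seed=11)
        pairs, _ = greedy_match(res.S_F, c.truth.S_F_true)
        for i, _ in pairs:
            est = abs(np.corrcoef(res.A_F[:, i], res.A_G[:, i])[0, 1])
            assert est == pytest.approx(0.5, abs=0.05)

    def test_subject_mismatch_rejected(self, small_cohort):
        dm_f = df.DeltaMatrix(small_cohort.delta_fnc, "fnc_cells", [f"a{i}" for i in range(300)])
        dm_g = df.DeltaMatrix(small_cohort.delta_gmv, "gmv_voxels", [f"b{i}" for i in range(300)])
        with pytest.raises(ValueError, match="subject"):
            df.mcca_jica(dm_f, dm_g, 5, seed=0)


class TestFixSignsAndOrder:
    def test_idempotent(self, small_cohort):
        res = df.mcca_jica(small_cohort.delta_fnc, small_cohort.delta_gmv, 5, seed=2)
        again = df.fix_signs_and_order(res)
        # idempotent up to re-normalization round-off of unit-norm rows
        assert np.allclose(again.S_F, res.S_F, rtol=1e-12, atol=0)
        assert np.allclose(again.A_G, res.A_G, rtol=1e-12, atol=0)

    def test_product_preserved(self, rng):
        a = rng.standard_normal((30, 4))
        s = rng.standard_normal((4, 100))
        res = df.fix_signs_and_order(df.FusionResult(A_F=a.copy(), S_F=s.copy()))
        assert np.allclose(res.A_F @ res.S_F, a @ s, atol=1e-12)

    def test_sign_invariance(self, rng):
        a = rng.standard_normal((30, 4))
        s = rng.standard_normal((4, 100))
        base = df.fix_signs_and_order(df.FusionResult(A_F=a.copy(), S_F=s.copy()))
        flipped = df.fix_signs_and_order(df.FusionResult(A_F=-a.copy(), S_F=-s.copy()))
        assert np.allclose(base.S_F, flipped.S_F)

    def test_unit_norm_sources(self, small_cohort):
        res = df.infomax_ica(small_cohort.delta_fnc, 5, seed=3)
        assert np.allclose(np.linalg.norm(res.S_F, axis=1), 1.0)
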