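"""Feature matrices, linear kernels, and the GPR/RVR regressors."""

import numpy as np
import pytest

from netage.gpr import GprOptions, NotPositiveSemidefiniteError, fit_gpr, predict_gpr
from netage.kernels import (
    build_feature_matrix,
    linear_similarity,
    trace_normalize,
    validate_similarity,
)
from netage.parcellation import NetworkMask
from netage.rvr import RvrOptions, fit_rvr, predict_rvr


class TestFeatureMatrix:
    def test_rows_are_flattened_images(self):
        a = np.array([[[1.0], [2.0]]]).reshape(2, 1, 1)
        b = np.array([[[3.0], [4.0]]]).reshape(2, 1, 1)
        f = build_feature_matrix([a, b])
        np.testing.assert_array_equal(f, [[1, 2], [3, 4]])

    def test_mask_restriction_preserves_gram_matrix(self, rng):
        imgs = [rng.random((4, 4, 4)) for _ in range(5)]
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[:2] = 1
        mask = NetworkMask(label="FPN", values=m)
        masked = [img * m for img in imgs]
        k_full = linear_similarity(build_feature_matrix(masked))
        k_restricted = linear_similarity(build_feature_matrix(masked, mask=mask))
        np.testing.assert_allclose(k_full, k_restricted, atol=1e-10)

    def test_nan_rejected(self):
        img = np.full((2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            build_feature_matrix([img])

    def test_mixed_dims_rejected(self, rng):
        with pytest.raises(ValueError, match="mixed"):
            build_feature_matrix([rng.random((2, 2, 2)), rng.random((3, 3, 3))])


class TestLinearSimilarity:
    def test_identity_features_give_identity_kernel(self):
        np.testing.assert_array_equal(linear_similarity(np.eye(2)), np.eye(2))

    def test_gram_psd_and_symmetric(self, rng):
        f = rng.standard_normal((10, 7))
        k = validate_similarity(linear_similarity(f))
        assert np.allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-8 * np.trace(k)

    def test_matches_double_loop_dot_product_oracle(self, rng):
        f = rng.standard_normal((5, 20))
        k = linear_similarity(f)
        for i in range(5):
            for j in range(5):
                expect = sum(f[i, c] * f[j, c] for c in range(20))
                assert k[i, j] == pytest.approx(expect, rel=1e-10)

    def test_cross_block_and_column_mismatch(self, rng):
        fa, fb = rng.standard_normal((4, 6)), rng.standard_normal((3, 6))
        kc = linear_similarity(fa, fb)
        assert kc.shape == (4, 3)
        with pytest.raises(ValueError, match="column mismatch"):
            linear_similarity(fa, rng.standard_normal((3, 5)))


class TestGpr:
    @pytest.fixture(scope="class")
    @staticmethod
    def linear_problem():
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 40))  # more features than subjects: PD K
        beta = rng.standard_normal(40)
        y = x @ beta + 0.3 * rng.standard_normal(30)
        return x, y, linear_similarity(x)

    def test_constant_targets_predict_that_constant(self, linear_problem):
        _, _, k = linear_problem
        y = np.full(30, 42.0)
        state = fit_gpr(k, y)
        np.testing.assert_allclose(predict_gpr(state, k[:5]), 42.0, atol=1e-8)

    def test_noise_free_limit_interpolates(self, linear_problem):
        x, y, k = linear_problem
        state = fit_gpr(
            k, y, GprOptions(theta2=1.0, sigma2=1e-10, optimize=False,
                             jitter_scale=0.0)
        )
        np.testing.assert_allclose(predict_gpr(state, k), y, atol=1e-6)

    def test_fixed_hyperparameters_equal_kernel_ridge_oracle(self, linear_problem):
        _, y, k = linear_problem
        theta2, sigma2 = 2.0, 0.3
        state = fit_gpr(
            k, y, GprOptions(theta2=theta2, sigma2=sigma2, optimize=False,
                             jitter_scale=0.0)
        )
        pred = predict_gpr(state, k)
        lam = sigma2 / theta2
        oracle = y.mean() + k @ np.linalg.solve(
            k + lam * np.eye(30), y - y.mean()
        )
        np.testing.assert_allclose(pred, oracle, atol=1e-8)

    def test_matches_gp_library_oracle_at_fixed_hyperparameters(self):
        """Cross-check the predictive mean against scikit-learn's GP."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (
            ConstantKernel,
            DotProduct,
            WhiteKernel,
        )

        rng = np.random.default_rng(8)
        x_train = rng.standard_normal((30, 12))
        x_test = rng.standard_normal((6, 12))
        y = x_train[:, 0] * 3 + 0.2 * rng.standard_normal(30)
        theta2, sigma2 = 1.7, 0.4
        kern = ConstantKernel(theta2, "fixed") * DotProduct(
            sigma_0=0.0, sigma_0_bounds="fixed"
        ) + WhiteKernel(sigma2, "fixed")
        ref = GaussianProcessRegressor(kernel=kern, optimizer=None)
        yc = y - y.mean()
        ref.fit(x_train, yc)
        expect = ref.predict(x_test) + y.mean()
        state = fit_gpr(
            linear_similarity(x_train), y,
            GprOptions(theta2=theta2, sigma2=sigma2, optimize=False,
                       jitter_scale=0.0),
        )
        pred = predict_gpr(state, linear_similarity(x_test, x_train))
        np.testing.assert_allclose(pred, expect, atol=1e-6)

    def test_zero_cross_kernel_predicts_prior_mean(self, linear_problem):
        _, y, k = linear_problem
        state = fit_gpr(k, y)
        np.testing.assert_allclose(
            predict_gpr(state, np.zeros((4, 30))), y.mean(), atol=1e-8
        )

    def test_lml_non_decreasing_over_accepted_steps(self, linear_problem):
        _, y, k = linear_problem
        state = fit_gpr(k, y)
        path = state.lml_path
        assert len(path) >= 2
        assert all(b >= a - 1e-7 for a, b in zip(path, path[1:]))

    def test_optimized_fit_beats_fixed_guess(self, linear_problem):
        _, y, k = linear_problem
        free = fit_gpr(k, y)
        fixed = fit_gpr(k, y, GprOptions(theta2=1e-6, sigma2=1e3,
                                         optimize=False))
        assert free.log_marginal_likelihood >= fixed.log_marginal_likelihood

    def test_non_psd_kernel_rejected(self):
        k = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(NotPositiveSemidefiniteError):
            fit_gpr(k, np.array([1.0, 2.0]))

    def test_prediction_invariant_to_subject_permutation(self, linear_problem):
        _, y, k = linear_problem
        perm = np.random.default_rng(0).permutation(30)
        state = fit_gpr(k, y)
        state_p = fit_gpr(k[np.ix_(perm, perm)], y[perm])
        pred = predict_gpr(state, k[:4])
        pred_p = predict_gpr(state_p, k[np.ix_(np.arange(4), perm)])
        np.testing.assert_allclose(pred, pred_p, rtol=1e-5, atol=1e-6)


class TestRvr:
    @pytest.fixture(scope="class")
    @staticmethod
    def kernel():
        rng = np.random.default_rng(5)
        f = rng.standard_normal((40, 25))
        return trace_normalize(linear_similarity(f))

    def test_zero_targets_give_null_model(self, kernel):
        state = fit_rvr(kernel, np.zeros(40))
        assert state.null_model or np.abs(state.mu).max() < 1e-10
        np.testing.assert_allclose(predict_rvr(state, kernel), 0.0, atol=1e-10)

    def test_single_basis_recovery_against_least_squares(self):
        """A target built from one kernel column is recovered with a weight
        matching least squares on the surviving bases.

        The kernel comes from a realistic voxel count (1000 features for 40
        subjects) so its columns are near-orthogonal and surviving spurious
        bases cannot shift the generating weight.
        """
        f = np.random.default_rng(5).standard_normal((40, 1000))
        kernel = trace_normalize(linear_similarity(f))
        rng = np.random.default_rng(6)
        y = 2.0 * kernel[:, 5] + 1e-2 * rng.standard_normal(40)
        state = fit_rvr(kernel, y)
        assert 6 in state.active  # design column 6 is kernel basis 5
        # oracle: least squares restricted to the surviving design columns
        phi = np.hstack([np.ones((40, 1)), kernel])
        phi_a = phi[:, state.active]
        w_ls, *_ = np.linalg.lstsq(phi_a, y, rcond=None)
        w5 = state.mu[list(state.active).index(6)]
        assert w5 == pytest.approx(w_ls[list(state.active).index(6)], abs=1e-3)

    def test_sparsity_bound_and_finite_training_error(self, kernel, rng):
        y = rng.uniform(18, 90, 40)
        state = fit_rvr(kernel, y)
        assert state.active.size <= 41
        mae = np.abs(predict_rvr(state, kernel) - y).mean()
        assert np.isfinite(mae)

    def test_evidence_non_decreasing(self, kernel):
        rng = np.random.default_rng(7)
        y = 3.0 * kernel[:, 2] + 0.05 * rng.standard_normal(40)
        state = fit_rvr(kernel, y)
        ev = state.evidence_path
        assert len(ev) >= 2
        assert all(b >= a - 1e-6 * max(1, abs(a)) for a, b in zip(ev, ev[1:]))

    def test_zero_cross_kernel_gives_bias_only(self, kernel, rng):
        y = rng.uniform(18, 90, 40)
        state = fit_rvr(kernel, y)
        pred = predict_rvr(state, np.zeros((3, 40)))
        bias = state.mu[0] if 0 in state.active else 0.0
        np.testing.assert_allclose(pred, bias, atol=1e-10)

    def test_duplicate_test_rows_identical_predictions(self, kernel, rng):
        y = rng.uniform(18, 90, 40)
        state = fit_rvr(kernel, y)
        kc = np.vstack([kernel[3], kernel[3]])
        pred = predict_rvr(state, kc)
        assert pred[0] == pred[1]

    def test_rvr_and_gpr_agree_on_generator_cohorts(self):
        """On synthetic aging cohorts both kernel methods are bounded by the
        same irreducible network-coherent noise, so their held-out MAEs
        agree within 20% on average over 10 seeds."""
        from netage.synthetic import CohortSpec, make_cohort, make_masks

        masks = make_masks((12, 12, 12), 1, seed=2)
        sup = masks[0].values.astype(bool)
        ratios = []
        for seed in range(10):
            spec = CohortSpec(n_subjects=55, grid_dims=(12, 12, 12),
                              n_networks=1, target_r=(-0.8,), seed=seed)
            subs, _ = make_cohort(spec, masks)
            ages = np.array([s.age for s in subs])
            feats = np.stack([s.gm.values[sup] for s in subs]).astype(float)
            k = trace_normalize(linear_similarity(feats))
            tr, te = np.arange(40), np.arange(40, 55)
            kn, kc = k[np.ix_(tr, tr)], k[np.ix_(te, tr)]
            mae_rvr = np.abs(
                predict_rvr(fit_rvr(kn, ages[tr]), kc) - ages[te]
            ).mean()
            mae_gpr = np.abs(
                predict_gpr(
                    fit_gpr(kn, ages[tr], GprOptions(center_kernel=True)), kc
                )
                - ages[te]
            ).mean()
            ratios.append(mae_rvr / mae_gpr)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_gpr_centering_recovers_signal_small_cohort(self):
        """Uncentered baseline-dominated kernels push the evidence to the
        mean predictor at small n; centering restores the age signal."""
        rng = np.random.default_rng(0)
        ages = rng.uniform(18, 90, 40)
        ages_t = rng.uniform(18, 90, 15)
        feats = lambda a: 0.6 - 0.002 * (a[:, None] - 54) + 0.05 * (
            rng.standard_normal((a.size, 60))
        )
        x, xt = feats(ages), feats(ages_t)
        k = linear_similarity(x)
        scale = np.trace(k) / 40
        kn, kc = k / scale, linear_similarity(xt, x) / scale
        pred = predict_gpr(
            fit_gpr(kn, ages, GprOptions(center_kernel=True)), kc
        )
        mae = np.abs(pred - ages_t).mean()
        base = np.abs(ages_t - ages.mean()).mean()
        assert mae < 0.5 * base

    def test_prediction_invariant_to_subject_permutation(self, kernel, rng):
        y = rng.uniform(18, 90, 40)
        perm = np.random.default_rng(1).permutation(40)
        pred = predict_rvr(fit_rvr(kernel, y), kernel[:5])
        pred_p = predict_rvr(
            fit_rvr(kernel[np.ix_(perm, perm)], y[perm]),
            kernel[np.ix_(np.arange(5), perm)],
        )
        np.testing.assert_allclose(pred, pred_p, rtol=1e-4, atol=1e-5)
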