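import numpy as np
import pytest
from hypothesis import given, strategies as st

from plmmkit import (
    PenaltySpec,
    design_from_arrays,
    fit_path,
    format_coefficients,
    kkt_violation,
    lambda_path,
    penalized_objective,
    plmm,
    scalar_update,
    soft_threshold,
)
from plmmkit.exceptions import ConfigurationError

from oracles import enet_objective, fista_enet


class TestScalarOperators:
    @pytest.mark.parametrize("z,t,expected", [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2)])
    def test_soft_threshold(self, z, t, expected):
        assert soft_threshold(z, t) == expected

    @given(st.floats(-50, 50), st.floats(0, 10))
    def test_soft_threshold_shrinks_toward_zero(self, z, t):
        out = soft_threshold(z, t)
        assert abs(out) <= abs(z) + 1e-12
        assert out * z >= 0

    def test_mcp_firm_threshold_value(self):
        spec = PenaltySpec("mcp", gamma=3.0)
        assert scalar_update(1.0, 0.5, spec) == pytest.approx(0.75)

    def test_mcp_identity_region(self):
        spec = PenaltySpec("mcp", gamma=3.0)
        assert scalar_update(2.0, 0.5, spec) == pytest.approx(2.0)

    @pytest.mark.parametrize("family", ["lasso", "mcp", "scad"])
    def test_zero_lambda_no_shrinkage(self, family):
        spec = PenaltySpec(family)
        assert scalar_update(1.7, 0.0, spec) == pytest.approx(1.7)

    def test_scad_matches_explicit_three_piece_rule(self):
        spec = PenaltySpec("scad", gamma=3.7)
        lam = 0.4
        # region 1: |z| <= 2*lam
        assert scalar_update(0.7, lam, spec) == pytest.approx(soft_threshold(0.7, lam))
        # region 3: |z| > gamma*lam -> identity
        assert scalar_update(2.0, lam, spec) == pytest.approx(2.0)
        # region 2 interpolates
        z = 1.0
        g = spec.gamma
        expected = soft_threshold(z, g * lam / (g - 1)) / (1 - 1 / (g - 1))
        assert scalar_update(z, lam, spec) == pytest.approx(expected)

    def test_unpenalized_column_gets_plain_ols_update(self):
        for family in ("lasso", "mcp", "scad"):
            spec = PenaltySpec(family)
            assert scalar_update(1.3, 5.0, spec, v=2.0, penalty_factor=0.0) == \
                pytest.approx(0.65)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ConfigurationError):
            PenaltySpec("mcp", gamma=1.0)
        with pytest.raises(ConfigurationError):
            PenaltySpec("scad", gamma=2.0)


class TestLambdaPath:
    def _toy(self, rng, n=40, p=12):
        X = rng.normal(size=(n, p))
        X = np.column_stack([np.ones(n), (X - X.mean(0)) / X.std(0)])
        y = rng.normal(size=n)
        pf = np.concatenate([[0.0], np.ones(p)])
        return X, y, pf

    def test_log_spacing_and_length(self, rng):
        X, y, pf = self._toy(rng)
        lams = lambda_path(X, y, pf, n_lambda=100, lambda_min_ratio=0.01)
        assert len(lams) == 100
        ratios = lams[1:] / lams[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)
        np.testing.assert_allclose(lams[-1] / lams[0], 0.01, rtol=1e-10)

    def test_null_model_at_lambda_max(self, rng):
        X, y, pf = self._toy(rng)
        lams = lambda_path(X, y, pf, n_lambda=5, lambda_min_ratio=0.5)
        fit = fit_path(X, y, PenaltySpec("lasso"), lams, pf)
        assert np.all(fit.beta[1:, 0] == 0.0)

    def test_just_below_lambda_max_activates_a_feature(self, rng):
        X, y, pf = self._toy(rng)
        lam_max = lambda_path(X, y, pf, n_lambda=2, lambda_min_ratio=0.99)[0]
        lams = np.array([lam_max, lam_max * (1 - 1e-6)])
        fit = fit_path(X, y, PenaltySpec("lasso"), lams, pf, tol=1e-10)
        assert np.all(fit.beta[1:, 0] == 0.0)
        assert np.any(fit.beta[1:, 1] != 0.0)

    def test_all_unpenalized_is_error(self, rng):
        X, y, _ = self._toy(rng)
        with pytest.raises(ConfigurationError):
            lambda_path(X, y, np.zeros(X.shape[1]))


class TestFitPath:
    def test_orthonormal_design_closed_form(self, rng):
        """With (1/n)X'X = I the lasso solution is the soft-thresholded OLS fit."""
        n, p = 64, 4
        M = rng.normal(size=(n, n))
        Q, _ = np.linalg.qr(M)
        X = Q[:, :p] * np.sqrt(n)  # columns orthogonal with mean square 1
        y = rng.normal(size=n)
        pf = np.ones(p)
        lam = 0.15
        fit = fit_path(X, y, PenaltySpec("lasso"), np.array([lam]), pf, tol=1e-12)
        z = X.T @ y / n
        expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0)
        np.testing.assert_allclose(fit.beta[:, 0], expected, atol=1e-8)

    def test_matches_proximal_gradient_oracle(self, rng):
        n, p = 20, 5
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 0.8 + rng.normal(size=n)
        pf = np.ones(p)
        lams = lambda_path(X, y, pf, n_lambda=10, lambda_min_ratio=0.05)
        fit = fit_path(X, y, PenaltySpec("lasso"), lams, pf, tol=1e-10)
        for i, lam in enumerate(lams):
            ours = enet_objective(X, y, fit.beta[:, i], lam, 1.0, pf)
            ref = enet_objective(X, y, fista_enet(X, y, lam, 1.0, pf), lam, 1.0, pf)
            assert abs(ours - ref) < 1e-7

    def test_mcp_large_gamma_approaches_lasso(self, rng):
        n, p = 50, 20
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        pf = np.ones(p)
        lams = lambda_path(X, y, pf, n_lambda=8, lambda_min_ratio=0.1)
        lasso = fit_path(X, y, PenaltySpec("lasso"), lams, pf, tol=1e-10)
        mcp = fit_path(X, y, PenaltySpec("mcp", gamma=1e6), lams, pf, tol=1e-10)
        assert np.abs(lasso.beta - mcp.beta).max() < 1e-4

    def test_kkt_certified_along_path(self, rng):
        n, p = 45, 25
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        pf = np.ones(p)
        for alpha in (1.0, 0.6):
            lams = lambda_path(X, y, pf, alpha=alpha, n_lambda=12,
                               lambda_min_ratio=0.05)
            fit = fit_path(X, y, PenaltySpec("lasso", alpha=alpha), lams, pf, tol=1e-9)
            for i, lam in enumerate(lams):
                assert kkt_violation(X, y, fit.beta[:, i], lam, pf, alpha) < 1e-6

    def test_objective_monotone_over_sweeps(self, rng):
        n, p = 30, 40
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        pf = np.ones(p)
        lams = lambda_path(X, y, pf, n_lambda=4, lambda_min_ratio=0.1)
        fit = fit_path(X, y, PenaltySpec("lasso"), lams, pf, record_objective=True)
        assert fit.objectives
        _, trace = fit.objectives[0]
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-10)

    def test_chunked_streaming_identical_to_dense(self, rng):
        n, p = 35, 30
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        pf = np.ones(p)
        lams = lambda_path(X, y, pf, n_lambda=6, lambda_min_ratio=0.1)
        dense = fit_path(X, y, PenaltySpec("lasso"), lams, pf)
        chunked = fit_path(X, y, PenaltySpec("lasso"), lams, pf, chunk_features=7)
        np.testing.assert_allclose(dense.beta, chunked.beta, atol=1e-12)


class TestFormat:
    def test_null_model_passthrough(self):
        beta_std = np.zeros((3, 2))
        beta_std[0] = [1.5, -0.5]
        out = format_coefficients(beta_std, np.array([1.0, 2.0]), np.array([2.0, 3.0]))
        np.testing.assert_array_equal(out, beta_std)

    def test_single_feature_hand_example(self):
        beta_std = np.array([[0.0], [1.0]])
        out = format_coefficients(beta_std, np.array([1.0]), np.array([2.0]))
        assert out[1, 0] == pytest.approx(0.5)
        assert out[0, 0] == pytest.approx(-0.5)

    def test_prediction_equivalence_raw_vs_standardized(self, rng):
        n, p = 25, 6
        X = rng.normal(size=(n, p)) * 3 + 1
        centers = X.mean(0)
        scales = np.sqrt(((X - centers) ** 2).mean(0))
        Xs = (X - centers) / scales
        beta_std = rng.normal(size=(p + 1, 4))
        out = format_coefficients(beta_std, centers, scales)
        pred_std = beta_std[0] + Xs @ beta_std[1:]
        pred_raw = out[0] + X @ out[1:]
        np.testing.assert_allclose(pred_raw, pred_std, atol=1e-10)


class TestPlmmPipeline:
    @pytest.mark.parametrize("family", ["lasso", "mcp", "scad"])
    def test_eta_zero_reduces_to_plain_regression(self, small_dataset, family):
        _, _, _, d = small_dataset
        plain = plmm(d, penalty=family, precondition=False, tol=1e-12, n_lambda=25)
        rotated = plmm(d, penalty=family, eta=0.0, lambdas=plain.lambdas, tol=1e-12)
        diff = np.abs(rotated.beta_original.toarray() - plain.beta_original.toarray())
        assert diff.max() < 1e-8

    def test_sparsity_at_lambda_max(self, small_dataset):
        _, _, _, d = small_dataset
        fit = plmm(d, n_lambda=20)
        assert fit.nonzero_counts()[0] == 0

    def test_rotated_consistency_of_stored_predictors(self, small_dataset):
        """Standardize-then-rotate-then-predict equals the stored rotated fit."""
        _, _, _, d = small_dataset
        fit = plmm(d, n_lambda=15)
        from plmmkit import build_preconditioner, rotate

        pc = build_preconditioner(fit.eig, fit.eta)
        X_aug = np.column_stack([np.ones(d.n_samples), np.asarray(d.X_std)])
        Xt, yt = rotate(pc, X_aug, d.y)
        B = fit.beta_std.toarray()
        lp_rot = Xt @ B
        lp_rot_expected = pc.apply(fit.linear_predictors)
        np.testing.assert_allclose(lp_rot, lp_rot_expected, atol=1e-8)

    def test_filebacked_pipeline_matches_in_memory(self, tmp_path):
        import plmmkit as pk

        spec = pk.SimSpec(n_samples=50, n_features=120, eta_true=0.4, seed=9,
                          missing_rate=0.02)
        g = pk.simulate_genotypes(spec)
        y, _ = pk.simulate_phenotype(g, spec)
        import pandas as pd

        tab = pd.DataFrame({"ID": [iid for _, iid in g.sample_ids], "y": y})
        d_mem = pk.create_design(g, tab, "ID", "y")
        g_fb = g.to_filebacked(tmp_path / "g.fbm", chunk_features=17)
        d_fb = pk.create_design(g_fb, tab, "ID", "y",
                                backing_path=tmp_path / "d", chunk_features=13)
        assert d_fb.storage_mode == "filebacked"
        np.testing.assert_allclose(np.asarray(d_fb.X_std), np.asarray(d_mem.X_std),
                                   atol=1e-12)
        f_mem = pk.plmm(d_mem, n_lambda=20, chunk_features=11)
        f_fb = pk.plmm(d_fb, n_lambda=20, chunk_features=11)
        np.testing.assert_allclose(f_fb.beta_original.toarray(),
                                   f_mem.beta_original.toarray(), atol=1e-10)
        assert abs(f_fb.eta - f_mem.eta) < 1e-10
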