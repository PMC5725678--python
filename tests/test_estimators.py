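"""IVW estimators, PCA-IVW, 2SLS, and their analytic identities."""

import numpy as np
import pytest
import scipy.linalg

from finemr import (
    DegenerateInstrumentError,
    LDMatrix,
    SingularMatrixError,
    SummarySet,
    build_omega,
    build_psi,
    compute_ld,
    ivw_correlated,
    ivw_uncorrelated,
    marginal_summaries,
    pca_ivw,
    two_stage_least_squares,
)
from finemr.simulate import LDSpec, gen_individual

from conftest import random_dataset


class TestIVWUncorrelated:
    def test_single_variant_is_the_ratio(self):
        data = SummarySet(["a"], [0.5], [0.05], [0.1], [0.05])
        est = ivw_uncorrelated(data)
        assert est.estimate == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.ci_lower == pytest.approx(0.2 - 1.959964 * 0.1)

    def test_duplicated_variant_pools_fixed_effect(self):
        one = SummarySet(["a"], [0.5], [0.05], [0.1], [0.05])
        two = SummarySet(["a", "b"], [0.5] * 2, [0.05] * 2, [0.1] * 2, [0.05] * 2)
        assert ivw_uncorrelated(two).estimate == pytest.approx(ivw_uncorrelated(one).estimate)
        assert ivw_uncorrelated(two).se == pytest.approx(ivw_uncorrelated(one).se / np.sqrt(2))

    def test_equals_weighted_zero_intercept_regression(self, rng):
        data, _ = random_dataset(rng, 10)
        est = ivw_uncorrelated(data)
        # independent oracle: closed-form normal equation of the weighted fit
        w = data.se_y ** -2
        slope = np.sum(w * data.beta_x * data.beta_y) / np.sum(w * data.beta_x ** 2)
        assert est.estimate == pytest.approx(slope, rel=1e-12)

    def test_all_zero_beta_x_rejected(self):
        data = SummarySet(["a", "b"], [0.0, 0.0], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1])
        with pytest.raises(DegenerateInstrumentError):
            ivw_uncorrelated(data)


class TestBuildOmega:
    def test_identity_rho_gives_diagonal(self, small_dataset):
        data, ld = small_dataset
        eye = LDMatrix(ld.variant_ids, np.eye(len(ld)))
        omega = build_omega(data, eye).omega
        np.testing.assert_allclose(omega, np.diag(data.se_y ** 2), atol=1e-15)

    def test_two_variant_off_diagonal(self):
        data = SummarySet(["a", "b"], [0.2, 0.2], [0.02, 0.02], [0.1, 0.1], [0.1, 0.2])
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        omega = build_omega(data, ld).omega
        assert omega[0, 1] == pytest.approx(0.1 * 0.2 * 0.5)

    def test_elementwise_formula(self, small_dataset):
        data, ld = small_dataset
        omega = build_omega(data, ld).omega
        np.testing.assert_allclose(omega, omega.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(omega), data.se_y ** 2, rtol=1e-12)
        for i in range(3):
            for j in range(3):
                assert omega[i, j] == pytest.approx(
                    data.se_y[i] * data.se_y[j] * ld.rho[i, j]
                )


class TestIVWCorrelated:
    def test_identity_rho_reduces_to_uncorrelated(self, small_dataset):
        data, ld = small_dataset
        eye = LDMatrix(ld.variant_ids, np.eye(len(ld)))
        a, b = ivw_correlated(data, eye), ivw_uncorrelated(data)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)

    def test_perfectly_correlated_duplicates_raise(self):
        data = SummarySet(["a", "b"], [0.5] * 2, [0.05] * 2, [0.1] * 2, [0.05] * 2)
        ld = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(SingularMatrixError, match="prun|PCA"):
            ivw_correlated(data, ld)

    def test_pseudo_inverse_only_behind_flag(self):
        data = SummarySet(["a", "b"], [0.5] * 2, [0.05] * 2, [0.1] * 2, [0.05] * 2)
        ld = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        est = ivw_correlated(data, ld, use_pseudo_inverse=True)
        assert est.estimate == pytest.approx(0.2)

    def test_diagnostics_attached_by_default(self, small_dataset):
        data, ld = small_dataset
        est = ivw_correlated(data, ld)
        assert est.diagnostics is not None
        assert est.diagnostics.condition_number >= 1.0

    def test_negative_variance_reported_not_raised(self):
        # indefinite (but invertible) correlation matrix: inconsistent inputs
        rho = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        assert np.linalg.eigvalsh(rho)[0] < 0
        data = SummarySet(["a", "b", "c"], [0.3, 0.05, 0.3], [0.02] * 3,
                          [0.05, -0.2, 0.05], [0.05] * 3)
        ld = LDMatrix(["a", "b", "c"], rho)
        est = ivw_correlated(data, ld)
        assert not est.se_defined
        assert np.isnan(est.se) and np.isnan(est.ci_lower)
        assert np.isfinite(est.estimate)
        assert est.diagnostics.negative_variance

    def test_ridge_perturbs_towards_stability(self, small_dataset):
        data, ld = small_dataset
        raw = ivw_correlated(data, ld)
        ridged = ivw_correlated(data, ld, ridge=0.1)
        assert ridged.method == "ivw-corr(ridge=0.1)"
        assert ridged.diagnostics.condition_number < raw.diagnostics.condition_number

    def test_matches_2sls_on_individual_level_data(self):
        spec = LDSpec(kind="ar1", block_sizes=(5,), decay=0.6)
        gamma = np.array([0.3, 0.15, 0.0, 0.2, -0.1])
        g, x, y = gen_individual(20_000, spec, gamma, theta=0.5,
                                 confounding=0.5, seed=42)
        exp, out = marginal_summaries(g, x, y)
        ld = compute_ld(g, exp.variant_ids)
        data = SummarySet(exp.variant_ids, exp.beta, exp.se, out.beta, out.se)
        ivw = ivw_correlated(data, ld, attach_diagnostics=False)
        tsls = two_stage_least_squares(x, y, g)
        assert ivw.estimate == pytest.approx(tsls.estimate, rel=0.01)


class TestPCAIVW:
    def test_full_rank_equals_ivw_correlated(self, small_dataset):
        data, ld = small_dataset
        full = pca_ivw(data, ld, k=len(data))
        ref = ivw_correlated(data, ld)
        assert full.estimate == pytest.approx(ref.estimate, rel=1e-10)
        assert full.se == pytest.approx(ref.se, rel=1e-10)

    def test_duplicate_variants_collapse_to_single_ratio(self):
        data = SummarySet(["a", "b"], [0.5] * 2, [0.05] * 2, [0.1] * 2, [0.05] * 2)
        ld = LDMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        est = pca_ivw(data, ld, variance_threshold=0.99)
        assert est.n_instruments == 1
        assert est.estimate == pytest.approx(0.1 / 0.5)

    def test_matches_independent_gls_on_transformed_triple(self, rng):
        data, ld = random_dataset(rng, 30)
        k = 5
        est = pca_ivw(data, ld, k=k)
        psi = build_psi(data, ld)
        wk = psi.loadings[:, :k]
        omega_t = wk.T @ (np.outer(data.se_y, data.se_y) * ld.rho) @ wk
        bx_t, by_t = wk.T @ data.beta_x, wk.T @ data.beta_y
        # independent GLS route: whiten with a Cholesky factor, then OLS
        c = scipy.linalg.cholesky(omega_t, lower=True)
        xw = scipy.linalg.solve_triangular(c, bx_t, lower=True)
        yw = scipy.linalg.solve_triangular(c, by_t, lower=True)
        slope = float(xw @ yw) / float(xw @ xw)
        se = float(xw @ xw) ** -0.5
        assert est.estimate == pytest.approx(slope, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_se_non_increasing_in_k(self, rng):
        data, ld = random_dataset(rng, 12)
        ses = [pca_ivw(data, ld, k=k).se for k in range(1, 13)]
        assert all(s2 <= s1 + 1e-12 for s1, s2 in zip(ses, ses[1:]))

    def test_reports_cumulative_variance(self, small_dataset):
        data, ld = small_dataset
        est = pca_ivw(data, ld, variance_threshold=0.9)
        assert 0.9 <= est.info["cumulative_variance"] <= 1.0


class TestTwoStageLeastSquares:
    def test_single_binary_instrument_is_wald_ratio(self, rng):
        g = rng.integers(0, 2, 500).astype(float)
        x = 0.8 * g + rng.standard_normal(500)
        y = 0.3 * x + rng.standard_normal(500)
        est = two_stage_least_squares(x, y, g)
        wald = (y[g == 1].mean() - y[g == 0].mean()) / (x[g == 1].mean() - x[g == 0].mean())
        assert est.estimate == pytest.approx(wald, rel=1e-10)

    def test_noiseless_limit_recovers_effect_exactly(self, rng):
        g = rng.integers(0, 3, (200, 3)).astype(float)
        x = g @ np.array([0.5, -0.2, 0.1])
        y = 0.3 * x
        est = two_stage_least_squares(x, y, g)
        assert est.estimate == pytest.approx(0.3, abs=1e-12)

    def test_matches_projection_matrix_formula(self, rng):
        g = rng.integers(0, 3, (300, 5)).astype(float)
        x = g @ rng.normal(0.2, 0.1, 5) + rng.standard_normal(300)
        y = 0.4 * x + rng.standard_normal(300)
        est = two_stage_least_squares(x, y, g)
        # independent closed form: theta = (X' P X)^-1 X' P Y on centered data
        gc = g - g.mean(axis=0)
        xc, yc = x - x.mean(), y - y.mean()
        p = gc @ np.linalg.solve(gc.T @ gc, gc.T)
        theta = float(xc @ p @ yc) / float(xc @ p @ xc)
        assert est.estimate == pytest.approx(theta, rel=1e-10)

    def test_rank_deficient_instruments_rejected(self, rng):
        g = rng.integers(0, 3, (100, 2)).astype(float)
        g = np.column_stack([g, g[:, 0]])
        with pytest.raises(SingularMatrixError):
            two_stage_least_squares(rng.standard_normal(100), rng.standard_normal(100), g)
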