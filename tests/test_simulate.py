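"""Synthetic-data generators and the three simulation study designs."""

import numpy as np
import pytest

from finemr import two_stage_least_squares
from finemr.simulate import (
    LDSpec,
    SimConfig,
    draw_summary,
    example_region,
    gen_individual,
    gen_ld,
    gen_reference_panel,
    high_ld_region,
    marginal_summaries,
    run_calibration,
    run_ld_bootstrap,
    run_subset_sensitivity,
)


class TestGenLD:
    def test_zero_decay_is_identity(self):
        ld = gen_ld(LDSpec(kind="ar1", block_sizes=(6,), decay=0.0))
        np.testing.assert_array_equal(ld.rho, np.eye(6))

    def test_ar1_decay_powers(self):
        ld = gen_ld(LDSpec(kind="ar1", block_sizes=(3,), decay=0.8))
        assert ld.rho[0, 2] == pytest.approx(0.64)
        assert ld.rho[0, 1] == pytest.approx(0.8)

    def test_blocks_are_uncorrelated(self):
        ld = gen_ld(LDSpec(kind="ar1", block_sizes=(3, 4), decay=0.9))
        assert np.all(ld.rho[:3, 3:] == 0)

    def test_positive_definite_over_seeds(self):
        for seed in range(20):
            spec = LDSpec(kind="haplotype", block_sizes=(25,),
                          n_haplotypes=10, panel_n=200)
            ld = gen_ld(spec, seed=seed)
            assert np.linalg.eigvalsh(ld.rho)[0] > 1e-8
        for decay in (0.5, 0.95, 0.99):
            ld = gen_ld(LDSpec(kind="ar1", block_sizes=(30,), decay=decay))
            assert np.linalg.eigvalsh(ld.rho)[0] > 1e-8

    def test_deterministic_given_seed(self):
        spec = LDSpec(kind="haplotype", block_sizes=(20,), n_haplotypes=10,
                      panel_n=150)
        a, b = gen_ld(spec, seed=3), gen_ld(spec, seed=3)
        np.testing.assert_array_equal(a.rho, b.rho)


class TestDrawSummary:
    def test_null_outcome_mean(self):
        config = example_region(n_iter=1, theta=0.0, seed=0)
        ld = gen_ld(config.ld_spec, config.ld_seed)
        rng = np.random.default_rng(0)
        draws = np.array([draw_summary(config, rng, ld).beta_y for _ in range(3000)])
        mc_se = config.se_y / np.sqrt(3000)
        assert np.all(np.abs(draws.mean(axis=0)) < 3.5 * mc_se)

    def test_uncorrelated_outcome_draws(self):
        spec = LDSpec(kind="ar1", block_sizes=(2,), decay=0.0)
        config = SimConfig(ld_spec=spec, mu_x=[0.3, 0.2], se_x=0.02,
                           se_y=0.05, theta=0.0, n_iter=1, seed=0)
        rng = np.random.default_rng(1)
        ld = gen_ld(spec)
        draws = np.array([draw_summary(config, rng, ld).beta_y for _ in range(4000)])
        corr = np.corrcoef(draws.T)[0, 1]
        assert abs(corr) < 3 / np.sqrt(4000)

    def test_empirical_covariance_matches_omega(self):
        spec = LDSpec(kind="ar1", block_sizes=(5,), decay=0.7)
        config = SimConfig(ld_spec=spec, mu_x=np.full(5, 0.2), se_x=0.02,
                           se_y=0.05, theta=0.0, n_iter=1, seed=0)
        ld = gen_ld(spec)
        rng = np.random.default_rng(2)
        draws = np.array([draw_summary(config, rng, ld).beta_y for _ in range(50_000)])
        omega = np.outer(config.se_y, config.se_y) * ld.rho
        emp = np.cov(draws.T)
        rel = np.linalg.norm(emp - omega) / np.linalg.norm(omega)
        assert rel < 0.05

    def test_rounding_applied(self):
        config = example_region(n_iter=1, decimals=2)
        data = draw_summary(config)
        assert np.all(data.beta_x == np.round(data.beta_x, 2))
        assert np.all(data.se_y == np.round(data.se_y, 2))

    def test_fixed_seed_reproducible(self):
        config = example_region(n_iter=1, seed=5)
        a, b = draw_summary(config), draw_summary(config)
        np.testing.assert_array_equal(a.beta_x, b.beta_x)
        np.testing.assert_array_equal(a.beta_y, b.beta_y)


class TestRunCalibration:
    def test_nominal_type_one_error_identity_ld(self):
        spec = LDSpec(kind="ar1", block_sizes=(10,), decay=0.0)
        config = SimConfig(ld_spec=spec, mu_x=np.full(10, 0.3), se_x=0.02,
                           se_y=0.05, theta=0.0, n_iter=2000, seed=7,
                           estimator_grid=[("ivw", None)])
        rep = run_calibration(config)
        rate = rep["ivw"].rejection_rate
        band = 3 * 100 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 5.0) < band

    def test_mean_se_tracks_sd_when_well_specified(self):
        spec = LDSpec(kind="ar1", block_sizes=(10,), decay=0.6)
        config = SimConfig(ld_spec=spec, mu_x=np.full(10, 0.3), se_x=0.02,
                           se_y=0.05, theta=0.0, n_iter=2000, seed=8,
                           estimator_grid=[("ivw-corr", None)])
        s = run_calibration(config)["ivw-corr"]
        assert s.mean_se == pytest.approx(s.sd_estimates, rel=0.07)
        assert abs(s.mean_estimate) < 3 * s.sd_estimates / np.sqrt(2000)

    def test_power_exceeds_size_for_every_estimator(self):
        null = example_region(n_iter=400, theta=0.0, seed=9)
        alt = example_region(n_iter=400, theta=0.1, seed=9)
        r0, r1 = run_calibration(null), run_calibration(alt)
        for label in r0.stats:
            assert r1[label].rejection_rate > r0[label].rejection_rate

    def test_reproducible_with_seed(self):
        config = example_region(n_iter=50, seed=4)
        a, b = run_calibration(config), run_calibration(config)
        for label in a.stats:
            assert a[label].mean_estimate == b[label].mean_estimate
            assert a[label].rejection_rate == b[label].rejection_rate


class TestSubsetSensitivity:
    def test_full_fraction_has_zero_variance(self):
        config = example_region(n_iter=1, seed=3)
        config.estimator_grid = [("prune", 0.4), ("pca", 0.99)]
        rep = run_subset_sensitivity(config, subset_fraction=1.0, n_rep=10)
        for label in rep.stats:
            assert rep[label].sd_estimates == pytest.approx(0.0, abs=1e-15)

    def test_single_dominant_signal_pca_invariant(self):
        # identity LD, one overwhelming signal pinned into every subset:
        # the PCA estimate is (nearly) the causal variant's ratio throughout
        spec = LDSpec(kind="ar1", block_sizes=(20,), decay=0.0)
        mu = np.zeros(20)
        mu[7] = 0.5
        config = SimConfig(ld_spec=spec, mu_x=mu, se_x=1e-4, se_y=0.05,
                           theta=0.1, n_iter=1, seed=11,
                           estimator_grid=[("pca", 0.99)])
        rep = run_subset_sensitivity(config, subset_fraction=0.5, n_rep=100,
                                     always_keep=["v008"])
        assert rep["pca(var=0.99)"].sd_estimates == pytest.approx(0.0, abs=1e-3)

    def test_pruning_more_sensitive_than_pca_in_high_ld(self):
        config = high_ld_region(n_iter=1, seed=13, decimals=2)
        config.estimator_grid = [("prune", 0.8), ("pca", 0.99)]
        rep = run_subset_sensitivity(config, subset_fraction=0.5, n_rep=200)
        assert rep["prune(rho=0.8)"].sd_estimates > rep["pca(var=0.99)"].sd_estimates


class TestLDBootstrap:
    def test_no_resampling_equals_baseline(self):
        config = example_region(n_iter=1, seed=21)
        config.estimator_grid = [("prune", 0.4)]
        rep = run_ld_bootstrap(config, ref_n=400, n_rep=3, resample=False)
        assert rep["prune(rho=0.4)"].sd_estimates == pytest.approx(0.0, abs=1e-15)

    def test_large_panel_shrinks_variability(self):
        config = example_region(n_iter=1, seed=22)
        config.estimator_grid = [("ivw-corr", None)]
        small = run_ld_bootstrap(config, ref_n=150, n_rep=60)
        big = run_ld_bootstrap(config, ref_n=4000, n_rep=60)
        assert big["ivw-corr"].sd_estimates < small["ivw-corr"].sd_estimates

    def test_high_ld_liberal_pruning_yields_undefined_ses(self):
        config = high_ld_region(n_iter=1, seed=23)
        config.estimator_grid = [("prune", 0.8), ("pca", 0.99)]
        rep = run_ld_bootstrap(config, ref_n=503, n_rep=50)
        assert rep["prune(rho=0.8)"].n_undefined > 0
        assert rep["pca(var=0.99)"].n_undefined == 0


class TestIndividualLevel:
    def test_unconfounded_null_2sls_near_zero(self):
        spec = LDSpec(kind="ar1", block_sizes=(4,), decay=0.4)
        g, x, y = gen_individual(10_000, spec, [0.3, 0.2, 0.1, 0.2],
                                 theta=0.0, confounding=0.0, seed=1)
        est = two_stage_least_squares(x, y, g)
        assert abs(est.estimate) < 3 * est.se

    def test_confounded_null_ols_biased_2sls_not(self):
        spec = LDSpec(kind="ar1", block_sizes=(4,), decay=0.4)
        g, x, y = gen_individual(20_000, spec, [0.3, 0.2, 0.1, 0.2],
                                 theta=0.0, confounding=0.8, seed=2)
        xc, yc = x - x.mean(), y - y.mean()
        ols = float(xc @ yc) / float(xc @ xc)
        ols_se = np.sqrt(float((yc - ols * xc) @ (yc - ols * xc)) / (len(x) - 2)
                         / float(xc @ xc))
        assert abs(ols) > 5 * ols_se  # confounding biases the observational fit
        tsls = two_stage_least_squares(x, y, g)
        assert abs(tsls.estimate) < 3 * tsls.se

    def test_marginal_summaries_recover_implied_marginals(self):
        spec = LDSpec(kind="ar1", block_sizes=(5,), decay=0.6)
        gamma = np.array([0.4, 0.0, 0.2, 0.0, -0.3])
        g, x, _ = gen_individual(80_000, spec, gamma, theta=0.0, seed=3)
        exp, _ = marginal_summaries(g, x, x)
        # implied marginal effects: Cov(G) gamma / Var(G_j), from the sample
        cov = np.cov(g, rowvar=False)
        implied = cov @ gamma / np.diag(cov)
        np.testing.assert_allclose(exp.beta, implied, atol=4 * np.max(exp.se))

    def test_haplotype_panel_dosages_are_diploid(self):
        spec = LDSpec(kind="haplotype", block_sizes=(15,), n_haplotypes=8,
                      panel_n=100)
        panel = gen_reference_panel(spec, 100, seed=4)
        assert panel.shape == (100, 15)
        assert set(np.unique(panel)) <= {0.0, 1.0, 2.0}
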