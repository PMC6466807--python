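"""Self-tests of the synthetic-data generator: distributions, planted
degradation designs and determinism."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from degnorm.simulate import (
    SimulationConfig,
    apply_degradation,
    calibrate_lognormal_mu,
    coverage_from_starts,
    mixture_start_cdf,
    sample_read_starts,
    simulate_dataset,
    simulate_latent_counts,
)


class TestLatentCounts:
    def test_de_label_fractions(self):
        cfg = SimulationConfig(n_genes=400, depth_range=(8e5, 1.2e6), seed=1)
        rng = np.random.default_rng(cfg.seed)
        _, labels, fold, _, _ = simulate_latent_counts(cfg, rng)
        assert (labels == "up").sum() == 20
        assert (labels == "down").sum() == 20
        assert (fold[labels != "null"] >= 1.5).all()
        assert (fold[labels == "null"] == 1.0).all()

    def test_nb_moments_match_closed_form(self):
        """Sample variance of NB draws matches mu + phi*mu^2 within 3
        Monte-Carlo standard errors."""
        rng = np.random.default_rng(7)
        mu, phi = 300.0, 0.15
        k = 1.0 / phi
        draws = rng.negative_binomial(k, k / (k + mu), size=10_000).astype(float)
        target = mu + phi * mu * mu
        # SE of the sample variance from the empirical fourth moment
        m4 = ((draws - draws.mean()) ** 4).mean()
        se = math.sqrt((m4 - draws.var() ** 2) / draws.size)
        assert abs(draws.var(ddof=1) - target) < 3 * se

    def test_depth_scaling_hits_drawn_range(self):
        cfg = SimulationConfig(n_genes=500, depth_range=(1e6, 1.5e6), seed=3)
        rng = np.random.default_rng(cfg.seed)
        counts, *_ = simulate_latent_counts(cfg, rng)
        totals = counts.sum(axis=0)
        # expected totals match the drawn depths up to sampling noise and
        # the DE-gene perturbation
        assert (totals > 0.6e6).all() and (totals < 2.2e6).all()


class TestReadStarts:
    def test_start_distribution_matches_mixture_cdf(self):
        """Empirical start CDF vs the exact discretized truncated-mixture
        CDF: Kolmogorov distance below the 1% critical value at n=1e5."""
        rng = np.random.default_rng(5)
        L, r = 1200, 100
        mixture = (np.array([300.0, 800.0]), np.array([150.0, 90.0]),
                   np.array([0.4, 0.6]))
        starts = sample_read_starts(100_000, L, r, mixture, rng)
        grid = np.arange(1, L - r + 2)
        emp = np.searchsorted(np.sort(starts), grid, side="right") / starts.size
        exact = mixture_start_cdf(grid, L, r, mixture)
        d = np.abs(emp - exact).max()
        assert d < 1.63 / math.sqrt(starts.size)

    def test_point_mass_starts_stack_exactly(self):
        starts = np.full(25, 11, dtype=np.int64)
        cov = coverage_from_starts(starts, L=200, read_length=50)
        assert (cov[10:60] == 25).all()
        assert cov.sum() == 25 * 50

    def test_near_uniform_starts_give_trapezoidal_coverage(self):
        """A very flat mixture yields the classic trapezoid: ramp up over
        one read length, plateau, ramp down."""
        rng = np.random.default_rng(9)
        L, r = 1000, 100
        mixture = (np.array([L / 2.0]), np.array([50.0 * L]), np.array([1.0]))
        starts = sample_read_starts(200_000, L, r, mixture, rng)
        cov = coverage_from_starts(starts, L, r)
        ramp_up, plateau, ramp_down = cov[:r], cov[r : L - r], cov[L - r :]
        assert ramp_up[0] < 0.05 * plateau.mean()
        assert np.corrcoef(np.arange(r), ramp_up)[0, 1] > 0.99
        assert np.corrcoef(np.arange(r), ramp_down)[0, 1] < -0.99
        assert plateau.std() < 0.05 * plateau.mean()


class TestDegradation:
    def test_lognormal_mu_calibration(self):
        mu = calibrate_lognormal_mu(0.3, 1.0)
        u = np.linspace(1e-6, 1, 20001)
        removal = np.trapezoid(1 - stats.lognorm.cdf(u, 1.0, scale=np.exp(mu)), u)
        assert removal == pytest.approx(0.3, abs=1e-3)

    def test_empirical_removal_matches_analytic_expectation(self):
        rng = np.random.default_rng(13)
        L, r = 1000, 100
        mixture = (np.array([400.0]), np.array([250.0]), np.array([1.0]))
        starts = sample_read_starts(10_000, L, r, mixture, rng)
        mu, sigma = calibrate_lognormal_mu(0.3, 1.0), 1.0
        keep = apply_degradation(starts, L, mu, sigma, rng)
        p_drop = 1 - stats.lognorm.cdf(starts / L, sigma, scale=np.exp(mu))
        expect = p_drop.mean()
        se = math.sqrt((p_drop * (1 - p_drop)).sum()) / starts.size
        assert abs((1 - keep.mean()) - expect) < 3 * se

    def test_five_prime_reads_removed_preferentially(self):
        rng = np.random.default_rng(21)
        starts = np.concatenate([np.full(4000, 10), np.full(4000, 900)])
        keep = apply_degradation(starts, 1000, calibrate_lognormal_mu(0.3, 1.0), 1.0, rng)
        assert keep[:4000].mean() < keep[4000:].mean()

    def test_higher_severity_removes_more(self):
        rng = np.random.default_rng(31)
        L = 1000
        starts = rng.integers(1, 900, 20_000)
        mu0 = calibrate_lognormal_mu(0.3, 1.0)
        kept_mild = apply_degradation(starts, L, mu0, 1.0, np.random.default_rng(1)).mean()
        kept_severe = apply_degradation(starts, L, mu0 + 1.0, 1.0, np.random.default_rng(1)).mean()
        assert kept_severe < kept_mild


class TestDatasets:
    def test_setting_i_is_identity(self):
        cfg = SimulationConfig(n_genes=40, depth_range=(8e4, 1.2e5), setting="I", seed=2)
        ds = simulate_dataset(cfg)
        assert (ds.observed_counts == ds.latent_counts).all()
        assert (ds.true_deg_fraction == 0).all()
        assert not ds.degraded_mask.any()

    def test_observed_never_exceeds_latent(self, small_sim_ii):
        assert (small_sim_ii.observed_counts <= small_sim_ii.latent_counts).all()

    def test_setting_ii_degrades_three_to_five_samples(self, small_sim_ii):
        ds = small_sim_ii
        per_gene = ds.degraded_mask.sum(axis=1)
        deg = per_gene > 0
        assert deg.sum() == int(round(0.8 * ds.config.n_genes))
        assert set(np.unique(per_gene[deg])) <= {3, 4, 5}

    def test_setting_ii_sample_count_marginal_is_uniform(self):
        cfg = SimulationConfig(n_genes=900, depth_range=(1e5, 1.5e5), setting="II", seed=8)
        rng = np.random.default_rng(cfg.seed)
        from degnorm.simulate import _degradation_plan

        mask, _ = _degradation_plan(cfg, rng)
        per_gene = mask.sum(axis=1)
        obs = [int((per_gene == k).sum()) for k in (3, 4, 5)]
        chi2 = stats.chisquare(obs)
        assert chi2.pvalue > 1e-3

    def test_setting_iii_degrades_exactly_one_condition(self):
        cfg = SimulationConfig(n_genes=60, depth_range=(1.2e5, 1.8e5), setting="III", seed=4)
        ds = simulate_dataset(cfg)
        ctrl = ds.degraded_mask[:, : cfg.n_control]
        trt = ds.degraded_mask[:, cfg.n_control :]
        deg = ds.degraded_mask.any(axis=1)
        one_condition = (ctrl.all(axis=1) & ~trt.any(axis=1)) | (
            trt.all(axis=1) & ~ctrl.any(axis=1)
        )
        assert (one_condition[deg]).all()

    def test_setting_iv_design(self):
        cfg = SimulationConfig(n_genes=50, depth_range=(1e5, 1.5e5), setting="IV", seed=6)
        ds = simulate_dataset(cfg)
        deg = ds.degraded_mask.any(axis=1)
        ctrl = ds.degraded_mask[deg, : cfg.n_control]
        trt = ds.degraded_mask[deg, cfg.n_control :]
        assert (ctrl.sum(axis=1) == 2).all()
        assert trt.all()

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(n_genes=25, depth_range=(5e4, 7e4), setting="II", seed=77)
        a = simulate_dataset(cfg)
        b = simulate_dataset(dataclasses.replace(cfg))
        assert (a.latent_counts == b.latent_counts).all()
        assert (a.observed_counts == b.observed_counts).all()
        assert all(
            (x.F == y.F).all() for x, y in zip(a.coverage, b.coverage)
        )
        assert (a.de_labels == b.de_labels).all()

    def test_severity_increases_mean_removal(self):
        base = SimulationConfig(n_genes=40, depth_range=(8e4, 1.2e5), setting="II", seed=9)
        heavy = dataclasses.replace(base, deg_mean_removal=0.5)
        da, db = simulate_dataset(base), simulate_dataset(heavy)
        assert (
            db.true_deg_fraction[db.degraded_mask].mean()
            > da.true_deg_fraction[da.degraded_mask].mean()
        )
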