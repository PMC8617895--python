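"""Rupture-force densities, survival curves, hazard extraction, dwell rates."""

import numpy as np
import pytest
from scipy import stats

from pullfold import (
    EmpiricalDistribution,
    RuptureForceSample,
    SimulationConfig,
    apply_fold_cutoff,
    dwell_rates_from_labels,
    generate_hopping_trace,
    rates_from_survival,
    rupture_density,
    sample_rupture_forces,
    survival_from_density,
    unfold_rate,
)


def be_ramp_survival(f, f0, k0, bx, r):
    """Closed-form survival for hazard k0*exp(bx*f) under an increasing ramp."""
    return np.exp(-(k0 / (r * bx)) * (np.exp(bx * f) - np.exp(bx * f0)))


def analytic_unfold_dist(cfg, edges):
    """Exact bin-averaged density and edge survival for the unfold hazard."""
    bx = cfg.ctx.beta * cfg.be.x_dagger
    k0 = np.exp(cfg.be.log_k0_unfold)
    surv = be_ramp_survival(edges, cfg.f_start, k0, bx, cfg.loading_rate)
    mass = surv[:-1] - surv[1:]
    mass = mass / mass.sum()
    density = mass / np.diff(edges)
    counts = np.full(edges.size - 1, 10_000)
    return EmpiricalDistribution(edges, density, counts), surv


class TestRuptureDensity:
    def test_point_mass_density(self):
        s = RuptureForceSample("unfold", np.full(10, 18.1), 6.0)
        dist = rupture_density(s, bin_width=0.5)
        assert dist.density.max() == pytest.approx(1 / 0.5)

    @pytest.mark.parametrize("n", [3, 50, 1000])
    def test_normalization(self, n):
        rng = np.random.default_rng(n)
        s = RuptureForceSample("unfold", rng.normal(18, 1.5, n), 6.0)
        dist = rupture_density(s, 0.5)
        assert np.sum(dist.density * np.diff(dist.bin_edges)) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        s = RuptureForceSample("unfold", np.array([]), 6.0)
        with pytest.raises(ValueError):
            rupture_density(s, 0.5)

    def test_large_sample_matches_analytic_density(self, sim_cfg):
        s = sample_rupture_forces(sim_cfg, "unfold", 10_000)
        bx = sim_cfg.ctx.beta * sim_cfg.be.x_dagger
        k0 = np.exp(sim_cfg.be.log_k0_unfold)

        def cdf(f):
            return 1.0 - be_ramp_survival(f, sim_cfg.f_start, k0, bx, sim_cfg.loading_rate)

        res = stats.kstest(s.forces, cdf)
        assert res.pvalue > 0.01


class TestSurvival:
    def test_unfold_boundaries(self):
        s = RuptureForceSample("unfold", np.random.default_rng(0).normal(18, 1, 500), 6.0)
        surv = survival_from_density(rupture_density(s, 0.5), "unfold")
        assert surv.prob[0] == pytest.approx(1.0)
        assert surv.prob[-1] == pytest.approx(0.0)
        assert np.all(np.diff(surv.prob) <= 0)

    def test_fold_boundaries(self):
        s = RuptureForceSample("fold", np.random.default_rng(0).normal(3.5, 0.6, 500), 6.0)
        surv = survival_from_density(rupture_density(s, 0.5), "fold")
        assert surv.prob[-1] == pytest.approx(1.0)
        assert surv.prob[0] == pytest.approx(0.0)
        assert np.all(np.diff(surv.prob) >= 0)

    def test_matches_closed_form_at_large_n(self, sim_cfg):
        s = sample_rupture_forces(sim_cfg, "unfold", 10_000)
        dist = rupture_density(s, 0.5)
        surv = survival_from_density(dist, "unfold")
        bx = sim_cfg.ctx.beta * sim_cfg.be.x_dagger
        k0 = np.exp(sim_cfg.be.log_k0_unfold)
        exact = be_ramp_survival(surv.force, sim_cfg.f_start, k0, bx, sim_cfg.loading_rate)
        assert np.max(np.abs(surv.prob - exact)) < 0.02

    def test_unnormalized_input_rejected(self):
        edges = np.array([0.0, 1.0, 2.0])
        dist = EmpiricalDistribution(edges, np.array([0.5, 0.5]), np.array([5, 5]))
        dist.density = dist.density * 1.5  # corrupt after validation
        with pytest.raises(ValueError):
            survival_from_density(dist, "unfold")


class TestRatesFromSurvival:
    def test_recovers_generating_hazard_exactly(self, sim_cfg, ctx):
        # analytic density + analytic survival -> k = r*rho/S is the hazard
        edges = np.arange(14.0, 23.0 + 0.05, 0.1)
        dist, surv_exact = analytic_unfold_dist(sim_cfg, edges)
        surv = survival_from_density(dist, "unfold")
        curve = rates_from_survival(dist, surv, sim_cfg.loading_rate, n_bootstrap=0)
        expected = unfold_rate(curve.force, sim_cfg.be, ctx)
        # the window-normalisation factor cancels between rho and P
        assert np.max(np.abs(curve.rate / expected - 1)) < 0.01

    def test_low_survival_bins_dropped(self):
        edges = np.array([0.0, 1.0, 2.0, 3.0])
        dist = EmpiricalDistribution(
            edges, np.array([0.5, 0.45, 0.05]), np.array([50, 45, 5])
        )
        surv = survival_from_density(dist, "unfold")
        curve = rates_from_survival(dist, surv, 6.0, min_survival=0.05, n_bootstrap=0)
        # last bin has midpoint survival 0.025 < 0.05 -> absent
        assert curve.force.size == 2
        assert np.all(curve.force < 2.0)

    def test_min_count_threshold(self):
        edges = np.array([0.0, 1.0, 2.0])
        dist = EmpiricalDistribution(edges, np.array([0.96, 0.04]), np.array([96, 4]))
        surv = survival_from_density(dist, "unfold")
        curve = rates_from_survival(dist, surv, 6.0, min_count=5, n_bootstrap=0)
        assert curve.force.size == 1

    def test_nonpositive_loading_rate_rejected(self):
        edges = np.array([0.0, 1.0])
        dist = EmpiricalDistribution(edges, np.array([1.0]), np.array([10]))
        surv = survival_from_density(dist, "unfold")
        with pytest.raises(ValueError):
            rates_from_survival(dist, surv, 0.0)

    def test_mode_identity(self, sim_cfg, ctx):
        # stationarity of rho = (k/r) S puts the mode where k(f*) = r*beta*x
        s = sample_rupture_forces(sim_cfg, "unfold", 10_000)
        dist = rupture_density(s, 0.5)
        f_mode = dist.midpoints[int(np.argmax(dist.density))]
        bx = ctx.beta * sim_cfg.be.x_dagger
        target = sim_cfg.loading_rate * bx
        f_analytic = np.log(target / np.exp(sim_cfg.be.log_k0_unfold)) / bx
        assert abs(f_mode - f_analytic) <= 0.5  # within one bin width

    def test_bootstrap_errors_are_reported(self, sim_cfg):
        s = sample_rupture_forces(sim_cfg, "unfold", 2000)
        dist = rupture_density(s, 0.5)
        surv = survival_from_density(dist, "unfold")
        curve = rates_from_survival(dist, surv, 6.0, n_bootstrap=100, seed=1)
        assert curve.se_log_rate is not None
        finite = np.isfinite(curve.se_log_rate)
        assert finite.sum() >= curve.force.size - 1
        assert np.all(curve.se_log_rate[finite] > 0)


class TestCensoring:
    def test_fold_cutoff_moves_events_to_censored(self):
        s = RuptureForceSample("fold", np.array([1.2, 1.8, 2.5, 3.0, 4.0]), 6.0)
        out = apply_fold_cutoff(s, 2.0)
        assert out.n_censored == 2
        assert out.forces.min() >= 2.0
        assert out.forces.size == 3

    def test_unfold_samples_unchanged(self):
        s = RuptureForceSample("unfold", np.array([15.0, 18.0]), 6.0)
        assert apply_fold_cutoff(s, 2.0) is s


class TestDwellRates:
    def test_alternating_unit_dwells(self):
        dt = 0.001
        one_second = int(1 / dt)
        labels = np.tile(np.repeat([0, 1], one_second), 5)
        times = np.arange(labels.size) * dt
        k_u, k_f = dwell_rates_from_labels(labels, times)
        assert k_u == pytest.approx(1.0, rel=0.01)
        assert k_f == pytest.approx(1.0, rel=0.01)

    def test_telegraph_recovery(self, ctx):
        # hairpin-like fast two-state kinetics: k_unfold=2/s, k_fold=5/s at 15 pN
        from pullfold import BellEvansParams, fold_rate

        f_level, x = 15.0, 9.0
        p = BellEvansParams(
            x_dagger=x,
            x_star=x,
            log_k0_unfold=float(np.log(2.0) - ctx.beta * f_level * x),
            log_k0_fold=float(np.log(5.0) + ctx.beta * f_level * x),
        )
        assert unfold_rate(f_level, p, ctx) == pytest.approx(2.0)
        assert fold_rate(f_level, p, ctx) == pytest.approx(5.0)
        duration = 1000 * (1 / 2.0 + 1 / 5.0)  # ~1000 dwells per state
        t, f, labels = generate_hopping_trace(
            p, f_level, duration, ctx=ctx, sampling_rate=1000.0, seed=4
        )
        k_u, k_f = dwell_rates_from_labels(labels, t)
        assert k_u == pytest.approx(2.0, rel=0.05)
        assert k_f == pytest.approx(5.0, rel=0.05)

    def test_single_state_trace_rejected(self):
        labels = np.zeros(100)
        times = np.arange(100) * 0.01
        with pytest.raises(ValueError, match="U"):
            dwell_rates_from_labels(labels, times)
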