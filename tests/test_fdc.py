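"""Median filtering, baseline fitting, state classification, event forces."""

import numpy as np
import pytest

from pullfold import (
    AnalysisConfig,
    PullingTrace,
    classify_states,
    first_transition_force,
    fit_folded_baseline,
    median_filter,
)
from pullfold.fdc import DegenerateModelError, FoldedBaseline
from pullfold.pipeline import detect_events


def make_trace(force, direction="unfold", k_eff=0.05, rate=6.0, fs=1000.0):
    force = np.asarray(force, dtype=float)
    n = force.size
    t = np.arange(n) / fs
    lam = (1.0 + rate * t) / k_eff if direction == "unfold" else (30.0 - rate * t) / k_eff
    return PullingTrace(t, lam, force, direction, rate, fs)


def two_branch_trace(k_eff=0.05, jump=0.8, f_rup=18.0, noise=0.0, seed=0, fs=1000.0, f_max=29.8):
    """Folded baseline rising at 6 pN/s with a rupture drop of `jump` pN."""
    rng = np.random.default_rng(seed)
    t = np.arange(0, (f_max - 1.0) / 6.0, 1 / fs)
    fb = 1.0 + 6.0 * t
    lam = fb / k_eff
    idx = int(np.argmax(fb >= f_rup))
    force = fb.copy()
    force[idx:] -= jump
    if noise:
        force += rng.normal(0, noise, force.size)
    trace = PullingTrace(t, lam, force, "unfold", 6.0, fs)
    return trace, idx


class TestMedianFilter:
    def test_window_one_is_identity(self):
        trace = make_trace(np.linspace(1, 20, 200))
        out = median_filter(trace, 1)
        assert np.array_equal(out.force, trace.force)

    def test_constant_trace_unchanged(self):
        trace = make_trace(np.full(100, 5.0))
        trace = PullingTrace(trace.time, trace.lam, trace.force, "unfold", 6.0, 1000.0)
        out = median_filter(trace, 11)
        assert np.allclose(out.force, 5.0)

    def test_removes_single_sample_spike(self):
        f = np.full(100, 5.0)
        f[50] += 5.0
        trace = make_trace(f)
        out = median_filter(trace, 5)
        assert np.allclose(out.force, 5.0)

    def test_even_window_rejected(self):
        trace = make_trace(np.linspace(1, 20, 50))
        with pytest.raises(ValueError):
            median_filter(trace, 4)

    def test_idempotent_on_monotone_segments(self):
        trace = make_trace(np.linspace(1, 20, 300))
        once = median_filter(trace, 11)
        twice = median_filter(once, 11)
        assert np.allclose(once.force, twice.force)


class TestFoldedBaseline:
    def test_exact_line_recovered(self):
        lam = np.linspace(20, 400, 500)
        trace = PullingTrace(np.arange(500) / 1000.0, lam, 0.05 * lam, "unfold", 6.0, 1000.0)
        base = fit_folded_baseline(trace, region=(20, 400))
        assert base.k_eff == pytest.approx(0.05, abs=1e-12)
        assert base.sigma == pytest.approx(0.0, abs=1e-12)

    def test_noisy_line_within_one_percent(self):
        rng = np.random.default_rng(8)
        lam = np.linspace(20, 400, 1000)
        f = 0.05 * lam + rng.normal(0, 0.2, lam.size)
        trace = PullingTrace(np.arange(1000) / 1000.0, lam, f, "unfold", 6.0, 1000.0)
        base = fit_folded_baseline(trace, region=(20, 400))
        assert base.k_eff == pytest.approx(0.05, rel=0.01)
        assert base.sigma == pytest.approx(0.2, rel=0.25)

    def test_too_few_samples_rejected(self):
        trace = make_trace(np.linspace(1, 20, 100))
        with pytest.raises(ValueError):
            fit_folded_baseline(trace, region=(1e6, 2e6))


class TestClassifyStates:
    def test_noiseless_trace_labelled_exactly(self):
        trace, idx = two_branch_trace(noise=0.0)
        base = FoldedBaseline(k_eff=0.05, intercept=0.0, sigma=0.01, n_points=100)
        labels = classify_states(trace, base, expected_jump=0.8, debounce=5)
        truth = (np.arange(trace.force.size) >= idx).astype(int)
        assert np.array_equal(labels.states, truth)
        assert [tr[0] for tr in labels.transitions] == [idx]

    def test_zero_sigma_on_component_means_is_nearest_mean(self):
        trace, idx = two_branch_trace(noise=0.0)
        base = FoldedBaseline(k_eff=0.05, intercept=0.0, sigma=0.0, n_points=100)
        labels = classify_states(trace, base, expected_jump=0.8, debounce=5)
        assert labels.states[idx:].all() and not labels.states[:idx].any()

    def test_zero_sigma_off_means_is_degenerate(self):
        trace, _ = two_branch_trace(noise=0.05, seed=1)
        base = FoldedBaseline(k_eff=0.05, intercept=0.0, sigma=0.0, n_points=100)
        with pytest.raises(DegenerateModelError):
            classify_states(trace, base, expected_jump=0.8)

    def test_all_folded_trace_has_no_transitions(self):
        f = 1.0 + 6.0 * np.arange(0, 3, 0.001)
        trace = make_trace(f)
        base = FoldedBaseline(k_eff=0.05, intercept=0.0, sigma=0.05, n_points=100)
        labels = classify_states(trace, base, expected_jump=0.8)
        assert not labels.states.any()
        assert labels.transitions == []

    def test_noisy_accuracy_above_95_percent(self):
        accuracies = []
        for seed in range(5):
            # low-force sweep segment, the regime where folding events live
            trace, idx = two_branch_trace(jump=0.5, f_rup=3.5, noise=0.2, seed=seed, f_max=8.0)
            trace = median_filter(trace, 11)
            # baseline region restricted below the rupture force (1-3 pN)
            base = fit_folded_baseline(trace, region=(20.0, 60.0))
            labels = classify_states(trace, base, expected_jump=0.5, debounce=5)
            truth = (np.arange(trace.force.size) >= idx).astype(int)
            accuracies.append(np.mean(labels.states == truth))
        assert min(accuracies) >= 0.95

    def test_lambda_offset_invariance_with_intercept(self):
        trace, idx = two_branch_trace(noise=0.2, seed=3)
        filt = median_filter(trace, 11)
        shifted = PullingTrace(
            filt.time, filt.lam + 500.0, filt.force, "unfold", 6.0, 1000.0
        )
        base0 = fit_folded_baseline(filt, fit_intercept=True)
        base1 = fit_folded_baseline(shifted, fit_intercept=True)
        l0 = classify_states(filt, base0, expected_jump=0.8)
        l1 = classify_states(shifted, base1, expected_jump=0.8)
        assert np.array_equal(l0.states, l1.states)


class TestFirstTransitionForce:
    def test_embedded_rupture_force_recovered(self):
        trace, idx = two_branch_trace(f_rup=18.2, noise=0.2, seed=5)
        filt = median_filter(trace, 11)
        base = fit_folded_baseline(filt)
        labels = classify_states(filt, base, expected_jump=0.8)
        event = first_transition_force(labels, filt, baseline=base)
        assert event is not None and not event.censored
        assert event.force == pytest.approx(18.2, abs=0.2)

    def test_no_transition_returns_none(self):
        f = 1.0 + 6.0 * np.arange(0, 3, 0.001)
        trace = make_trace(f)
        base = FoldedBaseline(k_eff=0.05, intercept=0.0, sigma=0.05, n_points=100)
        labels = classify_states(trace, base, expected_jump=0.8)
        assert first_transition_force(labels, trace, baseline=base) is None

    def test_low_force_folding_event_is_censored(self):
        # folding trace: starts unfolded, folds at 1.4 pN (< 2 pN cutoff)
        fs, rate, k_eff, jump = 1000.0, 6.0, 0.05, 0.4
        t = np.arange(0, 4.8, 1 / fs)
        fb = 30.0 - rate * t
        lam = fb / k_eff
        idx = int(np.argmax(fb <= 1.4))
        force = fb.copy()
        force[:idx] -= jump
        trace = PullingTrace(t, lam, force, "fold", rate, fs)
        base = FoldedBaseline(k_eff=k_eff, intercept=0.0, sigma=0.05, n_points=100)
        labels = classify_states(trace, base, expected_jump=jump)
        event = first_transition_force(labels, trace, fold_cutoff=2.0, baseline=base)
        assert event is not None and event.censored
        assert event.force == pytest.approx(1.4, abs=0.1)


class TestDetectionClosure:
    def test_simulator_events_recovered(self, sim_cfg):
        from pullfold import generate_fdc_trace

        cfg = AnalysisConfig()
        rng = np.random.default_rng(21)
        traces, truths = [], []
        for i in range(6):
            for d in ("unfold", "fold"):
                tr, tru = generate_fdc_trace(sim_cfg, d, rng=rng, cycle_id=i)
                traces.append(tr)
                truths.append(tru)
        table = detect_events(traces, cfg)
        hits = 0
        total = 0
        for (_, row), tru in zip(table.iterrows(), truths):
            if tru.direction == "fold" and tru.true_force < cfg.fold_cutoff:
                continue
            total += 1
            if row["detected"] and not row["censored"]:
                hits += abs(row["force_pN"] - tru.true_force) < 0.2
        assert total > 0
        assert hits / total >= 0.9
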