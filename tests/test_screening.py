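"""Two-criterion trace screening: line-fit residual and histogram spike."""

import math

import numpy as np
import pytest

from smbjdna import (
    GeneratorConfig,
    MixtureSpec,
    ScreeningConfig,
    SpeciesModel,
    Trace,
    default_mixture,
    fit_semilog_line,
    per_trace_histogram,
    screen_ensemble,
    screen_trace,
    simulate_ensemble,
    simulate_trace,
)
from smbjdna.screening import TraceTooShortError, window_edges


def make_trace(log_values, step=0.002, bias=0.1, fs=40_000.0, v=80.0):
    log_values = np.asarray(log_values, dtype=float)
    return Trace(
        distance=np.arange(log_values.size) * step,
        conductance=10.0 ** log_values,
        bias=bias,
        sampling_rate=fs,
        retraction_rate=v,
    )


def brute_force_screen(trace, config):
    """Independent straightforward reimplementation of both criteria."""
    logg = [math.log10(g) for g in trace.conductance]
    lo, hi = config.window
    pts = [(d, y) for d, y in zip(trace.distance, logg) if lo <= y < hi]
    if len(pts) < 3:
        raise TraceTooShortError("trace too short to screen")
    n = len(pts)
    sx = sum(d for d, _ in pts)
    sy = sum(y for _, y in pts)
    sxx = sum(d * d for d, _ in pts)
    sxy = sum(d * y for d, y in pts)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    rss = sum((y - slope * d - intercept) ** 2 for d, y in pts)
    residual = math.sqrt(rss / n)
    n_bins = round((hi - lo) * config.bins_per_decade)
    counts = [0] * n_bins
    for _, y in pts:
        idx = int(math.floor((y - lo) * config.bins_per_decade))
        if 0 <= idx < n_bins:
            counts[idx] += 1
    return residual, max(counts), (
        residual >= config.residual_threshold and max(counts) >= config.amplitude_threshold
    )


class TestSemilogLineFit:
    def test_noiseless_tunneling_has_zero_residual(self, tunneling_mixture):
        cfg = GeneratorConfig(noise_sd=0.0)
        tr = simulate_trace(tunneling_mixture, cfg, np.random.default_rng(0))
        slope, _, residual = fit_semilog_line(tr)
        assert residual < 1e-9
        assert slope == pytest.approx(-cfg.beta, rel=1e-9)

    def test_constant_trace_is_degenerate_line(self):
        tr = make_trace(np.full(100, -3.0))
        slope, intercept, residual = fit_semilog_line(tr)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(-3.0)
        assert residual < 1e-12

    def test_plateau_insert_residual_matches_ols_oracle(self):
        # exact decay with a flat plateau inserted: residual must equal an
        # independent normal-equations least-squares computation, and be > 0
        decay = -1.2 - 6.0 * 0.002 * np.arange(200)
        plateau = np.full(150, -3.0)
        tr = make_trace(np.concatenate([decay[:150], plateau, decay[150:]]))
        cfg = ScreeningConfig()
        _, _, residual = fit_semilog_line(tr, cfg.window)
        oracle_resid, _, _ = brute_force_screen(tr, cfg)
        assert residual == pytest.approx(oracle_resid, rel=1e-9)
        assert residual > 0

    def test_too_few_in_window_samples_raises(self):
        tr = make_trace([-0.5, -0.4, -6.2, -6.3, -2.0, -2.1])
        with pytest.raises(TraceTooShortError, match="too short"):
            fit_semilog_line(tr)


class TestPerTraceHistogram:
    def test_all_samples_below_window_gives_zero_counts(self, screening_config):
        tr = make_trace(np.full(50, -6.0))
        counts = per_trace_histogram(tr, screening_config)
        assert counts.sum() == 0

    def test_plateau_spike_at_least_plateau_length(self, screening_config):
        # k noiseless plateau samples at a bin centre plus a sweep of decay
        edges = window_edges(screening_config.window, screening_config.bins_per_decade)
        mu = 0.5 * (edges[100] + edges[101])
        decay = -1.2 - 6.0 * 0.002 * np.arange(300)
        tr = make_trace(np.concatenate([decay, np.full(120, mu)]))
        counts = per_trace_histogram(tr, screening_config)
        assert counts.max() >= 120

    def test_hand_listed_samples_match_enumeration(self):
        cfg = ScreeningConfig(window=(-5.0, -1.0), bins_per_decade=2)
        # bins of width 0.5 from -5.0: sample -> bin by construction
        values = [-4.9, -4.6, -4.4, -2.01, -1.0, -0.5]
        tr = make_trace(values)
        counts = per_trace_histogram(tr, cfg)
        expected = np.zeros(8, dtype=int)
        expected[0] += 2  # -4.9, -4.6 in [-5.0, -4.5)
        expected[1] += 1  # -4.4 in [-4.5, -4.0)
        expected[5] += 1  # -2.01 in [-2.5, -2.0)
        # -1.0 and -0.5 fall at/above the upper window edge: excluded
        np.testing.assert_array_equal(counts, expected)


class TestScreenTrace:
    def test_tunneling_decay_is_rejected(self, gen_config, tunneling_mixture):
        tr = simulate_trace(tunneling_mixture, gen_config, np.random.default_rng(2))
        result = screen_trace(tr)
        assert result.residual < ScreeningConfig().residual_threshold
        assert not result.selected

    def test_forced_noiseless_junction_is_selected(self):
        sp = SpeciesModel(name="sp", mu=-3.0, sigma_between=0.0, plateau_length_sd=0.0)
        mix = MixtureSpec(components=((sp, 1e-6),), p_junction=1.0)
        cfg = GeneratorConfig(noise_sd=0.0, plateau_slope=0.0)
        tr = simulate_trace(mix, cfg, np.random.default_rng(0), force_junction=True)
        result = screen_trace(tr)
        assert result.selected
        assert result.max_bin_count >= 150
        assert abs(result.max_bin_center - (-3.0)) < 0.05

    def test_plateau_below_window_rejected_despite_residual(self):
        # the plateau sits below the window, but its distance offset shifts
        # the post-plateau decay so the in-window samples are two parallel
        # segments: the residual criterion passes, the spike criterion must
        # still reject because the plateau spike itself is out of window
        decay_in = -1.2 - 6.0 * 0.002 * np.arange(300)  # -1.2 .. -4.8
        plateau = np.full(200, -6.2)  # below window low of -5.5
        decay_out = -4.8 - 6.0 * 0.002 * np.arange(1, 120)
        tr = make_trace(np.concatenate([decay_in, plateau, decay_out]))
        cfg = ScreeningConfig()
        result = screen_trace(tr, cfg)
        assert result.residual >= cfg.residual_threshold
        assert result.max_bin_count < cfg.amplitude_threshold
        assert not result.selected

    def test_screening_is_pure(self, gen_config):
        tr = simulate_trace(default_mixture(), gen_config, np.random.default_rng(9))
        assert screen_trace(tr) == screen_trace(tr)


class TestScreenEnsemble:
    def test_no_junctions_and_no_noise_selects_nothing(self, tunneling_mixture):
        cfg = GeneratorConfig(noise_sd=0.0)
        traces = simulate_ensemble(100, tunneling_mixture, cfg, seed=3)
        _, fraction, _ = screen_ensemble(traces)
        assert fraction == 0.0

    def test_label_oracle_recall_and_false_positive_rate(self, gen_config):
        traces = simulate_ensemble(2000, default_mixture(), gen_config, seed=21)
        selected, _, results = screen_ensemble(traces)
        junction = [t.label is not None for t in traces]
        picked = [r.selected for r in results]
        n_junc = sum(junction)
        recall = sum(1 for j, s in zip(junction, picked) if j and s) / n_junc
        fpr = sum(1 for j, s in zip(junction, picked) if not j and s) / (2000 - n_junc)
        assert recall >= 0.9
        assert fpr <= 0.01

    def test_order_preserved(self, gen_config):
        traces = simulate_ensemble(200, default_mixture(), gen_config, seed=4)
        selected, _, results = screen_ensemble(traces)
        expected = [t for t, r in zip(traces, results) if r.selected]
        assert [id(t) for t in selected] == [id(t) for t in expected]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            screen_ensemble([])


class TestScreeningProperties:
    def test_equivalence_with_brute_force_oracle(self, gen_config):
        # selected sets must match an independent reimplementation exactly
        traces = simulate_ensemble(50, default_mixture(), gen_config, seed=17)
        cfg = ScreeningConfig()
        _, _, results = screen_ensemble(traces, cfg)
        for tr, res in zip(traces, results):
            oracle_resid, oracle_max, oracle_sel = brute_force_screen(tr, cfg)
            assert res.residual == pytest.approx(oracle_resid, rel=1e-9)
            assert res.max_bin_count == oracle_max
            assert res.selected == oracle_sel

    def test_raising_thresholds_shrinks_selection(self, gen_config):
        traces = simulate_ensemble(400, default_mixture(), gen_config, seed=8)
        base = ScreeningConfig()
        stricter = [
            ScreeningConfig(residual_threshold=base.residual_threshold * 2),
            ScreeningConfig(amplitude_threshold=base.amplitude_threshold * 2),
        ]
        _, _, base_results = screen_ensemble(traces, base)
        base_set = {i for i, r in enumerate(base_results) if r.selected}
        for cfg in stricter:
            _, _, results = screen_ensemble(traces, cfg)
            strict_set = {i for i, r in enumerate(results) if r.selected}
            assert strict_set <= base_set
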