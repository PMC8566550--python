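"""Unit and property tests for fluorescence-trace operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synphys.traces import (
    DegenerateBaselineError,
    TimeSeriesTrace,
    WindowSpec,
    above_background_gate,
    baseline_stats,
    classify_responder,
    delta_f_over_f,
    gcamp_prestimulus_exclusion,
    moving_average,
    normalize_expression,
    rank_traces,
    window_metric,
)

from conftest import make_dff_trace


def make_f_trace(F, F_bg=None, dt=0.1, trace_id="tr"):
    F = np.asarray(F, dtype=float)
    t = np.arange(F.size) * dt
    bg = None if F_bg is None else np.full_like(F, float(F_bg))
    return TimeSeriesTrace(trace_id=trace_id, t=t, F=F, F_bg=bg)


class TestDeltaFOverF:
    def test_constant_trace_gives_zero(self):
        tr = make_f_trace(np.full(300, 10.0))
        out = delta_f_over_f(tr, WindowSpec(0, 10))
        np.testing.assert_allclose(out.dff, 0.0)

    def test_step_normalization(self):
        F = np.full(300, 10.0)
        F[150] = 25.0
        out = delta_f_over_f(make_f_trace(F), WindowSpec(0, 10))
        assert out.dff[150] == pytest.approx(1.5)

    def test_background_subtracted_before_normalizing(self):
        F = np.full(300, 12.0)
        F[150] = 22.0
        out = delta_f_over_f(make_f_trace(F, F_bg=2.0), WindowSpec(0, 10))
        assert out.dff[150] == pytest.approx(1.0)
        assert out.dff[0] == pytest.approx(0.0)

    def test_scale_invariance(self, rng):
        F = 50 + 10 * rng.random(200)
        tr = make_f_trace(F, F_bg=5.0)
        scaled = make_f_trace(3.7 * F, F_bg=3.7 * 5.0)
        w = WindowSpec(0, 5)
        np.testing.assert_allclose(
            delta_f_over_f(tr, w).dff, delta_f_over_f(scaled, w).dff
        )

    def test_degenerate_baseline_raises(self):
        tr = make_f_trace(np.full(100, 2.0), F_bg=2.0)
        with pytest.raises(DegenerateBaselineError):
            delta_f_over_f(tr, WindowSpec(0, 5))

    def test_empty_baseline_raises(self):
        tr = make_f_trace(np.full(100, 10.0))
        with pytest.raises(ValueError, match="baseline"):
            delta_f_over_f(tr, WindowSpec(50, 60))


class TestMovingAverage:
    def test_constant_unchanged(self):
        tr = make_dff_trace(np.full(100, 0.7))
        np.testing.assert_allclose(moving_average(tr, 1.0).dff, 0.7)

    def test_single_sample_width_is_identity(self, rng):
        tr = make_dff_trace(rng.random(100))
        np.testing.assert_allclose(moving_average(tr, 0.1).dff, tr.dff)

    def test_impulse_spread_over_three_samples(self):
        dff = np.zeros(50)
        dff[25] = 1.0
        out = moving_average(make_dff_trace(dff), 0.3)
        np.testing.assert_allclose(out.dff[24:27], 1 / 3)
        assert out.dff[23] == 0.0 and out.dff[27] == 0.0

    def test_even_sample_count_rounds_down_to_odd(self):
        # 1 s at 0.1 s sampling -> 10 samples -> 9-sample boxcar
        dff = np.zeros(101)
        dff[50] = 1.0
        out = moving_average(make_dff_trace(dff), 1.0)
        np.testing.assert_allclose(out.dff[46:55], 1 / 9)
        assert out.dff[45] == 0.0

    def test_edges_truncate_and_preserve_length(self):
        dff = np.zeros(50)
        dff[0] = 1.0
        out = moving_average(make_dff_trace(dff), 0.5)
        assert out.dff.size == 50
        # left edge window shrinks to 3 samples: [x0 x1 x2]
        assert out.dff[0] == pytest.approx(1 / 3)

    def test_width_below_interval_raises(self):
        tr = make_dff_trace(np.zeros(10))
        with pytest.raises(ValueError, match="width"):
            moving_average(tr, 0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=5, max_size=60),
           st.integers(1, 5))
    def test_never_extends_input_range(self, values, halfwidth):
        tr = make_dff_trace(values)
        out = moving_average(tr, (2 * halfwidth + 1) * 0.1)
        assert out.dff.min() >= min(values) - 1e-12
        assert out.dff.max() <= max(values) + 1e-12


class TestBaselineStats:
    def test_constant_window(self):
        tr = make_dff_trace(np.full(50, 0.3))
        mean, sd, mode = baseline_stats(tr, WindowSpec(0, 5))
        assert mean == pytest.approx(0.3)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert mode == pytest.approx(0.3)

    def test_hand_computed_mean_sd_mode(self):
        tr = make_dff_trace([0.0, 0.0, 0.0, 1.0])
        mean, sd, mode = baseline_stats(tr, WindowSpec(0, 1))
        assert mean == pytest.approx(0.25)
        assert sd == pytest.approx(0.5)
        assert mode == pytest.approx(0.0)

    def test_bimodal_majority_bin_wins(self):
        tr = make_dff_trace([0.0] * 5 + [0.5] * 4)
        _, _, mode = baseline_stats(tr, WindowSpec(0, 1))
        assert mode == pytest.approx(0.0)

    def test_tie_resolves_to_lowest_bin(self):
        tr = make_dff_trace([0.0] * 4 + [0.5] * 4)
        _, _, mode = baseline_stats(tr, WindowSpec(0, 1))
        assert mode == pytest.approx(0.0)

    def test_empty_window_raises(self):
        tr = make_dff_trace(np.zeros(10))
        with pytest.raises(ValueError):
            baseline_stats(tr, WindowSpec(100, 101))


class TestAboveBackgroundGate:
    def _bg(self, rng):
        return make_f_trace(10 + rng.standard_normal(100), trace_id="bg")

    def test_bright_trace_kept(self, rng):
        bg = self._bg(rng)
        tr = make_f_trace(np.full(100, 100.0))
        assert above_background_gate(tr, bg, WindowSpec(0, 10)) is True

    def test_dim_trace_excluded(self, rng):
        bg = self._bg(rng)
        tr = make_f_trace(np.full(100, 10.0))
        assert above_background_gate(tr, bg, WindowSpec(0, 10)) is False

    def test_boundary_equality_excludes(self, rng):
        # the exclusion rule is "mean <= mean + 3 SD", so equality excludes
        bg = self._bg(rng)
        w = WindowSpec(0, 10)
        vals = bg.F[w.mask(bg.t)]
        threshold = vals.mean() + 3 * vals.std(ddof=1)
        at = make_f_trace(np.full(100, threshold))
        above = make_f_trace(np.full(100, threshold + 1e-9))
        assert above_background_gate(at, bg, w) is False
        assert above_background_gate(above, bg, w) is True


class TestClassifyResponder:
    def test_clean_step_is_responder(self, rng):
        dff = 0.01 * rng.standard_normal(300)
        dff[100:200] += 1.0
        call = classify_responder(
            make_dff_trace(dff), WindowSpec(0, 10), WindowSpec(10, 20), 1.0
        )
        assert call.responder
        assert call.peak_value == pytest.approx(1.0, abs=0.05)
        assert 10 <= call.peak_time < 20

    def test_flat_trace_is_not_responder(self, flat_dff_trace):
        call = classify_responder(
            flat_dff_trace, WindowSpec(0, 10), WindowSpec(10, 20), 1.0
        )
        assert not call.responder
        assert call.reason == "below_threshold"

    def test_threshold_arithmetic_at_k3(self, rng):
        # with identity smoothing the decision reduces to max vs mean + 3 sd
        base = 0.1 * rng.standard_normal(100)
        for margin, expect in [(-0.01, False), (+0.01, True)]:
            dff = np.concatenate([base, np.zeros(200)])
            thr = base.mean() + 3 * base.std(ddof=1)
            dff[150] = thr + margin
            call = classify_responder(
                make_dff_trace(dff), WindowSpec(0, 10), WindowSpec(10, 20), 0.1
            )
            assert call.responder is expect

    def test_decrease_direction_mirrors_increase(self, rng):
        dff = 0.01 * rng.standard_normal(300)
        dff[100:200] -= 0.8
        call = classify_responder(
            make_dff_trace(dff), WindowSpec(0, 10), WindowSpec(10, 20), 1.0,
            direction="decrease",
        )
        assert call.responder
        assert call.peak_value == pytest.approx(-0.8, abs=0.05)

    def test_failed_background_gate_blocks_responder(self, rng):
        dff = np.zeros(300)
        dff[100:200] = 1.0
        call = classify_responder(
            make_dff_trace(dff), WindowSpec(0, 10), WindowSpec(10, 20), 1.0,
            above_background=False,
        )
        assert not call.responder and not call.above_background
        assert call.reason == "below_background"

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.001, 2.0))
    def test_monotone_in_response_amplitude(self, boost):
        rng = np.random.default_rng(7)
        dff = 0.05 * rng.standard_normal(300)
        dff[100:200] += 0.1
        lo = classify_responder(
            make_dff_trace(dff), WindowSpec(0, 10), WindowSpec(10, 20), 0.1
        )
        dff2 = dff.copy()
        dff2[100:200] += boost
        hi = classify_responder(
            make_dff_trace(dff2), WindowSpec(0, 10), WindowSpec(10, 20), 0.1
        )
        assert hi.responder or not lo.responder


class TestWindowMetric:
    def test_rectangle_auc(self):
        tr = make_dff_trace(np.ones(301))
        assert window_metric(tr, WindowSpec(0, 10), "auc") == pytest.approx(10.0)

    def test_zero_auc(self, flat_dff_trace):
        assert window_metric(flat_dff_trace, WindowSpec(0, 10), "auc") == 0.0

    def test_triangle_ramp_auc(self):
        t = np.arange(0, 30, 0.1)
        dff = np.interp(t, [0, 5, 10, 30], [0, 1, 0, 0])
        tr = make_dff_trace(dff)
        assert window_metric(tr, WindowSpec(0, 10), "auc") == pytest.approx(5.0)

    def test_auc_additive_over_adjacent_windows(self, rng):
        tr = make_dff_trace(rng.standard_normal(301))
        whole = window_metric(tr, WindowSpec(0, 20), "auc")
        parts = window_metric(tr, WindowSpec(0, 8), "auc") + window_metric(
            tr, WindowSpec(8, 20), "auc"
        )
        assert parts == pytest.approx(whole)

    def test_extrema(self, rng):
        vals = rng.standard_normal(300)
        tr = make_dff_trace(vals)
        w = WindowSpec(5, 15)
        m = w.mask(tr.t)
        assert window_metric(tr, w, "max") == vals[m].max()
        assert window_metric(tr, w, "min") == vals[m].min()


class TestGcampPrestimulusExclusion:
    def _group(self, rng, n=4, noise=0.05):
        return [
            make_dff_trace(noise * rng.standard_normal(300), trace_id=f"g{i}",
                           genotype="wt")
            for i in range(n)
        ]

    def test_flat_traces_all_kept(self):
        traces = [
            make_dff_trace(np.zeros(300), trace_id=f"f{i}", genotype="wt")
            for i in range(3)
        ]
        assert all(gcamp_prestimulus_exclusion(traces).values())

    def test_single_transient_trace_excluded(self, rng):
        traces = self._group(rng)
        bad = traces[1].dff.copy()
        bad[45:55] += 10.0  # transient at t = 5 s
        traces[1] = make_dff_trace(bad, trace_id="g1", genotype="wt")
        keep = gcamp_prestimulus_exclusion(traces)
        assert keep == {"g0": True, "g1": False, "g2": True, "g3": True}

    def test_agrees_with_bruteforce_recomputation(self, rng):
        from synphys.traces import moving_average as ma

        traces = self._group(rng, n=6, noise=0.05)
        spike = traces[2].dff.copy()
        spike[50] += 0.2
        traces[2] = make_dff_trace(spike, trace_id="g2", genotype="wt")
        keep = gcamp_prestimulus_exclusion(traces, filter_width=0.5, k=5)

        # independent brute-force re-derivation of the rule
        smoothed = [ma(tr, 0.5).dff[:100] for tr in traces]
        pooled = np.mean([s.std(ddof=1) for s in smoothed])
        for tr, s in zip(traces, smoothed):
            lo = s.min()
            nbins = int(np.floor((s.max() - lo) / 0.01 + 0.5)) + 1
            edges = lo - 0.005 + 0.01 * np.arange(nbins + 1)
            mode = lo + 0.01 * np.argmax(np.histogram(s, bins=edges)[0])
            assert keep[tr.trace_id] == (s.max() <= mode + 5 * pooled)

    def test_pooling_is_per_genotype(self, rng):
        quiet = self._group(rng, n=3, noise=0.001)
        noisy = [
            make_dff_trace(0.5 * rng.standard_normal(300), trace_id=f"n{i}",
                           genotype="mut")
            for i in range(3)
        ]
        bump = quiet[0].dff.copy()
        bump[45:55] += 0.01  # tiny for 'mut' noise, huge for 'wt' noise
        quiet[0] = make_dff_trace(bump, trace_id="g0", genotype="wt")
        keep = gcamp_prestimulus_exclusion(quiet + noisy)
        assert keep["g0"] is False  # judged against its own genotype's pooled SD


class TestNormalizeExpression:
    def test_two_step_hand_computation(self):
        tr = make_f_trace(np.full(100, 12.0), F_bg=2.0)
        assert normalize_expression(tr, WindowSpec(0, 5), 5.0) == pytest.approx(2.0)

    def test_zero_baseline_gives_zero(self):
        tr = make_f_trace(np.full(100, 3.0), F_bg=3.0)
        assert normalize_expression(tr, WindowSpec(0, 5), 50.0) == 0.0

    def test_invalid_intensity_raises(self):
        tr = make_f_trace(np.full(100, 10.0))
        with pytest.raises(ValueError):
            normalize_expression(tr, WindowSpec(0, 5), 0.0)


class TestRankTraces:
    def _traces(self, means):
        return [
            make_dff_trace(np.full(300, m), trace_id=f"t{i}")
            for i, m in enumerate(means)
        ]

    def test_descending_by_window_mean(self):
        ranked = rank_traces(self._traces([0.5, 0.1, 0.9]), WindowSpec(10, 15))
        assert [tr.trace_id for tr in ranked] == ["t2", "t0", "t1"]

    def test_ties_preserve_input_order(self):
        ranked = rank_traces(self._traces([0.3, 0.3, 0.3]), WindowSpec(10, 15))
        assert [tr.trace_id for tr in ranked] == ["t0", "t1", "t2"]

    def test_tiny_differences_are_distinct(self):
        ranked = rank_traces(self._traces([0.2, 0.2 - 1e-12]), WindowSpec(10, 15))
        assert [tr.trace_id for tr in ranked] == ["t0", "t1"]
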