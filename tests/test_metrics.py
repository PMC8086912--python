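"""Metric tests: snapshot observables, pattern analysis, phase records,
time-resolved summaries, and the independent delta-phase oracle."""

from types import SimpleNamespace

import numpy as np
import pytest

from segdyn import ModelConfig, preset, run
from segdyn import metrics as met


def _state(tau1, signal=None, phase=None, switch=None):
    tau1 = np.asarray(tau1, dtype=float)
    return SimpleNamespace(
        t=0,
        L=len(tau1),
        tau1=tau1,
        tau2=None,
        tau3=None,
        phase=None if phase is None else np.asarray(phase, dtype=float),
        osc=None,
        switch=None if switch is None else np.asarray(switch, dtype=int),
        signal=None if signal is None else np.asarray(signal, dtype=bool),
        psc_active=True,
    )


class TestSazLength:
    def test_all_mature(self):
        assert met.saz_length(_state([0, 0, 0])) == 0

    def test_excludes_signal_positive(self):
        tau1 = [0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
        sig = [False] * 7 + [True] * 3
        assert met.saz_length(_state(tau1, sig)) == 5

    def test_single_signal_cell(self):
        assert met.saz_length(_state([1.0], [True])) == 0


class TestWavefrontPosition:
    def test_all_immature(self):
        assert met.wavefront_position(_state([1, 1, 1])) == 0

    def test_mid_run(self):
        assert met.wavefront_position(_state([0] * 5 + [0.5] * 5)) == 5

    def test_all_fated(self):
        assert met.wavefront_position(_state([0] * 10)) == 10


class TestSazPhaseDifference:
    def test_synchronous_saz(self):
        st = _state([0, 1, 1, 1], signal=[False, False, False, True], phase=[0, 2, 2, 2])
        assert met.saz_phase_difference(st) == 0.0

    def test_gradient(self):
        st = _state(
            [0, 0.2, 0.6, 1.0, 1.0],
            signal=[False, False, False, False, True],
            phase=[1.0, 1.3, 1.8, 2.4, 2.4],
        )
        assert met.saz_phase_difference(st) == pytest.approx(1.1)

    def test_empty_saz_is_nan(self):
        st = _state([0, 0, 1], signal=[False, False, True], phase=[0, 0, 0])
        assert np.isnan(met.saz_phase_difference(st))


class TestSegmentLengths:
    def test_single_complete_repeat(self):
        assert met.segment_lengths([1, 1, 2, 2, 1, 1, 2, 2, 1]).tolist() == [4]

    def test_uniform_pattern_flagged_empty(self):
        assert len(met.segment_lengths([2, 2, 2, 2])) == 0

    def test_onset_at_origin_not_counted(self):
        # leading boundary state has no observable transition into it
        assert met.boundary_onsets([1, 2, 1, 2, 1]).tolist() == [2, 4]

    def test_anterior_class_set(self):
        pattern = [1, 2, 3, 4, 5, 6, 1, 2, 3, 4, 5, 6, 1]
        segs = met.segment_lengths(pattern, boundary_state=[1, 4])
        assert segs.tolist() == [3, 3, 3]

    def test_steady_state_run_matches_p_times_v(self, clock_timer_history):
        pattern = clock_timer_history.final_pattern()
        segs = met.segment_lengths(pattern[pattern > 0])
        assert np.all(segs == 4)


class TestRepeatingUnit:
    def test_alternating(self):
        p, unit = met.repeating_unit([1, 2, 1, 2, 1, 2, 1, 2])
        assert p == 2 and unit.tolist() == [1, 2]

    def test_constant(self):
        p, unit = met.repeating_unit([3] * 8)
        assert p == 1 and unit.tolist() == [3]

    def test_rejects_unfated(self):
        with pytest.raises(met.MetricError):
            met.repeating_unit([1, 0, 1])


class TestPatternEquivalence:
    def test_identical(self):
        res = met.pattern_equivalence([1, 2, 3] * 5, [1, 2, 3] * 5)
        assert res.equivalent and res.mismatches == 0

    def test_different_truncation_same_repeat(self):
        a = [3, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2]
        b = [2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3]
        assert met.pattern_equivalence(a, b).equivalent

    def test_different_repeat_lengths(self):
        res = met.pattern_equivalence([1, 2] * 8, [1, 2, 3] * 6)
        assert not res.equivalent and res.mismatches is None

    def test_same_length_counts_mismatches(self):
        res = met.pattern_equivalence([1, 2, 2, 3] * 5, [1, 2, 3, 3] * 5)
        assert not res.equivalent and res.mismatches == 1


class TestRecordedPhases:
    def test_rejects_non_freeze_variant(self, clock_timer_history):
        with pytest.raises(met.MetricError):
            met.frozen_phases(clock_timer_history)

    def test_freeze_with_incommensurate_period_covers_all_bins(self):
        # with P coprime to the addition interval, release phases cycle
        # through the whole circle: the histogram is approximately uniform
        # releases every 5 steps against P = 21 cycle through 21 evenly
        # spaced phases; 7 bins hold exactly 3 of those values each
        cfg = ModelConfig(variant="freeze", P=21.0, v=0.2, T1=40.0, steps=2200)
        hist = run(cfg)
        phist = met.recorded_phase_distribution(hist, bins=7, min_fix_time=100)
        counts = phist.counts[0]
        assert np.all(counts > 0)
        assert counts.max() - counts.min() <= 3

    def test_elongation_feedback_occupies_at_most_half_circle(self):
        hist = run(preset("freeze_elongation_feedback"))
        span = met.circular_span(met.frozen_phases(hist))
        assert span <= 0.5

    def test_histogram_counts_sum_to_frozen_cells(self):
        hist = run(preset("freeze_baseline"))
        ph = met.frozen_phases(hist)
        phist = met.recorded_phase_distribution(hist)
        assert phist.counts.sum() == len(ph)

    def test_empty_history_gives_empty_histogram(self):
        hist = run(ModelConfig(variant="freeze", steps=0))
        phist = met.recorded_phase_distribution(hist)
        assert phist.counts.sum() == 0

    def test_circular_span_wraps(self):
        assert met.circular_span([0.95, 0.05]) == pytest.approx(0.1)


class TestPartitionInvariant:
    def test_cells_partition_into_three_classes(self, clock_timer_history):
        hist = clock_timer_history
        for t in range(0, hist.steps + 1, 7):
            st = hist.state_at(t)
            fated = int(np.count_nonzero(st.tau1 == 0.0))
            sig = int(np.count_nonzero(st.signal))
            assert met.saz_length(st) + fated + sig == st.L


class TestDeltaPhaseOracle:
    def test_matches_frequency_difference_summation(self, clock_timer_history):
        """Independent oracle: re-accumulate each cell's phase from the
        recorded tau1 trajectory and compare the endpoint difference."""
        hist = clock_timer_history
        cfg = hist.config
        profile = cfg.freq_profile_obj()
        tau1 = hist.data["tau1"]
        n_t, n_c = tau1.shape
        phase = np.full((n_t, n_c), np.nan)
        phase[0, : int(hist.L[0])] = 0.0
        for t in range(1, n_t):
            prev_alive = int(hist.L[t - 1])
            alive = int(hist.L[t])
            gate = tau1[t - 1, :prev_alive]
            adv = np.where(gate > 0, profile(gate) / cfg.P, 0.0)
            phase[t, :prev_alive] = phase[t - 1, :prev_alive] + adv
            # newborn cells copy the posterior cell's just-updated phase
            phase[t, prev_alive:alive] = phase[t, prev_alive - 1]
        for t in range(50, n_t, 50):
            st = hist.state_at(t)
            saz = (st.tau1 > 0) & ~st.signal
            if not saz.any():
                continue
            idx = np.flatnonzero(saz)
            oracle = phase[t, idx[-1]] - phase[t, idx[0]]
            assert met.saz_phase_difference(st) == pytest.approx(
                oracle, abs=1e-9 * (t + 1)
            )


class TestSummaryCurves:
    def test_series_lengths_match_run(self, growth_history):
        curves = met.summary_curves(growth_history)
        assert len(curves.frame) == growth_history.steps + 1

    def test_segment_formation_times_increase_along_axis(self, growth_history):
        segs = met.segments_with_formation(growth_history)
        assert len(segs) > 5
        assert segs["t_formed"].is_monotonic_increasing

    def test_completion_time(self, growth_history):
        done = met.completion_time(growth_history)
        pattern = growth_history.final_pattern()
        assert done is not None and (pattern > 0).all()

    def test_roundtrip_through_files(self, tmp_path, clock_timer_history):
        from segdyn.io import read_history, write_history

        write_history(clock_timer_history, tmp_path)
        back = read_history(tmp_path)
        t = clock_timer_history.steps
        assert met.saz_length(back.state_at(t)) == met.saz_length(
            clock_timer_history.state_at(t)
        )
        assert met.saz_phase_difference(back.state_at(t)) == pytest.approx(
            met.saz_phase_difference(clock_timer_history.state_at(t))
        )
        a = met.segment_lengths(clock_timer_history.final_pattern())
        b = met.segment_lengths(back.final_pattern())
        assert np.array_equal(a, b)


class TestLagScaling:
    def test_ramped_growth_has_positive_best_lag(self):
        cfg = ModelConfig(
            variant="clock_three_timers",
            T1=40.0,
            T3=500.0,
            growth_profile=[[0.0, 0.0], [1.0, 0.4]],
            steps=700,
        )
        hist = run(cfg)
        res = met.lag_scaling(hist, max_lag=150)
        assert res.informative
        assert res.best_lag > 0
        assert res.best_corr > res.corr_at_zero

    def test_constant_velocity_flagged(self, clock_timer_history):
        res = met.lag_scaling(clock_timer_history, max_lag=100)
        assert not res.informative

    def test_excessive_lag_window_rejected(self, clock_timer_history):
        with pytest.raises(met.MetricError):
            met.lag_scaling(clock_timer_history, max_lag=10_000)


class TestMonotoneImage:
    def test_monotone_with_ties(self):
        assert met.monotone_image([3, 3, 2, 2, 1], [10, 9, 9, 6, 2])

    def test_discordant_pair_detected(self):
        assert not met.monotone_image([1, 2, 3], [5, 9, 7])
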