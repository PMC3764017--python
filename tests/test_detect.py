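"""Spontaneous-event detection and evoked-response measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmjquant import (
    DetectionConfig,
    Sweep,
    Trace,
    classify_event_amplitude,
    detect_spontaneous,
    event_frequency,
    measure_epp,
)
from nmjquant.detect import DetectedEvent
from nmjquant.simulate import SimParams, simulate_evoked, simulate_gapfree

from conftest import make_trace


class TestClassification:
    @pytest.mark.parametrize(
        "amp,expected",
        [(0.15, "rejected"), (0.2, "MEPP"), (0.5, "MEPP"), (0.999, "MEPP"),
         (1.0, "GMEPP"), (2.5, "GMEPP")],
    )
    def test_amplitude_bands(self, amp, expected):
        assert classify_event_amplitude(amp) == expected

    @pytest.mark.parametrize("amp", [-0.1, float("nan"), float("inf")])
    def test_invalid_amplitudes_raise(self, amp):
        with pytest.raises(ValueError):
            classify_event_amplitude(amp)

    @given(st.floats(min_value=0.0, max_value=5.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_every_amplitude_in_exactly_one_class(self, amp):
        cls = classify_event_amplitude(amp)
        in_mepp_band = 0.2 <= amp < 1.0
        assert (cls == "MEPP") == in_mepp_band
        assert (cls == "GMEPP") == (amp >= 1.0)
        assert (cls == "rejected") == (amp < 0.2)


class TestDetector:
    def test_baseline_only_trace_yields_no_events(self):
        trace, _ = make_trace([], noise_sd=0.05)
        assert detect_spontaneous(trace) == []

    def test_noise_free_events_recovered_within_one_percent(self):
        trace, onsets = make_trace([(1.0, 0.5), (2.0, 0.5), (3.5, 0.5)])
        events = detect_spontaneous(trace)
        assert len(events) == 3
        for ev, t in zip(events, onsets):
            assert ev.event_class == "MEPP"
            assert ev.amplitude == pytest.approx(0.5, rel=0.01)
            assert ev.onset_time == pytest.approx(t, abs=1e-3)
            assert ev.onset_time < ev.peak_time

    def test_giant_and_miniature_event_classified_separately(self):
        trace, _ = make_trace([(1.0, 1.5), (3.0, 0.5)])
        events = detect_spontaneous(trace)
        assert [e.event_class for e in events] == ["GMEPP", "MEPP"]

    def test_baseline_shift_invariance(self):
        layout = [(1.0, 0.4), (2.2, 0.9), (3.6, 1.4)]
        t1, _ = make_trace(layout, noise_sd=0.05, seed=3)
        t2 = Trace(t1.sampling_rate, t1.voltage + 5.0, rmp_estimate=-65.0)
        e1, e2 = detect_spontaneous(t1), detect_spontaneous(t2)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert a.amplitude == pytest.approx(b.amplitude, abs=1e-9)
            assert a.rise_time == pytest.approx(b.rise_time, nan_ok=True, abs=1e-9)
            assert a.decay_time == pytest.approx(b.decay_time, nan_ok=True, abs=1e-9)

    def test_low_sampling_rate_warns_but_detects(self):
        trace, _ = make_trace([(1.0, 0.6)], fs=1000.0)
        with pytest.warns(RuntimeWarning):
            events = detect_spontaneous(trace)
        assert len(events) == 1

    def test_short_trace_rejected(self):
        trace = Trace(10_000.0, np.full(1000, -70.0))
        with pytest.raises(ValueError):
            detect_spontaneous(trace)

    @pytest.mark.parametrize("detector", ["template", "derivative"])
    def test_recall_and_precision_on_noisy_trace(self, detector):
        """At 0.05 mV noise, both detectors reach >=0.95 recall/precision
        against ground truth for amplitudes >= 0.2 mV."""
        p = SimParams(duration=60.0, mepp_rate=1.0, mepp_amp_mean=0.5,
                      gmepp_rate=0.2, noise_sd=0.05, seed=42)
        trace, gt = simulate_gapfree(p)
        config = DetectionConfig(detector=detector)
        events = detect_spontaneous(trace, config)
        det_t = np.array([e.onset_time for e in events])
        truth = gt.event_times[gt.event_amplitudes >= 0.2]
        matched_truth = sum(np.any(np.abs(det_t - t) < 0.003) for t in truth)
        matched_det = sum(np.any(np.abs(gt.event_times - t) < 0.003) for t in det_t)
        assert matched_truth / truth.size >= 0.95  # recall
        assert matched_det / det_t.size >= 0.95  # precision

    def test_near_coincident_events_merge_with_flag(self):
        # two onsets 3 ms apart fall inside the 5 ms merge window
        trace, _ = make_trace([(1.0, 0.6), (1.003, 0.6), (3.0, 0.5)])
        events = detect_spontaneous(trace)
        assert len(events) == 2
        assert "merged" in events[0].flags
        assert events[1].flags == ()

    def test_unknown_detector_rejected(self):
        trace, _ = make_trace([(1.0, 0.5)])
        with pytest.raises(ValueError):
            detect_spontaneous(trace, DetectionConfig(detector="wavelet"))


class TestEvokedMeasurement:
    def test_noise_free_epp_within_half_percent(self):
        p = SimParams(duration=1.0, noise_sd=0.0, quantal_mean=33.0, n_sweeps=5, seed=8)
        sweeps, gt = simulate_evoked(p)
        for sw, true_amp in zip(sweeps, gt.true_epp_amplitudes):
            got = measure_epp(sw).epp_amplitude
            assert got == pytest.approx(true_amp, rel=5e-3)

    def test_no_response_measures_near_zero(self):
        p = SimParams(duration=1.0, quantal_mean=0.0, noise_sd=0.05, n_sweeps=3, seed=9)
        sweeps, _ = simulate_evoked(p)
        for sw in sweeps:
            assert abs(measure_epp(sw).epp_amplitude) < 3 * 0.05

    def test_baseline_shift_leaves_amplitude_unchanged(self):
        p = SimParams(duration=1.0, noise_sd=0.0, quantal_mean=30.0, n_sweeps=1, seed=10)
        sweeps, _ = simulate_evoked(p)
        sw = sweeps[0]
        shifted = Sweep(
            trace=Trace(sw.trace.sampling_rate, sw.trace.voltage - 5.0),
            stimulus_time=sw.stimulus_time,
            rmp_at_sweep=sw.rmp_at_sweep - 5.0,
        )
        assert measure_epp(shifted).epp_amplitude == pytest.approx(
            measure_epp(sw).epp_amplitude, abs=1e-9
        )

    def test_window_beyond_sweep_raises(self):
        p = SimParams(duration=1.0, n_sweeps=1, seed=1)
        sweeps, _ = simulate_evoked(p)
        with pytest.raises(ValueError):
            measure_epp(sweeps[0], window_ms=1e4)


class TestEventFrequency:
    def _events(self, n_mepp, n_gmepp):
        out = []
        for k in range(n_mepp):
            out.append(DetectedEvent(k, k + 0.001, 0.5, 1.0, 3.0, "MEPP"))
        for k in range(n_gmepp):
            out.append(DetectedEvent(k, k + 0.001, 1.5, 1.0, 3.0, "GMEPP"))
        return out

    def test_rates_per_class(self):
        freq = event_frequency(self._events(64, 33), duration=100.0)
        assert freq["MEPP"] == pytest.approx(0.64)
        assert freq["GMEPP"] == pytest.approx(0.33)

    def test_empty_and_invalid(self):
        assert event_frequency([], 100.0) == {"MEPP": 0.0, "GMEPP": 0.0}
        with pytest.raises(ValueError):
            event_frequency([], 0.0)
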