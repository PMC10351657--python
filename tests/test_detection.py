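"""Band-power timelines (FIR and Percept-FFT modes) and event detection.

Closed-form oracles: the mean square of a unit sinusoid is 1/2; white
noise allocates power to a band in proportion to its width; a stored
(mean, sd) baseline makes the window z-score a hand computation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from pulvfp import (
    LEFT,
    RIGHT,
    BandPowerTimeline,
    DetectionParams,
    FrequencyBand,
    IEEGRecording,
    SeizureSpec,
    SyntheticConfig,
    detect_events,
    evaluate_against_diary,
    fir_band_power,
    generate_background,
    generate_emu_dataset,
    percept_timeline,
)
from pulvfp.synthetic import SeizureAnnotation

FS = 250.0
FINGERPRINT = FrequencyBand(12.15, 17.15)


def _recording(x, fs=FS):
    return IEEGRecording(samples=np.atleast_2d(x), fs_hz=fs, channel_labels=["ch0"])


def _sine(freq, duration_s, fs=FS, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def _timeline(values, window_s=10.0, channel="ch0"):
    return BandPowerTimeline(
        values=np.asarray(values, dtype=float), window_s=window_s,
        band=FINGERPRINT, channel=channel,
    )


class TestFirBandPower:
    def test_zero_signal_zero_timeline(self):
        tl = fir_band_power(_recording(np.zeros(int(60 * FS))), "ch0",
                            FINGERPRINT, window_s=10.0)
        assert tl.n_windows == 6
        np.testing.assert_allclose(tl.values, 0.0, atol=1e-20)

    def test_in_band_sinusoid_mean_square_is_half(self):
        x = _sine(14.65, 60.0)
        tl = fir_band_power(_recording(x), "ch0", FINGERPRINT, window_s=10.0)
        # interior windows avoid the zero-phase filter's edge transients
        assert tl.values[1:-1] == pytest.approx(0.5, rel=0.05)

    def test_out_of_band_sinusoid_attenuated(self):
        x = _sine(30.0, 60.0)
        tl = fir_band_power(_recording(x), "ch0", FINGERPRINT, window_s=10.0)
        assert np.max(tl.values[1:-1]) < 0.005

    def test_partial_trailing_window_dropped(self):
        x = np.zeros(int(25 * FS))
        tl = fir_band_power(_recording(x), "ch0", FINGERPRINT, window_s=10.0)
        assert tl.n_windows == 2

    def test_recording_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than one window"):
            fir_band_power(_recording(np.zeros(100)), "ch0", FINGERPRINT, 10.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fir_band_power(
                _recording(np.zeros(int(30 * FS))), "ch0",
                FrequencyBand(120.0, 130.0), 10.0,
            )


class TestPerceptTimeline:
    def test_zero_signal_zero_timeline(self):
        tl = percept_timeline(_recording(np.zeros(int(60 * FS))), "ch0",
                              FINGERPRINT, window_s=10.0)
        np.testing.assert_allclose(tl.values, 0.0, atol=1e-20)
        assert tl.mode == "fft"

    def test_in_band_sinusoid_mean_square_is_half(self):
        x = _sine(14.65, 60.0)
        tl = percept_timeline(_recording(x), "ch0", FINGERPRINT, window_s=10.0)
        assert tl.values == pytest.approx(0.5, rel=0.02)

    def test_white_noise_band_power_proportional_to_width(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(200 * FS))
        tl = percept_timeline(_recording(x), "ch0", FINGERPRINT, window_s=10.0)
        # 5 Hz of a flat 0-125 Hz spectrum of unit total power
        assert tl.values.mean() == pytest.approx(5.0 / 125.0, rel=0.1)

    def test_parseval_full_band_returns_total_power(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(int(20 * FS))
        tl = percept_timeline(
            _recording(x), "ch0", FrequencyBand(1e-6, 126.0), window_s=10.0
        )
        # the band excludes the DC bin, so compare to power about the mean
        windows = x.reshape(2, int(10 * FS))
        expected = np.mean(windows**2, axis=1) - np.mean(windows, axis=1) ** 2
        assert tl.values == pytest.approx(expected, rel=1e-6)

    def test_resamples_non_250hz_input(self):
        x = _sine(14.65, 60.0, fs=500.0)
        tl = percept_timeline(_recording(x, fs=500.0), "ch0", FINGERPRINT, 10.0)
        assert tl.values == pytest.approx(0.5, rel=0.05)

    def test_fir_and_fft_timelines_rank_correlate(self):
        # needs a few hundred windows for a stable rank statistic
        specs = [
            SeizureSpec(onset_s=t, duration_s=60.0, channel=LEFT)
            for t in (400.0, 1000.0, 1600.0)
        ]
        cfg = SyntheticConfig(duration_s=2000.0, seizure_specs=specs, seed=21)
        rec, _ = generate_emu_dataset(cfg)
        a = fir_band_power(rec, LEFT, FINGERPRINT, window_s=10.0)
        b = percept_timeline(rec, LEFT, FINGERPRINT, window_s=10.0)
        rho = spearmanr(a.values, b.values).statistic
        assert rho > 0.95


class TestDetectEvents:
    def test_all_windows_equal_no_events(self):
        tl = _timeline(np.ones(50))
        assert detect_events(tl, DetectionParams()) == []

    def test_stored_baseline_hand_computed_z(self):
        values = np.ones(30)
        values[17] = 1.6
        tl = _timeline(values)
        params = DetectionParams(explicit_baseline=(1.0, 0.1))
        events = detect_events(tl, params)
        assert len(events) == 1
        assert events[0].window_index == 17
        assert events[0].time_s == pytest.approx(170.0)
        assert events[0].z == pytest.approx(6.0)  # (1.6 - 1.0) / 0.1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        tl = _timeline(rng.lognormal(0.0, 1.0, size=300))
        counts = [
            len(detect_events(tl, DetectionParams(z_threshold=z)))
            for z in (1.0, 2.0, 3.0, 5.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_consecutive_windows_merge_to_one_event(self):
        values = np.ones(40)
        values[10:14] = 9.0
        tl = _timeline(values)
        events = detect_events(tl, DetectionParams(explicit_baseline=(1.0, 0.1)))
        assert [e.window_index for e in events] == [10]

    def test_merge_gap_bridges_single_dropout(self):
        values = np.ones(40)
        values[[10, 12]] = 9.0
        tl = _timeline(values)
        params = DetectionParams(explicit_baseline=(1.0, 0.1), merge_gap_windows=0)
        assert [e.window_index for e in detect_events(tl, params)] == [10, 12]
        params = DetectionParams(explicit_baseline=(1.0, 0.1), merge_gap_windows=1)
        assert [e.window_index for e in detect_events(tl, params)] == [10]

    def test_ratio_threshold_mode(self):
        values = np.ones(40)
        values[20] = 6.0
        tl = _timeline(values)
        params = DetectionParams(
            explicit_baseline=(1.0, 0.5), threshold_mode="ratio", z_threshold=5.0
        )
        events = detect_events(tl, params)
        assert [e.window_index for e in events] == [20]

    def test_insufficient_baseline_rejected(self):
        tl = _timeline(np.arange(1.0, 6.0))
        with pytest.raises(ValueError, match="windows"):
            detect_events(tl, DetectionParams(baseline=3))

    def test_degenerate_baseline_rejected(self):
        values = np.ones(40)
        values[30] = 5.0
        tl = _timeline(values)
        with pytest.raises(ValueError, match="degenerate"):
            detect_events(tl, DetectionParams(baseline=20))

    def test_explicit_interval_baseline(self):
        rng = np.random.default_rng(6)
        values = rng.normal(1.0, 0.05, size=100).clip(min=0)
        values[60] = 3.0
        tl = _timeline(values, window_s=10.0)
        params = DetectionParams(baseline=(0.0, 500.0))
        events = detect_events(tl, params)
        assert [e.window_index for e in events] == [60]


class TestEndToEnd:
    def test_fir_and_fft_detections_agree_within_one_window(self, emu_dataset):
        cfg, rec, _ = emu_dataset
        params = DetectionParams(merge_gap_windows=1)
        ev_fir = detect_events(fir_band_power(rec, LEFT, FINGERPRINT, 10.0), params)
        ev_fft = detect_events(percept_timeline(rec, LEFT, FINGERPRINT, 10.0), params)
        assert len(ev_fir) == len(ev_fft)
        for a, b in zip(ev_fir, ev_fft):
            assert abs(a.window_index - b.window_index) <= 1

    def test_planted_seizures_detected_on_planted_channel(self, emu_dataset):
        cfg, rec, anns = emu_dataset
        params = DetectionParams(merge_gap_windows=1)
        events = detect_events(fir_band_power(rec, LEFT, FINGERPRINT, 10.0), params)
        assert len(events) == len(anns) == 2
        report = evaluate_against_diary(events, anns, 1, window_s=10.0)
        assert report.n_detected == 2 and report.n_false_positive == 0

    def test_left_seizures_never_fire_right_channel(self):
        violations = 0
        for seed in range(10):
            spec = SeizureSpec(onset_s=150.0, duration_s=60.0, channel=LEFT,
                               ictal_amplitude=5.0)
            cfg = SyntheticConfig(duration_s=400.0, seizure_specs=[spec],
                                  seed=700 + seed)
            rec, _ = generate_emu_dataset(cfg)
            tl = fir_band_power(rec, RIGHT, FINGERPRINT, window_s=10.0)
            violations += bool(detect_events(tl, DetectionParams()))
        assert violations <= 1

    def test_null_false_positive_rate(self):
        """Seizure-free records of 200 windows produce zero z>5 events in
        at least 19/20 runs (no-false-positive operating point)."""
        clean = 0
        for seed in range(20):
            rec = generate_background(
                SyntheticConfig(duration_s=2000.0, seed=900 + seed)
            )
            tl = fir_band_power(rec, LEFT, FINGERPRINT, window_s=10.0)
            assert tl.n_windows == 200
            clean += not detect_events(tl, DetectionParams())
        assert clean >= 19


class TestEvaluate:
    def _event(self, idx, window_s=10.0, channel=LEFT):
        from pulvfp.detection import DetectionEvent

        return DetectionEvent(window_index=idx, time_s=idx * window_s, z=9.0,
                              channel=channel)

    def test_empty_inputs_all_zero(self):
        report = evaluate_against_diary([], [], window_s=10.0)
        assert (report.n_true, report.n_detected, report.n_false_positive) == (0, 0, 0)

    def test_all_annotations_matched(self):
        anns = [
            SeizureAnnotation(onset_s=100.0 * k + 50.0, offset_s=100.0 * k + 80.0,
                              channel=LEFT)
            for k in range(5)
        ]
        events = [self._event(int(a.onset_s // 10)) for a in anns]
        report = evaluate_against_diary(events, anns, 1, window_s=10.0)
        assert report.n_true == 5
        assert report.n_detected == 5
        assert report.n_false_positive == 0

    def test_far_event_is_false_positive(self):
        anns = [SeizureAnnotation(onset_s=50.0, offset_s=80.0, channel=LEFT)]
        events = [self._event(40)]  # 400 s, far from the 50-80 s seizure
        report = evaluate_against_diary(events, anns, 1, window_s=10.0)
        assert report.n_detected == 0
        assert report.n_false_positive == 1

    def test_one_to_one_matching(self):
        anns = [SeizureAnnotation(onset_s=50.0, offset_s=80.0, channel=LEFT)]
        events = [self._event(5), self._event(6)]
        report = evaluate_against_diary(events, anns, 1, window_s=10.0)
        assert report.n_detected == 1
        assert report.n_false_positive == 1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=12, max_size=60),
    st.floats(min_value=1.0, max_value=8.0),
)
def test_events_are_exactly_maximal_supra_threshold_runs(values, z_thr):
    """With a stored baseline, detect_events reports one event per maximal
    run of supra-threshold windows, at the run's first window."""
    v = np.asarray(values)
    tl = _timeline(v)
    params = DetectionParams(z_threshold=z_thr, explicit_baseline=(1.0, 1.0))
    events = detect_events(tl, params)
    hot = v > 1.0 + z_thr  # oracle: z = (v - 1) / 1
    if np.all(v == v[0]):
        expected_starts = []
    else:
        expected_starts = [
            i for i in np.flatnonzero(hot) if i == 0 or not hot[i - 1]
        ]
    assert [e.window_index for e in events] == expected_starts
    for e in events:
        assert e.z > z_thr
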