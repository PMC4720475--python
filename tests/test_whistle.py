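"""Whistle detector: click suppression, detection function, gating."""

import numpy as np
import pytest

from pamtrack.sonar import NoiseModel
from pamtrack.synth import WhistleSpec, synth_ambient, synth_clicks, synth_whistle
from pamtrack.whistle import (
    DetectorConfig,
    GateConfig,
    SpectrogramParams,
    click_suppress,
    compute_spectrogram,
    detect_whistles,
    detection_function,
    false_positive_gate,
    measure_slope_duration,
    threshold_events,
)

FS = 100000.0


def _record_with_whistle(spec, rng, band_snr_db=20.0, lead=0.7, tail=0.7):
    noise = synth_ambient(0, FS, lead + spec.duration + tail, NoiseModel(), rng)
    w = synth_whistle(spec, FS)
    x = noise
    i0 = int(lead * FS)
    x[i0:i0 + len(w)] += w * 10.0 ** ((69.0 + band_snr_db) / 20.0)
    return x


class TestSpectrogram:
    def test_pure_tone_single_ridge_bin(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 10000 * t)
        sp = compute_spectrogram(x, SpectrogramParams(fs=FS))
        expected_bin = round(10000 / (FS / 1024))
        assert np.all(np.argmax(sp.power, axis=0) == expected_bin)

    def test_framing(self):
        sp = compute_spectrogram(np.zeros(int(FS)), SpectrogramParams(fs=FS))
        assert sp.freqs[1] - sp.freqs[0] == pytest.approx(FS / 1024)
        hop = sp.times[1] - sp.times[0]
        assert hop == pytest.approx(256 / FS)
        assert np.all(sp.power == 0.0)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(np.zeros(100), SpectrogramParams(fs=FS))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SpectrogramParams(nfft=1000)
        with pytest.raises(ValueError):
            SpectrogramParams(overlap=1.0)


class TestClickSuppression:
    def test_track_stays_on_tone_through_clicks(self, rng):
        spec = WhistleSpec(shape="flat", f_start=10000, f_end=10000,
                           duration=1.0, flat_drift_hz=0.0)
        x = _record_with_whistle(spec, rng)
        x += synth_clicks(10.0, FS, len(x) / FS) * 10.0 ** (95.0 / 20.0)
        sp = compute_spectrogram(x, SpectrogramParams(fs=FS))
        m_hz, _ = click_suppress(sp)
        during = (sp.times > 0.75) & (sp.times < 1.65)
        on_tone = np.abs(m_hz[during] - 10000) < 2 * FS / 1024
        assert np.mean(on_tone) > 0.9

    def test_clicks_alone_give_unstable_track(self, rng):
        x = synth_ambient(0, FS, 2.0, NoiseModel(), rng)
        x += synth_clicks(20.0, FS, 2.0) * 10.0 ** (95.0 / 20.0)
        sp = compute_spectrogram(x, SpectrogramParams(fs=FS))
        m_hz, _ = click_suppress(sp)
        # no stable ridge: the track wanders over most of the band
        assert np.std(m_hz) > 1000.0

    def test_single_nonzero_bin_is_the_track(self):
        sp = compute_spectrogram(np.zeros(4096), SpectrogramParams(fs=FS))
        sel = (sp.freqs >= 5000) & (sp.freqs <= 15000)
        target = np.flatnonzero(sel)[17]
        sp.power[target, :] = 1.0
        m_hz, m_bins = click_suppress(sp)
        assert np.all(m_bins == 17)
        assert np.all(m_hz == sp.freqs[target])

    def test_band_outside_spectrogram_rejected(self):
        sp = compute_spectrogram(np.zeros(4096), SpectrogramParams(fs=FS))
        with pytest.raises(ValueError):
            click_suppress(sp, band=(60000.0, 70000.0))


class TestDetectionFunction:
    def test_constant_track_gives_unity(self):
        m = np.full(50, 40.0)
        w, _ = detection_function(m, p=10, threshold=2.0)
        assert np.all(w == 1.0)

    def test_all_violations_closed_form(self):
        # quadratic track: M'(k) = M(k+2)-M(k) grows linearly, so every
        # |L| = 8 bins exceeds a 2-bin threshold and W = 0.8^P throughout
        m = 2.0 * np.arange(60, dtype=float) ** 2
        w, _ = detection_function(m, p=10, threshold=2.0)
        np.testing.assert_allclose(w, 0.8 ** 10)

    def test_bounds_hold_for_random_tracks(self, rng):
        m = rng.integers(0, 100, 300).astype(float)
        w, _ = detection_function(m, p=10, threshold=2.0)
        assert np.all(w >= 0.8 ** 10 - 1e-12)
        assert np.all(w <= 1.0 + 1e-12)

    def test_invariant_under_constant_offset(self, rng):
        m = rng.integers(0, 100, 200).astype(float)
        w1, _ = detection_function(m)
        w2, _ = detection_function(m + 37.0)
        np.testing.assert_allclose(w1, w2)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            detection_function(np.zeros(5), p=10)

    def test_threshold_events_merges_runs(self):
        w = np.array([0.1, 0.9, 0.95, 1.0, 0.9, 0.1, 0.1, 0.9, 0.9, 0.9])
        centers = np.arange(10) + 6
        times = np.arange(20) * 0.00256
        events = threshold_events(w, centers, times, w_threshold=0.8, min_columns=3)
        assert len(events) == 2
        assert events[0]["w_peak"] == pytest.approx(1.0)


class TestSlopeDuration:
    def test_linear_chirp_slope_within_5_percent(self, rng):
        spec = WhistleSpec(shape="rise", f_start=5000, f_end=15000, duration=1.0)
        x = _record_with_whistle(spec, rng)
        dets = detect_whistles(x)
        assert len(dets) == 1
        assert dets[0].slope == pytest.approx(10000.0, rel=0.05)

    def test_flat_tone_slope_and_duration(self, rng):
        spec = WhistleSpec(shape="flat", f_start=9000, f_end=9000,
                           duration=1.0, flat_drift_hz=0.0)
        x = _record_with_whistle(spec, rng)
        dets = detect_whistles(x)
        assert len(dets) == 1
        assert abs(dets[0].slope) < 500.0
        hop = 256 / FS
        assert dets[0].duration == pytest.approx(1.0, abs=2 * hop + 0.01)

    def test_outliers_do_not_move_slope(self):
        times = np.arange(200) * 0.00256
        m_hz = 5000 + 10000 * times
        clean, _, _ = measure_slope_duration(100, m_hz, times)
        corrupted = m_hz.copy()
        corrupted[[90, 101, 108]] += np.array([4000.0, -5000.0, 3000.0])
        robust, _, _ = measure_slope_duration(100, corrupted, times)
        assert robust == pytest.approx(clean, rel=0.05)

    def test_edge_window_flagged_truncated(self):
        times = np.arange(30) * 0.00256
        m_hz = np.full(30, 8000.0)
        _, _, truncated = measure_slope_duration(2, m_hz, times, window=40)
        assert truncated


class TestGate:
    def test_typical_whistle_accepted(self):
        assert false_positive_gate(10000.0, 0.4)

    def test_sustained_flat_screech_rejected(self):
        # mooring-cable screech mimics a very long flat whistle
        assert not false_positive_gate(0.0, 2.0)

    def test_disabled_gate_passes_everything(self):
        gate = GateConfig(enabled=False)
        assert false_positive_gate(0.0, 99.0, gate)

    def test_nonfinite_rejected(self):
        assert not false_positive_gate(float("nan"), 0.4)


class TestEndToEnd:
    def test_rising_whistle_detected_only_inside_interval(self, rng):
        spec = WhistleSpec(shape="rise", f_start=6000, f_end=14000, duration=0.5)
        x = _record_with_whistle(spec, rng, band_snr_db=15.0, lead=1.0, tail=1.0)
        dets = [d for d in detect_whistles(x) if d.accepted]
        assert len(dets) == 1
        assert 0.9 < dets[0].start < 1.6
        assert 0.9 < dets[0].end < 1.7

    def test_click_suppression_no_extra_events_on_tone(self, rng):
        spec = WhistleSpec(shape="convex", f_start=7000, f_end=12000, duration=0.5)
        x_plain = _record_with_whistle(spec, np.random.default_rng(3))
        x_clicky = x_plain + synth_clicks(15.0, FS, len(x_plain) / FS) * 10 ** (92 / 20)
        n_plain = len(detect_whistles(x_plain))
        n_clicky = len(detect_whistles(x_clicky))
        assert n_clicky <= n_plain + 1  # clicks must not inflate event count
        assert n_plain >= 1
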