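"""Synthetic scene generator: waveforms, noise levels, rendered delays."""

import numpy as np
import pytest
from scipy import signal

from pamtrack.geometry import ArrayGeometry, Attitude, UnitConfig, PAIRS
from pamtrack.sonar import NoiseModel
from pamtrack.synth import (
    AttitudeSeries,
    BoatSpec,
    Scene,
    SceneSource,
    WhistleSpec,
    fractional_delay,
    render_scene,
    sinc_resample,
    synth_ambient,
    synth_boat,
    synth_clicks,
    synth_whistle,
    whistle_contour,
)
from pamtrack.whistle import SpectrogramParams, compute_spectrogram, click_suppress

FS = 100000.0


class TestWhistleSynthesis:
    def test_flat_tone_ridge_at_contour_frequency(self):
        spec = WhistleSpec(shape="flat", f_start=10000, f_end=10000,
                           duration=1.0, flat_drift_hz=0.0)
        x = synth_whistle(spec, FS)
        sp = compute_spectrogram(x, SpectrogramParams(fs=FS))
        ridge = sp.freqs[np.argmax(sp.power, axis=0)]
        df = FS / 1024
        assert np.all(np.abs(ridge[2:-2] - 10000) <= df)

    def test_rising_chirp_slope(self):
        spec = WhistleSpec(shape="rise", f_start=5000, f_end=15000, duration=1.0)
        x = synth_whistle(spec, FS)
        sp = compute_spectrogram(x, SpectrogramParams(fs=FS))
        ridge = sp.freqs[np.argmax(sp.power, axis=0)]
        t = sp.times
        slope = np.polyfit(t[5:-5], ridge[5:-5], 1)[0]
        assert slope == pytest.approx(10000.0, rel=0.05)

    def test_zero_duration_empty(self):
        assert len(synth_whistle(WhistleSpec(duration=0.0), FS)) == 0

    def test_contour_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            synth_whistle(WhistleSpec(f_start=30000, f_end=60000), FS)

    @pytest.mark.parametrize("shape", ["concave", "convex", "sine", "multi-loop"])
    def test_curved_contours_stay_in_band(self, shape):
        spec = WhistleSpec(shape=shape, f_start=6000, f_end=14000, duration=0.5)
        f = whistle_contour(spec, np.linspace(0, 0.5, 500))
        assert f.min() > 2000 and f.max() < 20000
        # endpoints honour the start/end frequencies
        assert f[0] == pytest.approx(spec.f_start, rel=0.02)
        assert f[-1] == pytest.approx(spec.f_end, rel=0.02)


class TestOtherSources:
    def test_click_train_count(self):
        x = synth_clicks(10.0, FS, 1.0)
        peaks, _ = signal.find_peaks(np.abs(x), height=0.5, distance=int(0.05 * FS))
        assert len(peaks) == 10

    def test_boat_harmonic_comb(self):
        spec = BoatSpec(fundamental=120.0, n_harmonics=5, broadband=0.05)
        x = synth_boat(spec, FS, duration=2.0)
        f = np.fft.rfftfreq(len(x), 1 / FS)
        mag = np.abs(np.fft.rfft(x))
        for k in range(1, 6):
            lo, hi = np.searchsorted(f, [120 * k - 10, 120 * k + 10])
            band_peak = mag[lo:hi].max()
            floor = np.median(mag[(f > 50) & (f < 1000)])
            assert band_peak > 10 * floor

    def test_ambient_band_level_matches_wenz_entry(self, rng):
        x = synth_ambient(0, FS, 2.0, NoiseModel(), rng)
        # measured 5-15 kHz band level vs the configured 69 dB
        f, psd = signal.welch(x, FS, nperseg=4096)
        band = (f >= 5000) & (f <= 15000)
        level = 10 * np.log10(np.trapezoid(psd[band], f[band]))
        assert level == pytest.approx(69.0, abs=0.5)

    def test_ambient_sea_state_ordering(self, rng):
        x0 = synth_ambient(0, FS, 0.5, NoiseModel(), rng)
        x4 = synth_ambient(4, FS, 0.5, NoiseModel(), rng)
        assert np.std(x4) > 5 * np.std(x0)


class TestFractionalDelay:
    def test_integer_delay_shifts_exactly(self, rng):
        x = rng.standard_normal(4000)
        y = fractional_delay(x, 7.0)
        np.testing.assert_allclose(y[100:3900], x[93:3893], atol=1e-3)

    def test_fractional_delay_measured_by_correlation(self, rng):
        t = np.arange(8000) / FS
        # broadband chirp: the correlation peak is unambiguous
        x = signal.chirp(t, 5000, t[-1], 15000) * signal.windows.tukey(8000, 0.2)
        d = 3.37
        y = fractional_delay(x, d)
        corr = signal.correlate(y, x)
        lags = signal.correlation_lags(len(y), len(x))
        k = np.argmax(corr)
        c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
        frac = 0.5 * (c0 - c2) / (c0 - 2 * c1 + c2)
        assert lags[k] + frac == pytest.approx(d, abs=0.02)

    def test_sinc_resample_recovers_samples(self, rng):
        x = rng.standard_normal(2000)
        pos = np.arange(100, 1900).astype(float)
        np.testing.assert_allclose(sinc_resample(x, pos), x[100:1900], atol=1e-3)


class TestSceneRendering:
    @pytest.fixture(scope="class")
    def east_scene(self):
        unit = UnitConfig("u", 44.0, 9.0, depth=20.0)
        src = SceneSource("whistle",
                          WhistleSpec(shape="rise", duration=0.4),
                          start=0.1, position=np.array([1000.0, 0.0, 0.0]))
        scene = Scene(duration=1.4, sea_state=0, seed=11, sources=[src])
        res = render_scene(scene, [unit], ArrayGeometry.default(),
                           unit_positions={"u": np.array([0.0, 0.0, -20.0])})
        return res["u"]

    def test_truth_bearing_due_east(self, east_scene):
        tr = east_scene.truth[0]
        assert tr["bearing_deg"] == pytest.approx(90.0, abs=1e-9)
        assert tr["range"] == pytest.approx(1000.2, abs=0.5)

    def test_rendered_tdoas_match_plane_wave_model(self, east_scene, geometry):
        from pamtrack.tdoa import tdoa_set

        tr = east_scene.truth[0]
        seg = east_scene.audio[:, int(0.7 * FS):int(1.3 * FS)]
        ts = tdoa_set(seg, FS, geometry)
        assert ts.valid
        np.testing.assert_allclose(ts.tdoas, tr["expected_tdoas"],
                                   atol=2.0 / FS)

    def test_east_aligned_pair_sees_full_delay(self, east_scene, geometry):
        # identity attitude: body x = East; wave due West along pair (0,2),
        # foreshortened only by the 20 m depth elevation cosine
        tr = east_scene.truth[0]
        k02 = PAIRS.index((0, 2))
        k13 = PAIRS.index((1, 3))
        cos_el = 1000.0 / tr["range"]
        assert abs(tr["expected_tdoas"][k02]) == pytest.approx(
            5.0 / 1500.0 * cos_el, rel=1e-9)
        assert tr["expected_tdoas"][k13] == pytest.approx(0.0, abs=1e-12)

    def test_determinism_same_seed_bit_identical(self):
        unit = UnitConfig("u", 44.0, 9.0)
        def render():
            src = SceneSource("whistle", WhistleSpec(duration=0.2), start=0.05,
                              position=np.array([500.0, 500.0, 0.0]))
            scene = Scene(duration=0.8, seed=42, sources=[src])
            return render_scene(scene, [unit], ArrayGeometry.default(),
                                unit_positions={"u": np.zeros(3)})["u"].audio
        a, b = render(), render()
        assert np.array_equal(a, b)

    def test_equidistant_source_symmetric_between_units(self):
        units = [UnitConfig("a", 44.0, 9.0), UnitConfig("b", 44.0, 9.1)]
        src = SceneSource("whistle", WhistleSpec(duration=0.3), start=0.05,
                          position=np.array([0.0, 1500.0, 0.0]))
        scene = Scene(duration=1.6, seed=5, sources=[src])
        res = render_scene(scene, units, ArrayGeometry.default(),
                           unit_positions={"a": np.array([-900.0, 0.0, -20.0]),
                                           "b": np.array([900.0, 0.0, -20.0])})
        ra = res["a"].truth[0]["range"]
        rb = res["b"].truth[0]["range"]
        assert ra == pytest.approx(rb, abs=1e-6)
        # inter-unit arrival difference ~ 0: first-arrival sample indices agree
        xa = np.abs(res["a"].audio[0])
        xb = np.abs(res["b"].audio[0])
        ia = np.argmax(xa > 10 * np.median(xa))
        ib = np.argmax(xb > 10 * np.median(xb))
        assert abs(ia - ib) < 0.01 * FS

    def test_close_source_records_plane_wave_warning(self):
        unit = UnitConfig("u", 44.0, 9.0)
        src = SceneSource("whistle", WhistleSpec(duration=0.1), start=0.02,
                          position=np.array([50.0, 0.0, 0.0]))
        scene = Scene(duration=0.4, seed=1, sources=[src])
        res = render_scene(scene, [unit], ArrayGeometry.default(),
                           unit_positions={"u": np.array([0.0, 0.0, -20.0])})["u"]
        assert any("100 m" in w for w in res.warnings)

    def test_moving_source_tdoa_tracks_position(self, geometry):
        from pamtrack.boat import correlogram_stream

        unit = UnitConfig("u", 44.0, 9.0)
        traj = np.array([[0.0, 300.0, 0.0, 0.0], [4.0, 300.0, 0.0, 0.0]])
        src = SceneSource("boat", BoatSpec(duration=3.0, source_level=165.0),
                          start=0.0, trajectory=traj)
        scene = Scene(duration=3.2, seed=9, sources=[src])
        res = render_scene(scene, [unit], geometry,
                           unit_positions={"u": np.array([0.0, 0.0, -20.0])})["u"]
        t, dt20, dt31, _, _ = correlogram_stream(
            res.audio[:, int(0.5 * FS):int(2.5 * FS)], FS, lc=5.0 / 1500.0)
        got = np.nanmedian(dt20)
        # boat due East: dT20 (= t0 - t2) at its positive extreme, shortened
        # by the elevation cosine of the 20 m-deep pair
        r = res.truth[0]["range"]
        horiz = 300.0
        expected = (5.0 / 1500.0) * horiz / r
        assert got == pytest.approx(expected, abs=2.0 / FS)
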