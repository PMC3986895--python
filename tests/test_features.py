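"""Spectral analysis: preset arithmetic, spectrogram contracts, energy
quartiles (closed-form oracles), contour trend algebra, F0 recovery on
synthesized elements, and the feature-vector registry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import barkit as bk
from barkit.features import (
    FEATURE_COLUMNS,
    PRESETS,
    compute_spectrogram,
    extract_f0_contour,
    extract_features,
    frame_energy_percentiles,
    frame_energy_quartiles,
    linear_trend,
)


def make_call(f0_start=254.0, f0_end=254.0, duration_ms=250.0,
              tonal_fraction=1.0, rate=22050, seed=0):
    """One single-element call embedded in a padded bout waveform."""
    el = bk.synthesize_element(f0_start, f0_end, duration_ms,
                               tonal_fraction=tonal_fraction,
                               sampling_rate=rate, seed=seed)
    pad = np.zeros(int(0.2 * rate))
    bout = bk.Waveform(np.concatenate([pad, el.samples, pad]), rate)
    onset = len(pad) / rate
    offset = (len(pad) + len(el.samples)) / rate
    call = bk.CallRecord([bk.ElementLabel(onset, offset, "Ex1")])
    return call, bout


class TestPresets:
    def test_hop_and_bin_arithmetic(self):
        assert PRESETS["energy"].hop == 64          # 1024 * (1 - 0.9375)
        assert PRESETS["f0"].hop == 32              # 1024 * (1 - 0.9687), rounded
        assert PRESETS["energy"].bin_width_hz == pytest.approx(15.625)
        assert PRESETS["f0"].bin_width_hz == pytest.approx(7.8125)
        # both presets step 4 ms per frame at their respective rates
        assert PRESETS["energy"].hop / 16000 == pytest.approx(0.004)
        assert PRESETS["f0"].hop / 8000 == pytest.approx(0.004)

    def test_tonality_preset_is_energy_plus_lowpass(self):
        e, t = PRESETS["energy"], PRESETS["tonality"]
        assert t.lowpass_hz == 1200.0
        assert (t.target_rate, t.fft_size, t.overlap_pct) == \
            (e.target_rate, e.fft_size, e.overlap_pct)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="power of two"):
            bk.SpectrogramConfig(target_rate=16000, fft_size=1000)
        with pytest.raises(ValueError, match="overlap"):
            bk.SpectrogramConfig(target_rate=16000, overlap_pct=100.0)
        with pytest.raises(ValueError):
            bk.SpectrogramConfig(target_rate=8000, lowpass_hz=5000.0)


class TestSpectrogram:
    def test_pure_tone_peaks_in_its_bin(self):
        cfg = PRESETS["energy"]
        f_tone = 32 * cfg.bin_width_hz  # exactly on a bin center (500 Hz)
        t = np.arange(16000) / 16000
        w = bk.Waveform(np.sin(2 * np.pi * f_tone * t), 16000)
        freqs, times, mag = compute_spectrogram(w, cfg)
        assert np.all(freqs[np.argmax(mag, axis=1)] == f_tone)
        assert len(freqs) == cfg.fft_size // 2 + 1

    def test_frame_count_and_times(self):
        cfg = PRESETS["energy"]
        w = bk.Waveform(np.random.default_rng(0).standard_normal(16000), 16000)
        _, times, mag = compute_spectrogram(w, cfg)
        expected = (16000 - cfg.fft_size) // cfg.hop + 1
        assert mag.shape[0] == len(times) == expected
        # frame centers: fft_size/2 then steps of hop
        assert times[0] == pytest.approx(512 / 16000)
        np.testing.assert_allclose(np.diff(times), cfg.hop / 16000)

    def test_shorter_than_one_frame_raises(self):
        w = bk.Waveform(np.ones(500), 16000)
        with pytest.raises(bk.TooShortError):
            compute_spectrogram(w, PRESETS["energy"])


class TestEnergyQuartiles:
    def test_flat_spectrum_quartiles(self):
        freqs = np.arange(513) * 15.625
        mag = np.ones(513)
        q1, q2, q3 = frame_energy_percentiles(mag, freqs, (25, 50, 75))
        span = freqs[-1]
        assert q2 == pytest.approx(span / 2)           # exact by symmetry
        assert q1 == pytest.approx(span / 4, abs=15.625)
        assert q3 == pytest.approx(3 * span / 4, abs=15.625)

    def test_point_mass_in_one_bin(self):
        freqs = np.arange(513) * 15.625
        mag = np.zeros(513)
        mag[100] = 3.0
        q1, q2, q3, peak = frame_energy_quartiles(mag, freqs)
        assert peak == freqs[100]
        assert q2 == pytest.approx(freqs[100])          # bin center
        half = 15.625 / 2
        assert q1 == pytest.approx(freqs[100] - half / 2)
        assert q3 == pytest.approx(freqs[100] + half / 2)

    def test_two_equal_point_masses(self):
        freqs = np.arange(513) * 15.625
        mag = np.zeros(513)
        mag[[50, 200]] = 1.0
        q1, q2, q3, _ = frame_energy_quartiles(mag, freqs)
        # 25 % of the energy sits mid-way through the first occupied bin
        assert q1 == pytest.approx(freqs[50])
        assert q3 == pytest.approx(freqs[200])
        assert freqs[50] < q2 < freqs[200]

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError, match="no energy"):
            frame_energy_percentiles(np.zeros(10), np.arange(10.0), (50,))

    @given(st.lists(st.floats(0.0, 100.0), min_size=4, max_size=64)
           .filter(lambda v: sum(v) > 0))
    def test_quartiles_ordered_and_in_range(self, mags):
        freqs = np.arange(len(mags)) * 15.625
        q1, q2, q3, peak = frame_energy_quartiles(np.array(mags), freqs)
        assert q1 <= q2 <= q3
        half = 15.625 / 2
        assert freqs[0] - half <= q1 and q3 <= freqs[-1] + half
        assert peak in freqs


class TestLinearTrend:
    def test_exact_line_from_300_to_258(self):
        values = np.linspace(300.0, 258.0, 15)
        trend, deviation = linear_trend(values)
        assert trend == pytest.approx(-42.0 / 279.0)   # total change / mean
        assert deviation == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_residual_pattern_gives_its_magnitude(self):
        # +10, -10, -10, +10 is orthogonal to both constant and linear terms
        base = np.array([200.0, 210.0, 220.0, 230.0])
        trend_b, _ = linear_trend(base)
        values = base + np.array([10.0, -10.0, -10.0, 10.0])
        trend, deviation = linear_trend(values)
        assert deviation == pytest.approx(10.0)
        assert trend == pytest.approx(trend_b)          # the line is unchanged

    def test_nans_dropped_short_contours_nan(self):
        assert np.isnan(linear_trend([5.0])).all()
        assert np.isnan(linear_trend([np.nan, 1.0, np.nan])).all()
        t, d = linear_trend([np.nan, 100.0, 110.0, np.nan])
        assert np.isfinite(t) and d == pytest.approx(0.0, abs=1e-10)

    def test_flat_contour_zero_trend(self):
        trend, deviation = linear_trend(np.full(20, 254.0))
        assert trend == pytest.approx(0.0, abs=1e-12)
        assert deviation == pytest.approx(0.0, abs=1e-10)


class TestF0Contour:
    def test_constant_f0_recovered_within_one_bin(self):
        call, bout = make_call(f0_start=254.0, f0_end=254.0)
        contour = extract_f0_contour(
            bout.slice(call.ex1.onset, call.ex1.offset))
        voiced = contour.f0[contour.voiced]
        assert len(voiced) > 10
        assert np.median(voiced) == pytest.approx(254.0, abs=7.8125)

    def test_downward_sweep_sign(self):
        call, bout = make_call(f0_start=320.0, f0_end=250.0, duration_ms=300)
        feats = extract_features(call, bout)
        assert feats["f0_start"] > feats["f0_end"]
        assert feats["f0_linear_trend"] < 0
        assert feats["f0_start"] == pytest.approx(320.0, abs=25.0)
        assert feats["f0_end"] == pytest.approx(250.0, abs=25.0)

    def test_tonal_element_high_noise_element_low_tonality(self):
        tonal, bout_t = make_call(tonal_fraction=1.0)
        noisy, bout_n = make_call(tonal_fraction=0.0)
        t_tonal = extract_features(tonal, bout_t)["tonality"]
        t_noise = extract_features(noisy, bout_n)["tonality"]
        assert t_tonal > 80.0
        assert t_noise < 10.0


class TestExtractFeatures:
    def test_registry_complete_and_ordered(self):
        assert len(FEATURE_COLUMNS) == 31
        call, bout = make_call()
        feats = extract_features(call, bout)
        assert list(feats) == list(FEATURE_COLUMNS)

    def test_temporal_features_from_labels(self):
        call, bout = make_call(duration_ms=250.0)
        feats = extract_features(call, bout)
        assert feats["element_number"] == 1.0
        assert feats["ex1_duration"] == pytest.approx(250.0, abs=1.0)
        assert feats["duration"] == feats["ex1_duration"]

    def test_amplitude_scale_invariance(self):
        call, bout = make_call(seed=7)
        quiet = bk.Waveform(0.3 * bout.samples, bout.rate)
        a = extract_features(call, bout)
        b = extract_features(call, quiet)
        for name in FEATURE_COLUMNS:
            assert a[name] == pytest.approx(b[name], rel=1e-6, nan_ok=True), name

    def test_sampling_rate_robustness(self):
        """The same element analysed from a 44.1 kHz and a 16 kHz recording
        gives closely matching spectral features (both are resampled to the
        preset rates internally)."""
        call_hi, bout_hi = make_call(rate=44100, seed=3)
        call_lo, bout_lo = make_call(rate=16000, seed=3)
        a = extract_features(call_hi, bout_hi)
        b = extract_features(call_lo, bout_lo)
        for name in ("f0_mean", "q2_median", "tonality"):
            assert a[name] == pytest.approx(b[name], rel=0.02), name

    def test_quartile_medians_ordered(self):
        call, bout = make_call(tonal_fraction=0.5, seed=11)
        feats = extract_features(call, bout)
        assert feats["q1_median"] <= feats["q2_median"] <= feats["q3_median"]
        assert feats["frequency_range"] > 0

    def test_feature_table_one_row_per_call(self):
        call, bout = make_call()
        table = bk.extract_feature_table([call, call], bout,
                                         identifiers={"population": "x",
                                                      "male_id": "m1"})
        assert len(table) == 2
        assert list(table["call_id"]) == ["c001", "c002"]
        assert set(FEATURE_COLUMNS) <= set(table.columns)
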