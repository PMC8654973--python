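"""Feature formulas vs independent oracles, plus bed-motion correction rules."""

import numpy as np
import pytest
import pywt

from conftest import make_window
from icumotion import features as ft

FS = 10.0
N = 50


def sinusoid(f, n=N, fs=FS, amp=1.0, phase=0.3):
    return amp * np.sin(2 * np.pi * f * np.arange(n) / fs + phase)


class TestSMA:
    def test_constant_unit_signal_closed_form(self):
        # (0.1/10) * sum_{n=1}^{49} 6 = 0.01*49*6 = 2.94
        w = make_window(np.ones(N), np.ones(N), np.ones(N))
        assert ft.sma(w) == pytest.approx(2.94, abs=1e-12)

    def test_zero_window(self):
        assert ft.sma(make_window(np.zeros(N))) == 0.0

    def test_absolute_homogeneity(self, rng):
        x, y, z = rng.normal(size=(3, N))
        base = ft.sma(make_window(x, y, z))
        assert ft.sma(make_window(-2.5 * x, -2.5 * y, -2.5 * z)) == pytest.approx(
            2.5 * base, rel=1e-12)

    def test_incomplete_window_is_missing(self):
        assert np.isnan(ft.sma(make_window(np.ones(N), complete=False)))

    def test_matches_printed_sum_oracle(self, rng):
        x, y, z = rng.normal(size=(3, N))
        total = sum(abs(v[n + 1]) + abs(v[n]) for v in (x, y, z)
                    for n in range(N - 1))
        assert ft.sma(make_window(x, y, z)) == pytest.approx(0.1 / 10 * total, rel=1e-12)


class TestHLF:
    def test_zero_window(self):
        assert ft.hlf(make_window(np.zeros(N))) == (0.0, 0.0)

    def test_constant_signal_split(self):
        c = 0.7
        hi, lo = ft.hlf(make_window(c * np.ones(N), c * np.ones(N), c * np.ones(N)))
        assert lo == pytest.approx(np.sqrt(3) * c, rel=0.10)   # low-pass keeps DC
        assert hi < 0.1 * c                                    # high-pass rejects it

    def test_4hz_sinusoid_prefers_highpass(self):
        s = sinusoid(4.0)
        hi, lo = ft.hlf(make_window(s, s, s))
        assert hi >= lo


class TestMFR:
    @staticmethod
    def oracle_axis(v):
        """Brute-force cumulative-power scan over one-sided DFT bins."""
        spec = np.abs(np.fft.rfft(v)) ** 2
        freqs = np.fft.rfftfreq(len(v), d=1 / FS)
        total = spec.sum()
        if total == 0:
            return 0.0
        cum = 0.0
        for p, f in zip(spec, freqs):
            cum += p
            if cum >= total / 2:
                return f
        return freqs[-1]

    def test_pure_2hz_tone(self):
        w = make_window(sinusoid(2.0))
        assert ft.mfr(w) == pytest.approx(2.0, abs=1e-9)

    def test_identical_1hz_on_all_axes(self):
        s = sinusoid(1.0)
        assert ft.mfr(make_window(s, s, s)) == pytest.approx(np.sqrt(3) * 1.0, abs=1e-9)

    def test_zero_window(self):
        assert ft.mfr(make_window(np.zeros(N))) == 0.0

    def test_matches_scan_oracle_on_random_windows(self, rng):
        for _ in range(20):
            x, y, z = rng.normal(size=(3, N))
            expected = np.sqrt(sum(self.oracle_axis(v) ** 2 for v in (x, y, z)))
            assert ft.mfr(make_window(x, y, z)) == pytest.approx(expected, rel=1e-10)


class TestFDE:
    def test_uniform_spectrum_reaches_sqrt3(self, rng):
        # white phase-random signal with exactly flat magnitude spectrum
        phases = rng.uniform(0, 2 * np.pi, N)
        spec = np.exp(1j * phases)
        v = np.fft.ifft(spec)          # complex signal with |V_k| = 1 for all k
        out = ft.fde_batch(v[None, :], v[None, :], v[None, :], FS)
        assert out[0] == pytest.approx(np.sqrt(3), rel=1e-9)

    def test_single_bin_spectrum_zero_entropy(self):
        v = np.exp(2j * np.pi * 3 * np.arange(N) / N)   # complex exponential
        z = np.zeros(N)
        out = ft.fde_batch(v[None, :], z[None, :], z[None, :], FS)
        assert out[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_window_convention(self):
        assert ft.fde(make_window(np.zeros(N))) == 0.0

    def test_bounded_by_sqrt3(self, rng):
        for _ in range(20):
            x, y, z = rng.normal(size=(3, N))
            assert 0 <= ft.fde(make_window(x, y, z)) <= np.sqrt(3) + 1e-12


class TestBPW:
    def test_zero_window(self):
        assert ft.bpw(make_window(np.zeros(N))) == 0.0

    def test_in_band_tone_beats_out_of_band(self):
        in_band = ft.bpw(make_window(sinusoid(1.0)))
        out_band = ft.bpw(make_window(sinusoid(4.6)))
        assert in_band > out_band

    def test_quadratic_homogeneity(self, rng):
        x, y, z = rng.normal(size=(3, N))
        base = ft.bpw(make_window(x, y, z))
        assert ft.bpw(make_window(3 * x, 3 * y, 3 * z)) == pytest.approx(
            9 * base, rel=1e-10)

    def test_matches_bin_summation_oracle(self, rng):
        x, y, z = rng.normal(size=(3, N))
        df = FS / N
        freqs = np.fft.rfftfreq(N, d=1 / FS)
        sel = (freqs >= 0.3) & (freqs <= 3.5)
        parts = []
        for v in (x, y, z):
            p = (np.abs(np.fft.rfft(v)[sel]) ** 2 * df).sum()
            parts.append(p ** 2)
        expected = np.sqrt(sum(parts)) / 3.2
        assert ft.bpw(make_window(x, y, z)) == pytest.approx(expected, rel=1e-10)


class TestWVL:
    @staticmethod
    def oracle_energy(v):
        """Independent db5 DWT: symmetric extension + direct convolution."""
        w = pywt.Wavelet("db5")
        lo = np.array(w.dec_lo)
        hi = np.array(w.dec_hi)
        fl = len(lo)

        def dwt_step(x, filt):
            ext = np.concatenate([x[:fl][::-1], x, x[-fl:][::-1]])
            full = np.convolve(ext, filt, mode="full")
            out_len = (len(x) + fl - 1) // 2
            return full[fl + 1::2][:out_len]

        energy = 0.0
        approx = np.asarray(v, dtype=float)
        for level in range(1, 7):
            detail = dwt_step(approx, hi)
            approx = dwt_step(approx, lo)
            if 2 <= level <= 6:
                energy += float((detail ** 2).sum())
        return energy

    def test_zero_window(self):
        assert ft.wvl(make_window(np.zeros(N))) == 0.0

    def test_single_axis_equals_axis_energy(self, rng):
        x = rng.normal(size=N)
        val = ft.wvl(make_window(x))
        assert val == pytest.approx(self.oracle_energy(x), rel=1e-8)

    def test_matches_independent_transform_on_noise(self, rng):
        for _ in range(5):
            x, y, z = rng.normal(size=(3, N))
            expected = np.sqrt(sum(self.oracle_energy(v) ** 2 for v in (x, y, z)))
            assert ft.wvl(make_window(x, y, z)) == pytest.approx(expected, rel=1e-8)


class TestPDA:
    def test_all_below_threshold(self):
        assert ft.pda([0.01, 0.02, 0.1]) == 0.0

    def test_quarter_dynamic(self):
        series = [0.2, 0.2, 0.2] + [0.0] * 9
        assert ft.pda(series) == 0.25

    def test_zero_threshold_boundary(self):
        assert ft.pda([0.3, 0.4], threshold=0.0) == 1.0

    def test_empty_series_missing(self):
        assert np.isnan(ft.pda([np.nan, np.nan]))

    def test_non_increasing_in_threshold(self, rng):
        series = rng.uniform(0, 0.5, 100)
        vals = [ft.pda(series, t) for t in np.linspace(0, 0.5, 20)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))


class TestBedCorrection:
    def test_zero_bed_sma_gives_empty_mask(self):
        mask = ft.detect_bed_events(np.zeros(30), np.random.default_rng(0).uniform(0, 0.1, 30))
        assert not mask.any()

    def test_bed_event_with_following_spike_flagged(self):
        bed = np.zeros(30)
        bed[10] = 0.5
        ext = np.full(30, 0.02)
        ext[11] = 1.0
        mask = ft.detect_bed_events(bed, ext)
        assert mask[10] and mask.sum() == 1

    def test_bed_event_with_flat_extremity_not_flagged(self):
        # 20-window toy series: flat extremity never exceeds median + 3*MAD
        bed = np.zeros(20)
        bed[8] = 0.5
        ext = np.full(20, 0.05)
        mask = ft.detect_bed_events(bed, ext)
        assert not mask.any()

    def test_zero_bed_vector_identity(self, rng):
        ranges = ft.StaticRange({f: (0.0, 10.0) for f in ft.FEATURES})
        extremity = {f: 0.05 * (i + 1) for i, f in enumerate(ft.FEATURES)}
        bed = {f: 0.0 for f in ft.FEATURES}
        assert ft.correct_features(extremity, bed, ranges, rng) == extremity

    def test_additive_rule_for_frequency_features(self, rng):
        ranges = ft.StaticRange({f: (0.0, 10.0) for f in ft.FEATURES})
        extremity = {f: 1.0 for f in ft.FEATURES}
        bed = {f: 0.5 for f in ft.FEATURES}
        out = ft.correct_features(extremity, bed, ranges, rng)
        assert out["MFR"] == pytest.approx(1.5)
        assert out["SMA"] == pytest.approx(0.5)

    def test_out_of_range_value_replaced_uniformly(self):
        rng = np.random.default_rng(7)
        ranges = ft.StaticRange({f: (0.0, 0.135) for f in ft.FEATURES})
        extremity = {f: 0.0 for f in ft.FEATURES}
        extremity["SMA"] = 0.2
        bed = {f: 0.0 for f in ft.FEATURES}
        bed["SMA"] = 0.05
        out = ft.correct_features(extremity, bed, ranges, rng)
        # 0.15 exceeds the 0.135 static bound -> uniform replacement in range
        assert 0.0 <= out["SMA"] <= 0.135

    def test_missing_static_range_is_config_error(self, rng):
        ranges = ft.StaticRange({"SMA": (0.0, 1.0)})
        with pytest.raises(ValueError, match="static range"):
            ft.correct_features({f: 1.0 for f in ft.FEATURES},
                                {f: 0.0 for f in ft.FEATURES}, ranges, rng)


def test_shared_spectral_pass_matches_individual_features(rng):
    xw, yw, zw = rng.normal(size=(3, 30, N))
    mfr_v, fde_v, bpw_v = ft._spectral_batch(xw, yw, zw, FS)
    np.testing.assert_allclose(mfr_v, ft.mfr_batch(xw, yw, zw, FS), rtol=1e-12)
    np.testing.assert_allclose(fde_v, ft.fde_batch(xw, yw, zw, FS), rtol=1e-12)
    np.testing.assert_allclose(bpw_v, ft.bpw_batch(xw, yw, zw, FS), rtol=1e-12)


class TestInvariants:
    def test_axis_permutation_invariance(self, rng):
        x, y, z = rng.normal(size=(3, N))
        for fn in (ft.sma, ft.mfr, ft.fde, ft.bpw, ft.wvl):
            a = fn(make_window(x, y, z))
            b = fn(make_window(z, x, y))
            assert a == pytest.approx(b, rel=1e-10)

    def test_parseval_consistency(self, rng):
        v = rng.normal(size=N)
        spec_energy = (np.abs(np.fft.fft(v)) ** 2).sum() / N
        time_energy = (v ** 2).sum()
        assert spec_energy == pytest.approx(time_energy, rel=1e-10)
        # and the one-sided form used by MFR/BPW covers the full power
        one_sided = np.abs(np.fft.rfft(v)) ** 2
        doubled = 2 * one_sided.sum() - one_sided[0] - (one_sided[-1] if N % 2 == 0 else 0)
        assert doubled / N == pytest.approx(time_energy, rel=1e-10)

    def test_all_features_nonnegative(self, feature_series):
        vals = feature_series.frame.to_numpy()
        assert np.nanmin(vals) >= 0

    def test_static_range_estimation_brackets_quiet_windows(self, feature_series):
        ranges = ft.estimate_static_ranges([feature_series])
        for f in ft.FEATURES:
            lo, hi = ranges[f]
            assert lo == 0.0 and hi >= 0.0


def test_extract_features_marks_gap_windows_missing(patient_recording, feature_series):
    frac_missing = feature_series.frame.isna().to_numpy().mean()
    assert 0 < frac_missing < 0.2


def test_tidy_roundtrip_schema(feature_series):
    tidy = ft.features_to_tidy(feature_series)
    assert set(tidy.columns) == {"patient", "placement", "window_start_s",
                                 "feature", "value", "missing"}
    assert len(tidy) == feature_series.frame.size
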