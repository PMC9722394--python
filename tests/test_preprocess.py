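import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsfc.preprocess import (PreprocConfig, bandpass, compute_snr_db,
                               detect_motion, extinction_matrix,
                               intensity_to_od, od_to_hb, qc_channels,
                               spline_correct)

CFG = PreprocConfig()
FS = 19.0


class TestSNR:
    def test_amplitude_ratio_convention(self):
        d = np.array([99.0, 101.0])  # mean 100, std 1
        assert compute_snr_db(d) == pytest.approx(40.0)

    def test_unity_ratio_is_zero_db(self):
        d = 10.0 + 10.0 * np.array([-0.99, 1.0, -0.01]) / np.std([-0.99, 1.0, -0.01])
        d = d[d > 0]
        assert compute_snr_db(d) == pytest.approx(
            20 * np.log10(d.mean() / d.std()))

    def test_constant_series_is_infinite(self):
        assert compute_snr_db(np.full(50, 3.0)) == np.inf

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_snr_db(np.array([1.0, -1.0, 2.0]))

    def test_channel_just_below_threshold_flagged(self):
        # 20*log10(100/31.99) = 9.897 dB < 10 dB
        t = np.tile([-1.0, 1.0], 50)
        good = 100.0 + 1.0 * t
        bad = 100.0 + 31.99 * t
        intensity = np.stack([np.stack([good, good]), np.stack([bad, bad])])
        mask, snr, summary = qc_channels(intensity, CFG)
        assert mask.tolist() == [True, False]
        assert snr[1, 0] == pytest.approx(9.897, abs=0.01)
        assert summary["n_fail"] == 1

    def test_qc_monotone_in_threshold(self, rng):
        intensity = 1.0 + 0.05 * rng.standard_normal((10, 2, 200))
        intensity[3] = 1.0 + 0.4 * rng.standard_normal((2, 200))
        masks = [
            qc_channels(np.abs(intensity) + 0.01,
                        PreprocConfig(snr_threshold_db=thr))[0]
            for thr in (5.0, 10.0, 20.0, 40.0)
        ]
        for lo, hi in zip(masks, masks[1:]):
            assert np.all(lo | ~hi)  # raising the bar never admits a channel


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self):
        od = intensity_to_od(np.full(100, 2.5))
        assert np.allclose(od, 0.0)

    def test_tenth_of_mean_gives_unit_od(self):
        x = np.ones(1000)
        x[500] = 999.0 / 9999.0   # exactly mean/10 after inclusion
        od = intensity_to_od(x)
        assert od[500] == pytest.approx(1.0)

    def test_nonpositive_sample_named(self):
        x = np.ones((2, 10))
        x[1, 3] = 0.0
        with pytest.raises(ValueError, match=r"\(1, 3\)"):
            intensity_to_od(x)


class TestMotionDetection:
    def _clean(self, rng, n=2280):
        return 0.003 * bandpass(rng.standard_normal(n + 800), FS)[400:400 + n]

    def test_clean_signal_yields_no_segments(self, rng):
        assert detect_motion(self._clean(rng), FS, CFG) == []

    def test_single_spike_one_padded_segment(self, rng):
        od = self._clean(rng)
        spike_at = 1000
        od[spike_at] += 30 * CFG.amp_thresh * 0.001 + 0.5  # far above threshold
        segs = detect_motion(od, FS, CFG)
        assert len(segs) == 1
        start, stop = segs[0]
        assert start <= spike_at < stop
        pad = int(CFG.t_mask * FS)
        w = int(CFG.t_motion * FS)
        assert spike_at - start <= pad + w + 1
        assert stop - spike_at <= pad + w + 1

    def test_nearby_spikes_merge(self, rng):
        od = self._clean(rng)
        od[1000] += 0.5
        od[1000 + int(0.5 * FS)] += 0.5   # 0.5 s apart, t_mask = 1 s
        segs = detect_motion(od, FS, CFG)
        assert len(segs) == 1

    def test_step_detected(self, rng):
        od = self._clean(rng)
        od[1200:] += 0.05
        segs = detect_motion(od, FS, CFG)
        assert any(a <= 1200 < b for a, b in segs)


class TestSplineCorrection:
    def test_empty_segment_list_identity(self, rng):
        od = self._series(rng)
        assert np.array_equal(spline_correct(od, [], FS, CFG), od)

    def _series(self, rng, n=2280):
        return 0.003 * bandpass(rng.standard_normal(n + 800), FS)[400:400 + n]

    def test_step_height_reduced(self, rng):
        od = self._series(rng)
        step = 0.1
        od_bad = od.copy()
        od_bad[1100:] += step
        seg = [(1100 - 19, 1100 + 19)]
        fixed = spline_correct(od_bad, seg, FS, CFG)
        before = np.mean(od_bad[1119:1219]) - np.mean(od_bad[981:1081])
        after = np.mean(fixed[1119:1219]) - np.mean(fixed[981:1081])
        assert abs(after) < 0.1 * abs(before)

    def test_outside_samples_only_level_shifted(self, rng):
        od = self._series(rng)
        od_bad = od.copy()
        od_bad[1000:1050] += 0.3
        seg = [(990, 1060)]
        fixed = spline_correct(od_bad, seg, FS, CFG)
        assert np.array_equal(fixed[:990], od_bad[:990])
        tail_diff = fixed[1060:] - od_bad[1060:]
        assert np.ptp(tail_diff) == pytest.approx(0.0, abs=1e-12)

    def test_near_idempotent(self, rng):
        od = self._series(rng)
        # slow motion bump, the shape the spline is designed to track
        idx = np.arange(990, 1030)
        od[idx] += 0.4 * np.exp(-0.5 * ((idx - 1010) / 4.0) ** 2)
        seg = [(990, 1030)]
        once = spline_correct(od, seg, FS, CFG)
        twice = spline_correct(once, seg, FS, CFG)
        assert np.sqrt(np.mean((twice - once) ** 2)) < 0.01 * np.std(od)

    def test_short_segment_linear_fallback(self, rng):
        od = self._series(rng)
        fixed = spline_correct(od, [(100, 103)], FS, CFG)
        assert np.all(np.isfinite(fixed))

    def test_out_of_bounds_segment_rejected(self, rng):
        with pytest.raises(ValueError):
            spline_correct(self._series(rng), [(0, 99999)], FS, CFG)


class TestBandpass:
    def _amp(self, freq, n=19000):
        t = np.arange(n) / FS
        y = bandpass(np.sin(2 * np.pi * freq * t), FS)
        mid = y[n // 4: 3 * n // 4]
        return np.ptp(mid) / 2

    def test_passband_centre(self):
        assert 0.89 <= self._amp(0.05) <= 1.0

    def test_cardiac_stopband(self):
        assert self._amp(1.1) < 0.1

    def test_respiratory_stopband_20db(self):
        assert self._amp(0.25) < 0.1

    def test_dc_removed(self):
        y = bandpass(np.full(4000, 5.0), FS)
        assert np.max(np.abs(y)) < 1e-6

    def test_zero_phase(self):
        t = np.arange(19000) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, FS)
        sl = slice(4000, 15000)
        lags = range(-10, 11)
        corr = [np.dot(x[sl], np.roll(y, k)[sl]) for k in lags]
        assert list(lags)[int(np.argmax(corr))] == 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.ones(10), FS)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(100), FS, band=(0.1, 0.01))


class TestBeerLambert:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = od_to_hb(np.zeros(10), np.zeros(10), CFG)
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_exact_round_trip(self, rng):
        hbo = rng.standard_normal(500)
        hbr = rng.standard_normal(500)
        e = extinction_matrix(CFG.wavelengths)
        path = CFG.dpf * CFG.sd_distance
        od730 = (e[0, 0] * hbo + e[0, 1] * hbr) * path
        od850 = (e[1, 0] * hbo + e[1, 1] * hbr) * path
        hbo2, hbr2 = od_to_hb(od730, od850, CFG)
        assert np.allclose(hbo2, hbo, atol=1e-10)
        assert np.allclose(hbr2, hbr, atol=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        a730, a850 = r.standard_normal((2, 50))
        b730, b850 = r.standard_normal((2, 50))
        ha, _ = od_to_hb(a730, a850, CFG)
        hb_, _ = od_to_hb(b730, b850, CFG)
        hsum, _ = od_to_hb(a730 + b730, a850 + b850, CFG)
        assert np.allclose(hsum, ha + hb_, atol=1e-9)

    def test_degenerate_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            extinction_matrix((730.0, 730.0))

    def test_unknown_wavelength_rejected(self):
        with pytest.raises(KeyError):
            extinction_matrix((730.0, 808.0))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            od_to_hb(np.zeros(5), np.zeros(6), CFG)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"band": (0.1, 0.01)},
        {"spline_p": 1.5},
        {"sd_thresh": -1.0},
        {"t_mask": 0.0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            PreprocConfig(**kw)
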