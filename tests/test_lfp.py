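"""LFP extraction, band filtering, theta maps, phase spread, envelopes, PSD."""

import numpy as np
import pytest

from orgephys.bursts import BurstCatalog
from orgephys.io import LFPSet, ValidationError
from orgephys.lfp import (
    BANDS, band_filter, compute_psd, envelope_threshold_stats, extract_lfp,
    phase_spread, signal_average_theta, theta_correlation_map,
)


def _lfp(data, fs=1000.0):
    data = np.atleast_2d(data)
    pos = np.column_stack([np.arange(data.shape[0]) * 100.0,
                           np.zeros(data.shape[0])])
    return LFPSet(data, fs, pos, band="lfp")


class TestExtractLFP:
    def test_passband_amplitude_preserved(self):
        fs = 20000.0
        t = np.arange(int(2 * fs)) / fs
        raw = LFPSet(10 * np.sin(2 * np.pi * 5 * t)[None, :], fs,
                     np.zeros((1, 2)))
        out = extract_lfp(raw)
        assert out.fs == 1000.0
        assert out.data.max() == pytest.approx(10.0, rel=0.01)

    def test_stopband_attenuated(self):
        fs = 20000.0
        t = np.arange(int(2 * fs)) / fs
        raw = LFPSet(10 * np.sin(2 * np.pi * 5000 * t)[None, :], fs,
                     np.zeros((1, 2)))
        out = extract_lfp(raw)
        assert np.sqrt(np.mean(out.data ** 2)) < 0.1 * 10 / np.sqrt(2)

    def test_dc_preserved(self):
        raw = LFPSet(np.full((1, 40000), 7.0), 20000.0, np.zeros((1, 2)))
        assert extract_lfp(raw).data == pytest.approx(7.0)

    def test_low_native_rate_rejected(self):
        raw = LFPSet(np.zeros((1, 1000)), 1000.0, np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            extract_lfp(raw)


class TestBandFilter:
    def test_theta_sinusoid_envelope(self):
        t = np.arange(20000) / 1000.0
        band = band_filter(_lfp(20 * np.cos(2 * np.pi * 6 * t)), "theta")
        mid = band.envelope[0, 2000:-2000]
        assert np.allclose(mid, 20.0, rtol=0.02)

    def test_phase_zero_at_signal_maxima(self):
        t = np.arange(20000) / 1000.0
        x = 20 * np.cos(2 * np.pi * 6 * t)
        band = band_filter(_lfp(x), "theta")
        peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        peaks = peaks[(peaks > 2000) & (peaks < 18000)]
        assert np.all(np.abs(band.phase[0, peaks]) < 0.05)

    def test_zero_group_delay_in_band(self):
        # filtering must not move the peaks of an in-band sinusoid
        t = np.arange(20000) / 1000.0
        x = np.cos(2 * np.pi * 6 * t)
        band = band_filter(_lfp(x), "theta")
        raw_peaks = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        y = band.lfp.data[0]
        filt_peaks = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1
        raw_peaks = raw_peaks[(raw_peaks > 2000) & (raw_peaks < 18000)]
        for p in raw_peaks:
            assert np.min(np.abs(filt_peaks - p)) <= 1

    def test_white_noise_band_power_small(self, rng):
        x = rng.normal(0, 10, 30000)
        band = band_filter(_lfp(x), "theta")
        assert np.sqrt(np.mean(band.lfp.data ** 2)) < 0.25 * x.std()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            band_filter(_lfp(np.zeros(5000), fs=100.0), BANDS["gamma"])


def _theta_band(n_el=3, offsets=(0.0, np.pi / 2, 0.0), amp=20.0, seed=0,
                duration=30.0, noise=0.0):
    fs = 1000.0
    t = np.arange(int(duration * fs)) / fs
    rng = np.random.default_rng(seed)
    rows = [amp * np.cos(2 * np.pi * 6 * t - off) + noise * rng.standard_normal(t.size)
            for off in offsets[:n_el]]
    return band_filter(_lfp(np.vstack(rows)), "theta")


class TestThetaCorrelationMap:
    def test_identical_channels(self):
        band = _theta_band(offsets=(0.3, 0.3, 0.3))
        out = theta_correlation_map(band)
        assert np.allclose(out.correlation, 1.0, atol=1e-6)
        assert np.allclose(out.lag_ms, 0.0, atol=1e-9)

    def test_quarter_period_lag(self):
        band = _theta_band(n_el=2, offsets=(0.0, np.pi / 2))
        out = theta_correlation_map(band)
        lag = abs(out.lag_ms[1 - out.seed_electrode])
        assert lag == pytest.approx(1000.0 / 6 / 4, abs=1.5)

    def test_noise_channels_uncorrelated(self, rng):
        fs = 1000.0
        data = rng.normal(0, 20, (3, 30000))
        band = band_filter(_lfp(data), "theta")
        out = theta_correlation_map(band, amplitude_floor_uv=0.0)
        others = [e for e in range(3) if e != out.seed_electrode]
        # max-over-lags inflates the null, but stays well below 1
        assert all(out.correlation[e] < 0.5 for e in others)

    def test_subthreshold_electrode_excluded(self):
        band = _theta_band(n_el=3, offsets=(0.0, 0.1, 0.0),
                           amp=20.0)
        band.envelope[2] = 1.0  # force below the 10 uV floor
        out = theta_correlation_map(band)
        assert out.excluded[2]


class TestSignalAverage:
    def test_phase_consistent_amplitude_preserved(self):
        band = _theta_band(offsets=(0.0, 0.0, np.pi / 3))
        out = signal_average_theta(band, anchors="seed_peaks", seed_electrode=0)
        assert out["amplitude"][0] == pytest.approx(20.0, rel=0.05)

    def test_random_anchors_average_out(self, rng):
        band = _theta_band(offsets=(0.0,), n_el=1, duration=120.0)
        anchors = np.sort(rng.uniform(5, 115, 300))
        out = signal_average_theta(band, anchors=anchors, seed_electrode=0)
        assert out["amplitude"][0] < 4.0  # destructive interference

    def test_fixed_offset_recovered(self):
        band = _theta_band(n_el=2, offsets=(0.0, np.pi / 3))
        out = signal_average_theta(band, anchors="seed_peaks", seed_electrode=0)
        assert abs(out["phase_offset_rad"][1]) == pytest.approx(np.pi / 3,
                                                                abs=0.05)

    def test_too_few_anchors_rejected(self):
        band = _theta_band()
        with pytest.raises(ValidationError):
            signal_average_theta(band, anchors=np.array([1.0, 2.0]),
                                 seed_electrode=0)


class TestPhaseSpread:
    def _catalog(self, peaks):
        peaks = np.asarray(peaks)
        return BurstCatalog(peaks, peaks - 0.2, peaks + 0.3,
                            np.ones_like(peaks))

    def test_burst_locked_theta_small_spread_at_peak(self):
        # theta phase is identical at every burst peak (peaks on the cycle)
        band = _theta_band(n_el=1, offsets=(0.0,), duration=60.0)
        peaks = np.arange(5.0, 55.0, 3.0)  # 3 s = 18 cycles: same phase
        traces = phase_spread(band, self._catalog(peaks))
        k = np.argmin(np.abs(traces[0].offsets_ms))
        assert traces[0].circular_std_rad[k] < 0.1
        assert traces[0].coherent_window_ms is not None

    def test_uniform_phase_large_spread(self, rng):
        band = _theta_band(n_el=1, offsets=(0.0,), duration=120.0)
        peaks = np.sort(rng.uniform(5, 115, 40))  # anchors at random phases
        traces = phase_spread(band, self._catalog(peaks))
        assert np.median(traces[0].circular_std_rad) > 1.0

    def test_rotation_invariance(self):
        band = _theta_band(n_el=2, offsets=(0.0, 1.1), duration=60.0)
        peaks = np.arange(5.0, 55.0, 3.0)
        traces = phase_spread(band, self._catalog(peaks))
        assert np.allclose(traces[0].circular_std_rad,
                           traces[1].circular_std_rad, atol=0.05)

    def test_needs_five_bursts(self):
        band = _theta_band(n_el=1, offsets=(0.0,))
        with pytest.raises(ValidationError):
            phase_spread(band, self._catalog([5.0, 8.0]))


class TestEnvelopeStats:
    def test_constant_envelope_never_exceeds(self):
        band = _theta_band(n_el=1, offsets=(0.0,))
        cat = BurstCatalog(np.array([10.0]), np.array([9.0]),
                           np.array([11.0]), np.ones(1))
        out = envelope_threshold_stats(band, cat, k_values=(1.5,))
        assert out["k"][1.5]["fraction_overall"][0] == pytest.approx(0.0,
                                                                     abs=0.01)

    def test_burst_gated_envelope_split(self):
        # sparse strong bursts keep the envelope rms low enough that every
        # k-threshold separates burst from non-burst epochs
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        gate = np.sin(2 * np.pi * t / 10) > 0.866
        x = 10 * (1.0 + 4.0 * gate) * np.cos(2 * np.pi * 6 * t)
        band = band_filter(_lfp(x), "theta")
        on = np.flatnonzero(np.diff(gate.astype(int)) == 1) / fs
        cat = BurstCatalog(on + 0.5, on, on + 1.0, np.ones_like(on))
        out = envelope_threshold_stats(band, cat, k_values=(1.0, 1.5, 2.0))
        for k in (1.0, 1.5, 2.0):
            d = out["k"][k]
            assert np.nanmean(d["fraction_burst"]) > np.nanmean(
                d["fraction_nonburst"])

    def test_reference_rms_used(self):
        band = _theta_band(n_el=1, offsets=(0.0,))
        cat = BurstCatalog(np.array([10.0]), np.array([9.0]),
                           np.array([11.0]), np.ones(1))
        ref = np.full((1, band.lfp.n_samples), 1.0)  # tiny reference floor
        out = envelope_threshold_stats(band, cat, k_values=(2.0,),
                                       reference_env=ref)
        assert out["k"][2.0]["fraction_overall"][0] > 0.9


class TestPSD:
    def test_sinusoid_power_parseval(self):
        t = np.arange(60000) / 1000.0
        out = compute_psd(_lfp(np.sin(2 * np.pi * 6 * t)), segment_s=2.0)
        f, p = out["freq_hz"], out["psd"][0]
        assert f[np.argmax(p)] == pytest.approx(6.0, abs=0.5)
        assert np.trapezoid(p, f) == pytest.approx(0.5, rel=0.05)

    def test_white_noise_flat(self, rng):
        x = rng.normal(0, 1, 120000)
        out = compute_psd(_lfp(x), segment_s=0.5)
        f, p = out["freq_hz"], out["psd"][0]
        sel = (f > 10) & (f < 400)
        assert p[sel].max() / p[sel].min() < 3.0

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            compute_psd(_lfp(np.zeros(300)), segment_s=0.5)
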