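"""LFP extraction, band filtering and theta-oscillation mapping.

The LFP is the low-pass (<500 Hz) component of the raw extracellular
voltage, downsampled to 1 kHz.  Oscillatory sub-bands (delta 0.5-4, theta
4-8, alpha 8-13, beta 13-30, gamma 30-50 Hz) come from a zero-phase FIR
band-pass; amplitude envelope and instantaneous phase come from the
analytic signal, with phase 0 at the oscillation maximum.

Mapping stages: pairwise normalized cross-correlation / lag maps of theta
against a seed electrode; event-triggered signal averages anchored on seed
theta peaks or population-burst peaks; circular phase spread around burst
peaks; envelope threshold statistics inside vs outside bursts; Welch PSDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from .bursts import BurstCatalog
from .circular import circular_std
from .io import LFPSet, ValidationError

__all__ = [
    "BandDefinition", "BANDS", "FilteredBand", "ThetaMap", "PhaseSpreadTrace",
    "extract_lfp", "band_filter", "theta_correlation_map",
    "signal_average_theta", "phase_spread", "envelope_threshold_stats",
    "compute_psd",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValidationError("need 0 < low < high")


BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 50.0),
}


@dataclass
class FilteredBand:
    """Band-passed LFP with its analytic envelope and phase."""

    lfp: LFPSet
    envelope: np.ndarray    # microvolts, electrodes x samples
    phase: np.ndarray       # radians in (-pi, pi], 0 at oscillation peak
    band: BandDefinition

    @property
    def fs(self) -> float:
        return self.lfp.fs


@dataclass
class ThetaMap:
    seed_electrode: int
    correlation: np.ndarray      # per electrode vs seed
    lag_ms: np.ndarray
    phase_offset_rad: np.ndarray
    excluded: np.ndarray         # bool, mostly-subthreshold electrodes
    n_above_threshold: int
    corr_matrix: np.ndarray


@dataclass
class PhaseSpreadTrace:
    electrode: int
    offsets_ms: np.ndarray
    circular_std_rad: np.ndarray
    min_spread_time_ms: float        # NaN when never below 1 rad
    coherent_window_ms: tuple[float, float] | None


def extract_lfp(
    raw: LFPSet,
    cutoff_hz: float = 500.0,
    order: int = 4,
    fs_out: float = 1000.0,
) -> LFPSet:
    """Low-pass the raw signal (zero-phase Butterworth) and decimate."""
    if raw.fs < 2000.0:
        raise ValidationError("extract_lfp expects a native rate >= 2 kHz")
    if raw.fs < 2 * cutoff_hz:
        raise ValidationError("sampling rate below 2x the cutoff")
    factor = raw.fs / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValidationError("fs must be an integer multiple of fs_out")
    b, a = sps.butter(order, cutoff_hz, btype="low", fs=raw.fs)
    filt = sps.filtfilt(b, a, raw.data, axis=1)
    out = filt[:, :: int(round(factor))]
    return LFPSet(out, fs_out, raw.electrode_positions, band="lfp", t0=raw.t0)


def band_filter(lfp: LFPSet, band: BandDefinition | str) -> FilteredBand:
    """Zero-phase FIR band-pass plus analytic envelope and phase.

    Windowed-sinc design (Hamming), numtaps ~ 3 x fs / low_cutoff, applied
    forward-backward so in-band components keep zero group delay.
    """
    if isinstance(band, str):
        band = BANDS[band]
    if lfp.fs < 4 * band.high_hz:
        raise ValidationError("sampling rate must be >= 4x the band's upper edge")
    numtaps = int(3 * lfp.fs / band.low_hz)
    numtaps += 1 - numtaps % 2  # odd
    numtaps = min(numtaps, max(3, 2 * (lfp.n_samples // 3) - 1))
    taps = sps.firwin(numtaps, [band.low_hz, band.high_hz],
                      pass_zero=False, window="hamming", fs=lfp.fs)
    padlen = min(3 * numtaps, lfp.n_samples - 1)
    filt = sps.filtfilt(taps, [1.0], lfp.data, axis=1, padlen=padlen)
    analytic = hilbert(filt, axis=1)
    out = LFPSet(filt, lfp.fs, lfp.electrode_positions, band=band.name, t0=lfp.t0)
    return FilteredBand(out, np.abs(analytic), np.angle(analytic), band)


# ---------------------------------------------------------------------------
# Theta correlation / lag maps
# ---------------------------------------------------------------------------

def _masked_xcorr(x, y, mx, my, max_lag: int) -> tuple[float, int]:
    """Max Pearson-style cross-correlation and its lag on masked signals.

    Signals are z-scored on their valid samples and zeroed elsewhere; each
    lag is normalized by the number of jointly valid samples.
    """
    n = x.size
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fx = np.fft.rfft(x, nfft)
    fy = np.fft.rfft(y, nfft)
    fmx = np.fft.rfft(mx.astype(np.float64), nfft)
    fmy = np.fft.rfft(my.astype(np.float64), nfft)
    cc = np.fft.irfft(fx * np.conj(fy), nfft)
    cm = np.fft.irfft(fmx * np.conj(fmy), nfft)
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.size)
    for i, lag in enumerate(lags):
        ov = cm[lag] if lag >= 0 else cm[nfft + lag]
        cv = cc[lag] if lag >= 0 else cc[nfft + lag]
        vals[i] = cv / ov if ov > n * 0.01 else -np.inf
    # periodic signals tie at full-period shifts (up to O(1/N) edge bias);
    # take the smallest |lag| among near-maximal values
    vmax = float(vals.max())
    near = np.flatnonzero(vals >= vmax - 2e-3)
    k = near[int(np.argmin(np.abs(lags[near])))]
    return float(min(vals[k], 1.0)), int(lags[k])


def theta_correlation_map(
    band: FilteredBand,
    amplitude_floor_uv: float = 10.0,
    corr_threshold: float = 0.2,
    burst_windows: np.ndarray | None = None,
    mask_drop_fraction: float = 0.9,
) -> ThetaMap:
    """Pairwise theta cross-correlation map against a seed electrode.

    Samples whose envelope is below ``amplitude_floor_uv`` are masked
    (electrodes > 90% masked are excluded); correlation is the maximum of
    the normalized cross-correlation over +-2 oscillation periods and the
    lag map is taken at that maximum.  The seed is the electrode with the
    largest summed correlation.  With ``burst_windows`` the analysis is
    restricted to burst epochs.
    """
    lfp = band.lfp
    n_el = lfp.n_electrodes
    if n_el < 2:
        raise ValidationError("need >= 2 electrodes")
    mask = band.envelope >= amplitude_floor_uv
    if burst_windows is not None and len(burst_windows):
        in_burst = np.zeros(lfp.n_samples, dtype=bool)
        for start, stop in burst_windows:
            lo = max(0, int(np.floor((start - lfp.t0) * lfp.fs)))
            hi = min(lfp.n_samples, int(np.ceil((stop - lfp.t0) * lfp.fs)))
            in_burst[lo:hi] = True
        mask = mask & in_burst[None, :]
    excluded = mask.mean(axis=1) < (1.0 - mask_drop_fraction)

    center = 0.5 * (band.band.low_hz + band.band.high_hz)
    max_lag = int(round(2.0 / center * lfp.fs))
    z = np.zeros_like(lfp.data)
    for ch in range(n_el):
        v = lfp.data[ch][mask[ch]]
        if v.size > 1 and v.std() > 0:
            z[ch][mask[ch]] = (lfp.data[ch][mask[ch]] - v.mean()) / v.std()

    corr = np.eye(n_el)
    lag = np.zeros((n_el, n_el))
    for i in range(n_el):
        if excluded[i]:
            continue
        for j in range(i + 1, n_el):
            if excluded[j]:
                continue
            c, l = _masked_xcorr(z[i], z[j], mask[i], mask[j], max_lag)
            corr[i, j] = corr[j, i] = c
            lag[i, j] = l / lfp.fs * 1000.0
            lag[j, i] = -lag[i, j]
    corr[excluded, :] = 0.0
    corr[:, excluded] = 0.0

    summed = corr.sum(axis=1)
    summed[excluded] = -np.inf
    seed = int(np.argmax(summed))
    corr_seed = corr[seed].copy()
    corr_seed[seed] = 1.0
    lag_seed = lag[seed].copy()
    phase_offset = 2 * np.pi * center * lag_seed / 1000.0
    n_above = int(np.sum(corr_seed[~excluded] >= corr_threshold)) - 1  # minus seed
    return ThetaMap(seed, corr_seed, lag_seed, phase_offset, excluded,
                    max(n_above, 0), corr)


# ---------------------------------------------------------------------------
# Event-triggered averages
# ---------------------------------------------------------------------------

def _spatial_average(lfp: LFPSet, radius_um: float = 70.0) -> np.ndarray:
    """Average each electrode with its neighbours within a square window."""
    pos = lfp.electrode_positions
    out = np.empty_like(lfp.data)
    for i in range(lfp.n_electrodes):
        near = (np.abs(pos[:, 0] - pos[i, 0]) <= radius_um) & \
               (np.abs(pos[:, 1] - pos[i, 1]) <= radius_um)
        out[i] = lfp.data[near].mean(axis=0)
    return out


def signal_average_theta(
    band: FilteredBand,
    anchors: str | np.ndarray = "seed_peaks",
    seed_electrode: int | None = None,
    catalog: BurstCatalog | None = None,
    window_ms: float = 500.0,
    peak_min_uv: float = 10.0,
    peak_min_dist_ms: float = 100.0,
    spatial_average: bool = False,
) -> dict:
    """Event-triggered theta averages per electrode.

    Anchors are either peaks of the seed electrode's theta trace
    (``"seed_peaks"``: minimum height 10 uV, minimum distance 100 ms), the
    peak times of a burst catalog (``"burst_peaks"``), or an explicit array
    of anchor times (s).  The envelope amplitude of the average quantifies
    phase consistency (phase-jittered oscillations average toward zero);
    the per-electrode phase offset is read at the anchor sample relative to
    the reference electrode.
    """
    lfp = band.lfp
    data = _spatial_average(lfp, 70.0) if spatial_average else lfp.data
    if isinstance(anchors, str):
        if anchors == "seed_peaks":
            if seed_electrode is None:
                raise ValidationError("seed_peaks anchors need seed_electrode")
            idx, _ = sps.find_peaks(
                data[seed_electrode], height=peak_min_uv,
                distance=max(1, int(round(peak_min_dist_ms / 1000.0 * lfp.fs))))
            anchor_t = lfp.t0 + idx / lfp.fs
        elif anchors == "burst_peaks":
            if catalog is None:
                raise ValidationError("burst_peaks anchors need a catalog")
            anchor_t = catalog.peak_times
        else:
            raise ValidationError(f"unknown anchors {anchors!r}")
    else:
        anchor_t = np.asarray(anchors, dtype=np.float64)
    half = int(round(window_ms / 2.0 / 1000.0 * lfp.fs))
    centers = np.round((anchor_t - lfp.t0) * lfp.fs).astype(np.int64)
    centers = centers[(centers - half >= 0) & (centers + half < lfp.n_samples)]
    if centers.size < 5:
        raise ValidationError("need >= 5 usable anchor events")
    win = np.arange(-half, half + 1)
    avg = np.zeros((lfp.n_electrodes, win.size))
    for c in centers:
        avg += data[:, c + win]
    avg /= centers.size
    analytic = hilbert(avg, axis=1)
    env = np.abs(analytic)
    phase_at_anchor = np.angle(analytic[:, half])
    ref = seed_electrode if seed_electrode is not None else 0
    return {
        "offsets_ms": win / lfp.fs * 1000.0,
        "average": avg,
        "envelope": env,
        "amplitude": env.max(axis=1),
        "phase_offset_rad": np.angle(
            np.exp(1j * (phase_at_anchor - phase_at_anchor[ref]))),
        "n_events": int(centers.size),
        "anchor_times": lfp.t0 + centers / lfp.fs,
    }


def phase_spread(
    band: FilteredBand,
    catalog: BurstCatalog,
    window_ms: tuple[float, float] = (-250.0, 500.0),
) -> list[PhaseSpreadTrace]:
    """Circular SD of theta phase across bursts, vs time from burst peak.

    For each electrode and each offset in the window, the circular standard
    deviation sqrt(-2 ln R) of the phases observed across burst peaks.  The
    minimum-spread time is reported for electrodes whose spread falls below
    1 rad; the coherent window is the contiguous run below 1 rad containing
    that minimum.
    """
    if catalog.n_bursts < 5:
        raise ValidationError("phase spread needs >= 5 bursts")
    lfp = band.lfp
    offs = np.arange(window_ms[0], window_ms[1] + 0.5, 1000.0 / lfp.fs)
    off_idx = np.round(offs / 1000.0 * lfp.fs).astype(np.int64)
    centers = np.round((catalog.peak_times - lfp.t0) * lfp.fs).astype(np.int64)
    ok = (centers + off_idx[0] >= 0) & (centers + off_idx[-1] < lfp.n_samples)
    centers = centers[ok]
    if centers.size < 5:
        raise ValidationError("fewer than 5 bursts fit in the recording")
    traces = []
    for ch in range(lfp.n_electrodes):
        ph = band.phase[ch][centers[:, None] + off_idx[None, :]]
        spread = circular_std(ph, axis=0)
        below = spread < 1.0
        if np.any(below):
            k = int(np.argmin(spread))
            lo = k
            while lo > 0 and below[lo - 1]:
                lo -= 1
            hi = k
            while hi < below.size - 1 and below[hi + 1]:
                hi += 1
            trace = PhaseSpreadTrace(ch, offs, spread, float(offs[k]),
                                     (float(offs[lo]), float(offs[hi])))
        else:
            trace = PhaseSpreadTrace(ch, offs, spread, np.nan, None)
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# Envelope statistics and PSD
# ---------------------------------------------------------------------------

def envelope_threshold_stats(
    band: FilteredBand,
    catalog: BurstCatalog,
    k_values: tuple[float, ...] = (1.0, 1.5, 2.0),
    reference_env: np.ndarray | None = None,
) -> dict:
    """Fraction of time the band envelope exceeds k x rms, split by bursts.

    The rms per electrode comes from ``reference_env`` when given (e.g. a
    silenced blocker+TTX recording supplies the noise floor) and from the
    electrode's own envelope otherwise.  Also counts electrodes whose
    burst-epoch fraction exceeds the non-burst fraction by at least 10
    percentage-relative points, at each k.
    """
    lfp = band.lfp
    env = band.envelope
    rms_src = reference_env if reference_env is not None else env
    rms = np.sqrt(np.mean(np.asarray(rms_src, dtype=np.float64) ** 2, axis=1))
    in_burst = np.zeros(lfp.n_samples, dtype=bool)
    for start, stop in catalog.windows():
        lo = max(0, int(np.floor((start - lfp.t0) * lfp.fs)))
        hi = min(lfp.n_samples, int(np.ceil((stop - lfp.t0) * lfp.fs)))
        in_burst[lo:hi] = True
    out: dict = {"k": {}, "rms": rms}
    n_in = int(in_burst.sum())
    n_out = int((~in_burst).sum())
    for k in k_values:
        thr = k * rms
        above = env > thr[:, None]
        frac_all = above.mean(axis=1)
        frac_burst = (above[:, in_burst].mean(axis=1) if n_in else
                      np.full(lfp.n_electrodes, np.nan))
        frac_non = (above[:, ~in_burst].mean(axis=1) if n_out else
                    np.full(lfp.n_electrodes, np.nan))
        with np.errstate(invalid="ignore", divide="ignore"):
            increase = (frac_burst - frac_non) / np.where(frac_non == 0, np.nan,
                                                          frac_non)
        out["k"][k] = {
            "fraction_overall": frac_all,
            "fraction_burst": frac_burst,
            "fraction_nonburst": frac_non,
            "n_electrodes_10pct_increase": int(np.nansum(increase >= 0.10)),
        }
    return out


def compute_psd(lfp: LFPSet, segment_s: float = 0.5, overlap: float = 0.25) -> dict:
    """Welch power spectral density per electrode (uV^2/Hz)."""
    nperseg = int(round(segment_s * lfp.fs))
    if lfp.n_samples < 2 * nperseg:
        raise ValidationError("recording shorter than two Welch segments")
    f, pxx = sps.welch(lfp.data, fs=lfp.fs, nperseg=nperseg,
                       noverlap=int(round(overlap * nperseg)), axis=1)
    return {"freq_hz": f, "psd": pxx}
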