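"""Population firing rate, burst detection and burst-to-burst similarity.

The population rate is the 1 ms-binned spike count summed over units with
one of two smoothings: a 5 ms moving average (single-recording rate traces)
or a 20 ms sliding average followed by a 100 ms Gaussian kernel (the
multi-unit population-averaged rate used to anchor bursts).  Bursts are
local maxima above twice the rms of the rate with at least 1 s separation;
their extent is where the rate falls to 10% of the peak.  Burst-pair
similarity is the mean absolute difference of peak-aligned rate vectors,
and the condition contrast is the fractional change of its grand mean over
a grid of peak-relative windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import SpikeTrainSet, ValidationError

__all__ = [
    "PopulationRate", "BurstCatalog", "BurstSimilarity",
    "population_rate", "detect_bursts", "burst_similarity",
    "fractional_change_grid", "spike_count_change",
]

_BIN_S = 0.001
_EDGE_SEARCH_S = 2.0       # burst extent search limited to +-2 s around peak


@dataclass
class PopulationRate:
    t: np.ndarray              # seconds, 1 ms grid
    rate: np.ndarray           # spikes per bin after smoothing
    smoothing_spec: str

    def __post_init__(self) -> None:
        if self.t.shape != self.rate.shape:
            raise ValidationError("t and rate must align")

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.rate ** 2)))


@dataclass
class BurstCatalog:
    peak_times: np.ndarray     # s
    starts: np.ndarray         # s
    stops: np.ndarray          # s
    peak_amplitudes: np.ndarray

    @property
    def n_bursts(self) -> int:
        return int(self.peak_times.size)

    def windows(self) -> np.ndarray:
        return np.column_stack([self.starts, self.stops])


@dataclass
class BurstSimilarity:
    matrix: np.ndarray                 # pairwise mean |rate difference|
    window_ms: tuple[float, float]
    mean_over_pairs: float
    burst_vectors: np.ndarray          # bursts x samples, cached wide window
    vector_offsets_ms: np.ndarray      # time axis of burst_vectors


def _binned_counts(trains: SpikeTrainSet) -> tuple[np.ndarray, np.ndarray]:
    n_bins = int(np.ceil(trains.duration / _BIN_S))
    edges = np.arange(n_bins + 1) * _BIN_S
    counts = np.zeros(n_bins)
    for uid in trains.unit_ids:
        c, _ = np.histogram(trains.train(int(uid)), bins=edges)
        counts += c
    return 0.5 * (edges[:-1] + edges[1:]), counts


def _gaussian_kernel(sigma_bins: float) -> np.ndarray:
    half = max(1, int(np.ceil(4 * sigma_bins)))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def _moving_average(x: np.ndarray, n_bins: int) -> np.ndarray:
    return np.convolve(x, np.ones(n_bins) / n_bins, mode="same")


def population_rate(trains: SpikeTrainSet, mode: str = "unit_ma5") -> PopulationRate:
    """Summed 1 ms spike counts with the chosen smoothing.

    ``unit_ma5``: 5 ms moving average.  ``mua_smooth``: 20 ms sliding
    average then a 100 ms Gaussian kernel (truncated at +-4 sigma,
    unit area).  Both kernels are unit-area so total spike count is
    conserved.
    """
    if trains.n_units == 0 or trains.total_spikes() == 0:
        raise ValidationError("population_rate needs a nonempty spike set")
    t, counts = _binned_counts(trains)
    if mode == "unit_ma5":
        rate = _moving_average(counts, 5)
    elif mode == "mua_smooth":
        rate = _moving_average(counts, 20)
        rate = np.convolve(rate, _gaussian_kernel(100.0), mode="same")
    else:
        raise ValidationError(f"unknown smoothing mode {mode!r}")
    return PopulationRate(t, rate, mode)


def detect_bursts(
    rate: PopulationRate,
    peak_factor: float = 2.0,
    min_separation_s: float = 1.0,
    edge_attenuation: float = 0.9,
) -> BurstCatalog:
    """Population bursts: rate peaks above ``peak_factor`` x rms.

    Peaks keep a minimum separation; each burst's start/stop is the nearest
    time around the peak where the rate falls to
    ``(1 - edge_attenuation) x peak`` (searched within +-2 s).
    """
    if rate.t.size * _BIN_S < min_separation_s:
        raise ValidationError("rate trace shorter than min_separation_s")
    threshold = peak_factor * rate.rms
    distance = max(1, int(round(min_separation_s / _BIN_S)))
    idx, _ = signal.find_peaks(rate.rate, height=threshold, distance=distance)
    if idx.size == 0:
        z = np.empty(0)
        return BurstCatalog(z, z.copy(), z.copy(), z.copy())
    starts, stops = [], []
    floor_search = int(round(_EDGE_SEARCH_S / _BIN_S))
    for i in idx:
        level = (1.0 - edge_attenuation) * rate.rate[i]
        lo = max(0, i - floor_search)
        below = np.flatnonzero(rate.rate[lo:i] <= level)
        starts.append(rate.t[lo + below[-1]] if below.size else rate.t[lo])
        hi = min(rate.rate.size, i + floor_search)
        below = np.flatnonzero(rate.rate[i:hi] <= level)
        stops.append(rate.t[i + below[0]] if below.size else rate.t[hi - 1])
    return BurstCatalog(rate.t[idx], np.asarray(starts), np.asarray(stops),
                        rate.rate[idx])


def _burst_rate_vectors(
    trains: SpikeTrainSet,
    catalog: BurstCatalog,
    offsets_ms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-aligned population-rate vectors (5 ms MA then 5 ms Gaussian)."""
    t, counts = _binned_counts(trains)
    sm = _moving_average(counts, 5)
    sm = np.convolve(sm, _gaussian_kernel(5.0), mode="same")
    vecs, kept = [], []
    for k, pk in enumerate(catalog.peak_times):
        idx = np.round((pk + offsets_ms / 1000.0) / _BIN_S - 0.5).astype(np.int64)
        if idx[0] < 0 or idx[-1] >= sm.size:
            continue
        vecs.append(sm[idx])
        kept.append(k)
    return np.asarray(vecs), np.asarray(kept, dtype=np.int64)


def burst_similarity(
    trains: SpikeTrainSet,
    catalog: BurstCatalog,
    window_ms: tuple[float, float] = (-100.0, 350.0),
    cache_window_ms: tuple[float, float] = (-250.0, 550.0),
) -> BurstSimilarity:
    """Pairwise burst dissimilarity: mean |rate difference| in the window.

    Vectors over the wider ``cache_window_ms`` are retained so window grids
    can be re-evaluated without re-binning.
    """
    if catalog.n_bursts < 2:
        raise ValidationError("burst similarity needs >= 2 bursts")
    offsets = np.arange(cache_window_ms[0], cache_window_ms[1] + 0.5, 1.0)
    vecs, _ = _burst_rate_vectors(trains, catalog, offsets)
    if vecs.shape[0] < 2:
        raise ValidationError("fewer than 2 bursts fit inside the recording")
    sel = (offsets >= window_ms[0]) & (offsets <= window_ms[1])
    sub = vecs[:, sel]
    n = sub.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(sub[i + 1:] - sub[i])
        mat[i, i + 1:] = diff.mean(axis=1)
    mat = mat + mat.T
    iu = np.triu_indices(n, 1)
    return BurstSimilarity(
        matrix=mat,
        window_ms=tuple(window_ms),
        mean_over_pairs=float(mat[iu].mean()),
        burst_vectors=vecs,
        vector_offsets_ms=offsets,
    )


def _pair_diff_cumsum(vecs: np.ndarray) -> np.ndarray:
    """Prefix sums over time of |v_i - v_j| for all burst pairs."""
    n, t = vecs.shape
    iu, ju = np.triu_indices(n, 1)
    diffs = np.abs(vecs[iu] - vecs[ju])            # pairs x t
    cs = np.zeros((diffs.shape[0], t + 1))
    np.cumsum(diffs, axis=1, out=cs[:, 1:])
    return cs


def _grand_mean_from_cumsum(cs: np.ndarray, offsets: np.ndarray,
                            start_ms: float, stop_ms: float) -> float:
    sel = np.flatnonzero((offsets >= start_ms) & (offsets <= stop_ms))
    a, b = int(sel[0]), int(sel[-1]) + 1
    per_pair = (cs[:, b] - cs[:, a]) / (b - a)
    return float(per_pair.mean())


def fractional_change_grid(
    sim_control: BurstSimilarity,
    sim_drug: BurstSimilarity,
    start_range_ms: tuple[float, float, float] = (-200.0, 0.0, 10.0),
    stop_range_ms: tuple[float, float, float] = (0.0, 500.0, 10.0),
) -> dict:
    """(rho_C - rho_D)/(rho_C + rho_D) over a grid of peak-relative windows.

    rho is each condition's grand-mean burst-pair difference for the given
    window.  Cells with rho_C + rho_D = 0 are set to 0.  Returns the grid,
    its axes and the mean score over all cells.
    """
    starts = np.arange(start_range_ms[0], start_range_ms[1] + 0.5, start_range_ms[2])
    stops = np.arange(stop_range_ms[0], stop_range_ms[1] + 0.5, stop_range_ms[2])
    off_c = sim_control.vector_offsets_ms
    off_d = sim_drug.vector_offsets_ms
    cs_c = _pair_diff_cumsum(sim_control.burst_vectors)
    cs_d = _pair_diff_cumsum(sim_drug.burst_vectors)
    grid = np.zeros((starts.size, stops.size))
    for i, s0 in enumerate(starts):
        for j, s1 in enumerate(stops):
            if s1 <= s0:
                grid[i, j] = 0.0
                continue
            rc = _grand_mean_from_cumsum(cs_c, off_c, s0, s1)
            rd = _grand_mean_from_cumsum(cs_d, off_d, s0, s1)
            grid[i, j] = 0.0 if rc + rd == 0 else (rc - rd) / (rc + rd)
    return {
        "start_ms": starts,
        "stop_ms": stops,
        "grid": grid,
        "mean_score": float(grid.mean()),
    }


def spike_count_change(trains_a: SpikeTrainSet, trains_b: SpikeTrainSet) -> float:
    """Percent change in total spike count, 100 * (a - b) / a."""
    ca, cb = trains_a.total_spikes(), trains_b.total_spikes()
    if ca == 0:
        raise ValidationError("reference condition has no spikes")
    return 100.0 * (ca - cb) / ca
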