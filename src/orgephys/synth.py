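"""Synthetic organoid recordings with known ground truth.

The generator emulates the statistical structure the analysis stages
assume, at the scale of a high-density MEA recording:

* per-unit baseline firing as a gamma renewal process (shape 1 = Poisson)
  whose rate is modulated by a shared population-burst envelope (Gaussian
  bumps at burst times, >= 1 s apart);
* directed functional connections: each source spike is transmitted to its
  target with a fixed probability and a positive synaptic latency
  (Normal mean ~5 ms, truncated above 0.5 ms); a 2 ms absolute refractory
  period is enforced by deletion;
* LFP channels carrying a theta oscillation whose amplitude is modulated by
  the same burst envelope, with per-channel phase offsets, on top of 1/f
  background noise; channels outside the active region carry noise only;
* optional von Mises spike-phase coupling of units to the local theta
  phase, imposed by thinning.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LFPSet, SpikeTrainSet, ValidationError, write_json

__all__ = [
    "ARRAY_X_UM",
    "ARRAY_Y_UM",
    "GroundTruthEdge",
    "NetworkGroundTruth",
    "make_burst_times",
    "simulate_spike_network",
    "simulate_lfp",
    "attach_phase_locked_spikes",
]

# Sensing area of the planar CMOS array (micrometres).
ARRAY_X_UM = 3850.0
ARRAY_Y_UM = 2100.0

_REFRACTORY_S = 0.002
_MIN_LATENCY_S = 0.0005
_MIN_BURST_SEPARATION_S = 1.0


@dataclass(frozen=True)
class GroundTruthEdge:
    """A directed synthetic connection source -> target."""

    source: int
    target: int
    transmission_probability: float
    latency_mean_ms: float
    latency_sd_ms: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.transmission_probability <= 1.0:
            raise ValidationError("transmission_probability must be in [0, 1]")
        if self.latency_mean_ms <= 0:
            raise ValidationError("latency_mean_ms must be > 0")
        if self.latency_sd_ms < 0:
            raise ValidationError("latency_sd_ms must be >= 0")


@dataclass
class NetworkGroundTruth:
    """What the generator actually embedded, for recovery tests."""

    edges: list[GroundTruthEdge]
    unit_kinds: dict[int, str]            # driver | follower | background
    burst_times: np.ndarray               # seconds
    theta_params: dict | None = None      # per-electrode oscillation spec
    phase_coupling: dict[int, tuple[float, float]] = field(default_factory=dict)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.source, e.target) for e in self.edges}

    def to_json(self, path) -> None:
        write_json(
            {
                "edges": [
                    {
                        "source": e.source,
                        "target": e.target,
                        "p": e.transmission_probability,
                        "latency_mean_ms": e.latency_mean_ms,
                        "latency_sd_ms": e.latency_sd_ms,
                    }
                    for e in self.edges
                ],
                "unit_kinds": {str(k): v for k, v in self.unit_kinds.items()},
                "burst_times": self.burst_times,
                "phase_coupling": {
                    str(k): list(v) for k, v in self.phase_coupling.items()
                },
            },
            path,
        )


def make_burst_times(
    duration_s: float,
    burst_rate_per_min: float,
    rng: np.random.Generator,
    min_separation_s: float = _MIN_BURST_SEPARATION_S,
) -> np.ndarray:
    """Draw burst centre times uniformly with a minimum separation."""
    n = int(round(burst_rate_per_min * duration_s / 60.0))
    if n <= 0:
        return np.empty(0)
    lo, hi = 2.0 * min_separation_s, duration_s - 2.0 * min_separation_s
    if hi <= lo:
        return np.empty(0)
    times: list[float] = []
    for _ in range(10000):
        if len(times) >= n:
            break
        t = float(rng.uniform(lo, hi))
        if all(abs(t - s) >= min_separation_s for s in times):
            times.append(t)
    return np.sort(np.asarray(times))


def _burst_envelope(t: np.ndarray, burst_times: np.ndarray, width_s: float) -> np.ndarray:
    """Sum of unit-height Gaussian bumps at the burst times."""
    env = np.zeros_like(t)
    for bt in burst_times:
        lo = np.searchsorted(t, bt - 5 * width_s)
        hi = np.searchsorted(t, bt + 5 * width_s)
        env[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / width_s) ** 2)
    return env


def _renewal_train(
    duration_s: float,
    rate_hz: float,
    shape: float,
    warp_t: np.ndarray,
    warp_cum: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma renewal process in operational (rate-warped) time.

    ``warp_cum`` is the cumulative integrated rate-multiplier on grid
    ``warp_t``; ISIs are drawn with unit mean in warped time and mapped back
    through its inverse, so shape 1 yields an inhomogeneous Poisson process.
    """
    total_warped = warp_cum[-1]
    expected = rate_hz * total_warped
    n_draw = max(16, int(expected + 6 * np.sqrt(max(expected, 1.0)) + 10))
    isis = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_draw)
    warped = np.cumsum(isis)
    while warped.size and warped[-1] < total_warped:
        isis = rng.gamma(shape, 1.0 / (shape * rate_hz), size=n_draw)
        warped = np.append(warped, warped[-1] + np.cumsum(isis))
    warped = warped[warped < total_warped]
    return np.interp(warped, warp_cum, warp_t)


def _apply_refractory(t: np.ndarray, refractory_s: float = _REFRACTORY_S) -> np.ndarray:
    """Enforce an absolute refractory period, keeping earlier spikes."""
    t = np.sort(t)
    keep = np.ones(t.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if ti - last < refractory_s:
            keep[i] = False
        else:
            last = ti
    return t[keep]


def simulate_spike_network(
    n_units: int = 50,
    duration_s: float = 300.0,
    baseline_rate_hz: float = 2.0,
    renewal_shape: float = 1.0,
    burst_rate_per_min: float = 12.0,
    burst_width_ms: float = 50.0,
    burst_gain: float = 5.0,
    edges: list[GroundTruthEdge] | list[tuple] | None = None,
    seed: int = 0,
    allow_chaining: bool = False,
    positions: np.ndarray | None = None,
) -> tuple[SpikeTrainSet, NetworkGroundTruth]:
    """Simulate a network of spiking units with embedded directed edges.

    Returns the spike trains plus the ground truth actually used.  With
    ``renewal_shape=1`` and ``burst_gain=0`` each unit is a homogeneous
    Poisson process; large shapes yield near-periodic firing.  Follower
    spikes do not themselves transmit unless ``allow_chaining`` is set, so
    ground-truth directionality stays unambiguous.
    """
    if n_units < 1 or duration_s <= 0 or baseline_rate_hz <= 0 or renewal_shape <= 0:
        raise ValidationError("n_units, duration_s, rates and shape must be positive")
    rng = np.random.default_rng(seed)
    unit_ids = np.arange(n_units)

    norm_edges: list[GroundTruthEdge] = []
    for e in edges or []:
        if not isinstance(e, GroundTruthEdge):
            e = GroundTruthEdge(*e)
        if e.source not in unit_ids or e.target not in unit_ids:
            raise ValidationError(f"edge references unknown unit: {e}")
        norm_edges.append(e)

    burst_times = make_burst_times(duration_s, burst_rate_per_min, rng)
    grid = np.arange(0.0, duration_s, 0.001)
    env = _burst_envelope(grid, burst_times, burst_width_ms / 1000.0)
    multiplier = 1.0 + burst_gain * env
    warp_cum = np.concatenate([[0.0], np.cumsum(multiplier[:-1] * np.diff(grid))])

    base: dict[int, np.ndarray] = {}
    for uid in unit_ids:
        base[int(uid)] = _renewal_train(
            duration_s, baseline_rate_hz, renewal_shape, grid, warp_cum, rng)

    injected: dict[int, list[np.ndarray]] = {int(u): [] for u in unit_ids}
    for e in norm_edges:
        src = base[e.source]
        if allow_chaining and injected[e.source]:
            src = np.sort(np.concatenate([src] + injected[e.source]))
        fire = rng.random(src.size) < e.transmission_probability
        lat = rng.normal(e.latency_mean_ms, e.latency_sd_ms, size=src.size) / 1000.0
        good = fire & (lat > _MIN_LATENCY_S)
        injected[e.target].append(src[good] + lat[good])

    trains: dict[int, np.ndarray] = {}
    for uid in unit_ids:
        uid = int(uid)
        parts = [base[uid]] + injected[uid]
        t = _apply_refractory(np.concatenate(parts))
        trains[uid] = t[(t >= 0) & (t <= duration_s)]

    if positions is None:
        positions = np.column_stack([
            rng.uniform(0, ARRAY_X_UM, n_units),
            rng.uniform(0, ARRAY_Y_UM, n_units),
        ])
    pos = {int(u): (float(positions[i, 0]), float(positions[i, 1]))
           for i, u in enumerate(unit_ids)}

    kinds = {int(u): "background" for u in unit_ids}
    for e in norm_edges:
        kinds[e.source] = "driver"
    for e in norm_edges:
        if kinds[e.target] != "driver":
            kinds[e.target] = "follower"

    sts = SpikeTrainSet(unit_ids, trains, pos, duration_s,
                        meta={"seed": seed, "generator": "simulate_spike_network"})
    gt = NetworkGroundTruth(norm_edges, kinds, burst_times)
    return sts, gt


def simulate_lfp(
    n_electrodes: int = 16,
    duration_s: float = 60.0,
    fs: float = 1000.0,
    theta_freq_hz: float = 6.0,
    theta_amp_uv: float = 15.0,
    theta_mod_depth_uv: float = 30.0,
    phase_offsets: np.ndarray | None = None,
    burst_times: np.ndarray | None = None,
    burst_width_ms: float = 100.0,
    pink_noise_rms_uv: float = 3.0,
    n_active: int | None = None,
    positions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[LFPSet, dict]:
    """Synthesize LFP channels: burst-modulated theta over 1/f noise.

    Channel ``i < n_active`` carries a theta oscillation of amplitude
    ``theta_amp_uv + theta_mod_depth_uv * envelope(t)`` with its own phase
    offset; the rest are noise-only.  Returns the LFPSet and a dict of the
    per-channel ground-truth parameters.
    """
    if fs < 250:
        raise ValidationError("fs must be >= 250 Hz to carry a theta band")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    if burst_times is None:
        burst_times = make_burst_times(duration_s, 12.0, rng)
    env = _burst_envelope(t, np.asarray(burst_times), burst_width_ms / 1000.0)
    if n_active is None:
        n_active = n_electrodes
    if phase_offsets is None:
        phase_offsets = rng.uniform(-np.pi / 3, np.pi / 3, size=n_electrodes)
    phase_offsets = np.asarray(phase_offsets, dtype=np.float64)

    data = np.zeros((n_electrodes, t.size))
    for ch in range(n_electrodes):
        if pink_noise_rms_uv > 0:
            data[ch] = _pink_noise(t.size, pink_noise_rms_uv, rng)
        if ch < n_active:
            amp = theta_amp_uv + theta_mod_depth_uv * env
            data[ch] += amp * np.cos(2 * np.pi * theta_freq_hz * t - phase_offsets[ch])
        else:
            rng.normal()  # keep the stream aligned regardless of activity
    if positions is None:
        positions = np.column_stack([
            rng.uniform(0, ARRAY_X_UM, n_electrodes),
            rng.uniform(0, ARRAY_Y_UM, n_electrodes),
        ])
    lfp = LFPSet(data, fs, positions, band="lfp")
    truth = {
        "theta_freq_hz": theta_freq_hz,
        "theta_amp_uv": theta_amp_uv,
        "theta_mod_depth_uv": theta_mod_depth_uv,
        "phase_offsets": phase_offsets,
        "burst_times": np.asarray(burst_times),
        "n_active": n_active,
    }
    return lfp, truth


def _pink_noise(n: int, rms_uv: float, rng: np.random.Generator) -> np.ndarray:
    """1/f noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x = x - x.mean()
    s = x.std()
    return x * (rms_uv / s) if s > 0 else x


def attach_phase_locked_spikes(
    trains: SpikeTrainSet,
    theta_phase: np.ndarray,
    fs: float,
    coupling: dict[int, tuple[float, float]],
    unit_channel: dict[int, int] | None = None,
    seed: int = 0,
) -> SpikeTrainSet:
    """Impose von Mises spike-phase coupling by thinning.

    ``coupling`` maps unit_id -> (preferred angle mu [rad], concentration
    kappa); a spike at local theta phase ``theta`` survives with probability
    ``exp(kappa * (cos(theta - mu) - 1))``, so kappa = 0 keeps every spike
    and uncoupled units are untouched.  ``theta_phase`` is a channels x
    samples phase array; ``unit_channel`` assigns units to channels
    (default: channel 0).
    """
    rng = np.random.default_rng(seed)
    theta_phase = np.atleast_2d(np.asarray(theta_phase))
    n_samples = theta_phase.shape[1]
    out: dict[int, np.ndarray] = {}
    for uid in trains.unit_ids:
        uid = int(uid)
        t = trains.spike_times[uid]
        if uid not in coupling or t.size == 0:
            out[uid] = t
            continue
        mu, kappa = coupling[uid]
        if kappa < 0:
            raise ValidationError("kappa must be >= 0")
        ch = (unit_channel or {}).get(uid, 0)
        idx = np.clip(np.round(t * fs).astype(np.int64), 0, n_samples - 1)
        phases = theta_phase[ch, idx]
        accept = np.exp(kappa * (np.cos(phases - mu) - 1.0))
        out[uid] = t[rng.random(t.size) < accept]
    pos = trains.unit_positions
    result = SpikeTrainSet(trains.unit_ids.copy(), out, None if pos is None else dict(pos),
                           trains.duration, meta=dict(trains.meta))
    result.meta["phase_coupling"] = {int(k): tuple(v) for k, v in coupling.items()}
    return result
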