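"""Run configuration: every numeric analysis parameter with its default.

Defaults encode the study's parameter set (STTC window 20 ms, lower-bound
threshold 0.35, sender/receiver imbalance 0.8, burst threshold 2 x rms with
1 s peak separation and 90% edge attenuation, similarity window -100..+350
ms, theta 4-8 Hz with a 10 uV amplitude floor, 0.5 s / 25% Welch windows,
90th-percentile coherence threshold with >200 connections, Rayleigh
p < 0.05, ISI curation at 0.3 / 0.05 Hz / SNR 5).  The dataclass
round-trips through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "SynthConfig"]


@dataclass
class SynthConfig:
    """Synthetic-recording specification used when no data path is given."""

    n_units: int = 30
    duration_s: float = 180.0
    baseline_rate_hz: float = 2.0
    renewal_shape: float = 1.0
    burst_rate_per_min: float = 12.0
    burst_width_ms: float = 50.0
    burst_gain: float = 5.0
    n_edges: int = 6
    edge_probability: float = 0.6
    edge_latency_ms: float = 5.0
    edge_jitter_ms: float = 2.0
    lfp_electrodes: int = 12
    lfp_duration_s: float = 60.0
    lfp_fs: float = 1000.0
    theta_freq_hz: float = 6.0
    theta_amp_uv: float = 15.0
    theta_mod_depth_uv: float = 30.0
    pink_noise_rms_uv: float = 3.0
    phase_lock_kappa: float = 2.0
    phase_lock_mu_deg: float = 60.0
    n_phase_locked_units: int = 10


@dataclass
class AnalysisConfig:
    # unit curation
    isi_violation_max: float = 0.3
    isi_violation_refractory_ms: float = 1.5  # our metric's window; see docs
    rate_min_hz: float = 0.05
    snr_min: float = 5.0
    # ISI statistics
    isi_min_spikes: int = 30
    isi_window_s: float = 180.0
    isi_range_ms: tuple = (8.0, 100.0)
    isi_r2_threshold: float = 0.9
    # population bursts
    burst_peak_factor: float = 2.0
    burst_min_separation_s: float = 1.0
    burst_edge_attenuation: float = 0.9
    similarity_window_ms: tuple = (-100.0, 350.0)
    grid_start_ms: tuple = (-200.0, 0.0, 10.0)
    grid_stop_ms: tuple = (0.0, 500.0, 10.0)
    # connectivity
    sttc_delta_t_ms: float = 20.0
    sttc_threshold: float = 0.35
    latency_window_ms: float = 20.0
    fwhm_max_ms: float = 15.0
    dip_p_threshold: float = 0.1
    min_latencies: int = 10
    class_threshold: float = 0.8
    null_reps: int = 1
    edge_bin_width: float = 0.05
    edge_range: tuple = (0.35, 1.0)
    # LFP
    lfp_cutoff_hz: float = 500.0
    lfp_order: int = 4
    lfp_fs_out: float = 1000.0
    theta_band_hz: tuple = (4.0, 8.0)
    amplitude_floor_uv: float = 10.0
    corr_threshold: float = 0.2
    signal_average_window_ms: float = 500.0
    peak_min_dist_ms: float = 100.0
    phase_spread_window_ms: tuple = (-250.0, 500.0)
    envelope_k_values: tuple = (1.0, 1.5, 2.0)
    psd_segment_s: float = 0.5
    psd_overlap: float = 0.25
    # coherence / phase locking
    coherence_window_s: float = 0.5
    coherence_overlap: float = 0.25
    coherence_percentile: float = 90.0
    coherence_min_connections: int = 200
    rayleigh_alpha: float = 0.05
    phase_lock_n_min: int = 30
    # orchestration
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in d.items()})
        cfg.synth = SynthConfig(**synth) if isinstance(synth, dict) else synth
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
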