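"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` executes the stages in dependency order on a synthetic
recording (or a spike CSV / LFP HDF5 given in the config), writes each
stage's table under the output directory, and records a manifest of every
parameter actually used.  ``compare_conditions`` assembles the
control-vs-treatment contrasts (ISI KS, burst-variability grid, edge-set
changes, gamma-fit fractional difference, edge density, theta correlation
count, imaginary-coherence rank-sum), each delegated to its module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import bursts as bmod
from . import connectivity as cmod
from . import coherence as comod
from . import isi as imod
from . import lfp as lmod
from . import phaselock as pmod
from . import synth
from .config import AnalysisConfig
from .io import SpikeTrainSet, ValidationError, load_spike_trains, save_lfp, \
    save_spike_trains, write_json

__all__ = ["RunResult", "run_pipeline", "compare_conditions"]

_CSV_FLOAT = "%.10g"


@dataclass
class RunResult:
    config: AnalysisConfig
    outdir: Path
    trains: SpikeTrainSet
    ground_truth: synth.NetworkGroundTruth | None
    isi_records: list
    catalog: bmod.BurstCatalog
    similarity: bmod.BurstSimilarity | None
    graph: cmod.ConnectivityGraph
    null: dict
    edge_fits: dict | None
    theta: lmod.FilteredBand
    theta_map: lmod.ThetaMap
    coherence: comod.CoherenceMatrix
    pockets: dict
    phase_lock: dict
    manifest: dict = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _synthesize(cfg: AnalysisConfig, seed: int):
    s = cfg.synth
    rng = np.random.default_rng(seed)
    edges = []
    used = set()
    for _ in range(s.n_edges):
        for _ in range(100):
            a, b = rng.integers(0, s.n_units, 2)
            if a != b and (int(a), int(b)) not in used:
                used.add((int(a), int(b)))
                edges.append(synth.GroundTruthEdge(
                    int(a), int(b), s.edge_probability,
                    s.edge_latency_ms, s.edge_jitter_ms))
                break
    trains, gt = synth.simulate_spike_network(
        n_units=s.n_units, duration_s=s.duration_s,
        baseline_rate_hz=s.baseline_rate_hz, renewal_shape=s.renewal_shape,
        burst_rate_per_min=s.burst_rate_per_min, burst_width_ms=s.burst_width_ms,
        burst_gain=s.burst_gain, edges=edges, seed=int(rng.integers(2 ** 31)))
    lfp_raw, lfp_truth = synth.simulate_lfp(
        n_electrodes=s.lfp_electrodes, duration_s=s.lfp_duration_s,
        fs=s.lfp_fs, theta_freq_hz=s.theta_freq_hz, theta_amp_uv=s.theta_amp_uv,
        theta_mod_depth_uv=s.theta_mod_depth_uv,
        burst_times=gt.burst_times[gt.burst_times < s.lfp_duration_s],
        pink_noise_rms_uv=s.pink_noise_rms_uv,
        seed=int(rng.integers(2 ** 31)))
    gt.theta_params = lfp_truth
    # von Mises coupling for a subset of units
    band = lmod.band_filter(lfp_raw, "theta")
    coupled = [int(u) for u in trains.unit_ids[: s.n_phase_locked_units]]
    coupling = {u: (np.radians(s.phase_lock_mu_deg), s.phase_lock_kappa)
                for u in coupled}
    trains = synth.attach_phase_locked_spikes(
        trains, band.phase, s.lfp_fs, coupling,
        seed=int(rng.integers(2 ** 31)))
    gt.phase_coupling = coupling
    return trains, gt, lfp_raw


def run_pipeline(config: AnalysisConfig | str | Path, outdir, seed: int | None = None,
                 spike_csv=None) -> RunResult:
    """Run every stage and write its outputs under ``outdir``."""
    cfg = (AnalysisConfig.from_yaml(config)
           if isinstance(config, (str, Path)) else config)
    if seed is None:
        seed = cfg.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs ------------------------------------------------------------
    gt = None
    if spike_csv is not None:
        trains = load_spike_trains(spike_csv, format="csv")
        _, lfp_raw = None, None
        raise ValidationError("external recordings need an LFP source; "
                              "use the synthetic path or extend the config")
    trains, gt, lfp_raw = _synthesize(cfg, seed)
    save_spike_trains(trains, outdir / "spikes.csv")
    save_lfp(lfp_raw, outdir / "lfp.h5")
    if gt is not None:
        gt.to_json(outdir / "ground_truth.json")

    # --- single-unit ISI stats ---------------------------------------------
    window = min(cfg.isi_window_s, trains.duration)
    records = imod.compute_isi_stats(
        trains, min_spikes=cfg.isi_min_spikes, window_s=window,
        isi_range_ms=tuple(cfg.isi_range_ms), r2_threshold=cfg.isi_r2_threshold)
    imod.stats_table(records).to_csv(outdir / "isi_stats.csv", index=False,
                                     float_format=_CSV_FLOAT)

    # --- population bursts --------------------------------------------------
    rate = bmod.population_rate(trains, mode="mua_smooth")
    catalog = bmod.detect_bursts(
        rate, peak_factor=cfg.burst_peak_factor,
        min_separation_s=cfg.burst_min_separation_s,
        edge_attenuation=cfg.burst_edge_attenuation)
    pd.DataFrame({
        "peak_time_s": catalog.peak_times, "start_s": catalog.starts,
        "stop_s": catalog.stops, "peak_amplitude": catalog.peak_amplitudes,
    }).to_csv(outdir / "bursts.csv", index=False, float_format=_CSV_FLOAT)
    similarity = None
    if catalog.n_bursts >= 2:
        similarity = bmod.burst_similarity(
            trains, catalog, window_ms=tuple(cfg.similarity_window_ms))
        np.savetxt(outdir / "burst_similarity.csv", similarity.matrix,
                   delimiter=",", fmt=_CSV_FLOAT)

    # --- connectivity -------------------------------------------------------
    graph = cmod.build_graph(
        trains, sttc_threshold=cfg.sttc_threshold,
        delta_t_ms=cfg.sttc_delta_t_ms, fwhm_max_ms=cfg.fwhm_max_ms,
        class_threshold=cfg.class_threshold, min_latencies=cfg.min_latencies,
        dip_p_threshold=cfg.dip_p_threshold)
    graph.edge_table().to_csv(outdir / "edges.csv", index=False,
                              float_format=_CSV_FLOAT)
    graph.nodes.to_csv(outdir / "nodes.csv", index=False, float_format=_CSV_FLOAT)
    null = {}
    if catalog.n_bursts >= 1:
        null = cmod.null_threshold(
            trains, catalog, mode="burst_shuffle", n_reps=cfg.null_reps,
            seed=seed + 1, sttc_threshold=cfg.sttc_threshold,
            delta_t_ms=cfg.sttc_delta_t_ms)
        write_json({k: v for k, v in null.items() if k != "values"},
                   outdir / "null_sttc.json")
    edge_fits = None
    if len(graph.edges) >= 5:
        edge_fits = cmod.fit_edge_distributions(
            graph.strengths(), bin_width=cfg.edge_bin_width,
            strength_range=tuple(cfg.edge_range))
        write_json(
            {
                "best_model": edge_fits["best_model"],
                "models": {
                    name: {"params": r.params, "aic": r.aic,
                           "converged": r.converged}
                    for name, r in edge_fits["fits"].items()
                },
            },
            outdir / "edge_fits.json")
    write_json(
        {
            "n_edges": len(graph.edges),
            "edge_density": graph.edge_density,
            "n_bimodal_excluded": graph.n_bimodal_excluded,
            "largest_component": sorted(graph.largest_component),
            "second_component": sorted(graph.second_component),
            "class_counts": graph.nodes["class"].value_counts().to_dict(),
        },
        outdir / "graph_summary.json")

    # --- LFP / theta --------------------------------------------------------
    theta = lmod.band_filter(lfp_raw, "theta")
    tmap = lmod.theta_correlation_map(
        theta, amplitude_floor_uv=cfg.amplitude_floor_uv,
        corr_threshold=cfg.corr_threshold)
    pd.DataFrame({
        "electrode": np.arange(tmap.correlation.size),
        "x_um": theta.lfp.electrode_positions[:, 0],
        "y_um": theta.lfp.electrode_positions[:, 1],
        "correlation": tmap.correlation,
        "lag_ms": tmap.lag_ms,
        "phase_offset_rad": tmap.phase_offset_rad,
        "excluded": tmap.excluded,
    }).to_csv(outdir / "theta_map.csv", index=False, float_format=_CSV_FLOAT)

    lfp_catalog = bmod.BurstCatalog(
        *(arr[catalog.peak_times < theta.lfp.duration]
          for arr in (catalog.peak_times, catalog.starts, catalog.stops,
                      catalog.peak_amplitudes)))
    spread_rows = []
    if lfp_catalog.n_bursts >= 5:
        traces = lmod.phase_spread(
            theta, lfp_catalog, window_ms=tuple(cfg.phase_spread_window_ms))
        for tr in traces:
            spread_rows.append({
                "electrode": tr.electrode,
                "min_spread_time_ms": tr.min_spread_time_ms,
                "min_spread_rad": float(np.min(tr.circular_std_rad)),
            })
    pd.DataFrame(spread_rows).to_csv(outdir / "phase_spread.csv", index=False,
                                     float_format=_CSV_FLOAT)
    env_stats = {}
    if lfp_catalog.n_bursts >= 1:
        env_stats = lmod.envelope_threshold_stats(
            theta, lfp_catalog, k_values=tuple(cfg.envelope_k_values))
        write_json(
            {str(k): {kk: vv for kk, vv in d.items()}
             for k, d in env_stats["k"].items()},
            outdir / "envelope_stats.json")

    # --- imaginary coherence + phase locking --------------------------------
    cm = comod.imaginary_coherence(
        theta.lfp, window_s=cfg.coherence_window_s,
        overlap=cfg.coherence_overlap, band_hz=tuple(cfg.theta_band_hz))
    np.savetxt(outdir / "imaginary_coherence.csv", cm.values, delimiter=",",
               fmt=_CSV_FLOAT)
    pockets = comod.coherent_pockets(
        cm, percentile=cfg.coherence_percentile,
        min_connections=cfg.coherence_min_connections, seed=seed + 2)
    write_json(
        {
            "k": pockets.get("k"),
            "silhouette": pockets.get("silhouette"),
            "ranksum_p": pockets.get("ranksum_p"),
            "clusters": [sorted(int(s) for s in c["sites"])
                         for c in pockets.get("clusters", [])],
            "warning": pockets.get("warning"),
        },
        outdir / "coherent_pockets.json")

    pl = pmod.phase_locking(trains, theta, n_min=cfg.phase_lock_n_min,
                            alpha=cfg.rayleigh_alpha)
    pmod.phase_lock_table(pl).to_csv(outdir / "phase_lock.csv", index=False,
                                     float_format=_CSV_FLOAT)

    manifest = {
        "config": cfg.to_dict(),
        "seed": seed,
        "stages": [
            "synthesize", "isi", "bursts", "connectivity", "null",
            "edge_fits", "theta_map", "phase_spread", "envelope_stats",
            "imaginary_coherence", "coherent_pockets", "phase_locking",
        ],
        "outputs": {
            p.name: _hash_file(p) for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))

    return RunResult(cfg, outdir, trains, gt, records, catalog, similarity,
                     graph, null, edge_fits, theta, tmap, cm, pockets, pl,
                     manifest)


def compare_conditions(run_a: RunResult, run_b: RunResult) -> dict:
    """Contrast two runs (e.g. control vs drug) sharing unit identities."""
    ids_a = set(int(u) for u in run_a.trains.unit_ids)
    ids_b = set(int(u) for u in run_b.trains.unit_ids)
    if ids_a != ids_b:
        raise ValidationError(
            f"unit mismatch between conditions: {sorted(ids_a ^ ids_b)}")

    report: dict = {}

    cv_a = np.asarray([r.cv for r in run_a.isi_records])
    cv_b = np.asarray([r.cv for r in run_b.isi_records])
    if cv_a.size >= 2 and cv_b.size >= 2:
        ks = sstats.ks_2samp(cv_a, cv_b)
        report["cv_ks"] = {"statistic": float(ks.statistic),
                           "p_value": float(ks.pvalue),
                           "mean_cv_a": float(cv_a.mean()),
                           "mean_cv_b": float(cv_b.mean())}

    isis_a = np.concatenate([
        imod.unit_isis(run_a.trains, int(u), run_a.config.isi_window_s,
                       tuple(run_a.config.isi_range_ms))
        for u in run_a.trains.unit_ids]) if run_a.trains.n_units else np.empty(0)
    isis_b = np.concatenate([
        imod.unit_isis(run_b.trains, int(u), run_b.config.isi_window_s,
                       tuple(run_b.config.isi_range_ms))
        for u in run_b.trains.unit_ids]) if run_b.trains.n_units else np.empty(0)
    if isis_a.size >= 2 and isis_b.size >= 2:
        report["isi_ks"] = imod.compare_isi_distributions(isis_a, isis_b)

    if run_a.similarity is not None and run_b.similarity is not None:
        grid = bmod.fractional_change_grid(
            run_a.similarity, run_b.similarity,
            start_range_ms=tuple(run_a.config.grid_start_ms),
            stop_range_ms=tuple(run_a.config.grid_stop_ms))
        report["burst_grid_mean_score"] = grid["mean_score"]

    report["spike_count_change_pct"] = bmod.spike_count_change(
        run_a.trains, run_b.trains)

    report["edge_sets"] = {
        k: v for k, v in cmod.compare_edge_sets(run_a.graph, run_b.graph).items()
        if k in ("fractions", "ks_statistic", "ks_p_value")
    }
    da, db = run_a.graph.edge_density, run_b.graph.edge_density
    report["edge_density_change_pct"] = (
        100.0 * (db - da) / da if da > 0 else np.nan)

    if run_a.edge_fits and run_b.edge_fits:
        ga = run_a.edge_fits["fits"]["gamma"]
        gb = run_b.edge_fits["fits"]["gamma"]
        if ga.converged and gb.converged:
            curve = cmod.fractional_difference_curve(run_a.edge_fits,
                                                     run_b.edge_fits)
            report["gamma_fractional_difference"] = {
                "bin_centers": curve["bin_centers"].tolist(),
                "curve": curve["curve"].tolist(),
            }

    report["theta_corr_count_change"] = (
        int(run_b.theta_map.n_above_threshold)
        - int(run_a.theta_map.n_above_threshold))

    va = run_a.coherence.regional_strength
    vb = run_b.coherence.regional_strength
    va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
    if va.size and vb.size:
        rs = sstats.ranksums(va, vb)
        report["coherence_ranksum"] = {"statistic": float(rs.statistic),
                                       "p_value": float(rs.pvalue)}
    return report
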