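"""Generate the synthetic control and drug-like recordings used downstream.

Writes a control condition and a "drug" condition (lengthened ISIs via a
lower baseline rate and higher renewal shape, weak edges pruned by lower
transmission) that the later analysis steps contrast.
"""

import argparse
from pathlib import Path

import numpy as np

from orgephys import synth
from orgephys.io import save_lfp, save_spike_trains


def build_edges(rng, n_units, n_edges, p):
    edges, used = [], set()
    while len(edges) < n_edges:
        a, b = rng.integers(0, n_units, 2)
        key = (int(a), int(b))
        if a != b and key not in used and key[::-1] not in used:
            used.add(key)
            edges.append((int(a), int(b), p, 5.0, 2.0))
    return edges


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)

    # one underlying network, measured under two conditions: the drug
    # strengthens transmission on the shared anatomy while slowing and
    # regularizing baseline firing
    base_edges = build_edges(rng, 40, 8, 0.6)
    for name, kw in {
        "control": dict(baseline_rate_hz=2.0, renewal_shape=1.0,
                        edge_p=0.6, burst_gain=5.0),
        "drug": dict(baseline_rate_hz=1.2, renewal_shape=3.0,
                     edge_p=0.8, burst_gain=3.0),
    }.items():
        p = kw.pop("edge_p")
        edges = [(a, b, p, lat, sd) for a, b, _, lat, sd in base_edges]
        trains, gt = synth.simulate_spike_network(
            n_units=40, duration_s=240.0, burst_rate_per_min=12.0,
            burst_width_ms=50.0, edges=edges,
            seed=int(rng.integers(2 ** 31)), **kw)
        lfp, _ = synth.simulate_lfp(
            n_electrodes=12, duration_s=60.0,
            burst_times=gt.burst_times[gt.burst_times < 60.0],
            seed=int(rng.integers(2 ** 31)))
        # couple a third of the units to the local theta phase
        from orgephys.lfp import band_filter
        band = band_filter(lfp, "theta")
        coupling = {int(u): (np.radians(60.0), 2.0)
                    for u in trains.unit_ids[:13]}
        trains = synth.attach_phase_locked_spikes(
            trains, band.phase, lfp.fs, coupling,
            seed=int(rng.integers(2 ** 31)))
        out = args.out / name
        out.mkdir(parents=True, exist_ok=True)
        save_spike_trains(trains, out / "spikes.csv")
        save_lfp(lfp, out / "lfp.h5")
        gt.to_json(out / "ground_truth.json")
        print(f"{name}: {trains.n_units} units, {trains.total_spikes()} spikes, "
              f"{gt.burst_times.size} bursts, {len(gt.edges)} true edges -> {out}")


if __name__ == "__main__":
    main()
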