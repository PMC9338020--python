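"""STTC against a brute-force oracle; latency gating; graphs and nulls."""

import numpy as np
import pytest

from orgephys.bursts import BurstCatalog
from orgephys.connectivity import (
    Edge, build_graph, compare_edge_sets, compute_sttc, fit_edge_distributions,
    fractional_difference_curve, null_threshold, pair_latencies,
    _model_gamma,
)
from orgephys.io import SpikeTrainSet

from conftest import make_trains


# --- independent oracle -----------------------------------------------------

def sttc_oracle(a, b, delta_t_ms, duration_s):
    """Brute-force STTC: explicit interval-union tiling and O(n^2) matching."""
    dt = delta_t_ms / 1000.0

    def tiling(train):
        ivals = sorted((max(0.0, t - dt), min(duration_s, t + dt)) for t in train)
        merged = []
        for lo, hi in ivals:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return sum(hi - lo for lo, hi in merged) / duration_s

    def prop(xs, ys):
        hits = sum(1 for x in xs if any(abs(x - y) <= dt for y in ys))
        return hits / len(xs)

    ta, tb = tiling(a), tiling(b)
    pa, pb = prop(a, b), prop(b, a)
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


class TestSTTC:
    def test_identical_trains_are_one(self):
        a = np.array([0.5, 1.0, 3.0])
        assert compute_sttc(a, a, 20.0, 10.0) == pytest.approx(1.0)

    def test_worked_example_matches_oracle(self):
        a = np.array([1.0, 5.0])
        b = np.array([1.005, 5.015])
        got = compute_sttc(a, b, 20.0, 10.0)
        assert got == pytest.approx(sttc_oracle(a, b, 20.0, 10.0), abs=1e-12)

    def test_oracle_equivalence_on_random_instances(self, rng):
        for _ in range(100):
            dur = float(rng.uniform(5.0, 60.0))
            dt = float(rng.uniform(1.0, 50.0))
            na, nb = rng.integers(1, 51, size=2)
            a = np.sort(rng.uniform(0, dur, na))
            b = np.sort(rng.uniform(0, dur, nb))
            got = compute_sttc(a, b, dt, dur)
            assert got == pytest.approx(sttc_oracle(a, b, dt, dur), abs=1e-12)

    def test_symmetry_and_time_shift_invariance(self, rng):
        a = np.sort(rng.uniform(0, 50, 40))
        b = np.sort(rng.uniform(0, 50, 30))
        assert compute_sttc(a, b, 20, 60) == compute_sttc(b, a, 20, 60)
        # global shift of both trains, window kept inside the recording
        s = compute_sttc(a + 5, b + 5, 20, 70)
        assert s == pytest.approx(compute_sttc(a + 8, b + 8, 20, 76), abs=5e-3)

    def test_independent_poisson_near_zero(self, poisson_pair):
        a, b = poisson_pair
        assert abs(compute_sttc(a, b, 20.0, 300.0)) < 0.05

    def test_empty_train_is_nan(self):
        assert np.isnan(compute_sttc(np.array([]), np.array([1.0]), 20, 10))


class TestPairLatencies:
    def test_exact_shift_recovered(self):
        # zero-jitter shift: mean and FWHM are exact; unimodality is not
        # asserted because degenerate (tied) latencies are atoms to the dip
        a = np.arange(1.0, 50.0, 0.7)
        lat = pair_latencies(a, a + 0.005, min_latencies=4)
        assert lat.mean_latency_ms == pytest.approx(5.0)
        assert lat.fwhm_ms <= 1.0

    def test_realistic_jitter_is_unimodal(self, rng):
        a = np.sort(rng.uniform(5, 295, 600))
        b = np.sort(a + rng.normal(0.005, 0.001, a.size))
        lat = pair_latencies(a, b)
        assert lat.unimodal and lat.connectable

    def test_gaussian_jitter_fwhm(self, rng):
        a = np.sort(rng.uniform(5, 595, 1200))
        b = np.sort(a + rng.normal(0.005, 0.0026, a.size))
        lat = pair_latencies(a, b)
        assert lat.fwhm_ms == pytest.approx(2.355 * 2.6, rel=0.25)
        assert lat.mean_latency_ms == pytest.approx(5.0, abs=0.5)

    def test_two_latency_clusters_flagged_bimodal(self, rng):
        a = np.sort(rng.uniform(5, 595, 800))
        shift = np.where(rng.random(a.size) < 0.5, -0.008, 0.008)
        b = np.sort(a + shift + rng.normal(0, 3e-4, a.size))
        lat = pair_latencies(a, b)
        assert lat.dip_p < 0.1
        assert not lat.unimodal

    def test_too_few_matches_unconnectable(self):
        lat = pair_latencies(np.array([1.0, 2.0]), np.array([100.0, 101.0]))
        assert not lat.connectable


class TestBuildGraph:
    def test_chain_recovers_classes_and_direction(self, rng):
        from orgephys.synth import simulate_spike_network
        trains, gt = simulate_spike_network(
            n_units=3, duration_s=300, baseline_rate_hz=2.0,
            burst_rate_per_min=0, burst_gain=0,
            edges=[(0, 1, 0.9, 5.0, 1.0), (1, 2, 0.9, 5.0, 1.0)], seed=11)
        g = build_graph(trains)
        assert g.edge_set() == {(0, 1), (1, 2)}
        cls = dict(zip(g.nodes["unit_id"], g.nodes["class"]))
        assert cls[0] == "sender" and cls[1] == "broker" and cls[2] == "receiver"
        assert g.largest_component == {0, 1, 2}

    def test_class_boundary_is_strict(self):
        # D_out=9, D_in=1 gives an imbalance of exactly 0.8: broker
        from orgephys.connectivity import _classify
        assert _classify(d_in=0, d_out=10, threshold=0.8) == "sender"
        assert _classify(d_in=10, d_out=0, threshold=0.8) == "receiver"
        assert _classify(d_in=1, d_out=9, threshold=0.8) == "broker"
        assert _classify(d_in=0, d_out=0, threshold=0.8) == "broker"

    def test_class_fractions_sum_to_one(self, rng):
        from orgephys.synth import simulate_spike_network
        trains, _ = simulate_spike_network(
            n_units=12, duration_s=120, edges=[(0, 1, 0.8, 5, 1)], seed=2)
        g = build_graph(trains)
        counts = g.nodes["class"].value_counts()
        assert counts.sum() == g.nodes.shape[0]


class TestNullModels:
    def test_burst_shuffle_preserves_population_counts(self, rng):
        from orgephys.bursts import population_rate, detect_bursts, _binned_counts
        from orgephys.connectivity import _burst_shuffled_trains
        from orgephys.synth import simulate_spike_network
        trains, _ = simulate_spike_network(n_units=10, duration_s=60, seed=5)
        cat = detect_bursts(population_rate(trains, "mua_smooth"))
        assert cat.n_bursts >= 1
        surr = _burst_shuffled_trains(trains, cat, np.random.default_rng(0))
        _, c0 = _binned_counts(trains)
        _, c1 = _binned_counts(surr)
        assert np.array_equal(c0, c1)
        assert surr.total_spikes() == trains.total_spikes()

    def test_edge_swap_preserves_degree_sequence(self):
        import networkx as nx
        # a deterministic graph with 12 directed edges
        edges = [Edge(i, (i + k) % 8, 0.5, 20.0, None)
                 for i in range(8) for k in (1, 3) if i % 2 == 0
                 ] + [Edge(1, 4, 0.5, 20.0, None), Edge(3, 6, 0.5, 20.0, None),
                      Edge(5, 0, 0.5, 20.0, None), Edge(7, 2, 0.5, 20.0, None)]
        import pandas as pd
        from orgephys.connectivity import ConnectivityGraph
        nodes = pd.DataFrame({"unit_id": range(8), "D_in": 0, "D_out": 0})
        g = ConnectivityGraph(edges, nodes, set(), set(), 0.0, 0)
        und = nx.Graph((e.source, e.target) for e in edges)
        out = null_threshold(None, mode="edge_swap", graph=g, n_reps=3, seed=1)
        for rep in out["replicates"]:
            assert rep["n_edges"] == und.number_of_edges()
            assert rep["sender"] + rep["receiver"] + rep["broker"] == 8

    def test_null_requires_bursts(self):
        trains = make_trains({0: [1.0], 1: [2.0]}, 10.0)
        with pytest.raises(Exception):
            null_threshold(trains, BurstCatalog(*(np.empty(0),) * 4),
                           mode="burst_shuffle")


class TestEdgeDistributionFits:
    def test_gamma_counts_recovered(self):
        x = np.arange(0.375, 1.0, 0.05)
        true = {"a": 0.9, "b": 3.0, "c": 0.15}
        y = _model_gamma(x, **true)
        # build a strength sample whose histogram matches the curve
        strengths = np.repeat(x, np.round(y / y.sum() * 4000).astype(int))
        out = fit_edge_distributions(strengths)
        fit = out["fits"]["gamma"]
        assert fit.converged
        assert out["best_model"] == "gamma"
        assert fit.params["b"] == pytest.approx(true["b"], rel=0.05)
        assert fit.params["c"] == pytest.approx(true["c"], rel=0.05)

    def test_identical_conditions_zero_difference(self, rng):
        strengths = rng.gamma(3.0, 0.1, 800) + 0.35
        fa = fit_edge_distributions(strengths)
        fb = fit_edge_distributions(strengths)
        curve = fractional_difference_curve(fa, fb)["curve"]
        assert np.allclose(curve, 0.0, atol=1e-12)

    def test_sparse_histogram_fails_multi_parameter_models(self):
        strengths = np.array([0.37] * 5 + [0.42] * 3 + [0.47] * 2)
        out = fit_edge_distributions(strengths)
        assert not out["fits"]["gamma"].converged
        assert not out["fits"]["exponential"].converged


class TestCompareEdgeSets:
    def _graph(self, edges):
        import pandas as pd
        from orgephys.connectivity import ConnectivityGraph
        es = [Edge(s, t, w, 20.0, None) for s, t, w in edges]
        ids = sorted({s for s, _, _ in edges} | {t for _, t, _ in edges})
        nodes = pd.DataFrame({"unit_id": ids, "D_in": 0, "D_out": 0})
        return ConnectivityGraph(es, nodes, set(), set(), 0.0, 0)

    def test_self_comparison(self):
        g = self._graph([(0, 1, 0.5), (1, 2, 0.6)])
        out = compare_edge_sets(g, g)
        assert out["fractions"]["shared"] == 1.0
        assert out["fractions"]["silenced"] == 0.0

    def test_disjoint_sets(self):
        a = self._graph([(0, 1, 0.5)])
        b = self._graph([(2, 3, 0.5)])
        assert compare_edge_sets(a, b)["fractions"]["shared"] == 0.0

    def test_weak_pruned_strong_induced(self):
        a = self._graph([(0, 1, 0.38), (1, 2, 0.40), (2, 3, 0.7), (3, 4, 0.8)])
        b = self._graph([(2, 3, 0.7), (3, 4, 0.8), (4, 5, 0.9), (5, 6, 0.85)])
        out = compare_edge_sets(a, b)
        assert out["strengths"]["silenced"].mean() < out["strengths"]["induced"].mean()
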