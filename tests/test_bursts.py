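"""Population rate smoothing, burst detection and burst-pair similarity."""

import numpy as np
import pytest

from orgephys.bursts import (
    BurstCatalog, PopulationRate, burst_similarity, detect_bursts,
    fractional_change_grid, population_rate, spike_count_change,
)
from orgephys.io import ValidationError

from conftest import make_trains


class TestPopulationRate:
    def test_single_spike_conserved_and_local(self):
        trains = make_trains({0: [1.0]}, 4.0)
        rate = population_rate(trains, "unit_ma5")
        assert rate.rate.sum() == pytest.approx(1.0, abs=1e-9)
        nz = rate.t[rate.rate > 0]
        assert nz.min() >= 0.997 and nz.max() <= 1.003

    def test_two_units_additive(self):
        one = population_rate(make_trains({0: [1.0]}, 4.0), "unit_ma5")
        two = population_rate(make_trains({0: [1.0], 1: [1.0]}, 4.0), "unit_ma5")
        assert two.rate.max() == pytest.approx(2 * one.rate.max())

    def test_mua_smoothing_conserves_count(self, rng):
        # spikes kept clear of the trace edges so no kernel mass is truncated
        t = {u: np.sort(rng.uniform(1, 118, 200)) for u in range(5)}
        trains = make_trains(t, 120.0)
        rate = population_rate(trains, "mua_smooth")
        assert rate.rate.sum() == pytest.approx(1000.0, rel=1e-9)

    def test_constant_poisson_fluctuates_about_mean(self, rng):
        t = {u: np.cumsum(rng.exponential(0.1, 1500))[:1190] for u in range(4)}
        t = {u: v[v < 120] for u, v in t.items()}
        rate = population_rate(make_trains(t, 120.0), "mua_smooth")
        expected = sum(v.size for v in t.values()) / 120_000  # per 1 ms bin
        assert rate.rate.mean() == pytest.approx(expected, rel=0.05)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            population_rate(make_trains({0: [1.0]}, 2.0), "boxcar")


def _bump_rate(centers, amp, duration=12.0, width=0.05):
    t = np.arange(0, duration, 0.001)
    r = np.zeros_like(t)
    for c in centers:
        r += amp * np.exp(-0.5 * ((t - c) / width) ** 2)
    return PopulationRate(t, r, "synthetic")


class TestDetectBursts:
    def test_constant_rate_no_bursts(self):
        t = np.arange(0, 10, 0.001)
        rate = PopulationRate(t, np.full_like(t, 3.0), "synthetic")
        assert detect_bursts(rate).n_bursts == 0

    def test_three_bumps_located(self):
        rate = _bump_rate([2.0, 5.0, 8.0], amp=10.0)
        cat = detect_bursts(rate)
        assert cat.n_bursts == 3
        assert np.allclose(cat.peak_times, [2.0, 5.0, 8.0], atol=0.001)
        # extent at 10% of peak: |t - c| = width * sqrt(2 ln 10) ~ 107 ms
        assert np.allclose(cat.stops - cat.peak_times, 0.107, atol=0.01)

    def test_close_bumps_merged_by_min_separation(self):
        rate = _bump_rate([5.0, 5.5], amp=10.0)
        assert detect_bursts(rate).n_bursts == 1

    def test_scaling_invariance(self):
        rate = _bump_rate([2.0, 6.0], amp=8.0)
        scaled = PopulationRate(rate.t, 10 * rate.rate, "synthetic")
        a, b = detect_bursts(rate), detect_bursts(scaled)
        assert np.array_equal(a.peak_times, b.peak_times)


class TestBurstSimilarity:
    def _periodic_trains(self, jitter, rng, n_bursts=8):
        times = {}
        centers = 2.0 + 2.0 * np.arange(n_bursts)
        for u in range(6):
            t = []
            for c in centers:
                t.extend(c + rng.normal(0, 0.02, 20) + jitter * rng.normal())
            times[u] = np.unique(np.sort(np.asarray(t)))
        return make_trains(times, float(centers[-1] + 2)), centers

    def test_identical_bursts_zero_offdiagonal(self):
        # spikes placed mid-bin so float dust cannot flip a bin assignment
        trains = make_trains(
            {0: np.unique(np.concatenate([c + np.arange(0.0005, 0.2, 0.01)
                                          for c in (2.0, 5.0, 8.0)]))}, 12.0)
        # peak times on 1 ms bin centers, as detect_bursts reports them
        cat = BurstCatalog(np.array([2.1005, 5.1005, 8.1005]),
                           np.array([2.0, 5.0, 8.0]),
                           np.array([2.2, 5.2, 8.2]), np.ones(3))
        sim = burst_similarity(trains, cat)
        off = sim.matrix[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-9)
        assert sim.mean_over_pairs == pytest.approx(0.0, abs=1e-9)

    def test_pair_count(self, rng):
        trains, centers = self._periodic_trains(0.0, rng, n_bursts=10)
        cat = BurstCatalog(centers, centers - 0.3, centers + 0.5,
                           np.ones_like(centers))
        sim = burst_similarity(trains, cat)
        n = sim.matrix.shape[0]
        assert n * (n - 1) // 2 == 45

    def test_homogeneity_under_rate_scaling(self, rng):
        trains, centers = self._periodic_trains(0.01, rng)
        cat = BurstCatalog(centers, centers - 0.3, centers + 0.5,
                           np.ones_like(centers))
        sim1 = burst_similarity(trains, cat)
        doubled = {u: trains.train(u) for u in range(6)}
        doubled.update({u + 10: trains.train(u) + 1e-4 for u in range(6)})
        sim2 = burst_similarity(make_trains(doubled, trains.duration), cat)
        ratio = sim2.mean_over_pairs / sim1.mean_over_pairs
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_needs_two_bursts(self, rng):
        trains, centers = self._periodic_trains(0.0, rng)
        cat = BurstCatalog(centers[:1], centers[:1] - 0.3, centers[:1] + 0.5,
                           np.ones(1))
        with pytest.raises(ValidationError):
            burst_similarity(trains, cat)


class TestFractionalChangeGrid:
    def _sim(self, jitter, rng, seed_offset=0):
        times = {}
        centers = 2.0 + 2.0 * np.arange(10)
        for u in range(6):
            t = []
            for c in centers:
                n = 25 + int(jitter * rng.integers(0, 30))
                t.extend(c + rng.normal(0, 0.03 + jitter * rng.random() * 0.05, n))
            times[u] = np.unique(np.sort(np.asarray(t)))
        trains = make_trains(times, 24.0)
        cat = BurstCatalog(centers, centers - 0.3, centers + 0.5,
                           np.ones_like(centers))
        return burst_similarity(trains, cat)

    def test_identical_conditions_all_zero(self, rng):
        sim = self._sim(0.2, rng)
        out = fractional_change_grid(sim, sim)
        assert np.allclose(out["grid"], 0.0)
        assert out["mean_score"] == 0.0

    def test_known_ratio_gives_half(self, rng):
        sim_c = self._sim(0.0, rng)
        # rho_C = 3 rho_D exactly: scale the drug condition's vectors
        import copy
        sim_d = copy.deepcopy(sim_c)
        sim_d.burst_vectors = sim_c.burst_vectors / 3.0
        out = fractional_change_grid(sim_c, sim_d)
        inner = out["grid"][:, 5:]  # windows with nonzero width
        assert np.allclose(inner[np.nonzero(inner)], 0.5, atol=1e-9)

    def test_jittered_control_scores_positive(self, rng):
        sim_c = self._sim(1.0, rng)
        sim_d = self._sim(0.05, rng)
        out = fractional_change_grid(sim_c, sim_d)
        assert out["mean_score"] > 0.05


class TestSpikeCountChange:
    def test_complete_silencing(self):
        a = make_trains({0: np.arange(0.1, 10, 0.1)}, 10.0)
        b = make_trains({0: []}, 10.0)
        assert spike_count_change(a, b) == pytest.approx(100.0)

    def test_no_change(self):
        a = make_trains({0: np.arange(0.1, 10, 0.1)}, 10.0)
        assert spike_count_change(a, a) == 0.0

    def test_bernoulli_thinning_matches_keep_rate(self, rng):
        t = np.cumsum(rng.exponential(0.01, 20000))
        a = make_trains({0: t}, float(t[-1] + 1))
        keep = rng.random(t.size) < 0.28
        b = make_trains({0: t[keep]}, a.duration)
        assert spike_count_change(a, b) == pytest.approx(72.0, abs=1.5)

    def test_empty_reference_errors(self):
        a = make_trains({0: []}, 10.0)
        with pytest.raises(ValidationError):
            spike_count_change(a, a)
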