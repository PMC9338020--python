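"""STTC functional connectivity, latency-gated directed graphs and nulls.

Pairwise correlation strength is the spike time tiling coefficient

    STTC = 1/2 [ (P_A - T_B)/(1 - P_A T_B) + (P_B - T_A)/(1 - P_B T_A) ]

where T_X is the fraction of the recording tiled by +-dt windows around
X's spikes and P_X is the fraction of X's spikes falling within +-dt of the
other train.  Pairs become directed edges when their nearest-spike latency
distribution (within +-20 ms) is unimodal (dip test), narrow (FWHM <= 15
ms) and the STTC clears a lower-bound threshold calibrated on a
burst-shuffle surrogate; the edge points from the leading to the lagging
unit.  Nodes are classed sender / receiver / broker by the normalized
imbalance of out- vs in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dip import dip_test
from .io import SpikeTrainSet, ValidationError
from .bursts import BurstCatalog

__all__ = [
    "PairLatency", "Edge", "ConnectivityGraph", "EdgeFitResult",
    "compute_sttc", "sttc_tiling_fraction", "pair_latencies", "build_graph",
    "null_threshold", "fit_edge_distributions", "fractional_difference_curve",
    "compare_edge_sets",
]


# ---------------------------------------------------------------------------
# STTC
# ---------------------------------------------------------------------------

def sttc_tiling_fraction(train: np.ndarray, delta_t_s: float, duration_s: float) -> float:
    """Fraction of [0, duration] within +-delta_t of any spike (interval union)."""
    if train.size == 0:
        return 0.0
    lo = np.clip(train - delta_t_s, 0.0, duration_s)
    hi = np.clip(train + delta_t_s, 0.0, duration_s)
    # trains are sorted so hi is nondecreasing; the union length is each
    # window's extension beyond the previous coverage
    prev_hi = np.concatenate([[lo[0]], hi[:-1]])
    total = float(np.sum(np.maximum(0.0, hi - np.maximum(lo, prev_hi))))
    return total / duration_s


def _prop_within(a: np.ndarray, b: np.ndarray, delta_t_s: float) -> float:
    """Fraction of a's spikes with a spike of b within +-delta_t."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    return float(np.mean(np.minimum(left, right) <= delta_t_s + 1e-15))


def compute_sttc(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    delta_t_ms: float = 20.0,
    duration_s: float | None = None,
) -> float:
    """Spike time tiling coefficient of two trains (NaN if either is empty)."""
    a = np.asarray(spikes_a, dtype=np.float64)
    b = np.asarray(spikes_b, dtype=np.float64)
    if duration_s is None or duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    if delta_t_ms <= 0:
        raise ValidationError("delta_t_ms must be positive")
    if a.size == 0 or b.size == 0:
        return np.nan
    dt = delta_t_ms / 1000.0
    ta = sttc_tiling_fraction(a, dt, duration_s)
    tb = sttc_tiling_fraction(b, dt, duration_s)
    pa = _prop_within(a, b, dt)
    pb = _prop_within(b, a, dt)

    def term(p: float, t: float) -> float:
        denom = 1.0 - p * t
        if denom == 0.0:
            return 1.0  # p = t = 1: train tiles everything, treat as full overlap
        return (p - t) / denom

    return 0.5 * (term(pa, tb) + term(pb, ta))


# ---------------------------------------------------------------------------
# Latency distributions
# ---------------------------------------------------------------------------

@dataclass
class PairLatency:
    unit_a: int
    unit_b: int
    latencies_ms: np.ndarray     # signed, nearest b-spike relative to a-spike
    mean_latency_ms: float
    fwhm_ms: float
    dip_p: float
    unimodal: bool
    connectable: bool


def _fwhm_from_hist(lat_ms: np.ndarray, window_ms: float, bin_ms: float) -> float:
    edges = np.arange(-window_ms - bin_ms / 2, window_ms + bin_ms, bin_ms)
    counts, edges = np.histogram(lat_ms, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0
    # left crossing
    left = centers[0] - bin_ms / 2
    for i in range(peak, 0, -1):
        if counts[i - 1] < half <= counts[i]:
            frac = (half - counts[i - 1]) / (counts[i] - counts[i - 1])
            left = centers[i - 1] + frac * bin_ms
            break
    else:
        if counts[0] >= half:
            left = centers[0] - bin_ms / 2
    right = centers[-1] + bin_ms / 2
    for i in range(peak, counts.size - 1):
        if counts[i] >= half > counts[i + 1]:
            frac = (counts[i] - half) / (counts[i] - counts[i + 1])
            right = centers[i] + frac * bin_ms
            break
    else:
        if counts[-1] >= half:
            right = centers[-1] + bin_ms / 2
    return float(max(right - left, bin_ms * 0.5))


def pair_latencies(
    spikes_a: np.ndarray,
    spikes_b: np.ndarray,
    window_ms: float = 20.0,
    hist_bin_ms: float = 1.0,
    min_latencies: int = 10,
    unit_a: int = -1,
    unit_b: int = -1,
    dip_method: str = "table",
    dip_p_threshold: float = 0.1,
) -> PairLatency:
    """Nearest-spike latency distribution of a pair.

    For each spike of ``a``, the signed latency (ms) to the nearest spike of
    ``b``, kept when within ``+-window_ms``.  FWHM comes from a 1 ms
    histogram with linear interpolation at half the modal height; the dip
    test on the latencies sets the unimodality flag (p >= 0.1).  Pairs with
    fewer than ``min_latencies`` matches are marked unconnectable.
    """
    a = np.asarray(spikes_a, dtype=np.float64)
    b = np.asarray(spikes_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both trains must be nonempty")
    idx = np.searchsorted(b, a)
    cand_left = np.where(idx > 0, b[np.maximum(idx - 1, 0)] - a, -np.inf)
    cand_right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    nearest = np.where(np.abs(cand_left) <= np.abs(cand_right), cand_left, cand_right)
    lat_ms = nearest * 1000.0
    lat_ms = lat_ms[np.abs(lat_ms) <= window_ms]
    if lat_ms.size < max(min_latencies, 4):
        return PairLatency(unit_a, unit_b, lat_ms, np.nan, np.nan, np.nan,
                           False, False)
    mean_lat = float(lat_ms.mean())
    fwhm = _fwhm_from_hist(lat_ms, window_ms, hist_bin_ms)
    d = dip_test(lat_ms, method=dip_method)
    unimodal = bool(d["p_value"] >= dip_p_threshold)
    return PairLatency(unit_a, unit_b, lat_ms, mean_lat, fwhm,
                       float(d["p_value"]), unimodal, True)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

@dataclass
class Edge:
    source: int
    target: int
    sttc: float
    delta_t_ms: float
    latency: PairLatency


@dataclass
class ConnectivityGraph:
    edges: list[Edge]
    nodes: pd.DataFrame               # unit_id, D_in, D_out, class
    largest_component: set
    second_component: set
    edge_density: float
    n_bimodal_excluded: int
    meta: dict = field(default_factory=dict)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.source, e.target) for e in self.edges}

    def strengths(self) -> np.ndarray:
        return np.asarray([e.sttc for e in self.edges])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(int(u) for u in self.nodes["unit_id"])
        for e in self.edges:
            g.add_edge(e.source, e.target, sttc=e.sttc,
                       mean_latency_ms=e.latency.mean_latency_ms)
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "source": e.source, "target": e.target, "sttc": e.sttc,
                "mean_latency_ms": abs(e.latency.mean_latency_ms),
                "fwhm_ms": e.latency.fwhm_ms, "dip_p": e.latency.dip_p,
            }
            for e in self.edges
        ])


def _classify(d_in: int, d_out: int, threshold: float) -> str:
    total = d_in + d_out
    if total == 0:
        return "broker"
    if (d_out - d_in) / total > threshold:
        return "sender"
    if (d_in - d_out) / total > threshold:
        return "receiver"
    return "broker"


def build_graph(
    trains: SpikeTrainSet,
    sttc_threshold: float = 0.35,
    delta_t_ms: float = 20.0,
    fwhm_max_ms: float = 15.0,
    class_threshold: float = 0.8,
    min_latencies: int = 10,
    dip_p_threshold: float = 0.1,
    dip_method: str = "table",
) -> ConnectivityGraph:
    """Directed functional connectivity graph from spike trains.

    An unordered pair becomes an edge when (gates first, threshold second)
    its latency distribution is unimodal with FWHM <= ``fwhm_max_ms`` and
    its STTC >= ``sttc_threshold``; direction follows the sign of the mean
    latency (a -> b when b lags a).  Bimodal pairs are excluded and
    counted.  Node classes use the out/in imbalance with the > 0.8 rule;
    components are taken on the direction-ignored graph.
    """
    if trains.n_units < 2:
        raise ValidationError("graph needs >= 2 units")
    ids = [int(u) for u in trains.unit_ids]
    edges: list[Edge] = []
    n_bimodal = 0
    for i, ua in enumerate(ids):
        a = trains.train(ua)
        if a.size == 0:
            continue
        for ub in ids[i + 1:]:
            b = trains.train(ub)
            if b.size == 0:
                continue
            s = compute_sttc(a, b, delta_t_ms, trains.duration)
            if not np.isfinite(s) or s < sttc_threshold:
                continue
            lat = pair_latencies(a, b, window_ms=delta_t_ms,
                                 min_latencies=min_latencies,
                                 unit_a=ua, unit_b=ub, dip_method=dip_method,
                                 dip_p_threshold=dip_p_threshold)
            if not lat.connectable:
                continue
            if not lat.unimodal:
                n_bimodal += 1
                continue
            if not np.isfinite(lat.fwhm_ms) or lat.fwhm_ms > fwhm_max_ms:
                continue
            if lat.mean_latency_ms == 0.0:
                continue
            if lat.mean_latency_ms > 0:
                edges.append(Edge(ua, ub, s, delta_t_ms, lat))
            else:
                edges.append(Edge(ub, ua, s, delta_t_ms, lat))

    d_in = {u: 0 for u in ids}
    d_out = {u: 0 for u in ids}
    for e in edges:
        d_out[e.source] += 1
        d_in[e.target] += 1
    nodes = pd.DataFrame({
        "unit_id": ids,
        "D_in": [d_in[u] for u in ids],
        "D_out": [d_out[u] for u in ids],
    })
    nodes["class"] = [
        _classify(r.D_in, r.D_out, class_threshold) for r in nodes.itertuples()
    ]
    if trains.unit_positions is not None:
        nodes["x_um"] = [trains.unit_positions[u][0] for u in ids]
        nodes["y_um"] = [trains.unit_positions[u][1] for u in ids]

    und = nx.Graph()
    und.add_nodes_from(ids)
    und.add_edges_from((e.source, e.target) for e in edges)
    comps = sorted(nx.connected_components(und), key=len, reverse=True)
    comps = [c for c in comps if len(c) > 1] or [set()]
    largest = set(comps[0])
    second = set(comps[1]) if len(comps) > 1 else set()
    n_pairs = len(ids) * (len(ids) - 1) / 2
    return ConnectivityGraph(
        edges=edges, nodes=nodes,
        largest_component=largest, second_component=second,
        edge_density=len(edges) / n_pairs if n_pairs else 0.0,
        n_bimodal_excluded=n_bimodal,
        meta={"sttc_threshold": sttc_threshold, "delta_t_ms": delta_t_ms},
    )


# ---------------------------------------------------------------------------
# Null models
# ---------------------------------------------------------------------------

def _burst_shuffled_trains(
    trains: SpikeTrainSet, catalog: BurstCatalog, rng: np.random.Generator
) -> SpikeTrainSet:
    """Permute unit labels of spikes independently within each burst window.

    Spike times never move, so the 1 ms-binned population count vector is
    preserved exactly; spikes outside bursts keep their labels.
    """
    ids = [int(u) for u in trains.unit_ids]
    times = np.concatenate([trains.train(u) for u in ids])
    labels = np.concatenate([
        np.full(trains.n_spikes(u), u, dtype=np.int64) for u in ids
    ])
    order = np.argsort(times, kind="stable")
    times, labels = times[order], labels[order]
    for start, stop in catalog.windows():
        lo, hi = np.searchsorted(times, [start, stop])
        if hi - lo > 1:
            labels[lo:hi] = labels[lo:hi][rng.permutation(hi - lo)]
    new: dict[int, np.ndarray] = {}
    for u in ids:
        t = times[labels == u]
        t = np.unique(t)  # label collisions may duplicate a timestamp per unit
        new[u] = t
    pos = trains.unit_positions
    return SpikeTrainSet(np.asarray(ids), new, None if pos is None else dict(pos),
                         trains.duration, meta={"surrogate": "burst_shuffle"})


def null_threshold(
    trains: SpikeTrainSet,
    catalog: BurstCatalog | None = None,
    mode: str = "burst_shuffle",
    n_reps: int = 1,
    seed: int = 0,
    sttc_threshold: float = 0.35,
    delta_t_ms: float = 20.0,
    graph: ConnectivityGraph | None = None,
) -> dict:
    """Null models for the connectivity analysis.

    ``burst_shuffle``: permutes unit labels within each burst and recomputes
    the all-pairs STTC distribution; reports its quantiles and the fraction
    below the threshold.  ``edge_swap``: degree-preserving double edge swaps
    (10x the edge count) of the undirected topology, with each edge's
    direction then reassigned at random; reports sender/receiver counts per
    replicate.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "burst_shuffle":
        if catalog is None or catalog.n_bursts < 1:
            raise ValidationError("burst_shuffle requires >= 1 burst")
        values = []
        for _ in range(n_reps):
            surr = _burst_shuffled_trains(trains, catalog, rng)
            ids = [int(u) for u in surr.unit_ids]
            for i, ua in enumerate(ids):
                a = surr.train(ua)
                if a.size == 0:
                    continue
                for ub in ids[i + 1:]:
                    b = surr.train(ub)
                    if b.size == 0:
                        continue
                    s = compute_sttc(a, b, delta_t_ms, surr.duration)
                    if np.isfinite(s):
                        values.append(s)
        values = np.asarray(values)
        return {
            "mode": mode,
            "values": values,
            "quantiles": {
                "q90": float(np.quantile(values, 0.90)),
                "q95": float(np.quantile(values, 0.95)),
                "q99": float(np.quantile(values, 0.99)),
            },
            "fraction_below_threshold": float(np.mean(values < sttc_threshold)),
            "threshold": sttc_threshold,
            "seed": seed,
        }
    if mode == "edge_swap":
        if graph is None or not graph.edges:
            raise ValidationError("edge_swap requires a built graph with edges")
        und = nx.Graph()
        und.add_nodes_from(int(u) for u in graph.nodes["unit_id"])
        und.add_edges_from((e.source, e.target) for e in graph.edges)
        cls_thr = 0.8
        counts = []
        for _ in range(n_reps):
            g = und.copy()
            n_e = g.number_of_edges()
            try:
                nx.double_edge_swap(g, nswap=10 * n_e, max_tries=1000 * n_e,
                                    seed=int(rng.integers(2 ** 31)))
            except nx.NetworkXError:
                pass  # sparse graphs can exhaust swap attempts; keep partial
            d_in = {u: 0 for u in g.nodes}
            d_out = {u: 0 for u in g.nodes}
            for u, v in g.edges:
                if rng.random() < 0.5:
                    u, v = v, u
                d_out[u] += 1
                d_in[v] += 1
            cls = [_classify(d_in[u], d_out[u], cls_thr) for u in g.nodes]
            counts.append({
                "sender": cls.count("sender"),
                "receiver": cls.count("receiver"),
                "broker": cls.count("broker"),
                "n_edges": g.number_of_edges(),
            })
        return {"mode": mode, "replicates": counts, "seed": seed}
    raise ValidationError(f"unknown null mode {mode!r}")


# ---------------------------------------------------------------------------
# Edge-strength distribution models
# ---------------------------------------------------------------------------

def _model_power(x, a, b):
    return a * np.power(x, b)


def _model_exp(x, a, c, d):
    return a * np.exp(-c * x) + d


def _model_trunc_power(x, a, b, c):
    return a * np.power(x, b) * np.exp(-c * x)


def _model_gamma(x, a, b, c):
    with np.errstate(invalid="ignore", over="ignore"):
        return (a / (special.gamma(b) * np.power(c, b))) \
            * np.power(x, b - 1.0) * np.exp(-x / c)


_MODELS = {
    "power_law": (_model_power, ("a", "b")),
    "exponential": (_model_exp, ("a", "c", "d")),
    "truncated_power_law": (_model_trunc_power, ("a", "b", "c")),
    "gamma": (_model_gamma, ("a", "b", "c")),
}


@dataclass
class EdgeFitResult:
    model: str
    params: dict
    rss: float
    aic: float
    converged: bool
    bin_edges: np.ndarray
    fractions: np.ndarray


def _p0_for(model: str, x: np.ndarray, y: np.ndarray) -> tuple:
    ymax = max(float(y.max()), 1e-6)
    if model == "power_law":
        return (ymax, -1.0)
    if model == "exponential":
        return (ymax, 5.0, float(y.min()))
    if model == "truncated_power_law":
        return (ymax, 1.0, 5.0)
    xm = float(np.sum(x * y) / max(np.sum(y), 1e-12))
    return (1.0, 2.0, max(xm / 2.0, 1e-3))


def fit_edge_distributions(
    strengths: np.ndarray,
    bin_width: float = 0.05,
    strength_range: tuple[float, float] = (0.35, 1.0),
) -> dict:
    """Least-squares fits of four closed forms to the edge-strength histogram.

    Models: power law ``a x^b``; exponential ``a e^{-c x} + d``; truncated
    power law ``a x^b e^{-c x}``; gamma ``a / (Gamma(b) c^b) x^{b-1}
    e^{-x/c}``.  The histogram (fixed bins over [0.35, 1.0], width 0.05) is
    normalized to fractions of total edges.  Model comparison is by
    AIC = n ln(RSS/n) + 2k; non-converging models are excluded (flagged).
    """
    strengths = np.asarray(strengths, dtype=np.float64)
    edges = np.round(np.arange(strength_range[0], strength_range[1] + bin_width / 2,
                               bin_width), 10)
    counts, edges = np.histogram(strengths, bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no edges inside the fit range")
    y = counts / total
    x = 0.5 * (edges[:-1] + edges[1:])
    n_nonempty = int(np.count_nonzero(counts))
    results: dict[str, EdgeFitResult] = {}
    for name, (fn, pnames) in _MODELS.items():
        k = len(pnames)
        if n_nonempty < k + 1:
            results[name] = EdgeFitResult(name, {}, np.nan, np.nan, False,
                                          edges, y)
            continue
        try:
            popt, _ = optimize.curve_fit(fn, x, y, p0=_p0_for(name, x, y),
                                         maxfev=20000)
            pred = fn(x, *popt)
            if not np.all(np.isfinite(pred)):
                raise RuntimeError("non-finite prediction")
            rss = float(np.sum((y - pred) ** 2))
            aic = x.size * np.log(max(rss, 1e-300) / x.size) + 2 * k
            results[name] = EdgeFitResult(
                name, dict(zip(pnames, map(float, popt))), rss, float(aic),
                True, edges, y)
        except (RuntimeError, ValueError):
            results[name] = EdgeFitResult(name, {}, np.nan, np.nan, False,
                                          edges, y)
    converged = {n: r for n, r in results.items() if r.converged}
    best = min(converged, key=lambda n: converged[n].aic) if converged else None
    return {"fits": results, "best_model": best, "bin_centers": x, "fractions": y}


def fractional_difference_curve(fit_control: dict, fit_drug: dict) -> dict:
    """(f_d - f_c)/(f_d + f_c) across bins from the two gamma fits."""
    x = fit_control["bin_centers"]
    gc = fit_control["fits"]["gamma"]
    gd = fit_drug["fits"]["gamma"]
    if not (gc.converged and gd.converged):
        raise ValidationError("gamma fit did not converge in one condition")
    fc = _model_gamma(x, **gc.params)
    fd = _model_gamma(x, **gd.params)
    denom = fd + fc
    curve = np.where(denom != 0, (fd - fc) / np.where(denom == 0, 1, denom), 0.0)
    return {"bin_centers": x, "curve": curve}


# ---------------------------------------------------------------------------
# Condition contrasts on edge sets
# ---------------------------------------------------------------------------

def compare_edge_sets(graph_a: ConnectivityGraph, graph_b: ConnectivityGraph) -> dict:
    """Shared / silenced / induced edge sets between two conditions.

    Set operations on directed (source, target) pairs; fractions are
    relative to the union.  Also reports each set's strength values and a
    two-sample KS test between the two conditions' full strength
    distributions (the stability analysis reused as a contrast).
    """
    ea, eb = graph_a.edge_set(), graph_b.edge_set()
    union = ea | eb
    shared = ea & eb
    silenced = ea - eb
    induced = eb - ea
    sa = {(e.source, e.target): e.sttc for e in graph_a.edges}
    sb = {(e.source, e.target): e.sttc for e in graph_b.edges}
    n_union = max(len(union), 1)
    out = {
        "shared": sorted(shared),
        "silenced": sorted(silenced),
        "induced": sorted(induced),
        "fractions": {
            "shared": len(shared) / n_union,
            "silenced": len(silenced) / n_union,
            "induced": len(induced) / n_union,
        },
        "strengths": {
            "shared": np.asarray([sa[e] for e in sorted(shared)]),
            "silenced": np.asarray([sa[e] for e in sorted(silenced)]),
            "induced": np.asarray([sb[e] for e in sorted(induced)]),
        },
    }
    stra, strb = graph_a.strengths(), graph_b.strengths()
    if stra.size >= 2 and strb.size >= 2:
        ks = stats.ks_2samp(stra, strb)
        out["ks_statistic"] = float(ks.statistic)
        out["ks_p_value"] = float(ks.pvalue)
    return out
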