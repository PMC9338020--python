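"""Per-unit interspike-interval statistics.

For every qualifying unit: mean, SD and coefficient of variation (CV) of
the ISIs, an exponential fit ``f(x) = a * exp(-lambda * x)`` to the
normalized ISI histogram, and a classification as exponentially distributed
when the fit's R^2 exceeds a threshold.  The CV separates Poisson-like
irregular firing (CV -> 1) from regular, near-periodic firing (CV -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import SpikeTrainSet, ValidationError

__all__ = ["ISIStats", "compute_isi_stats", "fit_exponential_isi",
           "compare_isi_distributions", "unit_isis", "stats_table"]

_MAX_NFEV = 1000
_FIT_TOL = 1e-10


@dataclass
class ISIStats:
    unit_id: int
    mu: float                 # mean ISI, s
    sigma: float              # ISI standard deviation, s
    cv: float                 # sigma / mu
    n_isi: int
    exp_fit: dict             # {a, lam, r2, converged}
    is_exponential: bool


def unit_isis(
    trains: SpikeTrainSet,
    unit_id: int,
    window_s: float | None = 180.0,
    isi_range_ms: tuple[float, float] | None = (8.0, 100.0),
) -> np.ndarray:
    """ISIs of one unit within the analysis window and ISI range filter."""
    t = trains.train(unit_id)
    if window_s is not None:
        t = t[t < window_s]
    isis = np.diff(t)
    if isi_range_ms is not None:
        lo, hi = isi_range_ms[0] / 1000.0, isi_range_ms[1] / 1000.0
        isis = isis[(isis >= lo) & (isis <= hi)]
    return isis


def compute_isi_stats(
    trains: SpikeTrainSet,
    min_spikes: int = 30,
    window_s: float | None = 180.0,
    isi_range_ms: tuple[float, float] | None = (8.0, 100.0),
    r2_threshold: float = 0.9,
) -> list[ISIStats]:
    """ISI statistics for every unit with enough spikes in the window.

    Units with fewer than ``min_spikes`` spikes inside ``window_s`` are
    omitted.  ISIs outside ``isi_range_ms`` are discarded before the mean,
    SD, CV and the exponential fit (pass ``None`` to disable either filter).
    """
    if window_s is not None and window_s > trains.duration + 1e-9:
        raise ValidationError("window_s exceeds recording duration")
    out: list[ISIStats] = []
    for uid in trains.unit_ids:
        uid = int(uid)
        t = trains.train(uid)
        n_in_window = int((t < window_s).sum()) if window_s is not None else t.size
        if n_in_window < min_spikes:
            continue
        isis = unit_isis(trains, uid, window_s, isi_range_ms)
        if isis.size < 2:
            continue
        mu = float(isis.mean())
        sigma = float(isis.std(ddof=0))
        fit = fit_exponential_isi(isis, r2_threshold=r2_threshold)
        out.append(ISIStats(
            unit_id=uid, mu=mu, sigma=sigma,
            cv=sigma / mu if mu > 0 else np.nan,
            n_isi=int(isis.size),
            exp_fit=fit,
            is_exponential=bool(fit["converged"] and fit["r2"] > r2_threshold),
        ))
    return out


def fit_exponential_isi(
    isis: np.ndarray,
    bin_divisor: float = 15.0,
    r2_threshold: float = 0.9,
) -> dict:
    """Fit ``a * exp(-lam * x)`` to the unit-sum-normalized ISI histogram.

    Bin width is the median ISI divided by ``bin_divisor``; counts are
    normalized to sum to one and fitted by nonlinear least squares with
    initial values a = max bin height, lam = 1 / mean ISI.  R^2 is
    1 - RSS/TSS over the binned values.  Degenerate inputs (fewer than two
    nonempty bins) or non-convergence yield ``converged=False``, never an
    exception.
    """
    isis = np.asarray(isis, dtype=np.float64)
    failed = {"a": np.nan, "lam": np.nan, "r2": np.nan, "converged": False}
    if isis.size < 2:
        return failed
    med = float(np.median(isis))
    if med <= 0:
        return failed
    width = med / bin_divisor
    edges = np.arange(0.0, isis.max() + width, width)
    if edges.size < 3:
        edges = np.array([0.0, width, 2 * width])
    counts, edges = np.histogram(isis, bins=edges)
    if np.count_nonzero(counts) < 2:
        return failed
    y = counts / counts.sum()
    x = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(y.max()), 1.0 / float(isis.mean()))
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, a, lam: a * np.exp(-lam * xx),
            x, y, p0=p0, maxfev=_MAX_NFEV, ftol=_FIT_TOL, xtol=_FIT_TOL,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return failed
    a, lam = float(popt[0]), float(popt[1])
    pred = a * np.exp(-lam * x)
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return {"a": a, "lam": lam, "r2": r2, "converged": bool(np.isfinite(r2))}


def compare_isi_distributions(a, b) -> dict:
    """Two-sample two-sided Kolmogorov--Smirnov test between ISI samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("KS comparison needs >= 2 samples per side")
    res = stats.ks_2samp(a, b, alternative="two-sided")
    return {"ks_statistic": float(res.statistic), "p_value": float(res.pvalue)}


def stats_table(records: list[ISIStats]) -> pd.DataFrame:
    """Flatten ISI records to a table keyed by unit_id."""
    return pd.DataFrame([
        {
            "unit_id": r.unit_id, "mu_s": r.mu, "sigma_s": r.sigma, "cv": r.cv,
            "n_isi": r.n_isi, "exp_a": r.exp_fit["a"], "exp_lambda": r.exp_fit["lam"],
            "exp_r2": r.exp_fit["r2"], "is_exponential": r.is_exponential,
        }
        for r in records
    ])
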