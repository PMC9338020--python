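"""Imaginary coherence connectivity and coherent-pocket detection.

Coherency between two channels is S_xy / sqrt(S_xx S_yy) from Welch
cross-spectra (0.5 s windows, 25% overlap); the magnitude of its imaginary
part, averaged over the band's frequency bins, is insensitive to zero-lag
(volume-conducted) coupling: a channel has exactly zero imaginary coherence
with itself or any scaled copy.  Regional strength per electrode is the
Fisher-Z average of its row.  Coherent pockets are found by thresholding
the matrix at a percentile, keeping high-degree hub nodes, and k-means
clustering of connection profiles with silhouette model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps, stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import LFPSet, ValidationError

__all__ = ["CoherenceMatrix", "imaginary_coherence", "coherent_pockets",
           "overlap_fraction"]


@dataclass
class CoherenceMatrix:
    values: np.ndarray           # electrodes x electrodes, |Im coherency|
    regional_strength: np.ndarray
    window_s: float
    overlap: float
    band_hz: tuple[float, float]
    flagged: np.ndarray          # zero-variance channels


def imaginary_coherence(
    lfp: LFPSet,
    window_s: float = 0.5,
    overlap: float = 0.25,
    band_hz: tuple[float, float] = (4.0, 8.0),
) -> CoherenceMatrix:
    """Band-averaged |imaginary coherency| between every electrode pair."""
    nper = int(round(window_s * lfp.fs))
    if lfp.n_samples < 4 * nper:
        raise ValidationError("need >= 4 Welch windows of data")
    step = nper - int(round(overlap * nper))
    starts = np.arange(0, lfp.n_samples - nper + 1, step)
    win = np.hanning(nper)
    n_el = lfp.n_electrodes

    segs = np.stack([lfp.data[:, s:s + nper] for s in starts], axis=1)  # el x w x n
    segs = (segs - segs.mean(axis=2, keepdims=True)) * win
    spec = np.fft.rfft(segs, axis=2)                                    # el x w x f
    freqs = np.fft.rfftfreq(nper, 1.0 / lfp.fs)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    spec = spec[:, :, sel]

    auto = np.mean(np.abs(spec) ** 2, axis=1)                           # el x f
    flagged = auto.sum(axis=1) <= 0
    vals = np.zeros((n_el, n_el))
    for i in range(n_el):
        if flagged[i]:
            continue
        # Im(S_xy) from explicit real products: for proportional channels the
        # two terms are the same rounded product, so zero-lag coupling gives
        # an exact 0 (a complex multiply can break this via FMA)
        im_cross = np.mean(
            spec[i].imag[None, :, :] * spec[i + 1:].real
            - spec[i].real[None, :, :] * spec[i + 1:].imag, axis=1)
        denom = np.sqrt(auto[i][None, :] * auto[i + 1:])
        denom[denom == 0] = np.inf
        ic = (np.abs(im_cross) / denom).mean(axis=1)
        vals[i, i + 1:] = ic
        vals[i + 1:, i] = ic
    vals[flagged, :] = np.nan
    vals[:, flagged] = np.nan
    np.fill_diagonal(vals, 0.0)

    z = np.arctanh(np.clip(vals, 0.0, 1.0 - 1e-12))
    with np.errstate(invalid="ignore"):
        regional = np.tanh(np.nansum(z, axis=1) / np.maximum(
            np.sum(~np.isnan(z), axis=1) - 1, 1))
    regional[flagged] = np.nan
    return CoherenceMatrix(vals, regional, window_s, overlap, tuple(band_hz),
                           flagged)


def coherent_pockets(
    cm: CoherenceMatrix,
    percentile: float = 90.0,
    min_connections: int = 200,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    reference_n_electrodes: int = 1020,
) -> dict:
    """Spatially coherent electrode pockets from the thresholded matrix.

    The matrix is binarized at the given percentile of its off-diagonal
    values; hub nodes exceed ``min_connections`` (auto-scaled with the
    electrode count when none passes).  k-means runs on the connection
    profiles of hubs plus their neighbours; k is chosen by silhouette over
    ``k_range``; cluster-vs-rest coherence is compared by a rank-sum test.
    """
    vals = cm.values
    n_el = vals.shape[0]
    finite = np.isfinite(vals)
    off = vals[finite & ~np.eye(n_el, dtype=bool)]
    if off.size == 0:
        raise ValidationError("empty coherence matrix")
    thr = np.percentile(off, percentile)
    binary = (vals >= thr) & finite
    np.fill_diagonal(binary, False)
    degree = binary.sum(axis=1)

    eff_min = min_connections
    hubs = np.flatnonzero(degree > eff_min)
    scaled = False
    if hubs.size == 0:
        eff_min = max(1, int(round(min_connections * n_el / reference_n_electrodes)))
        hubs = np.flatnonzero(degree > eff_min)
        scaled = True
    if hubs.size == 0:
        return {"clusters": [], "warning": "no hub exceeds min_connections",
                "threshold": float(thr), "degree": degree}

    members = np.flatnonzero(binary[hubs].any(axis=0) | np.isin(
        np.arange(n_el), hubs))
    feats = binary[members].astype(float)
    best = None
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    for k in k_range:
        if k >= members.size:
            continue
        with warnings.catch_warnings():
            # duplicate connection profiles routinely collapse clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(feats, km.labels_)
        if best is None or sil > best["silhouette"]:
            best = {"k": k, "labels": km.labels_, "silhouette": float(sil)}
    if best is None:
        return {"clusters": [], "warning": "no stable clustering",
                "threshold": float(thr), "degree": degree}

    clusters = []
    for k in range(best["k"]):
        sites = members[best["labels"] == k]
        inside = vals[np.ix_(sites, sites)]
        within = float(np.nanmean(inside[~np.eye(sites.size, dtype=bool)])) \
            if sites.size > 1 else 0.0
        clusters.append({"sites": sites, "within_coherence": within})
    clusters.sort(key=lambda c: c["within_coherence"], reverse=True)

    top = clusters[0]["sites"]
    rest = np.setdiff1d(np.arange(n_el), top)
    within_vals = vals[np.ix_(top, top)][~np.eye(top.size, dtype=bool)]
    between_vals = vals[np.ix_(top, rest)].ravel()
    within_vals = within_vals[np.isfinite(within_vals)]
    between_vals = between_vals[np.isfinite(between_vals)]
    if within_vals.size and between_vals.size:
        rs = stats.ranksums(within_vals, between_vals)
        p = float(rs.pvalue)
    else:
        p = np.nan
    return {
        "clusters": clusters,
        "k": best["k"],
        "silhouette": best["silhouette"],
        "ranksum_p": p,
        "threshold": float(thr),
        "min_connections_used": eff_min,
        "min_connections_scaled": scaled,
        "degree": degree,
        "hubs": hubs,
    }


def overlap_fraction(site_set_a, site_set_b) -> dict:
    """Overlap of two electrode-site sets.

    Returns the Jaccard fraction |a & b| / |a | b| and the directional
    variant |a & b| / |a|.
    """
    a, b = set(site_set_a), set(site_set_b)
    if not a and not b:
        raise ValidationError("both site sets are empty")
    inter = len(a & b)
    return {
        "jaccard": inter / len(a | b),
        "fraction_of_a": inter / len(a) if a else np.nan,
    }
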