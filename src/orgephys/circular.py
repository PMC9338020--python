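"""Circular statistics helpers: resultant vector, circular SD, Rayleigh test."""

from __future__ import annotations

import numpy as np

__all__ = ["resultant_length", "circular_mean", "circular_std", "rayleigh_test"]


def resultant_length(phases: np.ndarray, axis=None) -> np.ndarray | float:
    """Mean resultant length R = |mean(exp(i theta))| in [0, 1]."""
    z = np.exp(1j * np.asarray(phases))
    return np.abs(np.mean(z, axis=axis))


def circular_mean(phases: np.ndarray, axis=None) -> np.ndarray | float:
    """Mean direction in (-pi, pi]."""
    z = np.exp(1j * np.asarray(phases))
    return np.angle(np.mean(z, axis=axis))


def circular_std(phases: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular standard deviation sqrt(-2 ln R) in radians."""
    r = resultant_length(phases, axis=axis)
    r = np.clip(r, 1e-12, 1.0)
    return np.sqrt(-2.0 * np.log(r))


def rayleigh_test(phases: np.ndarray) -> dict:
    """Rayleigh test of circular non-uniformity.

    z = n R^2 with Zar's finite-sample correction for the p-value:
    p ~ exp(-z) [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288 n^2)].
    """
    phases = np.asarray(phases, dtype=np.float64)
    n = phases.size
    if n < 1:
        raise ValueError("empty phase sample")
    r = float(resultant_length(phases))
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3 - 9.0 * z ** 4) / (288.0 * n * n)
    )
    return {
        "n": n,
        "R": r,
        "mean_angle": float(circular_mean(phases)),
        "z": float(z),
        "p_value": float(min(max(p, 0.0), 1.0)),
    }
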