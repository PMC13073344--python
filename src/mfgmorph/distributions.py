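"""Number- and volume-weighted particle-size-distribution metrics.

An imaging measurement yields one CE diameter per particle, so the
number-weighted distribution is observed directly: D[1,0] is the
arithmetic mean diameter and Pn10/50/90 are number percentiles. Laser
diffraction reports volume-weighted quantities, so for comparison each
particle is weighted by the volume of the sphere with its CE diameter
(∝ d³): D[4,3] = Σd⁴/Σd³ (De Brouckere mean) and Pv10/50/90 are
percentiles of the cumulative d³-weighted distribution. Treating an
agglomerate's CE diameter as a sphere diameter is a 2-D projection
approximation, inherited from the comparison being made.

Percentile convention (fixed, documented): both Pn and Pv come from one
weighted-quantile rule — sorted diameters with cumulative weight
evaluated at step midpoints, linear interpolation between neighbors, and
clamping to the extreme observed diameters outside the covered range.
Using the same rule for both weightings guarantees Pv-p ≥ Pn-p (the d³
reweighting is monotone-likelihood-ratio, hence stochastically larger).
No histogram binning is involved: metrics are computed on raw diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SizeDistributionSummary",
    "number_metrics",
    "volume_metrics",
    "weighted_percentile",
    "summarize",
]


@dataclass
class SizeDistributionSummary:
    d10_mean: float  # D[1,0], µm
    pn10: float
    pn50: float
    pn90: float
    d43: float  # D[4,3], µm
    pv10: float
    pv50: float
    pv90: float
    n: int


def _validate(diameters) -> np.ndarray:
    d = np.asarray(diameters, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty diameter list")
    if not np.all(d > 0):
        raise ValueError("all diameters must be positive")
    return d


def weighted_percentile(values, weights, p) -> float | np.ndarray:
    """Weighted percentile with midpoint cumulative positions.

    Sorted values v_(1..n) with normalized weights w_i sit at cumulative
    positions F_i = (Σ_{j<i} w_j) + w_i/2; the p/100 quantile is linearly
    interpolated between bracketing positions and clamped to
    [v_(1), v_(n)] outside.
    """
    v = np.asarray(values, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError("values and weights must have matching length")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    w = w / w.sum()
    positions = np.cumsum(w) - 0.5 * w
    return np.interp(np.asarray(p, dtype=float) / 100.0, positions, v)


def number_metrics(diameters) -> tuple[float, float, float, float]:
    """(D[1,0], Pn10, Pn50, Pn90) of a raw CE-diameter list (µm)."""
    d = _validate(diameters)
    pn10, pn50, pn90 = weighted_percentile(d, np.ones_like(d), [10, 50, 90])
    return float(d.mean()), float(pn10), float(pn50), float(pn90)


def volume_metrics(diameters) -> tuple[float, float, float, float]:
    """(D[4,3], Pv10, Pv50, Pv90): sphere-volume (d³) weighted metrics."""
    d = _validate(diameters)
    w = d**3
    d43 = float((d**4).sum() / w.sum())
    pv10, pv50, pv90 = weighted_percentile(d, w, [10, 50, 90])
    return d43, float(pv10), float(pv50), float(pv90)


def summarize(diameters) -> SizeDistributionSummary:
    """Full number + volume summary of one diameter list."""
    d = _validate(diameters)
    d10, pn10, pn50, pn90 = number_metrics(d)
    d43, pv10, pv50, pv90 = volume_metrics(d)
    return SizeDistributionSummary(
        d10_mean=d10, pn10=pn10, pn50=pn50, pn90=pn90,
        d43=d43, pv10=pv10, pv50=pv50, pv90=pv90, n=int(d.size),
    )
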