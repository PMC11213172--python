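"""Hartigan-Hartigan dip statistic and Monte-Carlo dip test.

The dip of a sample is the smallest sup-norm distance between its empirical
distribution function (ECDF) and any unimodal distribution function — any
CDF that is convex up to some mode and concave after it, with an atom
permitted at the mode.  Unimodal samples have dips near the 1/(2n) lower
bound; well-separated two-component mixtures approach the 1/4 supremum.

Computation
-----------
Every data value is scanned as a candidate mode.  For a fixed mode the
problem splits into a convex CDF piece on the left and a concave piece on
the right, fitted to the ECDF step corners:

* the convex piece fits within deviation ``d`` iff the greatest convex
  minorant (GCM) of the lower step corners stays within ``2d`` below the
  upper corners, and symmetrically for the least concave majorant (LCM) on
  the right;
* the two pieces must also meet at the mode (the atom absorbs any jump),
  which couples them: the lowest value the convex piece can reach at the
  mode — forced upward by chords through earlier floor/ceiling constraints —
  must not exceed the highest value the concave piece may start from.

The side conditions give a closed-form lower bound on the dip which is also
attained whenever the junction has slack; otherwise the exact value is
found by bisection on ``d`` with the full per-mode feasibility test.  The
p-value follows Hartigan's recommendation: Monte-Carlo calibration against
uniform samples of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["dip_statistic", "dip_test", "DipResult"]

_EPS = 1e-12


def _cross(ox: float, oy: float, ax: float, ay: float, bx: float, by: float) -> float:
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def _side_deviations(pos: np.ndarray, lower: np.ndarray, upper: np.ndarray):
    """Per-mode one-sided fit deviations.

    ``left[m]`` is the largest shortfall of the GCM of the lower corners of
    positions ``<= m`` below the upper corners strictly left of ``m`` (the
    convex piece fits iff ``left[m] <= 2d``); ``right[m]`` mirrors it.
    """
    k = pos.size
    left = np.zeros(k)
    hx: list[float] = []
    hy: list[float] = []
    for m in range(k):
        px, py = pos[m], lower[m]
        while len(hx) >= 2 and _cross(hx[-2], hy[-2], hx[-1], hy[-1], px, py) <= 0.0:
            hx.pop()
            hy.pop()
        hx.append(px)
        hy.append(py)
        if m > 0:
            gcm = np.interp(pos[:m], hx, hy)
            left[m] = max(0.0, float(np.max(upper[:m] - gcm)))
    right = np.zeros(k)
    hx = []
    hy = []
    for m in range(k - 1, -1, -1):
        px, py = pos[m], upper[m]
        while len(hx) >= 2 and _cross(px, py, hx[-1], hy[-1], hx[-2], hy[-2]) >= 0.0:
            hx.pop()
            hy.pop()
        hx.append(px)
        hy.append(py)
        if m < k - 1:
            lcm = np.interp(pos[m + 1:], hx[::-1], hy[::-1])
            right[m] = max(0.0, float(np.max(lcm - lower[m + 1:])))
    return left, right


def _feasible(d: float, pos, lower, upper, left_dev, right_dev) -> bool:
    """Is some unimodal CDF within sup-distance ``d`` of the ECDF?

    Bands at deviation ``d``: a continuous piece passing a step at position
    ``j`` must lie in ``[upper_j - d, lower_j + d]``.  The junction values are
    bounded through forced chord slopes: a chord from a ceiling at ``i`` up to
    a floor at ``j > i`` forces the convex piece at least that high ever after.
    """
    k = pos.size
    dx = pos[None, :] - pos[:, None]  # dx[i, j] = x_j - x_i
    tri = np.tril(np.ones((k, k), dtype=bool))  # i >= j
    with np.errstate(divide="ignore", invalid="ignore"):
        chord = (upper[None, :] - lower[:, None] - 2.0 * d) / dx
    chord = np.where(tri, -np.inf, chord)
    slope_fwd = np.maximum(chord.max(axis=0), 0.0)   # forced slope at j, left piece
    slope_bwd = np.maximum(chord.max(axis=1), 0.0)   # forced slope at i, right piece

    v = (upper[:, None] - d) + slope_fwd[:, None] * dx       # floor at j pushed to m > j
    v = np.where(tri, -np.inf, v)
    v1_min = np.maximum(lower - d, v.max(axis=0))

    w = (lower[:, None] + d) - slope_bwd[:, None] * (-dx)    # ceiling at j pulled to m < j
    w = np.where(tri.T, np.inf, w)
    v2_max = np.minimum(upper + d, w.min(axis=0))

    ok = (left_dev <= 2.0 * d + _EPS) & (right_dev <= 2.0 * d + _EPS) \
        & (v1_min <= v2_max + _EPS)
    return bool(np.any(ok))


def dip_statistic(values) -> float:
    """Exact dip statistic of a 1-D sample.

    Ties are allowed; a degenerate sample (all values equal) has dip 0
    because a point mass is itself unimodal.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("dip_statistic expects a 1-D sample")
    if x.size < 2:
        return 0.0
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    pos, counts = np.unique(x, return_counts=True)
    if pos.size == 1:
        return 0.0
    n = x.size
    upper = np.cumsum(counts) / n                  # F at each unique position
    lower = np.concatenate(([0.0], upper[:-1]))    # F just left of it

    left_dev, right_dev = _side_deviations(pos, lower, upper)
    d0 = 0.5 * float(np.min(np.maximum(left_dev, right_dev)))
    if _feasible(d0, pos, lower, upper, left_dev, right_dev):
        return d0
    # bracket: expand geometrically above the side-condition bound (the
    # junction correction is small), then bisect; the dip never exceeds 1/4
    lo, hi = d0, min(0.25, max(d0 * 1.05, d0 + 0.5 / n))
    while hi < 0.25 and not _feasible(hi, pos, lower, upper, left_dev, right_dev):
        lo, hi = hi, min(0.25, hi * 1.5)
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if _feasible(mid, pos, lower, upper, left_dev, right_dev):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte-Carlo p-value."""

    statistic: float
    pvalue: float
    n: int
    n_null: int


def dip_test(values, n_null: int = 2000, seed: int | None = None,
             rng: np.random.Generator | None = None) -> DipResult:
    """Dip test of unimodality with a Monte-Carlo calibrated p-value.

    The p-value is the fraction of ``n_null`` uniform samples of the same
    size whose dip is at least as large as the observed one, with the usual
    add-one correction so that p is never exactly zero.

    Parameters
    ----------
    values
        1-D sample; at least 4 distinct values are required.
    n_null
        Number of uniform null samples.
    seed, rng
        Integer seed or an existing generator for the null draws.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("dip test requires at least 4 distinct values")
    if rng is None:
        rng = np.random.default_rng(seed)
    stat = dip_statistic(x)
    n = x.size
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = dip_statistic(rng.uniform(0.0, 1.0, size=n))
    p = (1.0 + float(np.sum(null >= stat))) / (n_null + 1.0)
    return DipResult(statistic=stat, pvalue=p, n=n, n_null=n_null)
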