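"""Grassberger-Procaccia correlation sum and correlation dimension D2.

The correlation sum C(r) is the fraction of delay-vector pairs closer than
r (Euclidean), with temporally close pairs excluded by a Theiler window.
On a self-similar attractor C(r) ~ r^D2 over a scaling range of radii, and
the correlation dimension D2 is the slope of ln C(r) versus ln r there.
The package uses D2 as a proxy for the random-component level of a signal:
additive noise inflates the apparent dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .embedding import EmbeddingParams, TrajectoryMatrix, embed
from .errors import DegenerateSeriesError, ParameterError
from .glle import mean_period
from .series import TimeSeries

__all__ = ["CorrelationSumCurve", "D2Estimate", "correlation_sum", "estimate_d2"]


@dataclass(frozen=True)
class CorrelationSumCurve:
    """C(r) over a radius grid; C is non-decreasing and within [0, 1]."""

    radii: np.ndarray
    c_values: np.ndarray
    n_pairs: int  # admissible pairs after the Theiler exclusion


@dataclass(frozen=True)
class D2Estimate:
    """A fitted correlation dimension with its scaling window."""

    d2: float
    scaling_window: tuple[float, float]  # [r_lo, r_hi]
    r2: float
    low_confidence: bool
    curve: CorrelationSumCurve


def correlation_sum(traj: TrajectoryMatrix, radii, theiler: int = 0) -> CorrelationSumCurve:
    """Correlation sum over a sorted radius grid with a Theiler window.

    C(r) = fraction of row pairs (j, j') with |j - j'| > theiler whose
    Euclidean distance is strictly below r.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or radii.size < 1:
        raise ParameterError("radii must be a non-empty 1-D array")
    if np.any(np.diff(radii) < 0) or np.any(radii <= 0):
        raise ParameterError("radii must be positive and sorted ascending")
    X = traj.rows
    M = len(X)
    if M < 10:
        raise ParameterError("need at least 10 trajectory rows")
    if theiler < 0:
        raise ParameterError("theiler must be >= 0")
    counts = np.zeros(radii.size, dtype=np.int64)
    n_pairs = 0
    chunk = max(16, int(3.2e7 // max(1, M * traj.m)))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        # only pairs j' > j + theiler; each unordered pair counted once
        D = cdist(X[lo:hi], X, "euclidean")
        cols = np.arange(M)[None, :]
        rows = np.arange(lo, hi)[:, None]
        admissible = cols > rows + theiler
        d = D[admissible]
        n_pairs += d.size
        d.sort()  # one sort per chunk makes the per-radius count a bisect
        counts += np.searchsorted(d, radii, side="left")
    if n_pairs == 0:
        raise ParameterError("Theiler window excluded every pair")
    return CorrelationSumCurve(radii=radii, c_values=counts / n_pairs,
                               n_pairs=n_pairs)


def _distance_quantiles(X: np.ndarray, qs, max_points: int = 1500) -> np.ndarray:
    """Pairwise-distance quantiles from a deterministic row subsample."""
    M = len(X)
    if M > max_points:
        idx = (np.arange(max_points) * (M / max_points)).astype(int)
        X = X[idx]
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        raise DegenerateSeriesError("all embedded points coincide")
    return np.quantile(d, qs)


@dataclass(frozen=True)
class D2Config:
    """Tunables for the D2 fit: radius grid and scaling-window selection."""

    n_radii: int = 30
    radius_quantiles: tuple[float, float] = (0.001, 0.20)
    theiler: int | None = None  # None -> the series' mean period
    min_decades: float = 0.5  # window must span at least half a decade of r
    r2_floor: float = 0.98  # below this the estimate is flagged low-confidence


def estimate_d2(ts: TimeSeries, params: EmbeddingParams,
                config: D2Config | None = None) -> D2Estimate:
    """Correlation dimension by a max-r^2 scaling-window fit of ln C vs ln r.

    Radii are log-spaced between the 0.1 and 20 percent quantiles of
    pairwise distances: the correlation sum only scales as r^D2 well below
    the attractor diameter, and the upper half of the distance
    distribution is saturated curvature. Among all contiguous radius windows spanning at least
    ``min_decades`` decades with C(r) > 0 throughout, the one maximizing
    the r^2 of the ln-ln fit is chosen; if even the best window fits worse
    than ``r2_floor`` the result carries ``low_confidence=True``.
    """
    if len(ts) < 500:
        raise ParameterError("D2 estimation needs at least 500 samples")
    if np.ptp(ts.values) == 0:
        raise DegenerateSeriesError("D2 undefined for a constant series")
    config = config or D2Config()
    traj = embed(ts, params)
    theiler = (max(1, int(round(mean_period(ts))))
               if config.theiler is None else config.theiler)
    r_lo, r_hi = _distance_quantiles(traj.rows, config.radius_quantiles)
    if not (r_lo > 0 and r_hi > r_lo):
        raise DegenerateSeriesError("degenerate pairwise-distance distribution")
    radii = np.geomspace(r_lo, r_hi, config.n_radii)
    curve = correlation_sum(traj, radii, theiler=theiler)
    ok = curve.c_values > 0
    ln_r = np.log(radii)
    ln_c = np.where(ok, np.log(np.where(ok, curve.c_values, 1.0)), np.nan)

    best = None
    n = radii.size
    min_span = config.min_decades * np.log(10.0)
    for i in range(n):
        if not ok[i]:
            continue
        for j in range(i + 2, n):
            if not np.all(ok[i:j + 1]):
                break
            if ln_r[j] - ln_r[i] < min_span:
                continue
            t = ln_r[i:j + 1]
            y = ln_c[i:j + 1]
            tc = t - t.mean()
            yc = y - y.mean()
            stt = np.dot(tc, tc)
            sty = np.dot(tc, yc)
            syy = np.dot(yc, yc)
            slope = sty / stt
            r2 = (sty * sty) / (stt * syy) if syy > 0 else 0.0
            if best is None or r2 > best[0]:
                best = (r2, slope, radii[i], radii[j])
    if best is None:
        raise DegenerateSeriesError(
            "no radius window with positive correlation sums spans "
            f"{config.min_decades} decades")
    r2, slope, w_lo, w_hi = best
    return D2Estimate(d2=float(slope), scaling_window=(float(w_lo), float(w_hi)),
                      r2=float(r2), low_confidence=bool(r2 < config.r2_floor),
                      curve=curve)
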