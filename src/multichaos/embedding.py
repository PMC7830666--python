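"""Phase-space reconstruction: delay and dimension estimation, embedding.

A scalar series {x_1 ... x_N} is unfolded into delay vectors

    X_i = (x_i, x_{i+J}, ..., x_{i+(m-1)J}),  i = 1 ... M,  M = N - (m-1) J,

where J is the time delay in samples and m the embedding dimension. The
delay is chosen so successive coordinates are as independent as possible;
three standard estimators are provided (first zero of the autocorrelation,
first minimum of the mutual information, first minimum of the correlation
integral). The embedding dimension is chosen by Cao's method from the
saturation of the E1(d) neighbour-distance ratio; the companion E2(d)
curve separates deterministic from stochastic signals (E2 stays near 1 at
every d for i.i.d. noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import DegenerateSeriesError, EmbeddingError, ParameterError
from .series import TimeSeries

__all__ = [
    "EmbeddingParams",
    "TrajectoryMatrix",
    "embed",
    "estimate_delay_acf",
    "estimate_delay_mi",
    "estimate_delay_ci",
    "estimate_dim_cao",
    "estimate_embedding",
    "DelayScan",
    "CaoResult",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters: dimension m and delay J (both in samples)."""

    m: int
    J: int

    def __post_init__(self):
        if self.m < 1:
            raise ParameterError("embedding dimension m must be >= 1")
        if self.J < 1:
            raise ParameterError("time delay J must be >= 1")

    def min_length(self) -> int:
        """Smallest series length N admitting this embedding (M >= 1)."""
        return (self.m - 1) * self.J + 1


@dataclass(frozen=True)
class TrajectoryMatrix:
    """M delay vectors of dimension m reconstructed from one series."""

    rows: np.ndarray  # shape (M, m)
    params: EmbeddingParams
    dt: float

    def __post_init__(self):
        rows = np.ascontiguousarray(self.rows, dtype=float)
        rows.setflags(write=False)
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def m(self) -> int:
        return self.rows.shape[1]


@dataclass(frozen=True)
class DelayScan:
    """A delay estimate together with the scanned dependence curve."""

    lag: int
    lags: np.ndarray
    curve: np.ndarray
    warned: bool = False  # True when no qualifying zero/minimum was found


@dataclass(frozen=True)
class CaoResult:
    """Cao's method output: chosen m plus the E1/E2 diagnostic curves."""

    m: int
    dims: np.ndarray  # d values the curves are indexed by
    e1: np.ndarray
    e2: np.ndarray


def embed(ts: TimeSeries, params: EmbeddingParams) -> TrajectoryMatrix:
    """Build the trajectory matrix of delay vectors (row i starts at x_i)."""
    n = len(ts)
    m, J = params.m, params.J
    M = n - (m - 1) * J
    if M < 1:
        raise EmbeddingError(
            f"series of length {n} too short for m={m}, J={J}; "
            f"needs at least {params.min_length()} samples")
    x = ts.values
    rows = np.empty((M, m))
    for k in range(m):
        rows[:, k] = x[k * J:k * J + M]
    return TrajectoryMatrix(rows=rows, params=params, dt=ts.dt)


def _max_lag(n: int, requested: int | None) -> int:
    # long-lag statistics are poorly estimated; cap the scan at N/4
    cap = max(1, n // 4)
    return cap if requested is None else min(requested, cap)


def estimate_delay_acf(ts: TimeSeries, zero_tol: float = 0.05,
                       max_lag: int | None = None,
                       criterion: str = "zero",
                       full_output: bool = False):
    """Delay from the autocorrelation function.

    criterion="zero" (default): smallest J >= 1 with |acf(J)| <= zero_tol,
    the first (approximate) zero crossing. criterion="1/e": smallest J
    with acf(J) < 1 - 1/e, the classical drop-below-(1 - 1/e) rule from
    Lyapunov-estimation practice — for broadband maps this lands on J = 1
    where the zero-crossing rule can wander to long lags. If no lag up to
    N/4 qualifies, the lag of minimum |acf| is returned with a warning.
    """
    n = len(ts)
    if n < 50:
        raise ParameterError("acf delay estimation needs at least 50 samples")
    if criterion not in ("zero", "1/e"):
        raise ParameterError("criterion must be 'zero' or '1/e'")
    if np.ptp(ts.values) == 0:
        raise DegenerateSeriesError("autocorrelation undefined for a constant series")
    nlags = _max_lag(n, max_lag)
    rho = _sm_acf(ts.values, nlags=nlags, fft=True)
    abs_rho = np.abs(rho[1:])  # lags 1..nlags
    if criterion == "1/e":
        below = np.nonzero(rho[1:] < 1.0 - 1.0 / np.e)[0]
    else:
        below = np.nonzero(abs_rho <= zero_tol)[0]
    if below.size:
        lag, warned = int(below[0] + 1), False
    else:
        lag, warned = int(np.argmin(abs_rho) + 1), True
        warnings.warn(f"|acf| never reached {zero_tol} up to lag {nlags}; "
                      f"returning its minimum at lag {lag}", stacklevel=2)
    if full_output:
        return DelayScan(lag, np.arange(1, nlags + 1), abs_rho, warned)
    return lag


def _histogram_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Mutual information (nats) of two samples from a joint 2-D histogram."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def _first_local_min(curve: np.ndarray) -> int | None:
    """Index (0-based) of the first strict local minimum, None if absent."""
    for i in range(1, len(curve) - 1):
        if curve[i] < curve[i - 1] and curve[i] < curve[i + 1]:
            return i
    return None


def _first_minimum_plateau(curve: np.ndarray,
                           plateau_frac: float = 0.005) -> int | None:
    """First-local-minimum index, centred over any near-flat valley.

    Histogram estimators quantize smooth dependence curves into flat
    valleys; the strict first local minimum then lands at the valley's
    entrance. The valley is expanded to all contiguous points within
    ``plateau_frac`` of the curve's total range above the minimum, and its
    midpoint is returned.
    """
    i0 = _first_local_min(curve)
    if i0 is None:
        return None
    tol = plateau_frac * (np.max(curve) - np.min(curve))
    lo = i0
    while lo > 0 and curve[lo - 1] <= curve[i0] + tol:
        lo -= 1
    hi = i0
    while hi < len(curve) - 1 and curve[hi + 1] <= curve[i0] + tol:
        hi += 1
    return (lo + hi) // 2


def _first_prominent_min(curve: np.ndarray,
                         prominence_frac: float = 0.05,
                         plateau_frac: float = 0.25) -> int | None:
    """First minimum of the curve with prominence above a range fraction.

    Guards against the hairline local minima that sampling noise puts on
    monotone dependence curves. The qualifying minimum is then centred
    over its surrounding valley — the contiguous region within
    ``plateau_frac`` of the range above the curve floor — so shallow
    double-dip valleys (finite-sample wiggles around one broad minimum)
    resolve to the valley centre.
    """
    from scipy.signal import find_peaks

    rng = np.ptp(curve)
    if rng <= 0:
        return None
    peaks, _ = find_peaks(-curve, prominence=prominence_frac * rng)
    if peaks.size == 0:
        return None
    i0 = int(peaks[0])
    tol = plateau_frac * rng
    floor = np.min(curve)
    lo = i0
    while lo > 0 and curve[lo - 1] <= floor + tol:
        lo -= 1
    hi = i0
    while hi < len(curve) - 1 and curve[hi + 1] <= floor + tol:
        hi += 1
    return (lo + hi) // 2


def estimate_delay_mi(ts: TimeSeries, n_bins: int = 16,
                      max_lag: int | None = None,
                      full_output: bool = False):
    """Delay = first local minimum of the lagged mutual information.

    I(x_t; x_{t+J}) is estimated from an equal-width n_bins x n_bins
    histogram over the sample range. Lag J = 0 (self-information) is never
    scanned. If no strict local minimum exists up to N/4, the global
    minimum over the scan is returned with a warning.
    """
    n = len(ts)
    if n < 200:
        raise ParameterError("MI delay estimation needs at least 200 samples")
    if np.ptp(ts.values) == 0:
        raise DegenerateSeriesError("mutual information undefined: single-bin series")
    nlags = _max_lag(n, max_lag if max_lag is not None else 250)
    x = ts.values
    mi = np.array([_histogram_mi(x[:-j], x[j:], n_bins)
                   for j in range(1, nlags + 1)])
    # histogram MI of independent samples is biased up by ~(k-1)^2 / 2N;
    # a curve that never clears that floor carries no lag structure
    bias = (n_bins - 1) ** 2 / (2.0 * n)
    warned = False
    if np.max(mi) < 3.0 * bias:
        found = 1
    else:
        i0 = _first_minimum_plateau(mi)
        if i0 is not None:
            found = i0 + 1
        else:
            found = int(np.argmin(mi) + 1)
            warned = True
            warnings.warn("no local minimum of the MI curve up to lag "
                          f"{nlags}; returning its global minimum at lag {found}",
                          stacklevel=2)
    if full_output:
        return DelayScan(found, np.arange(1, nlags + 1), mi, warned)
    return found


def _subsample_rows(M: int, target: int) -> np.ndarray:
    """Evenly strided row indices, deterministic, at most ``target`` of them."""
    if M <= target:
        return np.arange(M)
    stride = M / target
    return np.unique((np.arange(target) * stride).astype(int))


def estimate_delay_ci(ts: TimeSeries, m_probe: int = 2,
                      radius_quantile: float = 0.10,
                      max_lag: int | None = None,
                      n_ref: int = 800,
                      full_output: bool = False):
    """Delay = first local minimum of the correlation integral ln C_m(J).

    For each candidate lag J the series is embedded at the probe dimension
    ``m_probe`` and the correlation integral C(r*) — the fraction of vector
    pairs closer than a fixed radius r* — is evaluated on a deterministic
    subsample of rows. The radius is frozen across lags at the
    ``radius_quantile`` quantile of pairwise distances of the J = 1
    embedding, following the minima-matching construction of Liebert and
    Schuster: minima of ln C(J) coincide with minima of the mutual
    information but cost far less to compute. A monotone dependence
    structure (e.g. a ramp) has no local minimum; the global minimum is
    then returned with a warning.
    """
    n = len(ts)
    if n < 200:
        raise ParameterError("CI delay estimation needs at least 200 samples")
    if np.ptp(ts.values) == 0:
        raise DegenerateSeriesError("correlation integral degenerate: constant series")
    if m_probe < 2:
        raise ParameterError("probe dimension must be >= 2")
    nlags = _max_lag(n, max_lag)
    nlags = min(nlags, n - (m_probe - 1) - 1)
    x = ts.values

    def embedded(J: int) -> np.ndarray:
        M = n - (m_probe - 1) * J
        idx = _subsample_rows(M, n_ref)
        cols = [x[idx + k * J] for k in range(m_probe)]
        return np.column_stack(cols)

    ref = embedded(1)
    d0 = pdist(ref)
    d0 = d0[d0 > 0]
    if d0.size == 0:
        raise DegenerateSeriesError("all embedded points coincide")
    r_star = float(np.quantile(d0, radius_quantile))

    lnc = np.empty(nlags)
    for J in range(1, nlags + 1):
        if n - (m_probe - 1) * J < 2:
            nlags = J - 1
            lnc = lnc[:nlags]
            break
        d = pdist(embedded(J))
        frac = np.mean(d < r_star)
        lnc[J - 1] = np.log(frac) if frac > 0 else -np.inf
    finite = np.isfinite(lnc)
    filled = np.where(finite, lnc, np.max(lnc[finite]))
    i = _first_prominent_min(filled)
    if i is not None:
        lag, warned = i + 1, False
    else:
        # no prominent minimum (monotone or flat dependence, e.g. a ramp)
        lag, warned = int(np.argmin(filled) + 1), True
        warnings.warn("no prominent minimum of ln C(J); the series has no "
                      f"usable lag structure (returning lag {lag})", stacklevel=2)
    if full_output:
        return DelayScan(lag, np.arange(1, nlags + 1), lnc, warned)
    return lag


def estimate_dim_cao(ts: TimeSeries, J: int, m_max: int = 10,
                     e1_threshold: float = 0.95) -> CaoResult:
    """Minimum embedding dimension by Cao's E1/E2 method.

    For each trial dimension d the nearest neighbour of every delay vector
    is found in the maximum norm, and

        E(d)  = mean_i ||y_{d+1}(i) - y_{d+1}(nn_d(i))|| / ||y_d(i) - y_d(nn_d(i))||
        E1(d) = E(d+1) / E(d)

    E1 saturates near 1 once d reaches the attractor's minimum embedding
    dimension; the returned m is d + 1 for the smallest d whose E1 exceeds
    ``e1_threshold`` at two consecutive dimensions. E2(d) = E*(d+1)/E*(d)
    (same construction on the extra-coordinate distance alone) is returned
    so callers can flag stochastic series, for which E2 stays near 1 at
    every d.
    """
    if m_max < 3:
        raise ParameterError("m_max must be >= 3")
    n = len(ts)
    # curves need embeddings up to dimension m_max + 1
    if n <= (m_max + 1) * J + 1:
        raise EmbeddingError(
            f"series of length {n} too short for Cao scan to m_max={m_max} "
            f"with J={J}; needs more than {(m_max + 1) * J + 1} samples")
    x = ts.values
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("Cao's method undefined for a constant series")

    dims = np.arange(1, m_max + 1)
    E = np.empty(m_max + 1)
    Estar = np.empty(m_max + 1)
    for d in range(1, m_max + 2):
        M = n - d * J  # rows for which the (d+1)-th coordinate also exists
        cols = [x[k * J:k * J + M] for k in range(d)]
        Y = np.column_stack(cols)
        extra = x[d * J:d * J + M]
        tree = cKDTree(Y)
        dist, nn = tree.query(Y, k=2, p=np.inf)
        dist, nn = dist[:, 1], nn[:, 1]
        ok = dist > 0  # coincident vectors carry no direction information
        if not np.any(ok):
            raise DegenerateSeriesError("all delay vectors coincide")
        grown = np.maximum(dist[ok], np.abs(extra[ok] - extra[nn[ok]]))
        E[d - 1] = np.mean(grown / dist[ok])
        Estar[d - 1] = np.mean(np.abs(extra - extra[nn]))
    e1 = E[1:] / E[:-1]
    e2 = Estar[1:] / Estar[:-1]

    m = m_max  # fall back to the scan ceiling when no saturation is seen
    for i in range(len(e1) - 1):
        if e1[i] >= e1_threshold and e1[i + 1] >= e1_threshold:
            m = int(dims[i]) + 1
            break
    else:
        warnings.warn(f"E1 never saturated above {e1_threshold} up to "
                      f"d={m_max}; returning m={m}", stacklevel=2)
    return CaoResult(m=m, dims=dims, e1=e1, e2=e2)


def estimate_embedding(ts: TimeSeries, delay_method: str = "mi",
                       m_max: int = 8, **kwargs) -> EmbeddingParams:
    """One-call (m, J) estimation: a delay estimator followed by Cao's method."""
    est = {"acf": estimate_delay_acf,
           "acf1e": lambda s, **kw: estimate_delay_acf(s, criterion="1/e", **kw),
           "mi": estimate_delay_mi,
           "ci": estimate_delay_ci}.get(delay_method)
    if est is None:
        raise ParameterError(
            f"delay_method must be acf, acf1e, mi or ci, not {delay_method!r}")
    J = est(ts, **kwargs)
    # keep the Cao scan feasible for large delays on short series
    while m_max > 3 and len(ts) <= (m_max + 1) * J + 1:
        m_max -= 1
    cao = estimate_dim_cao(ts, J, m_max=m_max)
    return EmbeddingParams(m=cao.m, J=J)
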