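"""Temporal statistics: exponential Q-Q test for Poisson event timing.

If fusion events occur at random in time (a homogeneous Poisson process),
the gaps between consecutive events (delta-T) are exponentially
distributed.  The test sorts the observed delta-T, plots them against
standard-exponential quantiles (a Q-Q plot), fits a variance-weighted line
(upper order statistics of an exponential sample are much noisier than
lower ones), simulates exponential samples consistent with the fitted
line to build a median/MAD envelope, and scores the departure of each
order statistic as

    z_i = (deltaT_(i) - (slope·q_i + intercept)) / (1.4826 · MAD_i)

(the 1.4826 factor puts the MAD on the standard-deviation scale, so the
|z| > 2 criterion is the conventional two-sigma rule).

|z| > 2 anywhere flags non-Poisson timing (bursting or periodicity);
per-cell Z-scores are interpolated onto a common axis for aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spatial import MAD_SCALE


@dataclass
class EventTimes:
    """Sorted event times (s) within one cell's observation span."""

    times: np.ndarray
    observation_span: float

    def __post_init__(self) -> None:
        t = np.sort(np.asarray(self.times, dtype=float))
        if self.observation_span <= 0:
            raise ValueError("observation_span must be positive")
        if t.size and (t[0] < 0 or t[-1] > self.observation_span):
            raise ValueError("event times must lie in [0, observation_span]")
        self.times = t

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class QQResult:
    delta_t_sorted: np.ndarray
    p: np.ndarray
    q_theoretical: np.ndarray
    slope: float
    intercept: float
    env_median: np.ndarray
    env_mad: np.ndarray
    z: np.ndarray
    usable: np.ndarray
    n_sims: int
    degenerate: bool = False

    @property
    def fitted_axis(self) -> np.ndarray:
        """Theoretical delta-T axis of each order statistic: slope·q + b."""
        return self.slope * self.q_theoretical + self.intercept


def delta_t_set(events: EventTimes) -> np.ndarray:
    """Sorted inter-event intervals (delta-T), ascending."""
    if events.n < 2:
        raise ValueError("delta-T needs at least 2 events")
    return np.sort(np.diff(events.times))


def qq_points(delta_t_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hazen plotting positions and standard-exponential quantiles.

    p_i = (i - 0.5)/n keeps p < 1 so q_i = -ln(1 - p_i) stays finite and is
    symmetric in rank.
    """
    n = np.asarray(delta_t_sorted).size
    if n < 2:
        raise ValueError("need at least 2 intervals")
    p = (np.arange(1, n + 1) - 0.5) / n
    return p, -np.log1p(-p)


def exponential_order_stat_variance(n: int) -> np.ndarray:
    """Var of the i-th order statistic of n standard exponentials.

    Var(E_(i:n)) = Σ_{j=1}^{i} (n - j + 1)^{-2}; it grows sharply toward the
    upper tail, which motivates the variance-weighted line fit.
    """
    j = np.arange(1, n + 1)
    return np.cumsum(1.0 / (n - j + 1) ** 2)


def variance_weighted_line(q_theoretical: np.ndarray,
                           delta_t_sorted: np.ndarray
                           ) -> tuple[float, float, bool]:
    """Weighted least-squares line through the Q-Q points.

    Weights are 1/Var(E_(i:n)) from exponential order-statistic theory, so
    the stable lower tail dominates the fit.  Returns (slope, intercept,
    degenerate); a degenerate flag marks all-equal intervals, for which the
    slope is 0 and no meaningful envelope can be built.
    """
    q = np.asarray(q_theoretical, float)
    y = np.asarray(delta_t_sorted, float)
    if q.size < 3:
        raise ValueError("line fit needs at least 3 intervals")
    w = 1.0 / exponential_order_stat_variance(q.size)
    sw = w.sum()
    qm = (w * q).sum() / sw
    ym = (w * y).sum() / sw
    denom = (w * (q - qm) ** 2).sum()
    slope = float((w * (q - qm) * (y - ym)).sum() / denom)
    intercept = float(ym - slope * qm)
    degenerate = np.ptp(y) == 0
    return slope, intercept, degenerate


def simulate_qq_envelope(n: int, slope: float, intercept: float,
                         n_sims: int = 400, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Median/MAD envelope of sorted exponential samples on the fitted line.

    Each of `n_sims` simulations draws n values slope·Exp(1) + intercept and
    sorts them; the envelope is the per-order-statistic median and MAD.
    """
    if n < 3:
        raise ValueError("envelope needs n >= 3")
    if not slope > 0:
        raise ValueError("envelope needs a positive fitted slope")
    rng = np.random.default_rng(seed)
    sims = np.sort(slope * rng.exponential(size=(n_sims, n)) + intercept,
                   axis=1)
    med = np.median(sims, axis=0)
    mad = np.median(np.abs(sims - med), axis=0)
    return med, mad


def temporal_zscore(delta_t_sorted: np.ndarray, q_theoretical: np.ndarray,
                    slope: float, intercept: float, env_mad: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Z-score of each order statistic against the fitted line.

    The envelope MAD is scaled by 1.4826 to standard-deviation units; see
    the module docstring.
    """
    y = np.asarray(delta_t_sorted, float)
    q = np.asarray(q_theoretical, float)
    mad = np.asarray(env_mad, float)
    if not y.shape == q.shape == mad.shape:
        raise ValueError("mismatched series lengths")
    usable = mad > 0
    z = np.zeros_like(y)
    z[usable] = ((y[usable] - (slope * q[usable] + intercept))
                 / (MAD_SCALE * mad[usable]))
    return z, usable


def analyze_times(events: EventTimes, n_sims: int = 400,
                  seed: int = 0) -> QQResult:
    """delta-T, Q-Q construction, line fit, envelope and Z in one call."""
    dt = delta_t_set(events)
    p, q = qq_points(dt)
    slope, intercept, degenerate = variance_weighted_line(q, dt)
    if degenerate or slope <= 0:
        # no meaningful exponential envelope; score against a flat MAD of 0
        z = np.zeros_like(dt)
        return QQResult(dt, p, q, slope, intercept,
                        np.full_like(dt, np.nan), np.zeros_like(dt), z,
                        np.zeros_like(dt, dtype=bool), n_sims,
                        degenerate=True)
    med, mad = simulate_qq_envelope(dt.size, slope, intercept, n_sims, seed)
    z, usable = temporal_zscore(dt, q, slope, intercept, mad)
    return QQResult(dt, p, q, slope, intercept, med, mad, z, usable, n_sims)


def aggregate_temporal(results: list[QQResult],
                       common_axis: np.ndarray | None = None,
                       n_points: int = 100
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate per-cell Z onto a common delta-T axis; mean and s.e.m.

    Each cell's Z is indexed by its fitted theoretical time slope·q + b and
    linearly interpolated onto `common_axis` (default: 100 points spanning
    the union of per-cell fitted ranges).  No extrapolation: outside a
    cell's range its values are omitted from the mean/s.e.m. at that point.
    Returns (axis, mean, sem).
    """
    if not results:
        raise ValueError("no cells to aggregate")
    axes = [r.fitted_axis for r in results]
    if common_axis is None:
        lo = min(a[0] for a in axes)
        hi = max(a[-1] for a in axes)
        common_axis = np.linspace(lo, hi, n_points)
    else:
        common_axis = np.asarray(common_axis, float)
        if not any(a[0] <= common_axis[-1] and common_axis[0] <= a[-1]
                   for a in axes):
            raise ValueError("common axis does not overlap any cell's range")
    stack = np.full((len(results), common_axis.size), np.nan)
    for i, (r, a) in enumerate(zip(results, axes)):
        inside = (common_axis >= a[0]) & (common_axis <= a[-1])
        stack[i, inside] = np.interp(common_axis[inside], a, r.z)
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
    mean[counts == 0] = np.nan
    sem[counts == 0] = np.nan
    return common_axis, mean, sem
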