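"""Minutes-scale variability of NS occurrence: Fano-factor scaling.

The NS train (absolute peak times, not referenced to stimuli) is sliced
into non-overlapping windows of duration ``T`` anchored at t = 0, over
a logarithmically spaced grid of ``T``.  The Fano factor
``FF(T) = var(Z(T)) / mean(Z(T))`` equals 1 for a Poisson process;
power-law growth ``FF ~ alpha * T**beta`` with 0 < beta < 1 over the
final rising section indicates long-range correlation of event
occurrence.  A surrogate obtained by shuffling the inter-event
intervals destroys that order while preserving the interval
distribution, and serves as the renewal-process control.

Sample variances use the n-1 denominator: the number of windows at the
largest T is small and unbiasedness matters there.  The n-1 correction
removes the iid bias only: for long-memory counts the window sample
mean absorbs low-frequency variance and FF is under-measured by a
factor of roughly ``1 - (T / duration)**(2 - 2H)``, which at
``duration / 10`` windows exceeds 50% for Hurst exponents near 1.  The
default grid therefore retains T only while at least 50 complete
windows exist; beyond that the estimator is bias- (not variance-)
limited and would systematically flatten the top of the curve.
"""
from __future__ import annotations

import warnings

import numpy as np

from .errors import ConfigError, DataFormatError
from .types import FanoCurve, NSTrain, PowerLawFit

DEFAULT_POINTS_PER_DECADE = 20
DEFAULT_MIN_WINDOWS = 50
MIN_FIT_POINTS = 5
#: Width cap (decades) of the default "post-minimum" fit section.
POST_MIN_MAX_DECADES = 1.25


def count_sequence(ns: NSTrain, T: float) -> np.ndarray:
    """Counts of NS peak times in contiguous windows [kT, (k+1)T) from t = 0.

    The partial final window is discarded.  Requires at least 2
    complete windows.
    """
    if T <= 0:
        raise ConfigError("T must be positive")
    n_win = int(np.floor(ns.duration / T))
    if n_win < 2:
        raise DataFormatError(f"T too large: only {n_win} complete window(s)")
    t = ns.peak_times
    t = t[t < n_win * T]
    idx = np.floor(t / T).astype(np.int64)
    return np.bincount(idx, minlength=n_win)[:n_win]


def log_grid(
    t_min: float,
    t_max: float,
    points_per_decade: int = DEFAULT_POINTS_PER_DECADE,
) -> np.ndarray:
    """Logarithmically spaced grid from ``t_min`` to ``t_max`` inclusive."""
    if not 0 < t_min < t_max:
        raise ConfigError("need 0 < t_min < t_max")
    if points_per_decade < 1:
        raise ConfigError("points_per_decade must be >= 1")
    n = int(np.floor(np.log10(t_max / t_min) * points_per_decade + 1e-9)) + 1
    grid = t_min * 10 ** (np.arange(n) / points_per_decade)
    if grid[-1] < t_max * (1 - 1e-9):
        grid = np.append(grid, t_max)
    return grid


def fano_curve(
    ns: NSTrain,
    t_min: float = 0.05,
    t_max: float | None = None,
    points_per_decade: int = DEFAULT_POINTS_PER_DECADE,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> FanoCurve:
    """FF(T) over a log-spaced grid; ``t_max`` defaults to duration/10.

    Grid points with fewer than ``min_windows`` complete windows, or a
    zero mean count, are dropped (the latter with a warning).  Fewer
    than 5 surviving points is an error.
    """
    if t_max is None:
        t_max = ns.duration / min_windows
    if t_max > ns.duration / min_windows + 1e-9:
        raise ConfigError("t_max must not exceed duration / min_windows")
    T_all = log_grid(t_min, t_max, points_per_decade)
    Ts, ffs, nws = [], [], []
    for T in T_all:
        n_win = int(np.floor(ns.duration / T))
        if n_win < max(min_windows, 2):
            continue
        z = count_sequence(ns, T)
        m = z.mean()
        if m == 0:
            warnings.warn(f"T={T:g}: zero mean count, dropped", stacklevel=2)
            continue
        ffs.append(z.var(ddof=1) / m)
        Ts.append(T)
        nws.append(n_win)
    if len(Ts) < MIN_FIT_POINTS:
        raise DataFormatError(f"only {len(Ts)} retained grid points (< {MIN_FIT_POINTS})")
    return FanoCurve(np.array(Ts), np.array(ffs), np.array(nws), ns.duration)


def shuffle_surrogate(ns: NSTrain, seed: int | np.random.Generator) -> NSTrain:
    """ISI-shuffled surrogate: permute inter-event intervals uniformly at random.

    The first event time, total span, and interval multiset are
    preserved exactly.  Peak rates keep their original order; onset
    times are collapsed onto the surrogate peaks (only the peak times
    carry meaning downstream of a surrogate).
    """
    if len(ns) < 3:
        raise DataFormatError("need at least 3 events to shuffle intervals")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = np.diff(ns.peak_times)
    peaks = ns.peak_times[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(intervals))])
    return NSTrain(peaks, ns.peak_rates.copy(), peaks.copy(), ns.duration)


def fit_powerlaw(
    curve: FanoCurve,
    range_rule: str | tuple[float, float] = "post-minimum",
) -> PowerLawFit:
    """OLS of log10(FF) on log10(T): beta = slope, alpha = 10**intercept.

    ``range_rule`` is either an explicit ``(t_lo, t_hi)`` pair or
    ``"post-minimum"``: the final rising section starts at
    ``2 * argmin_T FF`` and runs to the largest retained T, capped at
    the final ``POST_MIN_MAX_DECADES`` decades.  The cap matters: just
    above the refractoriness dip the curve is still bending away from
    its short-time plateau, and an uncapped post-minimum range mixes
    that curvature into the slope of the final straight section.
    Non-finite FF values in range are dropped with a warning; fewer
    than 5 remaining points is an error.
    """
    T, ff = curve.T, curve.ff
    if isinstance(range_rule, str):
        if range_rule != "post-minimum":
            raise ConfigError(f"unknown range rule {range_rule!r}")
        finite = np.isfinite(ff)
        t_hi = float(T.max())
        t_tail = t_hi / 10**POST_MIN_MAX_DECADES
        t_lo = max(2.0 * T[finite][np.argmin(ff[finite])], t_tail)
        if np.sum((T >= t_lo * (1 - 1e-9)) & finite) < MIN_FIT_POINTS:
            # flat or declining curve: no rising section after the minimum;
            # fit the final section anyway (slope ~ 0 is the honest answer)
            warnings.warn(
                "FF minimum falls inside the final section; fitting the "
                f"last {POST_MIN_MAX_DECADES} decades",
                stacklevel=2,
            )
            t_lo = t_tail
    else:
        t_lo, t_hi = map(float, range_rule)
        if not t_lo < t_hi:
            raise ConfigError("need t_lo < t_hi")
    in_range = (T >= t_lo * (1 - 1e-9)) & (T <= t_hi * (1 + 1e-9))
    good = in_range & np.isfinite(ff) & (ff > 0)
    if good.sum() < in_range.sum():
        warnings.warn("non-finite or non-positive FF values dropped from fit", stacklevel=2)
    if good.sum() < MIN_FIT_POINTS:
        raise DataFormatError(
            f"only {int(good.sum())} usable points in fit range (< {MIN_FIT_POINTS})"
        )
    x = np.log10(T[good])
    y = np.log10(ff[good])
    beta, intercept = np.polyfit(x, y, 1)
    resid = y - (beta * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return PowerLawFit(
        alpha=float(10**intercept),
        beta=float(beta),
        t_lo=float(t_lo),
        t_hi=float(t_hi),
        r2=r2,
        n_points=int(good.sum()),
    )
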