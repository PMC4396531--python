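"""Serial structure of response-feature series and the latency-decay plane.

Latency and decay series are treated as if equally spaced in time: the
autocorrelation is computed over **serial-index lags** (response
ordinals in the stream of successful responses), with the estimator

    rho[l] = sum_{i=1..n-l} (x_i - m)(x_{i+l} - m) / sum_{i=1..n} (x_i - m)^2

where ``m`` is the full-series mean.  The full-length denominator
(Bartlett convention) guarantees ``rho[0] == 1`` and ``|rho| <= 1``
and damps drift artefacts; it is implemented verbatim rather than
replaced by an unbiased per-lag variant.  A *warped* time axis converts
lags to seconds via the mean inter-response interval.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataFormatError
from .features import moving_average
from .types import ACF, SerialSeries, Trajectory

DEFAULT_MAX_LAG = 200
DEFAULT_SMOOTH_WINDOW = 11
DEFAULT_SEGMENT_LEN = 50


def extract_series(
    table: pd.DataFrame,
    column: str = "latency_ms",
    include_censored: bool = False,
) -> SerialSeries:
    """Pull a feature series over successful responses from a response table.

    Censored decays are excluded by default (a censored decay sits at
    the window ceiling and would inject an artefactual plateau).
    """
    mask = table["success"].to_numpy(dtype=bool) & np.isfinite(table[column].to_numpy())
    if column == "decay_ms" and not include_censored:
        mask &= ~table["censored_decay"].to_numpy(dtype=bool)
    vals = table.loc[mask, column].to_numpy(dtype=np.float64)
    times = table.loc[mask, "stim_time_s"].to_numpy(dtype=np.float64)
    return SerialSeries(vals, times)


def serial_autocorrelation(
    series: SerialSeries | np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    response_times: np.ndarray | None = None,
) -> ACF:
    """Serial-index autocorrelation up to ``max_lag``.

    When response times are available the warped (seconds) axis is
    attached: ``warped_lag_s[l] = l * mean inter-response interval``.
    """
    if isinstance(series, SerialSeries):
        x = series.values
        if response_times is None:
            response_times = series.response_times
    else:
        x = np.asarray(series, dtype=np.float64)
    n = x.size
    if n < max_lag + 2:
        raise DataFormatError(f"series length {n} < max_lag + 2 = {max_lag + 2}")
    d = x - x.mean()
    denom = float(np.sum(d * d))
    if denom == 0:
        raise DataFormatError("degenerate series: zero variance")
    full = np.correlate(d, d, mode="full")  # lags -(n-1)..(n-1)
    rho = full[n - 1 : n + max_lag] / denom
    lags = np.arange(max_lag + 1)
    warped = None
    if response_times is not None and np.asarray(response_times).size >= 2:
        warped = warped_time_axis(np.asarray(response_times), lags)
    return ACF(lags=lags, rho=rho, warped_lag_s=warped)


def warped_time_axis(response_times: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Seconds per serial lag: ``l * mean(diff(response_times))``."""
    t = np.asarray(response_times, dtype=np.float64)
    if t.size < 2:
        raise DataFormatError("need at least 2 response times for a warped axis")
    return np.asarray(lags, dtype=np.float64) * float(np.mean(np.diff(t)))


def first_acf_peak(acf: ACF, min_lag: int = 2) -> int | None:
    """Serial lag of the first local maximum of rho at lag >= min_lag."""
    r = acf.rho
    for l in range(max(min_lag, 1), r.size - 1):
        if r[l] > r[l - 1] and r[l] >= r[l + 1]:
            return l
    return None


def build_trajectory(
    table: pd.DataFrame,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    segment_len: int = DEFAULT_SEGMENT_LEN,
    include_censored: bool = False,
) -> Trajectory:
    """Latency-decay pairs of successive successful responses, smoothed.

    Smoothing is a centered moving average (edge-truncated) applied to
    each coordinate independently; ``segments`` are consecutive
    non-overlapping index ranges of ``segment_len`` responses (50 by
    default), the unit in which plane excursions are inspected.
    """
    if smooth_window % 2 == 0:
        raise ConfigError("smooth_window must be odd")
    mask = (
        table["success"].to_numpy(dtype=bool)
        & np.isfinite(table["latency_ms"].to_numpy())
        & np.isfinite(table["decay_ms"].to_numpy())
    )
    if not include_censored:
        mask &= ~table["censored_decay"].to_numpy(dtype=bool)
    pts = table.loc[mask, ["latency_ms", "decay_ms"]].to_numpy(dtype=np.float64)
    n = pts.shape[0]
    if n < smooth_window:
        warnings.warn("fewer successes than smoothing window; smoothing skipped", stacklevel=2)
        smoothed = pts.copy()
    else:
        smoothed = np.column_stack(
            [moving_average(pts[:, 0], smooth_window), moving_average(pts[:, 1], smooth_window)]
        )
    segments = [(k * segment_len, (k + 1) * segment_len) for k in range(n // segment_len)]
    return Trajectory(points=pts, smoothed=smoothed, segments=segments)


def plane_center_of_mass(traj: Trajectory, log_plane: bool = True) -> tuple[float, float]:
    """Coordinate-wise center of mass of the trajectory points.

    Computed on log10 coordinates by default (the latency-decay plane
    is inspected in log-log), i.e. the geometric mean per coordinate;
    ``log_plane=False`` gives the arithmetic mean.
    """
    if traj.points.shape[0] == 0:
        raise DataFormatError("empty trajectory")
    if log_plane:
        if np.any(traj.points <= 0):
            raise DataFormatError("log-plane center of mass needs positive coordinates")
        c = 10 ** np.mean(np.log10(traj.points), axis=0)
    else:
        c = np.mean(traj.points, axis=0)
    return float(c[0]), float(c[1])
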