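"""Sub-second features of single evoked responses.

For every successful stimulus a post-stimulus time histogram (PSTH) is
built from all electrodes over the 1500 ms following the stimulus, at
1 ms bins.  Two smoothed versions are kept:

* ``smooth5`` — 5 ms moving average; its first sufficiently prominent
  local maximum defines the **latency**;
* ``smooth_wide`` — 30-100 ms moving average (50 ms default), which
  irons out oscillations in the falling phase; the **decay duration**
  runs from the latency bin to the first drop of this trace below a
  rate floor of 0.15 spikes/ms.

Moving averages are centered with edge truncation: near the array edges
the window shrinks and the divisor is the number of bins actually used
(zero-padding would bias latencies near the window edges).

The **local response probability** of a stimulus is the fraction of
successes among up to ``half_width`` preceding and ``half_width``
following stimuli, the index stimulus itself excluded.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, DataFormatError
from .types import PSTH, SpikeTrainSet

logger = logging.getLogger(__name__)

PSTH_WINDOW_MS = 1500
DEFAULT_WIDE_MS = 50
DEFAULT_RATE_FLOOR = 0.15   # spikes/ms
DEFAULT_PROMINENCE = 0.5
DEFAULT_HALF_WIDTH = 10


def moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (shrinking windows)."""
    if width < 1:
        raise ConfigError("smoothing width must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / den


def build_psth(
    spikes: SpikeTrainSet,
    stim_time: float,
    wide_width_ms: int = DEFAULT_WIDE_MS,
) -> PSTH:
    """PSTH of the 1500 ms following ``stim_time`` at 1 ms bins."""
    if not 30 <= wide_width_ms <= 100:
        raise ConfigError("wide smoothing width must lie in [30, 100] ms")
    if stim_time + PSTH_WINDOW_MS / 1000.0 > spikes.duration + 1e-9:
        raise DataFormatError("truncated response window")
    lo, hi = np.searchsorted(spikes.times, [stim_time, stim_time + PSTH_WINDOW_MS / 1000.0])
    rel_ms = (spikes.times[lo:hi] - stim_time) * 1000.0
    idx = np.floor(rel_ms).astype(np.int64)
    np.clip(idx, 0, PSTH_WINDOW_MS - 1, out=idx)
    raw = np.bincount(idx, minlength=PSTH_WINDOW_MS).astype(np.float64)  # spikes/ms at 1 ms bins
    return PSTH(
        stim_time=stim_time,
        raw=raw,
        smooth5=moving_average(raw, 5),
        smooth_wide=moving_average(raw, int(wide_width_ms)),
        wide_width_ms=int(wide_width_ms),
    )


def latency(psth: PSTH, prominence_frac: float | None = DEFAULT_PROMINENCE) -> float:
    """Latency (ms): bin center of the first qualifying maximum of ``smooth5``.

    A local maximum qualifies when its height is at least
    ``prominence_frac`` times the global maximum; reverberatory second
    peaks make a pure global argmax ambiguous, while early sub-peaks
    below half height are noise.  With ``prominence_frac=None`` the
    earliest bin attaining the global maximum is used ("global" mode).
    Plateau ties resolve to the earliest bin.
    """
    y = psth.smooth5
    gmax = float(y.max())
    if gmax <= 0:
        raise DataFormatError("no response content")
    first_argmax = int(np.argmax(y))
    bin_idx = first_argmax
    if prominence_frac is not None:
        if not 0 < prominence_frac <= 1:
            raise ConfigError("prominence_frac must lie in (0, 1]")
        peaks, props = find_peaks(y, plateau_size=(1, None))
        left = props["left_edges"]
        for p, le in zip(peaks, left):
            if y[p] >= prominence_frac * gmax - 1e-12:
                bin_idx = int(le)
                break
    return bin_idx + 0.5


def decay_duration(
    psth: PSTH,
    latency_ms: float,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> tuple[float, bool]:
    """Decay (ms) from the latency bin to the first ``smooth_wide`` drop below the floor.

    Returns ``(decay, censored)``; ``censored`` is True when the trace
    never drops below the floor inside the 1500 ms window, in which
    case the decay is the remaining window length.
    """
    if rate_floor <= 0:
        raise ConfigError("rate_floor must be positive")
    lat_bin = int(latency_ms)  # bin whose center is latency_ms
    y = psth.smooth_wide
    if lat_bin >= y.size:
        raise DataFormatError("latency outside the PSTH window")
    if y[lat_bin] < rate_floor:
        logger.warning("latency bin already below rate floor; decay set to 0")
        return 0.0, False
    below = np.flatnonzero(y[lat_bin:] < rate_floor)
    if below.size == 0:
        return float(PSTH_WINDOW_MS - latency_ms), True
    first = lat_bin + int(below[0])
    return float((first + 0.5) - latency_ms), False


def local_response_probability(
    success: np.ndarray | pd.Series,
    index: int,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> float:
    """Fraction of successes among the neighbors of ``index`` (self excluded).

    At the edges of the series the window truncates and the denominator
    is the actual neighbor count.
    """
    if half_width < 1:
        raise ConfigError("half_width must be >= 1")
    s = np.asarray(success, dtype=bool)
    n = s.size
    if n < 2:
        raise DataFormatError("need at least 2 stimuli for a local probability")
    if not 0 <= index < n:
        raise DataFormatError("index out of range")
    lo = max(0, index - half_width)
    hi = min(n, index + half_width + 1)
    count = int(s[lo:hi].sum()) - int(s[index])
    denom = (hi - lo) - 1
    return count / denom


def local_probabilities(success: np.ndarray, half_width: int = DEFAULT_HALF_WIDTH) -> np.ndarray:
    """Vectorized :func:`local_response_probability` over all indices."""
    s = np.asarray(success, dtype=np.float64)
    n = s.size
    if n < 2:
        raise DataFormatError("need at least 2 stimuli for a local probability")
    csum = np.concatenate([[0.0], np.cumsum(s)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_width)
    hi = np.minimum(n, idx + half_width + 1)
    count = csum[hi] - csum[lo] - s
    denom = (hi - lo) - 1
    return count / denom


def compute_features(
    spikes: SpikeTrainSet,
    table: pd.DataFrame,
    wide_width_ms: int = DEFAULT_WIDE_MS,
    rate_floor: float = DEFAULT_RATE_FLOOR,
    prominence_frac: float | None = DEFAULT_PROMINENCE,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """Fill latency/decay/censoring/local-probability columns of a response table.

    Successful stimuli whose 1500 ms window would overrun the recording
    end are demoted to missing features (logged), not errors.
    """
    table = table.copy()
    n = len(table)
    lat = np.full(n, np.nan)
    dec = np.full(n, np.nan)
    cen = np.zeros(n, dtype=bool)
    for i in range(n):
        if not table["success"].iat[i]:
            continue
        t = float(table["stim_time_s"].iat[i])
        try:
            psth = build_psth(spikes, t, wide_width_ms)
            lat[i] = latency(psth, prominence_frac)
            dec[i], cen[i] = decay_duration(psth, lat[i], rate_floor)
        except DataFormatError as exc:
            logger.warning("stimulus %d at %.3f s: %s", i, t, exc)
            lat[i] = np.nan
            dec[i] = np.nan
    table["latency_ms"] = lat
    table["decay_ms"] = dec
    table["censored_decay"] = cen
    table["local_prob"] = local_probabilities(table["success"].to_numpy(), half_width)
    return table
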