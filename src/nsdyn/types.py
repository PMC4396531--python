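"""Core containers for MEA recordings and derived network-spike data.

Conventions used throughout the package:

* time is in **seconds** in every file and container;
* firing rates are **network-summed spikes per millisecond** (all
  electrodes pooled), matching the 0.15 spikes/ms rate floor used for
  decay measurement;
* binning intervals are half-open ``[start, end)``; the bin index of a
  time ``t`` is ``floor((t - start) / width)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

#: Column order of a persisted response table.
RESPONSE_COLUMNS = [
    "stim_index",
    "stim_time_s",
    "success",
    "ns_peak_time_s",
    "latency_ms",
    "decay_ms",
    "censored_decay",
    "local_prob",
]


@dataclass
class SpikeTrainSet:
    """Electrode-resolved spike timestamps for one recording session.

    Events are stored globally time-sorted.  ``electrode_ids`` and
    ``times`` are parallel arrays; electrode identity is carried along
    but no analysis stage in this package uses it.
    """

    electrode_ids: np.ndarray
    times: np.ndarray
    duration: float
    n_electrodes: int

    def __post_init__(self) -> None:
        self.electrode_ids = np.asarray(self.electrode_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.electrode_ids.shape != self.times.shape:
            raise DataFormatError("electrode_ids and times must be parallel arrays")
        if self.times.size and not np.all(np.diff(self.times) >= 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.electrode_ids = self.electrode_ids[order]
        if self.times.size:
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise DataFormatError("spike times must lie within [0, duration]")
            if self.electrode_ids.min() < 0 or self.electrode_ids.max() >= self.n_electrodes:
                raise DataFormatError("electrode_id out of range [0, n_electrodes)")
        if self.duration <= 0:
            raise DataFormatError("duration must be positive")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class StimulusTrain:
    """Ordered stimulus onset times, with optional amplitude metadata.

    ``period`` is the nominal inter-stimulus interval (median of
    successive onset differences); it is NaN when fewer than two onsets
    are present.
    """

    onsets: np.ndarray
    amplitude_mv: np.ndarray | None = None
    period: float = float("nan")

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.onsets.size and self.onsets.min() < 0:
            raise DataFormatError("stimulus onsets must be non-negative")
        d = np.diff(self.onsets)
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            raise DataFormatError(
                f"stimulus onsets not strictly increasing at index {int(bad[0]) + 1}"
            )
        if np.isnan(self.period):
            self.period = float(np.median(d)) if d.size else float("nan")
        if self.amplitude_mv is not None:
            self.amplitude_mv = np.asarray(self.amplitude_mv, dtype=np.float64)

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass
class NSTrain:
    """Detected network-spike events.

    ``peak_times`` are the fiducial timestamps used by all counting
    statistics; ``onset_times`` mark the first supra-threshold bin edge
    of each event; ``peak_rates`` are in network-summed spikes/ms.
    """

    peak_times: np.ndarray
    peak_rates: np.ndarray
    onset_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=np.float64)
        self.peak_rates = np.asarray(self.peak_rates, dtype=np.float64)
        self.onset_times = np.asarray(self.onset_times, dtype=np.float64)
        if not (self.peak_times.size == self.peak_rates.size == self.onset_times.size):
            raise DataFormatError("NSTrain arrays must be parallel")
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise DataFormatError("NS peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_times.size)


@dataclass
class RateSeries:
    """Population firing rate, binned.  Values are spikes/ms per bin."""

    start: float          # s
    bin_width_ms: float
    values: np.ndarray    # spikes/ms, length ceil(duration / bin_width)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def bin_centers_s(self) -> np.ndarray:
        w = self.bin_width_ms / 1000.0
        return self.start + (np.arange(self.values.size) + 0.5) * w


@dataclass
class PSTH:
    """Post-stimulus time histogram over a 1500 ms window at 1 ms bins.

    ``raw`` is the unsmoothed rate, ``smooth5`` its 5 ms moving average
    (used for latency), and ``smooth_wide`` a wider moving average
    (30-100 ms, used for decay measurement).
    """

    stim_time: float
    raw: np.ndarray
    smooth5: np.ndarray
    smooth_wide: np.ndarray
    wide_width_ms: int
    bin_width_ms: float = 1.0
    window_ms: int = 1500


@dataclass
class FanoCurve:
    """FF(T) = var/mean of window counts over a log-spaced T grid."""

    T: np.ndarray          # s, increasing
    ff: np.ndarray
    n_windows: np.ndarray  # complete windows available at each T
    duration: float

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        self.ff = np.asarray(self.ff, dtype=np.float64)
        self.n_windows = np.asarray(self.n_windows, dtype=np.int64)


@dataclass
class PowerLawFit:
    """OLS fit of log10 FF on log10 T: FF ~ alpha * T**beta."""

    alpha: float
    beta: float
    t_lo: float
    t_hi: float
    r2: float
    n_points: int


@dataclass
class ACF:
    """Serial-index autocorrelation with an optional warped (seconds) axis."""

    lags: np.ndarray
    rho: np.ndarray
    warped_lag_s: np.ndarray | None = None


@dataclass
class SerialSeries:
    """One scalar per successful response, in stimulus order."""

    values: np.ndarray
    response_times: np.ndarray  # s, time of each retained response

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.response_times = np.asarray(self.response_times, dtype=np.float64)
        if self.values.shape != self.response_times.shape:
            raise DataFormatError("values and response_times must be parallel")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class Trajectory:
    """Latency-decay plane trajectory of consecutive successful responses."""

    points: np.ndarray                     # (n, 2): latency_ms, decay_ms
    smoothed: np.ndarray                   # same shape
    segments: list = field(default_factory=list)  # [(lo, hi), ...) index ranges


def empty_response_table(n: int) -> pd.DataFrame:
    """Allocate a response table with NaN feature columns for n stimuli."""
    return pd.DataFrame(
        {
            "stim_index": np.arange(n, dtype=np.int64),
            "stim_time_s": np.full(n, np.nan),
            "success": np.zeros(n, dtype=bool),
            "ns_peak_time_s": np.full(n, np.nan),
            "latency_ms": np.full(n, np.nan),
            "decay_ms": np.full(n, np.nan),
            "censored_decay": np.zeros(n, dtype=bool),
            "local_prob": np.full(n, np.nan),
        }
    )
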