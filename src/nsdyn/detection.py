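"""Network-spike detection from the population firing rate.

A network spike (NS) is a transient (~100 ms) synchronized burst of
population firing.  Detection follows the classic recipe: bin the
network-summed firing rate (3 ms bins by default), threshold it, and
treat each maximal supra-threshold run as one event, merging runs that
are separated by less than a merge window (200 ms default, well below
the 1-10 s network refractory period).

The event fiducial used by all counting statistics downstream is the
**peak time** (center of the earliest bin attaining the run maximum;
ties broken to the earliest bin for determinism).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import NSTrain, RateSeries, SpikeTrainSet, StimulusTrain, empty_response_table

DEFAULT_BIN_MS = 3.0
DEFAULT_THRESHOLD = 0.15   # spikes/ms, network-summed
DEFAULT_MERGE_MS = 200.0
DEFAULT_PAIR_WINDOW_S = 1.0


def population_rate(spikes: SpikeTrainSet, bin_width_ms: float = DEFAULT_BIN_MS) -> RateSeries:
    """Bin the network-summed firing rate.

    ``values[k]`` is the spike count of all electrodes in bin ``k``
    divided by the bin width, in spikes/ms, so that
    ``sum(values) * bin_width == total spike count``.
    """
    if bin_width_ms <= 0:
        raise ConfigError("bin_width_ms must be positive")
    w_s = bin_width_ms / 1000.0
    n_bins = int(np.ceil(spikes.duration / w_s))
    if spikes.n_spikes == 0:
        return RateSeries(0.0, bin_width_ms, np.zeros(n_bins))
    idx = np.floor(spikes.times / w_s).astype(np.int64)
    # a spike exactly at t == duration belongs to the last bin
    np.clip(idx, 0, n_bins - 1, out=idx)
    counts = np.bincount(idx, minlength=n_bins)
    return RateSeries(0.0, bin_width_ms, counts / bin_width_ms)


def adaptive_threshold(
    rate: RateSeries,
    stims: StimulusTrain | None = None,
    window_s: float = 1.0,
    n_sd: float = 3.0,
) -> float:
    """Baseline mean + ``n_sd`` SD, computed over bins outside stimulus windows."""
    mask = np.ones(rate.values.size, dtype=bool)
    if stims is not None and len(stims):
        centers = rate.bin_centers_s()
        for t in stims.onsets:
            lo, hi = np.searchsorted(centers, [t, t + window_s])
            mask[lo:hi] = False
    baseline = rate.values[mask]
    if baseline.size == 0:
        raise ConfigError("no baseline bins outside stimulus windows")
    return float(baseline.mean() + n_sd * baseline.std())


def detect_network_spikes(
    rate: RateSeries,
    threshold: float = DEFAULT_THRESHOLD,
    merge_window_ms: float = DEFAULT_MERGE_MS,
) -> NSTrain:
    """Threshold the rate series into an NS train.

    Each maximal run of supra-threshold bins yields one event; runs
    separated by less than ``merge_window_ms`` are merged.  Per event:
    onset = left edge of the first supra-threshold bin, peak = center
    of the earliest bin attaining the run maximum, peak_rate = that
    maximum.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    if merge_window_ms < 0:
        raise ConfigError("merge_window_ms must be non-negative")
    v = rate.values
    supra = np.flatnonzero(v > threshold)
    duration = rate.start + v.size * rate.bin_width_ms / 1000.0
    if supra.size == 0:
        return NSTrain(np.empty(0), np.empty(0), np.empty(0), duration)
    # maximal runs of consecutive supra-threshold bins
    breaks = np.flatnonzero(np.diff(supra) > 1)
    starts = np.concatenate([[supra[0]], supra[breaks + 1]])
    ends = np.concatenate([supra[breaks], [supra[-1]]])  # inclusive
    # merge runs whose inter-run gap is shorter than the merge window
    gap_bins = max(int(np.ceil(merge_window_ms / rate.bin_width_ms)), 0)
    merged_starts = [starts[0]]
    merged_ends = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged_ends[-1] - 1 < gap_bins:
            merged_ends[-1] = e
        else:
            merged_starts.append(s)
            merged_ends.append(e)
    w_s = rate.bin_width_ms / 1000.0
    onset_times = np.empty(len(merged_starts))
    peak_times = np.empty(len(merged_starts))
    peak_rates = np.empty(len(merged_starts))
    for k, (s, e) in enumerate(zip(merged_starts, merged_ends)):
        run = v[s : e + 1]
        pk = s + int(np.argmax(run))  # argmax returns the earliest max
        onset_times[k] = rate.start + s * w_s
        peak_times[k] = rate.start + (pk + 0.5) * w_s
        peak_rates[k] = v[pk]
    return NSTrain(peak_times, peak_rates, onset_times, duration)


def pair_stimuli(
    ns: NSTrain,
    stims: StimulusTrain,
    window_s: float = DEFAULT_PAIR_WINDOW_S,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assign NS events to stimuli.

    A stimulus is a *success* iff at least one NS onset lies in
    ``[stim, stim + window)``; the earliest such NS is assigned, and an
    NS already assigned to one stimulus is never reassigned.  Returns
    the response table (feature columns left NaN) and the per-NS
    assignment vector (stimulus index, -1 = spontaneous).
    """
    if window_s <= 0:
        raise ConfigError("pairing window must be positive")
    if len(stims) > 1 and stims.period < window_s:
        warnings.warn(
            "stimulus period shorter than pairing window; "
            "earliest-stimulus-wins assignment",
            stacklevel=2,
        )
    n_stim = len(stims)
    success = np.zeros(n_stim, dtype=bool)
    peak = np.full(n_stim, np.nan)
    assigned = np.full(len(ns), -1, dtype=np.int64)
    j = 0  # index of the earliest not-yet-assigned NS
    onsets = ns.onset_times
    for i, t in enumerate(stims.onsets):
        while j < len(ns) and onsets[j] < t:
            j += 1
        if j < len(ns) and onsets[j] < t + window_s:
            success[i] = True
            peak[i] = ns.peak_times[j]
            assigned[j] = i
            j += 1
    table = empty_response_table(n_stim)
    table["stim_time_s"] = stims.onsets
    table["success"] = success
    table["ns_peak_time_s"] = peak
    return table, assigned
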