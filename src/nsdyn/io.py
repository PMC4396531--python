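"""Readers and writers for the package's plain-text (TSV) interchange files.

All files are tab-separated with an optional block of ``#``-prefixed
comment lines before the header.  Two comments carry metadata overrides
for spike tables and NS trains::

    # duration=3600
    # n_electrodes=60

Absent values are serialized as ``NA``.  Times round-trip at 1e-6 s and
rates at 1e-6 spikes/ms precision.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .types import RESPONSE_COLUMNS, NSTrain, SpikeTrainSet, StimulusTrain

_TIME_FMT = "%.6f"


def _split_comments(path: Path) -> tuple[dict, list[str], list[int]]:
    """Return (metadata, data lines incl. header, 1-based line numbers)."""
    meta: dict[str, float] = {}
    lines: list[str] = []
    numbers: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key in ("duration", "n_electrodes"):
                        try:
                            meta[key] = float(val.strip())
                        except ValueError as exc:
                            raise DataFormatError(
                                f"{path}: bad metadata comment at line {lineno}: {line!r}"
                            ) from exc
                continue
            lines.append(line)
            numbers.append(lineno)
    return meta, lines, numbers


def read_spike_table(path: str | Path) -> SpikeTrainSet:
    """Read a spike table (columns ``electrode_id``, ``time_s``).

    The reader emits globally time-sorted events.  ``duration`` defaults
    to the last spike time and ``n_electrodes`` to ``max(id) + 1``
    unless overridden by metadata comments.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: no such file")
    meta, lines, numbers = _split_comments(path)
    if not lines:
        raise DataFormatError(f"{path}: no spikes")
    header = lines[0].split("\t")
    if header[:2] != ["electrode_id", "time_s"]:
        raise DataFormatError(
            f"{path}: expected header 'electrode_id\\ttime_s', got {lines[0]!r}"
        )
    if len(lines) == 1:
        raise DataFormatError(f"{path}: no spikes")
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(lines[1:])),
            sep="\t",
            header=None,
            names=["electrode_id", "time_s"],
            dtype={"electrode_id": np.int64, "time_s": np.float64},
        )
        bad = np.flatnonzero(df["time_s"].to_numpy() < 0)
        if bad.size:
            raise DataFormatError(
                f"{path}: negative time at line {numbers[int(bad[0]) + 1]}"
            )
    except (ValueError, TypeError) as exc:
        if isinstance(exc, DataFormatError):
            raise
        # fall back to a row scan to name the offending line
        for line, lineno in zip(lines[1:], numbers[1:]):
            parts = line.split("\t")
            try:
                eid = int(parts[0])
                t = float(parts[1])
                if t < 0 or eid < 0:
                    raise ValueError
            except (ValueError, IndexError):
                raise DataFormatError(f"{path}: parse error at line {lineno}: {line!r}") from exc
        raise DataFormatError(f"{path}: parse error: {exc}") from exc
    ids = df["electrode_id"].to_numpy()
    times = df["time_s"].to_numpy()
    if ids.min() < 0:
        raise DataFormatError(f"{path}: negative electrode_id")
    duration = meta.get("duration", float(times.max()))
    n_electrodes = int(meta.get("n_electrodes", int(ids.max()) + 1))
    return SpikeTrainSet(ids, times, duration=duration, n_electrodes=n_electrodes)


def write_spike_table(spikes: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration={spikes.duration:.6f}\n")
        fh.write(f"# n_electrodes={spikes.n_electrodes}\n")
        fh.write("electrode_id\ttime_s\n")
        np.savetxt(
            fh,
            np.column_stack([spikes.electrode_ids, spikes.times]),
            fmt=["%d", _TIME_FMT],
            delimiter="\t",
        )


def read_stimulus_log(path: str | Path) -> StimulusTrain:
    """Read a stimulus log (``time_s`` and optional ``amplitude_mv``)."""
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: no such file")
    _, lines, _ = _split_comments(path)
    if not lines:
        raise DataFormatError(f"{path}: empty stimulus log")
    header = lines[0].split("\t")
    if header[0] != "time_s":
        raise DataFormatError(f"{path}: expected header starting with 'time_s'")
    has_amp = len(header) > 1 and header[1] == "amplitude_mv"
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(lines[1:])), sep="\t", header=None,
            names=header, dtype=np.float64,
        )
    except ValueError as exc:
        raise DataFormatError(f"{path}: parse error: {exc}") from exc
    onsets = df["time_s"].to_numpy()
    amp = df["amplitude_mv"].to_numpy() if has_amp else None
    return StimulusTrain(onsets, amplitude_mv=amp)


def write_stimulus_log(stims: StimulusTrain, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if stims.amplitude_mv is not None:
            fh.write("time_s\tamplitude_mv\n")
            np.savetxt(
                fh,
                np.column_stack([stims.onsets, stims.amplitude_mv]),
                fmt=[_TIME_FMT, "%.3f"],
                delimiter="\t",
            )
        else:
            fh.write("time_s\n")
            np.savetxt(fh, stims.onsets[:, None], fmt=_TIME_FMT)


def write_ns_train(ns: NSTrain, path: str | Path, assigned: np.ndarray | None = None) -> None:
    """Write an NS train; ``assigned`` is the per-event stimulus index (-1 = spontaneous)."""
    path = Path(path)
    if assigned is None:
        assigned = np.full(len(ns), -1, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write(f"# duration={ns.duration:.6f}\n")
        fh.write("peak_time_s\tpeak_rate\tonset_time_s\tassigned_stim\n")
        for pt, pr, ot, a in zip(ns.peak_times, ns.peak_rates, ns.onset_times, assigned):
            fh.write(f"{pt:.6f}\t{pr:.6f}\t{ot:.6f}\t{int(a)}\n")


def read_ns_train(path: str | Path) -> tuple[NSTrain, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: no such file")
    meta, lines, _ = _split_comments(path)
    if not lines or lines[0].split("\t")[:3] != ["peak_time_s", "peak_rate", "onset_time_s"]:
        raise DataFormatError(f"{path}: bad NS-train header")
    df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t")
    if "duration" not in meta:
        raise DataFormatError(f"{path}: missing '# duration=' comment")
    ns = NSTrain(
        df["peak_time_s"].to_numpy(),
        df["peak_rate"].to_numpy(),
        df["onset_time_s"].to_numpy(),
        duration=meta["duration"],
    )
    assigned = (
        df["assigned_stim"].to_numpy(dtype=np.int64)
        if "assigned_stim" in df
        else np.full(len(ns), -1, dtype=np.int64)
    )
    return ns, assigned


def write_response_table(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a response table; absent values become ``NA``."""
    path = Path(path)
    out = table.loc[:, RESPONSE_COLUMNS].copy()
    out["success"] = out["success"].astype(int)
    out["censored_decay"] = out["censored_decay"].astype(int)
    for col in ("stim_time_s", "ns_peak_time_s", "latency_ms", "decay_ms", "local_prob"):
        out[col] = out[col].map(lambda v: "NA" if pd.isna(v) else f"{v:.6f}")
    try:
        out.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def read_response_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: no such file")
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    df["stim_index"] = df["stim_index"].astype(np.int64)
    df["success"] = df["success"].astype(bool)
    df["censored_decay"] = df["censored_decay"].fillna(0).astype(bool)
    return df.loc[:, RESPONSE_COLUMNS]
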