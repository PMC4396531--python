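"""End-to-end orchestration: simulate -> detect -> features -> fano -> serial.

Every run writes plain-text stage outputs plus ``manifest.json`` with
the effective configuration, per-stage output paths and SHA-256
digests, and collected warnings.  Identical configuration and seed
give identical digests.  A stage failure leaves the completed stages'
outputs in place and records the failing stage in the manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import detection, fano, features, io, serial
from .config import RunConfig, load_config
from .errors import NsdynError, StageError
from .synth import generate_recording, write_truth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "features", "fano", "serial")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> dict:
    """Execute the pipeline described by a TOML config; return the manifest."""
    cfg = load_config(config_path)
    return run_pipeline_config(cfg, out_dir)


def run_pipeline_config(cfg: RunConfig, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("effective config: %s", json.dumps(cfg.snapshot(), sort_keys=True))
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.snapshot(),
        "outputs": {},
        "warnings": [],
        "failed_stage": None,
    }
    ana = cfg.analysis

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            if cfg.simulate:
                spikes, stims, truth = generate_recording(cfg.synth)
                io.write_spike_table(spikes, out / "spikes.tsv")
                io.write_stimulus_log(stims, out / "stimuli.tsv")
                write_truth(truth, out / "truth.tsv")
                record("spikes", out / "spikes.tsv")
                record("stimuli", out / "stimuli.tsv")
                record("truth", out / "truth.tsv")
            else:
                spikes = io.read_spike_table(out / "spikes.tsv")
                stims = io.read_stimulus_log(out / "stimuli.tsv")

            stage = "detect"
            rate = detection.population_rate(spikes, ana.bin_ms)
            ns = detection.detect_network_spikes(rate, ana.threshold, ana.merge_ms)
            table, assigned = detection.pair_stimuli(ns, stims, ana.pair_window_s)
            io.write_ns_train(ns, out / "ns_train.tsv", assigned)
            record("ns_train", out / "ns_train.tsv")

            stage = "features"
            table = features.compute_features(
                spikes,
                table,
                wide_width_ms=ana.wide_ms,
                rate_floor=ana.floor,
                prominence_frac=ana.prominence_frac,
                half_width=ana.half_width,
            )
            io.write_response_table(table, out / "responses.tsv")
            record("responses", out / "responses.tsv")

            stage = "fano"
            curve = fano.fano_curve(
                ns,
                t_min=ana.tmin,
                t_max=ana.tmax if ana.tmax > 0 else None,
                points_per_decade=ana.ppd,
                min_windows=ana.min_windows,
            )
            fit = fano.fit_powerlaw(curve, ana.fit_range())
            with open(out / "fano.tsv", "w") as fh:
                fh.write("T_s\tff\tn_windows\n")
                for T, f, nw in zip(curve.T, curve.ff, curve.n_windows):
                    fh.write(f"{T:.6f}\t{f:.6f}\t{nw}\n")
                fh.write(
                    f"# fit alpha={fit.alpha:.6g} beta={fit.beta:.6g} "
                    f"range={fit.t_lo:.6g}:{fit.t_hi:.6g} r2={fit.r2:.4f}\n"
                )
            record("fano", out / "fano.tsv")
            manifest["fano_fit"] = asdict(fit)

            stage = "serial"
            lat_series = serial.extract_series(table, "latency_ms")
            max_lag = min(ana.max_lag, max(len(lat_series) - 2, 1))
            acf = serial.serial_autocorrelation(lat_series, max_lag)
            with open(out / "acf.tsv", "w") as fh:
                fh.write("lag\trho\twarped_s\n")
                for l, r in zip(acf.lags, acf.rho):
                    w = acf.warped_lag_s[l] if acf.warped_lag_s is not None else float("nan")
                    fh.write(f"{l}\t{r:.6f}\t{w:.6f}\n")
            record("acf", out / "acf.tsv")
            traj = serial.build_trajectory(table, ana.smooth, ana.segment)
            with open(out / "trajectory.tsv", "w") as fh:
                fh.write("latency_ms\tdecay_ms\tsmooth_latency_ms\tsmooth_decay_ms\n")
                for p, s in zip(traj.points, traj.smoothed):
                    fh.write(f"{p[0]:.6f}\t{p[1]:.6f}\t{s[0]:.6f}\t{s[1]:.6f}\n")
            record("trajectory", out / "trajectory.tsv")

        manifest["warnings"] = [str(w.message) for w in caught]
    except NsdynError as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
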