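"""Run configuration: validated tunables for every analysis stage.

Configs are flat TOML files with two optional tables::

    seed = 1
    simulate = true

    [synth]
    duration = 3600.0
    latent_mode = "ou"

    [analysis]
    threshold = 2.0
    wide_ms = 50

Unknown keys are rejected; the effective configuration (defaults
included) is logged verbatim at the start of every pipeline run.
"""
from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigError
from .synth import SynthConfig


@dataclass
class AnalysisConfig:
    """Tunables of detection, features, Fano and serial stages."""

    # detection
    bin_ms: float = 3.0
    threshold: float = 0.15       # spikes/ms; "adaptive" handled by the CLI
    merge_ms: float = 200.0
    pair_window_s: float = 1.0
    # response features
    wide_ms: int = 50
    floor: float = 0.15
    prominence: float = 0.5       # <= 0 means "global argmax" mode
    half_width: int = 10
    # fano
    tmin: float = 0.05
    tmax: float = 0.0             # 0 = auto (duration / min_windows)
    ppd: int = 20
    min_windows: int = 50
    fit: str = "auto"             # "auto" (post-minimum) or "lo:hi"
    # serial
    max_lag: int = 200
    smooth: int = 11
    segment: int = 50
    log_plane: bool = True

    def __post_init__(self) -> None:
        if self.bin_ms <= 0 or self.pair_window_s <= 0:
            raise ConfigError("bin_ms and pair_window_s must be positive")
        if not 30 <= self.wide_ms <= 100:
            raise ConfigError("wide_ms must lie in [30, 100]")
        if self.half_width < 1:
            raise ConfigError("half_width must be >= 1")
        if self.fit != "auto":
            self.fit_range()  # validate format eagerly
        if self.smooth % 2 == 0:
            raise ConfigError("smooth window must be odd")

    def fit_range(self) -> tuple[float, float] | str:
        if self.fit == "auto":
            return "post-minimum"
        try:
            lo, hi = (float(v) for v in self.fit.split(":"))
        except ValueError as exc:
            raise ConfigError(f"fit must be 'auto' or 'lo:hi', got {self.fit!r}") from exc
        return lo, hi

    @property
    def prominence_frac(self) -> float | None:
        return None if self.prominence <= 0 else self.prominence


def _from_dict(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in [{where}]: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Full pipeline configuration: seed, optional simulation, analysis."""

    seed: int = 0
    simulate: bool = True
    synth: SynthConfig | None = None
    analysis: AnalysisConfig | None = None

    def __post_init__(self) -> None:
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)
        if self.analysis is None:
            self.analysis = AnalysisConfig()

    def snapshot(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate,
            "synth": asdict(self.synth),
            "analysis": asdict(self.analysis),
        }


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: no such config file")
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    top_known = {"seed", "simulate", "synth", "analysis"}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    synth_raw = dict(raw.get("synth", {}))
    synth_raw.setdefault("seed", seed)
    try:
        synth = _from_dict(SynthConfig, synth_raw, "synth")
        analysis = _from_dict(AnalysisConfig, dict(raw.get("analysis", {})), "analysis")
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig(
        seed=seed,
        simulate=bool(raw.get("simulate", True)),
        synth=synth,
        analysis=analysis,
    )
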