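"""TOML pipeline configuration with strict key validation.

A configuration file groups the knobs of every stage under one table per
stage; unknown keys are rejected so typos fail loudly instead of silently
falling back to defaults.  All physical quantities carry explicit units in
their key names (``*_nm``, ``*_hz``, ``*_n_m``, ...).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .maps import QCThresholds
from .synthetic import RingingConfig, SurfaceConfig
from .texture import SpectrumOptions

__all__ = ["ScreenOptions", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ScreenOptions:
    fdr: float = 0.05
    rho_gate: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if not 0.0 <= self.rho_gate <= 1.0:
            raise ValueError("rho_gate must lie in [0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "out"
    times_min: tuple[float, ...] = (5.0, 10.0, 30.0, 60.0, 120.0)
    n_cells: int = 20
    tau_min: float = 10.0
    ringing: RingingConfig = field(default_factory=RingingConfig)
    surface: SurfaceConfig = field(default_factory=SurfaceConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    spectrum: SpectrumOptions = field(default_factory=SpectrumOptions)
    screen: ScreenOptions = field(default_factory=ScreenOptions)


_SECTIONS = {
    "ringing": RingingConfig,
    "surface": SurfaceConfig,
    "qc": QCThresholds,
    "spectrum": SpectrumOptions,
    "screen": ScreenOptions,
}
_TOP_KEYS = {"seed", "out_dir", "times_min", "n_cells", "tau_min"}


def _build(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    if "plane_tilt" in data:
        data = dict(data, plane_tilt=tuple(data["plane_tilt"]))
    return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in _TOP_KEYS if k in raw}
    if "times_min" in kwargs:
        kwargs["times_min"] = tuple(float(t) for t in kwargs["times_min"])
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = _build(cls, raw[section], section)
    return PipelineConfig(**kwargs)
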