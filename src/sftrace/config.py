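"""Pipeline configuration: defaults, YAML overlay, strict key checking.

Every tunable of the mask, FA, SF and evaluation stages lives in one
:class:`PipelineConfig`; a resolved copy is written into every output
directory so results carry their provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from . import __version__
from .stressfibers import PenaltyConfig, SFPreprocessConfig

__all__ = [
    "MaskParams",
    "FAParams",
    "FitParams",
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Raised for unknown or malformed configuration keys."""


@dataclass(frozen=True)
class MaskParams:
    """Cell-mask stage parameters (defaults sized for 2048x2048 frames)."""

    dilation_radius: float = 4.0
    gaussian_sigma: float = 6.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area: float = 2000.0
    exclude_border: bool = True
    selector: str = "largest"
    select_label: int | None = None
    select_point: tuple[float, float] | None = None


@dataclass(frozen=True)
class FAParams:
    """FA segmentation parameters (defaults sized for 2048x2048 frames)."""

    median_radius: float = 2.0
    tophat_radius: float = 15.0
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area: float = 20.0
    max_area: float = 3000.0


@dataclass(frozen=True)
class FitParams:
    """Curve-search and acceptance parameters.

    The ``a`` grid spans ``[-grid_a_halfwidth, grid_a_halfwidth]`` at a chord
    of ``grid_a_ref_d`` px and scales inversely with the chord length.
    ``accept_threshold`` is on the preprocessed-intensity scale and was
    calibrated on the bundled default scene (see docs/methods.md).
    """

    grid_a_halfwidth: float = 0.02
    grid_a_n: int = 41
    grid_a_ref_d: float = 100.0
    grid_theta_max: float = 0.6
    grid_theta_n: int = 21
    n_samples_min: int = 64
    accept_threshold: float = 0.80
    d_max: float | None = None
    objective: str = "arith"


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of the mask -> FA -> SF -> evaluate pipeline."""

    mask: MaskParams = field(default_factory=MaskParams)
    fa: FAParams = field(default_factory=FAParams)
    sf_preprocess: SFPreprocessConfig = field(default_factory=SFPreprocessConfig)
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    fit: FitParams = field(default_factory=FitParams)
    seed: int = 0
    version: str = __version__


_SECTIONS = {
    "mask": MaskParams,
    "fa": FAParams,
    "sf_preprocess": SFPreprocessConfig,
    "penalty": PenaltyConfig,
    "fit": FitParams,
}
_TUPLE_KEYS = {"select_point"}


def _overlay_section(current, cls, values: dict, section: str):
    allowed = {f.name for f in fields(cls) if f.init}
    unknown = set(values) - allowed
    if unknown:
        raise ConfigError(f"unknown key '{section}.{sorted(unknown)[0]}' in config")
    coerced = {
        k: tuple(v) if k in _TUPLE_KEYS and v is not None else v for k, v in values.items()
    }
    return replace(current, **coerced)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, then overrides.

    Later sources win.  Unknown keys at any level raise :class:`ConfigError`
    naming the offending key.
    """
    cfg = PipelineConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _apply(cfg, raw)
    if overrides:
        cfg = _apply(cfg, overrides)
    return cfg


def _apply(cfg: PipelineConfig, values: dict) -> PipelineConfig:
    updates = {}
    for key, val in values.items():
        if key in _SECTIONS:
            if not isinstance(val, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            updates[key] = _overlay_section(getattr(cfg, key), _SECTIONS[key], val, key)
        elif key in ("seed", "version"):
            updates[key] = val
        else:
            raise ConfigError(f"unknown key '{key}' in config")
    return replace(cfg, **updates)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    payload = asdict(cfg)
    # t_rewind is fixed, not a free parameter
    payload["penalty"].pop("t_rewind", None)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
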