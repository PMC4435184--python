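"""Flat ``key = value`` configuration files for the study apparatus.

One file can carry any mix of scenario-sampling, calibration-grid, mesh and
rendering settings, using dotted keys grouped by component::

    ranges.d_min = 2.0
    ranges.d_max = 14.0
    calibration.sizes = 2, 8, 14
    mesh.fine_h = 1.0
    mesh.indent_mm = 2.0
    render.gain = 400

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses

from .fem import FemConfig
from .image import RenderConfig
from .phantom import CalibrationConfig, ScenarioRanges

__all__ = ["read_config", "write_config", "scenario_ranges", "calibration_config", "fem_config", "render_config"]


def _parse(value: str):
    value = value.strip()
    if "," in value:
        return tuple(_parse(v) for v in value.split(","))
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value


def read_config(path) -> dict:
    """Parse a flat key = value file into a dict (dotted keys preserved)."""
    out: dict = {}
    with open(path) as f:
        for lineno, raw in enumerate(f, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = _parse(value)
    return out


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        for key, value in cfg.items():
            if isinstance(value, tuple):
                value = ", ".join(str(v) for v in value)
            f.write(f"{key} = {value}\n")


def _section(cfg: dict, prefix: str) -> dict:
    return {k.split(".", 1)[1]: v for k, v in cfg.items() if k.startswith(prefix + ".")}


def _build(cls, fields: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(fields) - valid
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")
    return cls(**fields)


def scenario_ranges(cfg: dict) -> ScenarioRanges:
    """ranges.{d,h,E}_{min,max} -> ScenarioRanges."""
    s = _section(cfg, "ranges")
    kwargs = {}
    for name in ("d", "h", "E"):
        lo, hi = s.pop(f"{name}_min", None), s.pop(f"{name}_max", None)
        if lo is not None or hi is not None:
            default = getattr(ScenarioRanges(), f"{name}_range")
            kwargs[f"{name}_range"] = (
                default[0] if lo is None else lo,
                default[1] if hi is None else hi,
            )
    if s:
        raise ValueError(f"unknown ranges config keys: {sorted(s)}")
    return ScenarioRanges(**kwargs)


def calibration_config(cfg: dict) -> CalibrationConfig:
    return _build(CalibrationConfig, _section(cfg, "calibration"), "calibration")


def fem_config(cfg: dict) -> FemConfig:
    return _build(FemConfig, _section(cfg, "mesh"), "mesh")


def render_config(cfg: dict) -> RenderConfig:
    return _build(RenderConfig, _section(cfg, "render"), "render")
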