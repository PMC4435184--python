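"""Inclusion scenarios: the unknowns of the inverse problem plus fixed geometry.

A scenario describes one stiff spherical inclusion (a tumor surrogate) embedded
in a soft tissue slab that rests on a rigid base and is indented from above by
a square sensing probe.  The three estimation targets are the inclusion
diameter ``d`` (mm), its depth ``h`` (mm, measured from the tissue surface to
the *top* of the sphere) and its Young's modulus ``E_inc`` (kPa).  Everything
else — tissue extent and thickness, background modulus, Poisson ratio, probe
footprint — is fixed geometry shared by the whole study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InclusionScenario",
    "ScenarioRanges",
    "CalibrationConfig",
    "sample_scenarios",
    "calibration_scenarios",
    "scenarios_to_csv",
    "scenarios_from_csv",
]

_CSV_HEADER = [
    "id",
    "d_mm",
    "h_mm",
    "E_inc_kPa",
    "E_bg_kPa",
    "nu",
    "tissue_side_mm",
    "tissue_thickness_mm",
    "probe_side_mm",
]


@dataclass(frozen=True)
class InclusionScenario:
    """One forward-model input: inclusion parameters plus fixed geometry.

    Units: lengths in mm, moduli in kPa.  ``h`` is surface-to-inclusion-top.
    """

    d: float
    h: float
    E_inc: float
    E_bg: float = 5.0
    nu: float = 0.49
    tissue_side: float = 120.0
    tissue_thickness: float = 20.0
    probe_side: float = 25.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError(f"inclusion diameter must be positive, got d={self.d}")
        if self.h < 0:
            raise ValueError(f"inclusion depth must be nonnegative, got h={self.h}")
        if self.h + self.d > self.tissue_thickness + 1e-12:
            raise ValueError(
                "inclusion does not fit in the tissue: "
                f"h + d = {self.h + self.d} > tissue_thickness = {self.tissue_thickness}"
            )
        # equality permitted as the homogeneous verification limit
        if not (self.E_inc >= self.E_bg > 0):
            raise ValueError(
                f"moduli must satisfy E_inc >= E_bg > 0, got E_inc={self.E_inc}, E_bg={self.E_bg}"
            )
        if not (0 < self.nu < 0.5):
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got nu={self.nu}")
        if self.tissue_side <= 0 or self.tissue_thickness <= 0 or self.probe_side <= 0:
            raise ValueError("geometry dimensions must be positive")

    @property
    def params(self) -> tuple[float, float, float]:
        """The (d, h, E_inc) triple the inversion estimates."""
        return (self.d, self.h, self.E_inc)


@dataclass(frozen=True)
class ScenarioRanges:
    """Closed sampling intervals for (d, h, E_inc), same units as the scenario.

    Defaults bracket every concrete phantom value the study uses: inclusion
    sizes 2–14 mm, depths 3–12 mm in a 20 mm slab, moduli 20–120 kPa above a
    5 kPa background.
    """

    d_range: tuple[float, float] = (2.0, 14.0)
    h_range: tuple[float, float] = (3.0, 12.0)
    E_range: tuple[float, float] = (20.0, 120.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("d_range", self.d_range),
            ("h_range", self.h_range),
            ("E_range", self.E_range),
        ):
            if not lo <= hi:
                raise ValueError(f"{name} is empty: [{lo}, {hi}]")
        if self.d_range[0] <= 0:
            raise ValueError("d_range lower bound must be positive (d > 0)")
        if self.h_range[0] < 0:
            raise ValueError("h_range lower bound must be nonnegative (h >= 0)")
        if self.E_range[0] <= 0:
            raise ValueError("E_range lower bound must be positive")


def sample_scenarios(
    n: int,
    ranges: ScenarioRanges | None = None,
    seed: int = 0,
    **geometry: float,
) -> list[InclusionScenario]:
    """Draw ``n`` random scenarios, uniform and independent per parameter.

    Triples violating the containment constraint ``h + d <= tissue_thickness``
    are rejected and redrawn, so the marginals are uniform on the feasible set.
    Identical ``(n, ranges, seed)`` give an identical list.

    ``geometry`` overrides fixed-geometry fields (``E_bg``, ``nu``,
    ``tissue_side``, ``tissue_thickness``, ``probe_side``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or ScenarioRanges()
    thickness = float(geometry.get("tissue_thickness", 20.0))
    e_bg = float(geometry.get("E_bg", 5.0))
    if ranges.d_range[0] + ranges.h_range[0] > thickness:
        raise ValueError(
            "infeasible ranges: min d + min h = "
            f"{ranges.d_range[0] + ranges.h_range[0]} exceeds tissue_thickness = {thickness} "
            "(constraint h + d <= tissue_thickness can never hold)"
        )
    if ranges.E_range[0] <= e_bg and ranges.E_range[1] <= e_bg:
        raise ValueError(
            f"infeasible ranges: E_range {ranges.E_range} never exceeds background "
            f"modulus E_bg = {e_bg} (constraint E_inc > E_bg can never hold)"
        )

    rng = np.random.default_rng(seed)
    out: list[InclusionScenario] = []
    while len(out) < n:
        m = max(n - len(out), 16)
        d = rng.uniform(*ranges.d_range, size=m) if ranges.d_range[0] < ranges.d_range[1] else np.full(m, ranges.d_range[0])
        h = rng.uniform(*ranges.h_range, size=m) if ranges.h_range[0] < ranges.h_range[1] else np.full(m, ranges.h_range[0])
        e = rng.uniform(*ranges.E_range, size=m) if ranges.E_range[0] < ranges.E_range[1] else np.full(m, ranges.E_range[0])
        ok = (h + d <= thickness) & (e > e_bg)
        for di, hi, ei in zip(d[ok], h[ok], e[ok]):
            if len(out) == n:
                break
            out.append(InclusionScenario(d=float(di), h=float(hi), E_inc=float(ei), **geometry))
    return out


@dataclass(frozen=True)
class CalibrationConfig:
    """Grids for the 9-inclusion calibration phantom (3 sizes, 3 depths, 3 moduli).

    Each group of three varies one parameter while the other two sit at the
    defaults (d=8 mm, h=5 mm, E=120 kPa).
    """

    sizes: tuple[float, float, float] = (2.0, 8.0, 14.0)
    depths: tuple[float, float, float] = (3.0, 6.0, 9.0)
    moduli: tuple[float, float, float] = (40.0, 80.0, 120.0)
    d_default: float = 8.0
    h_default: float = 5.0
    E_default: float = 120.0

    def __post_init__(self) -> None:
        for name, grid in (("sizes", self.sizes), ("depths", self.depths), ("moduli", self.moduli)):
            if len(grid) != 3:
                raise ValueError(f"{name} grid must have exactly 3 values, got {len(grid)}")


def calibration_scenarios(
    config: CalibrationConfig | None = None, **geometry: float
) -> list[InclusionScenario]:
    """The 9 calibration-phantom scenarios: size, depth and hardness phantoms.

    Deterministic: three scenarios varying d only, three varying h only, three
    varying E only, in that order.
    """
    cfg = config or CalibrationConfig()
    out = []
    for d in cfg.sizes:
        out.append(InclusionScenario(d=d, h=cfg.h_default, E_inc=cfg.E_default, **geometry))
    for h in cfg.depths:
        out.append(InclusionScenario(d=cfg.d_default, h=h, E_inc=cfg.E_default, **geometry))
    for e in cfg.moduli:
        out.append(InclusionScenario(d=cfg.d_default, h=cfg.h_default, E_inc=e, **geometry))
    return out


def scenarios_to_csv(scenarios: Sequence[InclusionScenario], path_or_buf) -> None:
    # repr() floats round-trip bit-exactly through the CSV
    lines = [",".join(_CSV_HEADER)]
    for i, s in enumerate(scenarios):
        vals = (s.d, s.h, s.E_inc, s.E_bg, s.nu, s.tissue_side, s.tissue_thickness, s.probe_side)
        lines.append(str(i) + "," + ",".join(repr(float(v)) for v in vals))
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as f:
            f.write(text)


def scenarios_from_csv(path_or_buf) -> list[InclusionScenario]:
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    missing = set(_CSV_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"scenario CSV missing columns: {sorted(missing)}")
    return [
        InclusionScenario(
            d=row.d_mm,
            h=row.h_mm,
            E_inc=row.E_inc_kPa,
            E_bg=row.E_bg_kPa,
            nu=row.nu,
            tissue_side=row.tissue_side_mm,
            tissue_thickness=row.tissue_thickness_mm,
            probe_side=row.probe_side_mm,
        )
        for row in df.itertuples()
    ]
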