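"""Per-channel linear calibration between pixel features and FEM features.

The simulator measures probe deformation in mm / mm^2; the optical sensor
measures scattered-light pixels.  To use one inversion network for both, the
nine calibration-phantom inclusions are measured with both instruments and an
ordinary least-squares line is fitted per feature channel, pixels as the
predictor and FEM units as the response — deployment-time inputs are images,
while the network is trained in FEM feature units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .fem import FeatureTriple

__all__ = ["CalibrationMap", "fit_calibration", "apply_calibration", "save_calibration", "load_calibration"]

_CHANNELS = ("max", "total", "area")


@dataclass(frozen=True)
class CalibrationMap:
    """Three (slope, intercept) pairs mapping TSIS channels to FEM units."""

    slopes: tuple[float, float, float]
    intercepts: tuple[float, float, float]
    r2: tuple[float, float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not all(np.isfinite(self.slopes)) or not all(np.isfinite(self.intercepts)):
            raise ValueError("non-finite calibration coefficients")


def fit_calibration(
    tsis: Sequence[FeatureTriple], fem: Sequence[FeatureTriple]
) -> CalibrationMap:
    """OLS fit per channel: FEM feature = slope * TSIS feature + intercept."""
    if len(tsis) != len(fem):
        raise ValueError("tsis and fem lists must be paired (equal length)")
    if len(tsis) < 2:
        raise ValueError("calibration needs at least 2 paired points")
    X = np.array([t.as_array() for t in tsis])
    Y = np.array([f.as_array() for f in fem])
    slopes, intercepts, r2 = [], [], []
    for c, name in enumerate(_CHANNELS):
        if np.ptp(X[:, c]) == 0:
            raise ValueError(f"degenerate predictor: TSIS '{name}' channel has zero variance")
        res = stats.linregress(X[:, c], Y[:, c])
        slopes.append(float(res.slope))
        intercepts.append(float(res.intercept))
        r2.append(float(res.rvalue**2))
    return CalibrationMap(
        slopes=tuple(slopes), intercepts=tuple(intercepts), r2=tuple(r2), n_points=len(tsis)
    )


def apply_calibration(cmap: CalibrationMap, tsis: FeatureTriple) -> FeatureTriple:
    """Affine per-channel transform into FEM units; area floored at zero."""
    vals = cmap.slopes * tsis.as_array() + cmap.intercepts
    return FeatureTriple(
        f1=float(vals[0]), f2=float(vals[1]), f3=float(max(vals[2], 0.0)), unit_system="FEM"
    )


def save_calibration(cmap: CalibrationMap, path) -> None:
    """Plain-text serialization; round-trips bit-exactly (repr floats)."""
    with open(path, "w") as f:
        f.write("palpinv-calibration 1\n")
        f.write(f"n_points {cmap.n_points}\n")
        for name, s, b, r in zip(_CHANNELS, cmap.slopes, cmap.intercepts, cmap.r2):
            f.write(f"{name} {s!r} {b!r} {r!r}\n")


def load_calibration(path) -> CalibrationMap:
    with open(path) as f:
        if not f.readline().startswith("palpinv-calibration"):
            raise ValueError("not a palpinv calibration file")
        n = int(f.readline().split()[1])
        rows = {}
        for _ in range(3):
            name, s, b, r = f.readline().split()
            rows[name] = (float(s), float(b), float(r))
    return CalibrationMap(
        slopes=tuple(rows[c][0] for c in _CHANNELS),
        intercepts=tuple(rows[c][1] for c in _CHANNELS),
        r2=tuple(rows[c][2] for c in _CHANNELS),
        n_points=n,
    )
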