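"""Synthetic tactile-image rendering and the three pixel-feature extractors.

The optical sensor images light scattered where the waveguide deforms against
a stiff inclusion: brighter and larger blobs for bigger, stiffer, shallower
inclusions.  The renderer here is an explicit stand-in for that optics — an
affine deformation-to-intensity gain followed by a Gaussian point-spread blur
and additive sensor noise — chosen as the simplest monotone transfer that
preserves the ordering structure the downstream calibration and inversion
rely on.  It is a proxy, not a ray-traced model.

Pixel features (threshold ``k``, default 5):

* ``otsis1`` — pixel value at the intensity-weighted centroid of the above-k
  blob (falls back to the global maximum when no pixel exceeds k),
* ``otsis2`` — sum of all pixel values,
* ``otsis3`` — number of pixels above k.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .fem import DeformationField, FeatureTriple

__all__ = [
    "TactileImage",
    "RenderConfig",
    "render_tactile_image",
    "quantify_image",
    "read_image",
    "write_image",
]


@dataclass
class TactileImage:
    """8-bit grayscale tactile image with physical pixel pitch (mm/pixel)."""

    pixels: np.ndarray
    pitch_mm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RenderConfig:
    """Deformation-to-pixel transfer: gain (px per mm), blur, noise, size.

    The default gain of 400 px/mm puts the blob threshold k = 5 at 12.5 um of
    probe deformation — the detectability scale of the simulation-side area
    feature — and maps the excess-deformation range of the default forward
    model (up to roughly 0.1 mm) into the 8-bit range.  The probe footprint
    spans the full image width.
    """

    gain: float = 400.0
    blur_px: float = 8.0
    noise: float = 0.0
    seed: int = 0
    width: int = 1024
    height: int = 768

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.blur_px < 0 or self.noise < 0:
            raise ValueError("blur and noise must be nonnegative")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")


def render_tactile_image(field: DeformationField, cfg: RenderConfig | None = None) -> TactileImage:
    """Render a deformation field to a synthetic 8-bit tactile image.

    Deterministic for a fixed ``(field, cfg)`` pair: the noise is seeded.
    """
    cfg = cfg or RenderConfig()
    span_x = field.x[-1] - field.x[0]
    pitch = span_x / max(cfg.width - 1, 1)  # probe footprint spans the image width
    px = field.x[0] + np.arange(cfg.width) * pitch
    py = (np.arange(cfg.height) - (cfg.height - 1) / 2) * pitch
    interp = RegularGridInterpolator(
        (field.y, field.x), field.w, method="linear", bounds_error=False, fill_value=0.0
    )
    PX, PY = np.meshgrid(px, py)
    w = interp(np.column_stack([PY.ravel(), PX.ravel()])).reshape(cfg.height, cfg.width)
    intensity = cfg.gain * w
    if cfg.blur_px > 0:
        intensity = ndimage.gaussian_filter(intensity, cfg.blur_px, mode="constant")
    if cfg.noise > 0:
        rng = np.random.default_rng(cfg.seed)
        intensity = intensity + rng.normal(0.0, cfg.noise, intensity.shape)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return TactileImage(pixels=pixels, pitch_mm=pitch)


def quantify_image(img: TactileImage, k: int = 5, tsis1_mode: str = "centroid") -> FeatureTriple:
    """Extract the (max, total, area) pixel features at threshold ``k``.

    ``tsis1_mode="centroid"`` reads the first feature at the intensity-weighted
    centroid of the above-k region (the documented definition); ``"max"`` uses
    the plain global maximum for sensitivity checks.
    """
    if not 0 <= k <= 255:
        raise ValueError("threshold k must lie in [0, 255]")
    if tsis1_mode not in ("centroid", "max"):
        raise ValueError("tsis1_mode must be 'centroid' or 'max'")
    pix = img.pixels.astype(np.float64)
    mask = pix > k
    f2 = float(pix.sum())
    f3 = float(np.count_nonzero(mask))
    if tsis1_mode == "max" or not mask.any():
        f1 = float(pix.max())
    else:
        vals = pix[mask]
        rows, cols = np.nonzero(mask)
        ci = int(np.rint((rows * vals).sum() / vals.sum()))
        cj = int(np.rint((cols * vals).sum() / vals.sum()))
        f1 = float(pix[ci, cj])
    return FeatureTriple(f1=f1, f2=f2, f3=f3, unit_system="TSIS")


def write_image(img: TactileImage, path) -> None:
    """Write an 8-bit grayscale PNG/TIFF; lossless round-trip with read_image."""
    iio.imwrite(path, img.pixels)


def read_image(path, pitch_mm: float = 25.0 / 1024) -> TactileImage:
    """Read an 8-bit grayscale PNG/TIFF tactile image."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(
            "expected an 8-bit grayscale image, got a multi-channel image; "
            "convert to single-channel grayscale first"
        )
    if arr.dtype != np.uint8:
        raise ValueError(
            f"expected 8-bit pixel depth, got {arr.dtype}; convert to 8-bit grayscale first"
        )
    return TactileImage(pixels=arr, pitch_mm=pitch_mm)
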