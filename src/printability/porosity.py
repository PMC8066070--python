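"""Porosity by oil absorption and by image thresholding, plus their
cross-method regression.

The oil method infers bulk porosity from the relative weight gain after
immersion in paraffin oil; on the default wet basis the value is
``100 * (W_wet - W_dry) / W_wet``, bounded below 100% like a volume
fraction (dry basis selectable).  The image method thresholds an 8-bit
transmitted-light micrograph: bright pixels are open pores (light passes
through empty space), dark pixels solid material, and porosity is the
bright-pixel percentage.  The two are related by ordinary least squares of
image porosity on experimental porosity across a panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import stats
from skimage.filters import threshold_otsu

from .core import StatisticsError, ValidationError

__all__ = [
    "PoreImage",
    "PorosityRegression",
    "porosity_oil",
    "porosity_image",
    "regress_porosity",
]


@dataclass
class PoreImage:
    """2-D 8-bit grayscale raster with optional pixel size (um/pixel)."""

    pixels: np.ndarray
    scale: float | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 3:  # multi-channel: average luminance
            px = px.astype(float).mean(axis=2)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("image must be a non-empty 2-D raster")
        if px.min() < 0 or px.max() > 255:
            raise ValidationError("pixel values must lie in 0-255")
        self.pixels = px.astype(np.uint8)

    @classmethod
    def from_file(cls, path, scale: float | None = None) -> "PoreImage":
        """Read a PNG/TIFF image, converting multi-channel to luminance."""
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB")).astype(float).mean(axis=2) \
                if im.mode not in ("L", "I;16", "I") else np.asarray(im, dtype=float)
        if arr.max() > 255:  # 16-bit input
            arr = arr * (255.0 / arr.max())
        return cls(arr, scale=scale)

    def save(self, path) -> None:
        Image.fromarray(self.pixels, mode="L").save(path)


@dataclass
class PorosityRegression:
    """OLS of image porosity (y, %) on experimental porosity (x, %)."""

    slope: float
    intercept: float
    pearson_r: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise StatisticsError("regression needs n >= 3")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise StatisticsError("|r| must be <= 1")


def porosity_oil(weight_dry: float, weight_wet: float, basis: str = "wet") -> float:
    """Porosity (%) from the oil-absorption weight difference.

    ``basis="wet"`` (default) divides by the oil-soaked weight, bounding
    the value in [0, 100); ``basis="dry"`` divides by the dry weight.
    """
    if weight_dry <= 0:
        raise ValidationError("dry weight must be positive")
    if weight_wet < weight_dry:
        raise ValidationError(
            f"wet weight {weight_wet} < dry weight {weight_dry}: oil loss is unphysical")
    denom = weight_wet if basis == "wet" else weight_dry
    if basis not in ("wet", "dry"):
        raise ValidationError(f"basis must be 'wet' or 'dry', got {basis!r}")
    return 100.0 * (weight_wet - weight_dry) / denom


def porosity_image(image: PoreImage, threshold="otsu", pore_bright: bool = True) -> float:
    """Pore-area percentage of a thresholded micrograph.

    ``threshold`` is a gray level in 0-255 or ``"otsu"`` for automatic
    selection.  Pixels strictly above the threshold count as pore when
    ``pore_bright`` (transmitted light through empty space); pass
    ``pore_bright=False`` for reflected-light images with dark pores.
    """
    px = image.pixels
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValidationError(f"unknown threshold mode {threshold!r}")
        if px.min() == px.max():  # uniform image: no pore/solid contrast
            return 0.0
        thr = float(threshold_otsu(px))
    else:
        thr = float(threshold)
        if not (0 <= thr <= 255):
            raise ValidationError(f"threshold must lie in 0-255, got {thr}")
    pore = px > thr if pore_bright else px < thr
    return 100.0 * float(np.count_nonzero(pore)) / px.size


def regress_porosity(panel) -> PorosityRegression:
    """OLS regression of image porosity on experimental porosity."""
    pairs = [(r.porosity_exp, r.porosity_img) for r in panel
             if r.porosity_exp is not None and r.porosity_img is not None]
    if len(pairs) < 3:
        raise StatisticsError(
            f"porosity regression needs >= 3 complete pairs, have {len(pairs)}")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0:
        raise StatisticsError("porosity regression undefined: zero variance in x")
    lr = stats.linregress(x, y)
    return PorosityRegression(
        slope=float(lr.slope), intercept=float(lr.intercept),
        pearson_r=float(lr.rvalue), n=len(pairs))
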