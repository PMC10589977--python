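"""Image ingestion, cropping, polarity handling and background subtraction.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays of non-negative intensities;
* rows are the migration direction (larger row index = migrated farther);
* coordinates are 0-based, row-major, with half-open integer ranges;
* all computation assumes *signal-high* polarity — bands are bright on a
  dark background. Images where bands are dark on a light background (for
  example Ponceau-stained membranes photographed in transmission) are
  converted once, at read time, with the ``invert`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import disk
from scipy import ndimage

from .errors import InputError, ValidationError

#: Rec.709 luminance weights applied to RGB input.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

#: Default structuring-element radius (pixels) for rolling-ball subtraction.
DEFAULT_RADIUS = 50


@dataclass
class Raster:
    """A 2-D non-negative intensity image.

    Parameters
    ----------
    pixels
        ``H x W`` array of finite, non-negative intensities (arbitrary units).
    bit_depth_origin
        ``"8"``, ``"16"`` or ``"float"`` — the sample depth of the source
        file; informational only, all arithmetic is float64.
    polarity
        Always ``"signal-high"`` after ingestion; kept explicit so that the
        invariant is visible in the data model.
    """

    pixels: np.ndarray
    bit_depth_origin: str = "float"
    polarity: str = "signal-high"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("raster must be a 2-D H x W array with H,W >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("raster intensities must be finite")
        if np.any(px < 0):
            raise ValidationError("raster intensities must be non-negative")
        if self.bit_depth_origin not in ("8", "16", "float"):
            raise ValidationError("bit_depth_origin must be '8', '16' or 'float'")
        if self.polarity != "signal-high":
            raise ValidationError("internal rasters are always signal-high")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "Raster":
        return Raster(self.pixels.copy(), self.bit_depth_origin, self.polarity)


@dataclass(frozen=True)
class CropRect:
    """Axis-aligned crop rectangle; half-open in both directions."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("crop height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ValidationError("crop origin must be non-negative")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.top + self.height > h or self.left + self.width > w:
            raise ValidationError(
                f"crop rect {self.to_params()} exceeds image bounds {h}x{w}"
            )

    def compose(self, inner: "CropRect") -> "CropRect":
        """Rect equivalent to cropping by ``self`` and then by ``inner``."""
        inner.check_bounds((self.height, self.width))
        return CropRect(
            self.top + inner.top, self.left + inner.left, inner.height, inner.width
        )

    def to_params(self) -> dict:
        return {
            "top": self.top,
            "left": self.left,
            "height": self.height,
            "width": self.width,
        }

    @classmethod
    def from_params(cls, d: dict) -> "CropRect":
        return cls(int(d["top"]), int(d["left"]), int(d["height"]), int(d["width"]))


@dataclass(frozen=True)
class BackgroundSpec:
    """Whole-image background subtraction specification.

    ``rolling_ball`` estimates the background as the grayscale morphological
    opening of the image with a flat disk of the given ``radius`` and
    subtracts it. A flat (rather than hemispherical) structuring element is
    used deliberately: min/max filtering is exactly scale-equivariant, so
    downstream normalized values are invariant under global exposure changes.

    ``flat_percentile`` subtracts a single global intensity level, the given
    ``percentile`` (fraction in (0, 1]) of the intensity distribution,
    clamping at zero.
    """

    method: str = "none"
    radius: int | None = None
    percentile: float | None = None

    def __post_init__(self):
        if self.method not in ("none", "rolling_ball", "flat_percentile"):
            raise ValidationError(f"unknown background method {self.method!r}")
        if self.method == "rolling_ball":
            if self.radius is None or self.radius < 1:
                raise ValidationError("rolling_ball requires radius >= 1")
        if self.method == "flat_percentile":
            if self.percentile is None or not (0.0 < self.percentile <= 1.0):
                raise ValidationError("flat_percentile requires percentile in (0, 1]")

    def to_params(self) -> dict:
        d = {"method": self.method}
        if self.method == "rolling_ball":
            d["radius"] = int(self.radius)
        elif self.method == "flat_percentile":
            d["percentile"] = float(self.percentile)
        return d

    @classmethod
    def from_params(cls, d: dict) -> "BackgroundSpec":
        return cls(
            method=d.get("method", "none"),
            radius=d.get("radius"),
            percentile=d.get("percentile"),
        )


def read_image(path, invert: bool = False, page: int | None = None) -> Raster:
    """Read a grayscale or RGB image file into a signal-high :class:`Raster`.

    RGB input is reduced to Rec.709 luminance. With ``invert=True`` the
    polarity is flipped as ``max(pixels) - pixels``, which converts
    dark-bands-on-light images (e.g. Ponceau stains) to the internal
    signal-high convention.

    ``page`` selects a page from a multi-page TIFF; reading a multi-page
    file without it is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap all decoder failures
        raise InputError(f"could not read image {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        # stack of pages, not a color image
        if page is None:
            raise InputError(
                f"{path} is a multi-page TIFF ({arr.shape[0]} pages); "
                "select one with the page flag (--page)"
            )
        if not (0 <= page < arr.shape[0]):
            raise InputError(f"page {page} out of range for {path}")
        arr = arr[page]
    elif page is not None and arr.ndim == 2:
        if page != 0:
            raise InputError(f"page {page} requested but {path} has a single page")

    if arr.dtype == np.uint8:
        depth = "8"
    elif arr.dtype == np.uint16:
        depth = "16"
    else:
        depth = "float"

    px = np.asarray(arr, dtype=np.float64)
    if px.ndim == 3:  # RGB(A)
        px = px[..., :3] @ _LUMA
    if px.ndim != 2:
        raise InputError(f"unsupported image layout {arr.shape} in {path}")
    if invert:
        px = px.max() - px
    return Raster(px, bit_depth_origin=depth)


def crop(r: Raster, c: CropRect) -> Raster:
    """Return the half-open sub-grid selected by ``c``; ``r`` is unchanged."""
    c.check_bounds(r.shape)
    sub = r.pixels[c.top : c.top + c.height, c.left : c.left + c.width].copy()
    return Raster(sub, r.bit_depth_origin, r.polarity)


def _opening(px: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening with a flat disk: erosion followed by dilation."""
    footprint = disk(radius)
    eroded = ndimage.grey_erosion(px, footprint=footprint)
    return ndimage.grey_dilation(eroded, footprint=footprint)


def rolling_ball_background(r: Raster, radius: int) -> np.ndarray:
    """Background estimate: opening of the image with a flat disk."""
    h, w = r.shape
    if radius < 1:
        raise ValidationError("rolling-ball radius must be >= 1")
    if radius > min(h, w):
        raise ValidationError(
            f"rolling-ball radius {radius} exceeds the smaller image dimension {min(h, w)}"
        )
    return _opening(r.pixels, int(radius))


def subtract_background(r: Raster, spec: BackgroundSpec) -> Raster:
    """Subtract the background described by ``spec`` from a signal-high raster.

    The result is elementwise ``>= 0`` and ``<=`` the input (the opening is
    anti-extensive; the percentile subtraction clamps at zero).
    """
    if spec.method == "none":
        return r.copy()
    if spec.method == "rolling_ball":
        bg = rolling_ball_background(r, spec.radius)
        out = r.pixels - bg
        # anti-extensivity guarantees >= 0 up to float round-off
        np.clip(out, 0.0, None, out=out)
        return Raster(out, r.bit_depth_origin, r.polarity)
    if spec.method == "flat_percentile":
        level = np.percentile(r.pixels, 100.0 * spec.percentile)
        out = np.clip(r.pixels - level, 0.0, None)
        return Raster(out, r.bit_depth_origin, r.polarity)
    raise ValidationError(f"unknown background method {spec.method!r}")
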