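"""Raster I/O, processing-resolution standardization and color-space conversion.

A herbarium sheet arrives at archival resolution (typically >= 3000 x 4000 px).
All proposal/ranking/verification work happens on a downscaled *processing*
copy whose short side is fixed (default 1250 px, giving 1250 x 1875 for the
common 2:3 sheet).  ``SheetImage`` keeps both rasters plus the coordinate
mapping so detections can be reported in original-image coordinates.

Hue is quantized to 0-255 (not the 0-179 convention) so that every channel of
both color spaces shares a single 256-bin histogram domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageOps
from skimage.color import hsv2rgb
from skimage.transform import resize

logger = logging.getLogger(__name__)

MIN_SIDE = 125  # a processing raster must fit at least one 125 px window


class ImageDecodeError(ValueError):
    """Raised when a file cannot be decoded as an image."""


class InvalidImageError(ValueError):
    """Raised when an image violates pipeline preconditions."""


@dataclass
class SheetImage:
    """An RGB sheet raster with its processing-resolution copy.

    Attributes
    ----------
    pixels : ndarray, uint8, (H, W, 3)
        Processing-resolution raster (equals ``original`` until
        :func:`standardize` is applied).
    original : ndarray, uint8, (H, W, 3)
        The raster at provenance resolution, already rotated to portrait if
        the input was landscape.
    original_size, processing_size : (width, height) in px.
    scale_factors : (sx, sy)
        Elementwise ``original_size / processing_size``; maps processing
        coordinates to (portrait) original coordinates.
    portrait_rotation_cw : int
        Degrees (0 or 90) the as-loaded raster was rotated *clockwise* to
        enforce portrait orientation.
    """

    pixels: np.ndarray
    original: np.ndarray
    original_size: tuple[int, int]
    processing_size: tuple[int, int]
    scale_factors: tuple[float, float]
    portrait_rotation_cw: int = 0
    path: str | None = None
    loaded_size: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.loaded_size is None:
            self.loaded_size = self.original_size
        _validate_rgb(self.pixels)

    def to_original_box(self, box: tuple[float, float, float, float]) -> tuple[float, float, float, float]:
        """Map a processing-space box (x, y, w, h) to as-loaded coordinates."""
        x, y, w, h = box
        sx, sy = self.scale_factors
        xo, yo, wo, ho = x * sx, y * sy, w * sx, h * sy
        if self.portrait_rotation_cw == 90:
            # invert the clockwise portrait rotation: (xr, yr) = (H0 - y, x)
            lw, lh = self.loaded_size
            xo, yo, wo, ho = yo, lh - (xo + wo), ho, wo
        return (xo, yo, wo, ho)

    def to_processing_box(self, box: tuple[float, float, float, float]) -> tuple[float, float, float, float]:
        """Map an as-loaded box (x, y, w, h) into processing coordinates."""
        x, y, w, h = box
        if self.portrait_rotation_cw == 90:
            lw, lh = self.loaded_size
            x, y, w, h = lh - (y + h), x, h, w
        sx, sy = self.scale_factors
        return (x / sx, y / sy, w / sx, h / sy)


def _validate_rgb(pixels: np.ndarray) -> None:
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidImageError(f"expected an H x W x 3 raster, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise InvalidImageError(f"expected uint8 pixels, got {pixels.dtype}")


def from_array(pixels: np.ndarray, path: str | None = None) -> SheetImage:
    """Wrap an in-memory uint8 RGB raster as an unstandardized SheetImage."""
    pixels = np.ascontiguousarray(pixels)
    _validate_rgb(pixels)
    h, w = pixels.shape[:2]
    return SheetImage(
        pixels=pixels,
        original=pixels,
        original_size=(w, h),
        processing_size=(w, h),
        scale_factors=(1.0, 1.0),
        path=path,
    )


def load_image(path) -> SheetImage:
    """Read a JPEG/PNG/TIFF sheet image, honoring EXIF orientation.

    Grayscale input is replicated to 3 channels with a logged warning.
    """
    path = str(path)
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            if im.mode in ("L", "I;16", "I"):
                logger.warning("grayscale image %s: replicating to 3 channels", path)
                im = im.convert("L")
                arr = np.asarray(im, dtype=np.uint8)
                arr = np.stack([arr] * 3, axis=-1)
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, SyntaxError, ValueError) as exc:
        raise ImageDecodeError(f"cannot decode image file {path!r}: {exc}") from exc
    return from_array(arr, path=path)


def save_image(image: SheetImage | np.ndarray, path) -> None:
    """Write the original-resolution raster (or a bare array) to disk."""
    arr = image.original if isinstance(image, SheetImage) else image
    Image.fromarray(arr).save(str(path))


def standardize(image: SheetImage, target_short_side: int = 1250) -> SheetImage:
    """Return a copy with the processing raster's short side at *target_short_side*.

    Landscape inputs are first rotated 90 degrees clockwise (herbarium sheets
    are portrait); aspect ratio is preserved, so the long side is scaled
    proportionally and rounded to the nearest integer.
    """
    if target_short_side < MIN_SIDE:
        raise InvalidImageError(
            f"target_short_side must be >= {MIN_SIDE}, got {target_short_side}"
        )
    original = image.original
    rotation = image.portrait_rotation_cw
    h0, w0 = original.shape[:2]
    if w0 > h0:  # landscape -> portrait, clockwise
        original = np.ascontiguousarray(np.rot90(original, k=-1))
        rotation = 90
        h0, w0 = original.shape[:2]
    if min(w0, h0) < MIN_SIDE:
        raise InvalidImageError(
            f"image {image.path or '<memory>'} is {w0}x{h0}; "
            f"min side {MIN_SIDE} px required"
        )
    new_w = target_short_side
    new_h = int(round(h0 * target_short_side / w0))
    if (new_w, new_h) == (w0, h0):
        proc = original
    else:
        proc = resize(
            original, (new_h, new_w), order=1, anti_aliasing=(new_w < w0),
            preserve_range=True,
        )
        proc = np.clip(np.rint(proc), 0, 255).astype(np.uint8)
    return SheetImage(
        pixels=proc,
        original=original,
        original_size=(w0, h0),
        processing_size=(new_w, new_h),
        scale_factors=(w0 / new_w, h0 / new_h),
        portrait_rotation_cw=rotation,
        path=image.path,
        loaded_size=image.loaded_size,
    )


def to_hsv(pixels: np.ndarray) -> np.ndarray:
    """RGB uint8 -> HSV with every channel quantized to [0, 255].

    Hue is scaled from [0, 360) degrees to 0-255 so that H, S and V all share
    one 256-bin histogram domain (green, 120 deg, maps to ~85).  Vectorized
    single-precision implementation; agrees with the float reference
    conversion to within one quantization step per channel.
    """
    _validate_rgb(pixels)
    f = pixels.astype(np.float32)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    maxc = f.max(axis=-1)
    minc = f.min(axis=-1)
    delta = maxc - minc
    s = np.zeros_like(maxc)
    np.divide(delta, maxc, out=s, where=maxc > 0)
    hp = np.zeros_like(maxc)
    chroma = delta > 0
    rmax = chroma & (r >= maxc)
    gmax = chroma & ~rmax & (g >= maxc)
    bmax = chroma & ~rmax & ~gmax
    hp[rmax] = np.mod((g - b)[rmax] / delta[rmax], 6.0)
    hp[gmax] = (b - r)[gmax] / delta[gmax] + 2.0
    hp[bmax] = (r - g)[bmax] / delta[bmax] + 4.0
    out = np.empty(pixels.shape, dtype=np.uint8)
    out[..., 0] = np.clip(np.rint(hp * (255.0 / 6.0)), 0, 255)
    out[..., 1] = np.clip(np.rint(s * 255.0), 0, 255)
    out[..., 2] = maxc
    return out


def hsv_to_rgb(hsv_pixels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_hsv` (uint8 0-255 channels back to RGB uint8)."""
    rgb = hsv2rgb(hsv_pixels.astype(np.float64) / 255.0)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)
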