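"""Chart-driven post-processing: max-white balance and quadrant orientation.

Once the chart is located, its pure-white patch gives an in-image white
reference: scaling each channel so that patch maps to full intensity
(the "max white" rule, realized as gain = 255 / mean over the white region,
which is robust to compression noise) removes both color cast and
underexposure in one step.  The chart's quadrant relative to the image
center encodes sheet orientation: institutions place the chart in a fixed
corner, so the 90-degree rotation that returns it to the canonical quadrant
(default SE, configurable) rights a mis-rotated sheet losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imgio import SheetImage

# quadrant cycle under one 90-degree counterclockwise image rotation
_CCW_CYCLE = ["SE", "NE", "NW", "SW"]

MAX_GAIN = 8.0


class DegenerateRegionError(ValueError):
    """White region has a zero-mean channel; gains are undefined."""


class AmbiguousQuadrantError(ValueError):
    """Chart center sits exactly on an image center axis."""


@dataclass
class WhiteBalanceGains:
    gains: tuple[float, float, float]
    source: tuple[float, float, float, float]  # the white_region box used


@dataclass
class OrientationDecision:
    observed_quadrant: str
    target_quadrant: str
    rotation: int  # counterclockwise degrees in {0, 90, 180, 270}


def _crop_original(image: SheetImage, box) -> np.ndarray:
    # detection boxes are reported in as-loaded coordinates, so crop the
    # as-loaded raster (undoing any portrait rotation), not the working copy
    arr = _loaded_raster(image)
    x, y, w, h = box
    h_img, w_img = arr.shape[:2]
    x0, y0 = max(0, int(np.floor(x))), max(0, int(np.floor(y)))
    x1, y1 = min(w_img, int(np.ceil(x + w))), min(h_img, int(np.ceil(y + h)))
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"white region {box} lies outside the image")
    return arr[y0:y1, x0:x1]


def compute_gains(image: SheetImage, white_region) -> WhiteBalanceGains:
    """Per-channel gains 255 / mean(channel over white_region).

    Means are taken on the original-resolution raster so the archival image
    is what gets corrected.  Gains are clipped to (0, 8].
    """
    crop = _crop_original(image, white_region).astype(np.float64)
    means = crop.mean(axis=(0, 1))
    if np.any(means <= 0):
        raise DegenerateRegionError(
            f"white region has zero-mean channel(s): means {means.tolist()}"
        )
    gains = np.minimum(255.0 / means, MAX_GAIN)
    return WhiteBalanceGains(gains=tuple(float(g) for g in gains),
                             source=tuple(float(v) for v in white_region))


def apply_gains(image: SheetImage, gains: WhiteBalanceGains) -> SheetImage:
    """Multiply each channel by its gain; round and clip to [0, 255].

    Applied to both the original-resolution raster and the processing copy.
    """
    g = np.asarray(gains.gains)[None, None, :]

    def _scale(arr):
        return np.clip(np.rint(arr.astype(np.float64) * g), 0, 255).astype(np.uint8)

    new_original = _scale(image.original)
    if image.pixels is image.original:
        new_pixels = new_original
    else:
        new_pixels = _scale(image.pixels)
    return replace(image, pixels=new_pixels, original=new_original)


def quadrant_of(center: tuple[float, float], size: tuple[int, int]) -> str:
    """NW/NE/SW/SE of a point relative to the image center; exact ties error."""
    cx, cy = center
    w, h = size
    if cx == w / 2.0 or cy == h / 2.0:
        raise AmbiguousQuadrantError(
            f"chart center {center} lies on a center axis of a {w}x{h} image"
        )
    ns = "N" if cy < h / 2.0 else "S"
    ew = "W" if cx < w / 2.0 else "E"
    return ns + ew


def rotation_for(observed: str, target: str) -> int:
    """CCW degrees mapping *observed* quadrant onto *target* (unique in 0..270)."""
    k = (_CCW_CYCLE.index(target) - _CCW_CYCLE.index(observed)) % 4
    return k * 90


def orient(image: SheetImage, detection, target_quadrant: str = "SE"):
    """Rotate the sheet so the detected chart lands in the canonical quadrant.

    Rotation is a lossless multiple of 90 degrees, applied counterclockwise
    to the as-loaded original raster.  Returns ``(rotated SheetImage,
    OrientationDecision)``; the rotated image is unstandardized (processing
    copy reset), since its geometry changed.
    """
    if target_quadrant not in _CCW_CYCLE:
        raise ValueError(f"unknown quadrant {target_quadrant!r}")
    box = detection.reported_box()
    cx = box[0] + box[2] / 2.0
    cy = box[1] + box[3] / 2.0
    # detection boxes are in as-loaded coordinates
    h_img, w_img = _loaded_raster(image).shape[:2]
    observed = quadrant_of((cx, cy), (w_img, h_img))
    rot = rotation_for(observed, target_quadrant)
    decision = OrientationDecision(observed_quadrant=observed,
                                   target_quadrant=target_quadrant, rotation=rot)
    arr = _loaded_raster(image)
    if rot:
        arr = np.ascontiguousarray(np.rot90(arr, k=rot // 90))
    from .imgio import from_array  # local import to avoid a cycle at module load

    out = from_array(arr, path=image.path)
    return out, decision


def _loaded_raster(image: SheetImage) -> np.ndarray:
    """The raster in as-loaded orientation (undo the portrait rotation)."""
    if image.portrait_rotation_cw == 90:
        return np.ascontiguousarray(np.rot90(image.original, k=1))
    return image.original
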