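"""Synthetic herbarium sheets with planted color reference charts.

Real digitized sheets are light paper with dark pressed-plant material, text
labels, institutional logos and a small color reference chart (CRC) somewhere
on the sheet.  This module emulates those conditions so that training,
evaluation and the acceptance run need no downloads:

* a light, slightly noisy paper background;
* dark plant-like blob/stem clutter;
* label rectangles with text-like line fill;
* colorful logo blocks and ruler strips — the high-chroma regions known to
  distract a pure color-histogram ranker;
* a CRC rendered from a parameterized patch-grid template containing exactly
  one pure-white and one pure-black patch, pasted at a known position,
  optionally skewed (up to ~8 degrees) or partially occluded (<= 20%).

Photometric augmentations model capture variation: darkening, desaturation
and a white-balance cast, plus 90-degree sheet rotations and wrong-size
CRC-like decoy overlays.  White-balance multipliers are normalized so the
largest channel gain is the darkening factor: on an 8-bit render a gain above
1 would clip the white patch and make the cast unrecoverable, so casts are
expressed as relative attenuation, as a real under/mis-exposed capture is.

Every output is a pure function of the spec's seed (byte-identical rerenders).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import disk, polygon
from skimage.transform import rotate as _sk_rotate

from .imgio import save_image

# ---------------------------------------------------------------------------
# templates


@dataclass
class CRCTemplate:
    """A rows x cols grid of reference patch colors with a dark frame."""

    grid: np.ndarray          # (rows, cols, 3) uint8
    patch_px: int = 14        # side of one patch at render scale
    border_px: int = 3        # dark frame width
    name: str = "synthetic-25"
    frame_color: tuple[int, int, int] = (45, 45, 45)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.uint8)
        whites = np.all(self.grid == 255, axis=-1).sum()
        blacks = np.all(self.grid == 0, axis=-1).sum()
        if whites != 1 or blacks != 1:
            raise ValueError(
                "template must contain exactly one pure-white and one "
                f"pure-black patch (found {whites} white, {blacks} black)"
            )

    @property
    def side(self) -> int:
        r, c = self.grid.shape[:2]
        return max(r, c) * self.patch_px + 2 * self.border_px


# 25 patches: neutral ramp (incl. the mandatory pure white and pure black)
# plus saturated and natural hues, loosely in the spirit of commercial charts.
_PATCH_COLORS = [
    (255, 255, 255), (200, 200, 200), (150, 150, 150), (90, 90, 90), (0, 0, 0),
    (200, 30, 35), (60, 150, 70), (40, 60, 160), (230, 200, 40), (190, 60, 140),
    (60, 170, 180), (220, 120, 40), (110, 60, 140), (120, 80, 50), (230, 160, 170),
    (130, 40, 40), (130, 130, 50), (40, 120, 110), (40, 50, 100), (130, 170, 210),
    (200, 160, 130), (90, 110, 60), (120, 160, 200), (150, 110, 180), (180, 140, 110),
]


def default_template(patch_px: int = 14, border_px: int = 3) -> CRCTemplate:
    grid = np.array(_PATCH_COLORS, dtype=np.uint8).reshape(5, 5, 3)
    return CRCTemplate(grid=grid, patch_px=patch_px, border_px=border_px)


def render_template(template: CRCTemplate):
    """Rasterize a template.

    Returns (tile uint8, mask bool, white_center (x, y), black_center (x, y))
    with centers in tile coordinates.
    """
    rows, cols = template.grid.shape[:2]
    p, b = template.patch_px, template.border_px
    h, w = rows * p + 2 * b, cols * p + 2 * b
    tile = np.empty((h, w, 3), dtype=np.uint8)
    tile[:] = template.frame_color
    for r in range(rows):
        for c in range(cols):
            tile[b + r * p : b + (r + 1) * p, b + c * p : b + (c + 1) * p] = template.grid[r, c]
    mask = np.ones((h, w), dtype=bool)
    white_rc = np.argwhere(np.all(template.grid == 255, axis=-1))[0]
    black_rc = np.argwhere(np.all(template.grid == 0, axis=-1))[0]
    centers = {}
    for key, (r, c) in (("white", white_rc), ("black", black_rc)):
        centers[key] = (b + (c + 0.5) * p, b + (r + 0.5) * p)
    return tile, mask, centers["white"], centers["black"]


def _skew_template(tile, mask, centers_xy, angle_deg: float):
    """Rotate a rendered tile by a small angle (nearest-neighbor, exact colors)."""
    rot = _sk_rotate(tile.astype(float), angle_deg, resize=True, order=0,
                     cval=0.0, preserve_range=True)
    rot_mask = _sk_rotate(mask.astype(float), angle_deg, resize=True, order=0,
                          cval=0.0, preserve_range=True) > 0.5
    new_centers = []
    for cx, cy in centers_xy:
        marker = np.zeros(mask.shape, dtype=float)
        iy, ix = int(round(cy)), int(round(cx))
        marker[iy, ix] = 1.0
        m = _sk_rotate(marker, angle_deg, resize=True, order=0, cval=0.0,
                       preserve_range=True)
        my, mx = np.unravel_index(int(np.argmax(m)), m.shape)
        new_centers.append((float(mx), float(my)))
    return rot.astype(np.uint8), rot_mask, new_centers


# ---------------------------------------------------------------------------
# specs


@dataclass
class AugmentationParams:
    """Photometric / geometric capture variation applied to a rendered sheet."""

    darken: float = 1.0            # global exposure multiplier in [0.4, 1]
    desaturate: float = 0.0        # blend fraction toward luminance in [0, 1]
    wb_shift: tuple[float, float, float] = (1.0, 1.0, 1.0)  # cast, each in [0.6, 1.4]
    rotate_k: int = 0              # 90-degree CCW steps in {0, 1, 2, 3}
    overlay_crc: bool = False      # paste a wrong-size CRC-like decoy

    def __post_init__(self) -> None:
        if not (0.4 <= self.darken <= 1.0):
            raise ValueError("darken must lie in [0.4, 1]")
        if not (0.0 <= self.desaturate <= 1.0):
            raise ValueError("desaturate must lie in [0, 1]")
        if any(not (0.6 <= g <= 1.4) for g in self.wb_shift):
            raise ValueError("wb_shift components must lie in [0.6, 1.4]")
        if self.rotate_k not in (0, 1, 2, 3):
            raise ValueError("rotate_k must be one of 0..3")

    def effective_gains(self) -> tuple[float, float, float]:
        """Per-channel multipliers actually applied (cast normalized, <= 1)."""
        g = np.asarray(self.wb_shift, dtype=float)
        g = g / g.max()
        g = g * self.darken
        return tuple(float(v) for v in g)

    @classmethod
    def random(cls, rng: np.random.Generator, rotate: bool = True,
               overlay_prob: float = 0.2) -> "AugmentationParams":
        return cls(
            darken=float(rng.uniform(0.4, 1.0)),
            desaturate=float(rng.uniform(0.0, 1.0)),
            wb_shift=tuple(float(v) for v in rng.uniform(0.6, 1.4, size=3)),
            rotate_k=int(rng.integers(0, 4)) if rotate else 0,
            overlay_crc=bool(rng.random() < overlay_prob),
        )


@dataclass
class SheetSpec:
    """Full description of one synthetic sheet; the seed determines everything."""

    size: tuple[int, int] = (1250, 1875)          # (W, H)
    background: tuple[tuple[int, int, int], int] = ((236, 232, 224), 5)
    n_distractors: int = 8
    crc_template: CRCTemplate = field(default_factory=default_template)
    crc_position: tuple[int, int] | None = None   # top-left, or None for random
    crc_quadrant: str | None = None               # constrain random placement
    skew_prob: float = 0.3
    occlusion_prob: float = 0.1
    augmentation: AugmentationParams | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# distractor painters


def _boxes_intersect(a, b) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return not (ax + aw <= bx or bx + bw <= ax or ay + ah <= by or by + bh <= ay)


def _place_box(rng, img_w, img_h, w, h, avoid, tries: int = 25):
    """Random top-left for a w x h box avoiding all boxes in *avoid*."""
    if img_w <= w or img_h <= h:
        return None
    for _ in range(tries):
        x = int(rng.integers(0, img_w - w))
        y = int(rng.integers(0, img_h - h))
        box = (x - 5, y - 5, w + 10, h + 10)
        if all(not _boxes_intersect(box, a) for a in avoid):
            return x, y
    return None


def _paint_plant(img, rng, avoid) -> None:
    h, w = img.shape[:2]
    extent = int(rng.integers(60, 160))
    extent = min(extent, w - 2, h - 2)
    pos = _place_box(rng, w, h, extent, extent, avoid)
    if pos is None:
        return
    x0, y0 = pos
    base = np.array([rng.integers(30, 70), rng.integers(55, 105), rng.integers(25, 55)])
    for _ in range(int(rng.integers(4, 10))):
        cy = y0 + int(rng.integers(0, extent))
        cx = x0 + int(rng.integers(0, extent))
        r = int(rng.integers(8, max(9, extent // 4)))
        rr, cc = disk((cy, cx), r, shape=img.shape[:2])
        jitter = rng.integers(-15, 16, size=3)
        img[rr, cc] = np.clip(base + jitter, 10, 130)


def _paint_label(img, rng, avoid) -> None:
    h, w = img.shape[:2]
    lw = min(int(rng.integers(140, 300)), w - 2)
    lh = min(int(rng.integers(60, 130)), h - 2)
    pos = _place_box(rng, w, h, lw, lh, avoid)
    if pos is None:
        return
    x0, y0 = pos
    img[y0 : y0 + lh, x0 : x0 + lw] = (246, 245, 242)
    img[y0 : y0 + 2, x0 : x0 + lw] = (70, 70, 70)
    img[y0 + lh - 2 : y0 + lh, x0 : x0 + lw] = (70, 70, 70)
    n_lines = int(rng.integers(3, 7))
    for i in range(n_lines):
        ly = y0 + 10 + i * max(8, (lh - 20) // n_lines)
        if ly + 2 >= y0 + lh - 4:
            break
        ll = int(rng.integers(lw // 3, lw - 20))
        img[ly : ly + 2, x0 + 10 : x0 + 10 + ll] = (60, 58, 55)


def _paint_logo(img, rng, avoid) -> None:
    h, w = img.shape[:2]
    cells = int(rng.integers(2, 5))
    cell = int(rng.integers(10, 26))
    side = cells * cell
    pos = _place_box(rng, w, h, side, side, avoid)
    if pos is None:
        return
    x0, y0 = pos
    # saturated but never pure white/black: a hard case for a histogram ranker
    colors = rng.integers(25, 231, size=(cells, cells, 3))
    for r in range(cells):
        for c in range(cells):
            img[y0 + r * cell : y0 + (r + 1) * cell,
                x0 + c * cell : x0 + (c + 1) * cell] = colors[r, c]


def _paint_ruler(img, rng, avoid) -> None:
    h, w = img.shape[:2]
    cell = int(rng.integers(8, 16))
    n = int(rng.integers(6, 13))
    horiz = bool(rng.random() < 0.5)
    bw, bh = (n * cell, cell) if horiz else (cell, n * cell)
    pos = _place_box(rng, w, h, bw, bh, avoid)
    if pos is None:
        return
    x0, y0 = pos
    for i in range(n):
        col = (30, 30, 32) if i % 2 == 0 else (224, 222, 218)
        if horiz:
            img[y0 : y0 + cell, x0 + i * cell : x0 + (i + 1) * cell] = col
        else:
            img[y0 + i * cell : y0 + (i + 1) * cell, x0 : x0 + cell] = col


def _paint_stem(img, rng, avoid) -> None:
    h, w = img.shape[:2]
    length = min(int(rng.integers(120, 400)), h - 2)
    pos = _place_box(rng, w, h, min(40, w - 2), length, avoid)
    if pos is None:
        return
    x0, y0 = pos
    x1 = x0 + int(rng.integers(-30, 31))
    y1 = min(h - 1, y0 + length)
    thick = int(rng.integers(2, 6))
    xs = np.array([x0, x0 + thick, x1 + thick, x1])
    ys = np.array([y0, y0, y1, y1])
    rr, cc = polygon(ys, xs, shape=img.shape[:2])
    img[rr, cc] = (rng.integers(40, 80), rng.integers(35, 70), rng.integers(20, 50))


_PAINTERS = [_paint_plant, _paint_stem, _paint_label, _paint_logo, _paint_ruler]


def _paint_decoy_crc(img, rng, avoid) -> None:
    """A CRC-like grid at an implausible size (too small or too large)."""
    if rng.random() < 0.75:
        patch_px = int(rng.integers(3, 6))    # side 17..27 px, below the valid band
    else:
        patch_px = int(rng.integers(36, 45))  # side 186..231 px, above the band
    tpl = default_template(patch_px=patch_px)
    tile, _, _, _ = render_template(tpl)
    th, tw = tile.shape[:2]
    h, w = img.shape[:2]
    pos = _place_box(rng, w, h, tw, th, avoid)
    if pos is None:
        return
    x0, y0 = pos
    img[y0 : y0 + th, x0 : x0 + tw] = tile


# ---------------------------------------------------------------------------
# sheet rendering


def _quadrant_range(quadrant: str, img_w: int, img_h: int, tw: int, th: int):
    margin = 10
    half_w, half_h = img_w // 2, img_h // 2
    xr = {"W": (margin, half_w - tw - 1), "E": (half_w + 1, img_w - tw - margin)}
    yr = {"N": (margin, half_h - th - 1), "S": (half_h + 1, img_h - th - margin)}
    return xr[quadrant[1]], yr[quadrant[0]]


def _apply_photometric(img_f: np.ndarray, aug: AugmentationParams) -> np.ndarray:
    if aug.desaturate > 0:
        lum = img_f.mean(axis=2, keepdims=True)
        img_f = img_f + aug.desaturate * (lum - img_f)
    gains = np.asarray(aug.effective_gains())
    img_f = img_f * gains[None, None, :]
    return img_f


def _rot90_point(pt, img_w, img_h, k):
    x, y = pt
    for _ in range(k % 4):
        x, y = y, img_w - x
        img_w, img_h = img_h, img_w
    return (x, y)


def rot90_box(box, img_w, img_h, k):
    """Map an (x, y, w, h) box under k CCW quarter-turns of a W x H image."""
    x, y, w, h = box
    for _ in range(k % 4):
        x, y, w, h = y, img_w - (x + w), h, w
        img_w, img_h = img_h, img_w
    return (x, y, w, h)


def render_sheet(spec: SheetSpec):
    """Render one sheet.

    Returns ``(image uint8 HxWx3, ground_truth dict)`` where the ground truth
    holds the CRC box, the white/black patch centers (all in final,
    post-rotation coordinates), the rotation applied, and the effective
    per-channel gains.
    """
    rng = np.random.default_rng(spec.seed)
    img_w, img_h = spec.size
    (base, noise_amp) = spec.background
    img = np.empty((img_h, img_w, 3), dtype=np.int16)
    img[:] = np.asarray(base, dtype=np.int16)
    if noise_amp > 0:
        img += rng.integers(-noise_amp, noise_amp + 1, size=(img_h, img_w, 1)).astype(np.int16)
    img = np.clip(img, 0, 255).astype(np.uint8)

    # chart geometry first, so distractors can avoid it
    tile, mask, wc, bc = render_template(spec.crc_template)
    if rng.random() < spec.skew_prob:
        angle = float(rng.uniform(-8.0, 8.0))
        tile, mask, (wc, bc) = _skew_template(tile, mask, [wc, bc], angle)
    th, tw = tile.shape[:2]
    if tw > img_w - 20 or th > img_h - 20:
        raise ValueError("CRC template does not fit on the sheet")
    if spec.crc_position is not None:
        cx, cy = spec.crc_position
    elif spec.crc_quadrant is not None:
        (x_lo, x_hi), (y_lo, y_hi) = _quadrant_range(spec.crc_quadrant, img_w, img_h, tw, th)
        cx = int(rng.integers(x_lo, x_hi + 1))
        cy = int(rng.integers(y_lo, y_hi + 1))
    else:
        cx = int(rng.integers(10, img_w - tw - 10))
        cy = int(rng.integers(10, img_h - th - 10))
    if cx < 0 or cy < 0 or cx + tw > img_w or cy + th > img_h:
        raise ValueError("CRC position places the chart outside the sheet")
    crc_box = (cx, cy, tw, th)
    avoid = [crc_box]

    for _ in range(spec.n_distractors):
        painter = _PAINTERS[int(rng.integers(0, len(_PAINTERS)))]
        painter(img, rng, avoid)

    aug = spec.augmentation
    if aug is not None and aug.overlay_crc:
        _paint_decoy_crc(img, rng, avoid)

    # paste the chart last so clutter never covers it accidentally
    region = img[cy : cy + th, cx : cx + tw]
    region[mask] = tile[mask]

    occluded = False
    if rng.random() < spec.occlusion_prob:
        occluded = True
        corner = int(rng.integers(0, 4))
        ox = cx + (0 if corner % 2 == 0 else tw)
        oy = cy + (0 if corner < 2 else th)
        r = int(0.35 * max(tw, th))
        rr, cc = disk((oy, ox), r, shape=img.shape[:2])
        img[rr, cc] = (45, 70, 40)

    white_center = (cx + wc[0], cy + wc[1])
    black_center = (cx + bc[0], cy + bc[1])
    gains = (1.0, 1.0, 1.0)
    rotate_k = 0
    if aug is not None:
        img_f = _apply_photometric(img.astype(np.float64), aug)
        img = np.clip(np.rint(img_f), 0, 255).astype(np.uint8)
        gains = aug.effective_gains()
        rotate_k = aug.rotate_k
        if rotate_k:
            img = np.ascontiguousarray(np.rot90(img, k=rotate_k))
            crc_box = rot90_box(crc_box, img_w, img_h, rotate_k)
            white_center = _rot90_point(white_center, img_w, img_h, rotate_k)
            black_center = _rot90_point(black_center, img_w, img_h, rotate_k)

    ground_truth = {
        "crc_box": [float(v) for v in crc_box],
        "white_patch_center": [float(v) for v in white_center],
        "black_patch_center": [float(v) for v in black_center],
        "rotation_applied": rotate_k * 90,
        "gains_applied": [float(g) for g in gains],
        "crc_side": int(max(tw, th)),
        "occluded": occluded,
        "template": spec.crc_template.name,
        "seed": int(spec.seed),
    }
    return img, ground_truth


# ---------------------------------------------------------------------------
# patch datasets (training samples)


def _random_template(rng) -> CRCTemplate:
    return default_template(patch_px=int(rng.integers(9, 19)))


def _render_positive_patch(rng):
    canvas = np.empty((125, 125, 3), dtype=np.int16)
    canvas[:] = np.array([236, 232, 224]) + rng.integers(-12, 13, size=3)
    canvas += rng.integers(-5, 6, size=(125, 125, 1)).astype(np.int16)
    canvas = np.clip(canvas, 0, 255).astype(np.uint8)
    if rng.random() < 0.4:  # clutter near the chart
        _PAINTERS[int(rng.integers(0, len(_PAINTERS)))](canvas, rng, [])
    tile, mask, _, _ = render_template(_random_template(rng))
    if rng.random() < 0.3:
        tile, mask, _ = _skew_template(tile, mask, [], float(rng.uniform(-8, 8)))
    th, tw = tile.shape[:2]
    # allow the chart to overhang one side along one axis, keeping >= ~55% visible
    if rng.random() < 0.7:
        x = int(rng.integers(0, 126 - tw))
        y = int(rng.integers(0, 126 - th))
    elif rng.random() < 0.5:
        o = int(rng.uniform(0.0, 0.45) * tw)
        x = -o if rng.random() < 0.5 else 125 - tw + o
        y = int(rng.integers(0, 126 - th))
    else:
        o = int(rng.uniform(0.0, 0.45) * th)
        y = -o if rng.random() < 0.5 else 125 - th + o
        x = int(rng.integers(0, 126 - tw))
    sx0, sy0 = max(0, x), max(0, y)
    sx1, sy1 = min(125, x + tw), min(125, y + th)
    tx0, ty0 = sx0 - x, sy0 - y
    sub_mask = mask[ty0 : ty0 + (sy1 - sy0), tx0 : tx0 + (sx1 - sx0)]
    canvas[sy0:sy1, sx0:sx1][sub_mask] = tile[ty0 : ty0 + (sy1 - sy0), tx0 : tx0 + (sx1 - sx0)][sub_mask]
    visible_fraction = float(sub_mask.sum()) / float(mask.sum())
    return canvas, visible_fraction


def _paint_small_label(canvas, rng) -> None:
    """Text-label fragment sized for a 125 px window."""
    lw = int(rng.integers(60, 120))
    lh = int(rng.integers(35, 90))
    x0 = int(rng.integers(0, 126 - lw))
    y0 = int(rng.integers(0, 126 - lh))
    canvas[y0 : y0 + lh, x0 : x0 + lw] = (246, 245, 242)
    for i in range(int(rng.integers(2, 6))):
        ly = y0 + 8 + i * 12
        if ly + 2 >= y0 + lh - 4:
            break
        ll = int(rng.integers(lw // 2, lw - 10))
        canvas[ly : ly + 2, x0 + 5 : x0 + 5 + ll] = (60, 58, 55)


def _render_negative_patch(rng) -> np.ndarray:
    canvas = np.empty((125, 125, 3), dtype=np.int16)
    canvas[:] = np.array([236, 232, 224]) + rng.integers(-12, 13, size=3)
    canvas += rng.integers(-5, 6, size=(125, 125, 1)).astype(np.int16)
    canvas = np.clip(canvas, 0, 255).astype(np.uint8)
    kind = rng.random()
    if kind < 0.10:
        pass  # plain paper
    elif kind < 0.24:
        _paint_small_label(canvas, rng)
    elif kind < 0.40:
        # logo blocks are the canonical histogram-ranker false positive,
        # so the verifier sees plenty of them
        cells = int(rng.integers(2, 6))
        cell = int(rng.integers(8, min(30, 124 // cells)))
        side = cells * cell
        x0 = int(rng.integers(0, 126 - side))
        y0 = int(rng.integers(0, 126 - side))
        colors = rng.integers(25, 231, size=(cells, cells, 3))
        for r in range(cells):
            for c in range(cells):
                canvas[y0 + r * cell : y0 + (r + 1) * cell,
                       x0 + c * cell : x0 + (c + 1) * cell] = colors[r, c]
    elif kind < 0.64:
        n = int(rng.integers(1, 3))
        for _ in range(n):
            _PAINTERS[int(rng.integers(0, len(_PAINTERS)))](canvas, rng, [])
    elif kind < 0.82:
        # undersized chart-like decoy, fully visible
        tpl = default_template(patch_px=int(rng.integers(3, 6)))
        tile, _, _, _ = render_template(tpl)
        th, tw = tile.shape[:2]
        x0 = int(rng.integers(0, 126 - tw))
        y0 = int(rng.integers(0, 126 - th))
        canvas[y0 : y0 + th, x0 : x0 + tw] = tile
    else:
        # window over an oversized chart-like decoy: the scale cue matters,
        # and the window may land on the interior or across an edge
        tpl = default_template(patch_px=int(rng.integers(36, 45)))
        tile, _, _, _ = render_template(tpl)
        th, tw = tile.shape[:2]
        x = int(rng.integers(-(tw - 25), 101))
        y = int(rng.integers(-(th - 25), 101))
        sx0, sy0 = max(0, x), max(0, y)
        sx1, sy1 = min(125, x + tw), min(125, y + th)
        canvas[sy0:sy1, sx0:sx1] = tile[sy0 - y : sy1 - y, sx0 - x : sx1 - x]
    return canvas


def _augment_patch(patch: np.ndarray, rng) -> np.ndarray:
    """Per-patch capture augmentation for training samples.

    A third of the draws are forced into the hardest corner of the range
    (heavy darkening combined with strong desaturation): under uniform
    sampling that corner is rare, yet it is where chart appearance
    degenerates most, so training oversamples it.
    """
    if rng.random() < 0.35:
        aug = AugmentationParams(
            darken=float(rng.uniform(0.4, 0.6)),
            desaturate=float(rng.uniform(0.65, 1.0)),
            wb_shift=tuple(float(v) for v in rng.uniform(0.6, 1.4, size=3)),
            rotate_k=int(rng.integers(0, 4)),
        )
    else:
        aug = AugmentationParams.random(rng, rotate=True, overlay_prob=0.0)
    out = _apply_photometric(patch.astype(np.float64), aug)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if aug.rotate_k:
        out = np.ascontiguousarray(np.rot90(out, k=aug.rotate_k))
    return out


def make_patch_dataset(n: int, seed: int, augment: bool = True,
                       return_meta: bool = False):
    """Balanced labeled 125 x 125 training patches.

    Returns ``(X uint8 (n, 125, 125, 3), y int8 (n,))`` with exactly n//2
    positives (a chart covering >= ~50% of its area in-window) and n//2
    negatives (clutter, never a valid-size chart).  Deterministic in *seed*;
    training and benchmark streams use disjoint seed namespaces.  With
    ``return_meta`` a third element carries per-patch audit records
    (label, chart visible fraction).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng([int(seed), 0])  # namespace 0: training patches
    n_pos = n // 2
    n_neg = n - n_pos
    X = np.empty((n, 125, 125, 3), dtype=np.uint8)
    y = np.empty(n, dtype=np.int8)
    metas = []
    for i in range(n_pos):
        p, visible = _render_positive_patch(rng)
        X[i] = _augment_patch(p, rng) if augment else p
        y[i] = 1
        metas.append({"label": 1, "visible_fraction": visible})
    for i in range(n_neg):
        p = _render_negative_patch(rng)
        X[n_pos + i] = _augment_patch(p, rng) if augment else p
        y[n_pos + i] = 0
        metas.append({"label": 0, "visible_fraction": 0.0})
    order = rng.permutation(n)
    if return_meta:
        return X[order], y[order], [metas[i] for i in order]
    return X[order], y[order]


# ---------------------------------------------------------------------------
# benchmark suites


def random_sheet_spec(rng: np.random.Generator, size=(1250, 1875),
                      rotate: bool = True, quadrant: str | None = None) -> SheetSpec:
    """Draw one varied sheet spec (template size, placement, augmentation)."""
    return SheetSpec(
        size=size,
        n_distractors=int(rng.integers(5, 12)),
        crc_template=_random_template(rng),
        crc_quadrant=quadrant,
        augmentation=AugmentationParams.random(rng, rotate=rotate),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_benchmark(n_sheets: int, seed: int, out_dir, size=(1250, 1875),
                   rotate: bool = True):
    """Write a held-out suite of PNG sheets with ground-truth JSON sidecars.

    Returns the list of (image_path, json_path) pairs; also writes
    ``manifest.csv``.  Uses seed namespace 1, disjoint from training patches.
    """
    if n_sheets < 1:
        raise ValueError("need n_sheets >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), 1])  # namespace 1: benchmark
    pairs = []
    rows = []
    for i in range(n_sheets):
        spec = random_sheet_spec(rng, size=size, rotate=rotate)
        img, gt = render_sheet(spec)
        img_path = out_dir / f"sheet_{i:04d}.png"
        json_path = out_dir / f"sheet_{i:04d}.json"
        save_image(img, img_path)
        json_path.write_text(json.dumps(gt, indent=1))
        pairs.append((img_path, json_path))
        rows.append({"image": img_path.name, "ground_truth": json_path.name,
                     "crc_side": gt["crc_side"], "rotation": gt["rotation_applied"],
                     "occluded": gt["occluded"]})
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return pairs
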