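"""Candidate-partition generation.

Two proposal modes are provided:

* **normal** — an exhaustive sliding window (default 125 x 125 px, 25 px
  stride) over the processing raster, with a full-coverage rule that appends
  one extra final column/row whenever the regular grid does not reach the
  border, so a chart flush against the sheet edge is still covered.
* **quick** — a square-contour detector in the spirit of the classic OpenCV
  ``squares.py`` recipe: binarize the luminance at several levels, trace the
  iso-contours, approximate them by polygons and keep convex quadrilaterals
  with near-right angles whose bounding box is plausibly chart-sized.  When
  no square is found, quick mode falls back to the full sliding-window grid.

Quick mode typically emits a handful of proposals instead of thousands, which
is the mechanism that makes it substantially faster than the exhaustive scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import approximate_polygon, find_contours

from .imgio import SheetImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Partition:
    """An axis-aligned candidate box in processing-resolution pixels.

    The half-open box [x, x+w) x [y, y+h) must lie within the raster.
    """

    x: int
    y: int
    w: int
    h: int
    origin: str = "sliding_window"  # or "square_contour"

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.w, self.h)


@dataclass
class ProposalConfig:
    window_size: int = 125
    stride: int = 25
    quick_min_side: int = 40
    quick_max_side: int = 140
    quick_squareness_tol: float = 0.3   # max |cos| at the 4 corners
    quick_margin: int = 15              # context padding around detected squares
    quick_aspect_tol: float = 1.25
    quick_levels: int = 6               # threshold levels scanned by find_squares

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.window_size):
            raise ValueError("require 0 < stride <= window_size")
        if not (self.quick_min_side < self.quick_max_side):
            raise ValueError("require quick_min_side < quick_max_side")


def _axis_positions(extent: int, window: int, stride: int) -> list[int]:
    pos = list(range(0, extent - window + 1, stride))
    if pos[-1] != extent - window:  # full-coverage rule
        pos.append(extent - window)
    return pos


def sliding_windows(processing_size: tuple[int, int], config: ProposalConfig) -> list[Partition]:
    """Row-major grid of square windows covering the whole raster.

    Positions run x in {0, s, 2s, ...} with x + window <= W, plus one final
    column at x = W - window (same for rows) whenever the grid does not end
    on the border.
    """
    w_img, h_img = processing_size
    win, s = config.window_size, config.stride
    if w_img < win or h_img < win:
        raise ValueError(
            f"image {w_img}x{h_img} smaller than the {win} px window"
        )
    xs = _axis_positions(w_img, win, s)
    ys = _axis_positions(h_img, win, s)
    return [
        Partition(x, y, win, win, origin="sliding_window")
        for y in ys
        for x in xs
    ]


def _box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def _max_corner_cosine(quad: np.ndarray) -> float:
    """Max |cos angle| over the 4 corners of a quadrilateral (rows = vertices)."""
    worst = 0.0
    for i in range(4):
        p0, p1, p2 = quad[(i - 1) % 4], quad[i], quad[(i + 1) % 4]
        v1, v2 = p0 - p1, p2 - p1
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-9:
            return 1.0
        worst = max(worst, abs(float(np.dot(v1, v2) / denom)))
    return worst


def _is_convex(quad: np.ndarray) -> bool:
    signs = []
    for i in range(4):
        a, b, c = quad[i], quad[(i + 1) % 4], quad[(i + 2) % 4]
        cross = (b[0] - a[0]) * (c[1] - b[1]) - (b[1] - a[1]) * (c[0] - b[0])
        signs.append(cross >= 0)
    return all(signs) or not any(signs)


def _is_square_blob(filled: np.ndarray, tol: float) -> bool:
    """Does a filled binary blob approximate a convex right-angled quadrilateral?

    The blob's outline (traced on a padded copy so it is always closed) is
    simplified to a polygon; we require 4 vertices, convexity and corner
    cosines within *tol* — the classic contour-squareness test.
    """
    padded = np.pad(filled.astype(np.float64), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return False
    contour = max(contours, key=len)
    if len(contour) > 2 and np.allclose(contour[0], contour[-1]):
        # the trace starts at an arbitrary boundary point; restart it at the
        # point farthest from the centroid (a corner) so the simplifier does
        # not pin a spurious mid-edge vertex at the seam
        ring = contour[:-1]
        far = int(np.argmax(((ring - ring.mean(axis=0)) ** 2).sum(axis=1)))
        ring = np.roll(ring, -far, axis=0)
        contour = np.vstack([ring, ring[:1]])
    perim = np.sum(np.hypot(*np.diff(contour, axis=0).T))
    if perim <= 0:
        return False
    # two simplification strengths: crisp frames pass at 0.02 x perimeter,
    # jagged (skewed, resampled) frames need the coarser pass
    for tol_frac in (0.02, 0.045):
        approx = approximate_polygon(contour, tolerance=tol_frac * perim)
        if len(approx) >= 2 and np.allclose(approx[0], approx[-1]):
            approx = approx[:-1]
        if len(approx) != 4:
            continue
        quad = approx[:, ::-1]  # (row, col) -> (x, y)
        if _is_convex(quad) and _max_corner_cosine(quad) <= tol:
            return True
    return False


def _dark_blob_boxes(gray: np.ndarray, config: ProposalConfig):
    """Bounding boxes of square-like dark blobs at several threshold levels.

    A chart reads as a dark frame (plus dark patches) on light paper, so each
    level binarizes ``gray < level``; connected components are size- and
    shape-filtered before the expensive polygon test runs on the (small)
    blob crop.
    """
    from scipy import ndimage

    lo = float(gray.min())
    med = float(np.median(gray))
    if med - lo < 2.0:
        return
    seen: set[tuple[int, int, int, int]] = set()
    for frac in np.linspace(0.2, 0.85, config.quick_levels):
        level = lo + frac * (med - lo)
        labels, n = ndimage.label(gray < level)
        if n == 0:
            continue
        slices = ndimage.find_objects(labels)
        for idx, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            ys, xs = sl
            h = ys.stop - ys.start
            w = xs.stop - xs.start
            side = max(w, h)
            if not (config.quick_min_side <= side <= config.quick_max_side):
                continue
            if min(w, h) < 1 or side / min(w, h) > config.quick_aspect_tol:
                continue
            key = (xs.start, ys.start, w, h)
            if key in seen:
                continue
            seen.add(key)
            blob = labels[sl] == idx
            filled = ndimage.binary_fill_holes(blob)
            if filled.mean() < 0.75:  # a square's fill covers its bounding box
                continue
            if _is_square_blob(filled, config.quick_squareness_tol):
                yield key


def find_squares(image: SheetImage, config: ProposalConfig | None = None) -> list[Partition]:
    """Detect chart-sized squares on the processing raster.

    Returns the empty list when nothing qualifies (the no-detection signal).
    Surviving squares are expanded by ``quick_margin`` px of context, clipped
    to the raster, and near-duplicates (IoU > 0.8) are merged to the larger.
    """
    if config is None:
        config = ProposalConfig()
    gray = image.pixels.astype(np.float32).mean(axis=2)
    height, width = gray.shape
    boxes: list[tuple[int, int, int, int]] = []
    for (x0, y0, w, h) in _dark_blob_boxes(gray, config):
        m = config.quick_margin
        bx = max(0, x0 - m)
        by = max(0, y0 - m)
        bx1 = min(width, x0 + w + m)
        by1 = min(height, y0 + h + m)
        boxes.append((bx, by, bx1 - bx, by1 - by))

    merged: list[tuple[int, int, int, int]] = []
    for box in sorted(boxes, key=lambda b: -(b[2] * b[3])):
        if all(_box_iou(box, kept) <= 0.8 for kept in merged):
            merged.append(box)
    merged.sort(key=lambda b: (b[1], b[0]))
    return [Partition(x, y, w, h, origin="square_contour") for x, y, w, h in merged]


def partitions_to_csv(partitions, path) -> None:
    """Write proposals as CSV (x, y, w, h, origin) in processing coordinates."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "w", "h", "origin"])
        for p in partitions:
            writer.writerow([p.x, p.y, p.w, p.h, p.origin])


def propose(image: SheetImage, mode: str, config: ProposalConfig | None = None) -> list[Partition]:
    """Proposal front end: ``normal`` scans, ``quick`` detects with fallback."""
    if config is None:
        config = ProposalConfig()
    w_img, h_img = image.processing_size
    if mode == "normal":
        return sliding_windows((w_img, h_img), config)
    if mode == "quick":
        squares = find_squares(image, config)
        if squares:
            return squares
        logger.info("quick mode found no squares; falling back to sliding windows")
        return sliding_windows((w_img, h_img), config)
    raise ValueError(f"unknown proposal mode {mode!r}")
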