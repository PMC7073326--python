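"""End-to-end chart detection: standardize, propose, rank, verify, crop.

The cascade walks the histogram-ranked proposal list best-first and runs the
convolutional verifier on each partition, stopping at the first candidate
whose confidence clears ``accept_threshold``.  On typical sheets only a
handful of partitions ever reach the verifier, which is what keeps the
pipeline fast on a CPU despite the exhaustive sliding-window proposal grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from .features import extract_features
from .imgio import SheetImage, standardize
from .models import PATCH_SIZE, RankerModel, VerifierModel, verify_patch
from .proposals import Partition, ProposalConfig, find_squares, sliding_windows

logger = logging.getLogger(__name__)

NO_DETECTION_FLOOR = 0.1  # below this max confidence we report nothing at all


@dataclass
class DetectorConfig:
    accept_threshold: float = 0.5
    max_verify: int = 25
    proposal: ProposalConfig = field(default_factory=ProposalConfig)
    target_short_side: int = 1250

    def __post_init__(self) -> None:
        if self.max_verify < 1:
            raise ValueError("max_verify must be >= 1")
        if not (0.0 < self.accept_threshold < 1.0):
            raise ValueError("accept_threshold must lie in (0, 1)")


@dataclass
class CRCDetection:
    """The winning partition and everything derived from it.

    Boxes are (x, y, w, h); ``partition`` is in processing coordinates, all
    ``*_original`` / region boxes in as-loaded original-image coordinates.
    """

    partition: Partition
    partition_original: tuple[float, float, float, float]
    confidence: float
    n_verified: int
    mode_used: str                      # normal | quick | quick_fallback
    low_confidence: bool = False
    tight_box: tuple[float, float, float, float] | None = None
    white_region: tuple[float, float, float, float] | None = None
    black_region: tuple[float, float, float, float] | None = None

    def reported_box(self) -> tuple[float, float, float, float]:
        return self.tight_box if self.tight_box is not None else self.partition_original

    def to_json(self, **extra) -> str:
        d = asdict(self)
        d["partition"] = self.partition.as_tuple()
        d.update(extra)
        return json.dumps(d, sort_keys=True)


def _patch_for_verifier(image: SheetImage, part: Partition) -> np.ndarray:
    crop = image.pixels[part.y : part.y + part.h, part.x : part.x + part.w]
    if crop.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
        crop = resize(crop, (PATCH_SIZE, PATCH_SIZE), order=1, preserve_range=True,
                      anti_aliasing=max(crop.shape[:2]) > PATCH_SIZE)
        crop = np.clip(np.rint(crop), 0, 255).astype(np.uint8)
    return crop


def detect(image: SheetImage, ranker: RankerModel, verifier: VerifierModel,
           config: DetectorConfig | None = None, mode: str = "normal") -> CRCDetection | None:
    """Locate the chart on a sheet; returns None when nothing plausible exists.

    The image is standardized on entry if it is not already at the configured
    processing resolution.  Candidates are verified best-first with early
    stopping; if none of the first ``max_verify`` clears the acceptance
    threshold, the most confident one is returned flagged ``low_confidence``
    (or nothing, if even that confidence is below 0.1).
    """
    if config is None:
        config = DetectorConfig()
    if image.processing_size[0] != config.target_short_side:
        image = standardize(image, config.target_short_side)

    if mode == "normal":
        partitions = sliding_windows(image.processing_size, config.proposal)
        mode_used = "normal"
    elif mode == "quick":
        partitions = find_squares(image, config.proposal)
        if partitions:
            mode_used = "quick"
        else:
            logger.info("quick mode: no squares found, falling back to sliding windows")
            partitions = sliding_windows(image.processing_size, config.proposal)
            mode_used = "quick_fallback"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def _cascade(parts):
        feats = extract_features(image, parts)
        probs = ranker.predict_proba(feats)
        order = np.argsort(-probs, kind="stable")
        best_part, best_conf, n_ver, ok = None, -1.0, 0, False
        for idx in order[: config.max_verify]:
            part = parts[int(idx)]
            patch = _patch_for_verifier(image, part)
            conf = verify_patch(patch, verifier)
            n_ver += 1
            if conf > best_conf:
                best_conf = conf
                best_part = part
            if conf >= config.accept_threshold:
                ok = True
                break
        return best_part, best_conf, n_ver, ok

    best_part, best_conf, n_verified, accepted = _cascade(partitions)
    if mode_used == "quick" and not accepted:
        # none of the detected squares verified as a chart: the quick
        # hypothesis failed, so fall back to the exhaustive grid
        logger.info("quick mode: no square verified, falling back to sliding windows")
        grid = sliding_windows(image.processing_size, config.proposal)
        g_part, g_conf, g_ver, g_ok = _cascade(grid)
        n_verified += g_ver
        mode_used = "quick_fallback"
        if g_conf > best_conf:
            best_part, best_conf = g_part, g_conf
        accepted = g_ok

    if best_part is None or (not accepted and best_conf < NO_DETECTION_FLOOR):
        return None
    return CRCDetection(
        partition=best_part,
        partition_original=image.to_original_box(
            (best_part.x, best_part.y, best_part.w, best_part.h)
        ),
        confidence=float(best_conf),
        n_verified=n_verified,
        mode_used=mode_used,
        low_confidence=not accepted,
    )


# ---------------------------------------------------------------------------
# high-precision cropping


def _square_contour_in_region(image: SheetImage, region, config: ProposalConfig):
    """Largest square-ish 4-vertex contour inside *region* (processing coords)."""
    x0, y0, w, h = region
    sub = image.pixels[y0 : y0 + h, x0 : x0 + w]
    probe = SheetImage(
        pixels=sub, original=sub,
        original_size=(w, h), processing_size=(w, h), scale_factors=(1.0, 1.0),
    )
    local = ProposalConfig(
        window_size=config.window_size, stride=config.stride,
        quick_min_side=20, quick_max_side=max(w, h),
        quick_squareness_tol=config.quick_squareness_tol,
        quick_margin=0, quick_aspect_tol=1.3,
    )
    candidates = find_squares(probe, local)
    if not candidates:
        return None
    best = max(candidates, key=lambda p: p.w * p.h)
    return (x0 + best.x, y0 + best.y, best.w, best.h)


def _dark_component_box(image: SheetImage, region):
    """Bounding box of the dominant dark structure in *region*, or None.

    Recovery path for charts whose frame contour cannot be traced (partial
    occlusion, clutter touching the frame): the frame is still the darkest
    large structure near the winning partition, and since chart coverage is
    judged one-sided a slightly generous box is harmless.
    """
    from scipy import ndimage

    x0, y0, w, h = region
    sub = image.pixels[y0 : y0 + h, x0 : x0 + w].astype(np.float32).mean(axis=2)
    paper = float(np.median(image.pixels.astype(np.float32).mean(axis=2)))
    lo = float(sub.min())
    if paper - lo < 2.0:
        return None
    level = lo + 0.55 * (paper - lo)
    labels, n = ndimage.label(sub < level)
    if n == 0:
        return None
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    lab = int(counts.argmax())
    if counts[lab] < 100:
        return None
    ys, xs = np.nonzero(labels == lab)
    bx0, bx1 = int(xs.min()), int(xs.max()) + 1
    by0, by1 = int(ys.min()), int(ys.max()) + 1
    return (x0 + bx0, y0 + by0, bx1 - bx0, by1 - by0)


def _luminance_extreme_region(image: SheetImage, box, maximize: bool):
    """Small box over the brightest (or darkest) cell inside *box*.

    Scans a cell of about one sixth of the chart side with an integral image;
    cells tied with the extreme are averaged (their centroid) so the returned
    region sits centered on the extreme patch, then shrunk to its central 50%.
    """
    x0, y0, w, h = (int(round(v)) for v in box)
    lum = image.pixels[y0 : y0 + h, x0 : x0 + w].astype(np.float64).mean(axis=2)
    cell = max(3, min(w, h) // 6)
    if h < cell or w < cell:
        cell = max(1, min(w, h))
    integ = np.zeros((lum.shape[0] + 1, lum.shape[1] + 1))
    np.cumsum(np.cumsum(lum, axis=0), axis=1, out=integ[1:, 1:])
    ys = np.arange(0, lum.shape[0] - cell + 1)
    xs = np.arange(0, lum.shape[1] - cell + 1)
    sums = (integ[ys + cell][:, xs + cell] - integ[ys][:, xs + cell]
            - integ[ys + cell][:, xs] + integ[ys][:, xs])
    means = sums / (cell * cell)
    target = means.max() if maximize else means.min()
    tie = np.argwhere(np.abs(means - target) <= 1.0)
    cy, cx = tie.mean(axis=0)
    rx, ry = x0 + cx + cell / 2.0, y0 + cy + cell / 2.0  # cell center
    half = cell / 4.0  # central 50%
    return (rx - half, ry - half, 2 * half, 2 * half)


def precision_crop(image: SheetImage, detection: CRCDetection,
                   config: DetectorConfig | None = None, pad: int = 64) -> CRCDetection:
    """Tighten the detection to the chart boundary and locate white/black patches.

    Within the winning partition (padded by *pad* px) the dominant 4-vertex
    contour gives the tight box; the white (black) sample region is the
    brightest (darkest) grid-cell-sized area inside it, shrunk to its central
    half to stay clear of patch borders.  Without a contour the partition box
    itself is used (fallback, logged).

    The default pad is about a third of a window: an accepted window may
    cover just over half the chart, and the contour search must still see
    the whole frame to recover the full chart boundary.
    """
    if config is None:
        config = DetectorConfig()
    if image.processing_size[0] != config.target_short_side:
        image = standardize(image, config.target_short_side)
    p = detection.partition
    height, width = image.pixels.shape[:2]
    rx0 = max(0, p.x - pad)
    ry0 = max(0, p.y - pad)
    rx1 = min(width, p.x + p.w + pad)
    ry1 = min(height, p.y + p.h + pad)
    region = (rx0, ry0, rx1 - rx0, ry1 - ry0)
    tight = _square_contour_in_region(image, region, config.proposal)
    if tight is None:
        tight = _dark_component_box(image, region)
    if tight is None:
        logger.info("precision crop: no contour found, keeping the partition box")
        tight = (p.x, p.y, p.w, p.h)
    white = _luminance_extreme_region(image, tight, maximize=True)
    black = _luminance_extreme_region(image, tight, maximize=False)
    detection.tight_box = image.to_original_box(tight)
    detection.white_region = image.to_original_box(white)
    detection.black_region = image.to_original_box(black)
    return detection
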