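"""Scoring detections against ground truth and benchmarking the pipeline.

A detection is *correct* when the reported box crops at least 80% of the
chart's area and both the white-patch and black-patch centers fall inside
it — a mechanical version of the human judgment "at least 80% of the chart
with the whitest and blackest part visible".  The coverage denominator is
the chart area (one-sided), not the union.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from .detector import DetectorConfig, detect, precision_crop
from .imgio import load_image, standardize
from .proposals import find_squares, sliding_windows


def _intersection_area(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    return ix * iy


def _point_in_box(pt, box) -> bool:
    x, y = pt
    bx, by, bw, bh = box
    return bx <= x <= bx + bw and by <= y <= by + bh


def score_detection(detection, ground_truth: dict) -> dict:
    """Per-image record: coverage, white/black visibility, and correctness.

    *detection* may be None (a miss scores coverage 0).  The reported box is
    the tight crop when available, else the partition in original coords.
    """
    gt_box = ground_truth["crc_box"]
    record = {
        "correct": False,
        "coverage": 0.0,
        "white_visible": False,
        "black_visible": False,
        "n_verified": 0,
        "mode_used": None,
        "confidence": 0.0,
    }
    if detection is None:
        return record
    box = detection.reported_box()
    gt_area = gt_box[2] * gt_box[3]
    coverage = _intersection_area(box, gt_box) / gt_area if gt_area > 0 else 0.0
    white_ok = _point_in_box(ground_truth["white_patch_center"], box)
    black_ok = _point_in_box(ground_truth["black_patch_center"], box)
    record.update(
        correct=bool(coverage >= 0.80 and white_ok and black_ok),
        coverage=float(coverage),
        white_visible=white_ok,
        black_visible=black_ok,
        n_verified=detection.n_verified,
        mode_used=detection.mode_used,
        confidence=detection.confidence,
    )
    return record


def evaluate_sheet(image, ranker, verifier, config, mode: str, ground_truth: dict,
                   crop: bool = True, detector_fn=None) -> dict:
    """Detect on one (already loaded) sheet and score it, with timing."""
    t0 = time.perf_counter()
    if detector_fn is not None:
        det = detector_fn(image, mode)
    else:
        det = detect(image, ranker, verifier, config=config, mode=mode)
        if det is not None and crop:
            det = precision_crop(image, det, config=config)
    seconds = time.perf_counter() - t0
    record = score_detection(det, ground_truth)
    record["seconds"] = seconds
    return record


def run_benchmark(benchmark_dir, ranker, verifier, config: DetectorConfig | None = None,
                  modes=("normal", "quick"), report_dir=None, detector_fn=None):
    """Detect and score every sheet of a generated benchmark suite.

    Returns ``(per_image DataFrame, summary dict)``; optionally writes
    ``results.csv`` and ``report.md`` to *report_dir*.  Timings are reported
    but excluded from any pass/fail judgment (hardware-dependent); the
    quick-vs-normal comparison that matters is the proposal-count ratio.
    ``detector_fn(image, mode)`` substitutes the whole detection step when
    given (used for oracle/lower-bound harness checks).
    """
    if config is None:
        config = DetectorConfig()
    benchmark_dir = Path(benchmark_dir)
    images = sorted(benchmark_dir.glob("sheet_*.png"))
    if not images:
        raise FileNotFoundError(f"no benchmark sheets under {benchmark_dir}")
    rows = []
    for img_path in images:
        gt = json.loads(img_path.with_suffix(".json").read_text())
        sheet = standardize(load_image(img_path), config.target_short_side)
        for mode in modes:
            rec = evaluate_sheet(sheet, ranker, verifier, config, mode, gt,
                                 detector_fn=detector_fn)
            rec.update(image=img_path.name, mode=mode,
                       crc_side=gt.get("crc_side"), occluded=gt.get("occluded"))
            rows.append(rec)
    df = pd.DataFrame(rows)
    summary = {}
    for mode in modes:
        sub = df[df["mode"] == mode]
        summary[mode] = {
            "n": int(len(sub)),
            "accuracy_pct": float(100.0 * sub["correct"].mean()),
            "mean_coverage": float(sub["coverage"].mean()),
            "mean_n_verified": float(sub["n_verified"].mean()),
            "mean_seconds": float(sub["seconds"].mean()),
        }
    if "normal" in modes and "quick" in modes:
        sn = summary["normal"]["mean_seconds"]
        sq = summary["quick"]["mean_seconds"]
        summary["speed_ratio_quick_vs_normal"] = float(sn / sq) if sq > 0 else float("nan")
    if report_dir is not None:
        report_dir = Path(report_dir)
        report_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(report_dir / "results.csv", index=False)
        (report_dir / "report.md").write_text(_format_report(summary, config))
    return df, summary


def proposal_count_ratio(image, config: DetectorConfig | None = None) -> float | None:
    """Normal-grid size over quick-square count for one sheet (None if no square)."""
    if config is None:
        config = DetectorConfig()
    if image.processing_size[0] != config.target_short_side:
        image = standardize(image, config.target_short_side)
    squares = find_squares(image, config.proposal)
    if not squares:
        return None
    grid = sliding_windows(image.processing_size, config.proposal)
    return len(grid) / len(squares)


def _format_report(summary: dict, config: DetectorConfig) -> str:
    lines = [
        "# Chart-detection benchmark",
        "",
        "| Mode | Resolution (short side) | Accuracy (%) | Mean partitions verified | Mean seconds/image |",
        "|---|---|---|---|---|",
    ]
    for mode, s in summary.items():
        if not isinstance(s, dict):
            continue
        lines.append(
            f"| {mode} | {config.target_short_side} px | {s['accuracy_pct']:.3f} "
            f"| {s['mean_n_verified']:.2f} | {s['mean_seconds']:.2f} |"
        )
    ratio = summary.get("speed_ratio_quick_vs_normal")
    if ratio is not None:
        lines += ["", f"Quick mode wall-clock speedup over normal: {ratio:.2f}x"]
    lines.append("")
    return "\n".join(lines)
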