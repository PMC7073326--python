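# colornet-crc

CPU-friendly detection of small color reference charts (CRCs) on
high-resolution herbarium sheet images, with chart-driven white-balance and
orientation correction.

## The problem

Digitized herbarium sheets are archived at 3000 × 4000 px or more, with a
printed color reference chart — a grid of calibrated patches including pure
white and pure black — photographed next to the specimen. Automating
post-processing (white balance, orientation) requires finding that chart
first. Small charts (under 4 cm², roughly 2% of the sheet's width) defeat
generic object detectors, which downscale images until the chart dissolves,
and herbarium imaging stations rarely have a GPU.

This package implements a detection cascade designed around those
constraints:

1. **Standardize** the sheet to a working resolution of 1250 px on the short
   side (1250 × 1875 for a 2:3 sheet), portrait-oriented.
2. **Propose** candidate partitions. *Normal* mode slides a 125 × 125 px
   window with a 25 px stride over the whole raster (3266 partitions at
   1250 × 1875). *Quick* mode instead detects chart-sized square contours
   (dark frame on light paper) and proposes only those few boxes, falling
   back to the full grid when no square verifies.
3. **Rank** every partition with a multilayer perceptron over its color
   histogram. Each partition, regardless of size, is summarized by
   256 bins × 3 channels = 768 values per color space, RGB and HSV
   concatenated into a fixed 1536-vector — versus 125 × 125 × 3 = 46,875
   raw values for the window. Histograms are normalized to frequencies and
   enter the MLP through a Hellinger (square-root) map.
4. **Verify** partitions best-first with a small convolutional classifier on
   the raw pixels, stopping at the first candidate whose probability clears
   the acceptance threshold (0.5). On typical sheets the verifier examines
   one or two partitions instead of thousands.
5. **Precision-crop** the winning partition to the chart's frame contour and
   locate the white and black reference patches inside it.

The detected chart then drives two corrections: **max-white balancing**
(per-channel gain `g_c = 255 / mean_c(white patch)`) and **quadrant
orientation** (the 90°-multiple rotation that returns the chart to its
canonical corner, SE by default).

Everything runs on synthetic data: `colornet.synthdata` renders
herbarium-like sheets (paper texture, plant-like clutter, labels, colorful
logos, ruler strips) with a planted chart and full ground truth, under
capture augmentations — darkening, desaturation, white-balance casts,
90° rotations, wrong-size chart decoys, skew and partial occlusion — so
training, evaluation and the acceptance run need no downloads.

## Worked example

```python
from colornet import (render_sheet, SheetSpec, AugmentationParams, standardize)
from colornet.imgio import from_array
from colornet.pipeline import train_models
from colornet.detector import detect, precision_crop
from colornet.postprocess import compute_gains, apply_gains, orient

ranker, verifier = train_models(seed=101)   # ~5 min on one CPU

# a sheet whose chart sits in the SE corner, then mis-captured:
# darkened to 70%, red-heavy cast, rotated 90 degrees
spec = SheetSpec(seed=7, crc_quadrant="SE",
                 augmentation=AugmentationParams(darken=0.7,
                                                 wb_shift=(1.25, 1.0, 0.8),
                                                 rotate_k=1))
img, truth = render_sheet(spec)

sheet = standardize(from_array(img))
det = precision_crop(sheet, detect(sheet, ranker, verifier, mode="quick"))
print(det.to_json())
gains = compute_gains(sheet, det.white_region)
print("gains:", tuple(round(g, 3) for g in gains.gains))
balanced = apply_gains(sheet, gains)
righted, decision = orient(balanced, det, target_quadrant="SE")
print("orientation:", decision.observed_quadrant, "->",
      decision.target_quadrant, "rotate", decision.rotation, "deg")
```

prints

```
{"black_region": [1035.0, 329.0, 6.0, 6.0], "confidence": 0.9999999999961195,
 "low_confidence": false, "mode_used": "quick", "n_verified": 1,
 "partition": [837, 1013, 106, 106], "partition_original": [1013.0, 307.0, 106.0, 106.0],
 "tight_box": [1028.0, 322.0, 76.0, 76.0], "white_region": [1035.0, 385.0, 6.0, 6.0]}
gains: (1.433, 1.783, 2.237)
orientation: NE -> SE rotate 270 deg
```

Reading the output: quick mode proposed a single square, the verifier
accepted it on the first try (`n_verified: 1`), and the precision cropper
tightened the 106 px proposal to the chart's true 76 px extent. The
recovered gains invert the applied cast and darkening — the ground truth for
this sheet is (1.429, 1.786, 2.232) — and the 270° counterclockwise turn
undoes the 90° mis-rotation, returning the chart from NE to its SE
convention.

The same pipeline is available from the shell:

```bash
colornet train --out models
colornet detect --mode quick --models models sheet.jpg
colornet correct --wb --orient --target-quadrant SE sheet.jpg fixed.jpg
colornet evaluate --benchmark bench --generate 200 --seed 999 --mode all
```

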