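# Methods

This note records the models, parameters and design choices behind the
package, and what the synthetic experiments do and do not demonstrate.

## Detection cascade

The detector is a two-stage cascade over candidate partitions of a
standardized working raster.

**Standardization.** Sheets are resized so the short side is
`target_short_side` (default 1250 px; a 2:3 archival sheet becomes
1250 × 1875). Aspect ratio is preserved — sheet proportions vary, and the
window grid adapts to any long side — and landscape inputs are rotated 90°
clockwise to portrait, with the rotation recorded so all reported boxes are
mapped back to as-loaded coordinates. Downscaling uses bilinear
interpolation with anti-aliasing; the pipeline is histogram-based, so the
resampling filter is low-stakes.

**Proposals.** Normal mode is an exhaustive sliding window: 125 × 125 px,
25 px stride, row-major, with a *full-coverage rule* appending one final
column/row at `W − window` (resp. `H − window`) whenever the stride grid
does not reach the border — a chart flush against the sheet edge must still
be covered. At 1250 × 1875 the grid is exact: 46 × 71 = 3266 windows.
Quick mode binarizes the luminance below several levels between the darkest
pixel and the median (paper), keeps connected components whose bounding box
side is 40–140 px with aspect ratio ≤ 1.25 and fill ≥ 0.75, and accepts a
component if its (hole-filled) outline simplifies to a convex quadrilateral
with corner cosines ≤ 0.3 — the classic square-contour recipe. The outline
is re-seamed to start at the corner farthest from the centroid before
simplification; otherwise the simplifier pins a spurious vertex at the
trace's arbitrary starting point. Accepted squares are padded by 15 px of
context; near-duplicates (IoU > 0.8) merge to the larger. The 40–140 px
band covers a <4 cm² chart on a ~31 cm sheet at this resolution with margin
for skew and template variation.

**Features.** A partition of any size is summarized by six 256-bin
intensity histograms — R, G, B, then H, S, V in fixed order — i.e. 768
values per color space, 1536 in total. Hue is quantized to 0–255 rather
than the common 0–179 so every channel shares one 256-bin domain; this
costs a worst-case reconstruction error of ±3 levels on a round trip
through HSV (hue bin width 360/255°), which is irrelevant for histogram
ranking. Histograms are normalized to frequencies so Quick mode's
variable-size proposals and the fixed windows live on the same scale. For
the regular grid, per-window histograms are computed by a tiled
integral-histogram scheme (one `bincount` over the raster at stride-sized
tiles, then 2-D prefix sums), which makes the full 3266-window pass take a
fraction of a second.

**Ranker.** An MLP of widths 1536 → 512 → 128 → 1 (ReLU, sigmoid head),
trained with Adam on binary cross-entropy for 12 epochs, batch 64, learning
rate 1e-3 (scikit-learn's implementation; weights are extracted so inference
is a plain numpy forward pass). Features enter through a Hellinger
(element-wise square-root) map: histogram frequencies are spiky, and the
sqrt map stabilizes their variance — without it the MLP
leans on the few dominant bins and generalizes noticeably worse. The ranker only orders
candidates; its probabilities are never thresholded.

**Verifier.** A small CNN on the raw 125 × 125 × 3 patch: three 3 × 3
conv blocks (16/32/64 filters, each ReLU + 2 × 2 max-pool), a dense-64
layer and a sigmoid unit, written directly in numpy (im2col convolutions,
Adam, BCE; deterministic for a fixed seed). The stack runs at a reduced
internal resolution — the patch is box-averaged to 30 × 30 — which keeps
pure-numpy training in the low minutes at no measurable accuracy cost on
this task; the 125 × 125 × 3 interface is unchanged, and non-square Quick
proposals are resized (never cropped) to 125 × 125 beforehand. Training:
15 epochs, batch 64, lr 1e-3.

**Cascade policy.** Partitions are verified in ranked order with early
stopping at the first probability ≥ 0.5 (`accept_threshold`), examining at
most `max_verify` = 25. If nothing passes, the best candidate is returned
flagged low-confidence, or nothing at all if its probability is below 0.1.
In Quick mode, if no square candidate passes verification the detector
falls back to the full grid: "no appropriate square containing the chart"
is judged by the verifier, not by mere contour presence. Early stopping is
what bounds the expensive stage — on the synthetic benchmark the verifier
examines ~1–2 partitions per sheet on average.

**Precision crop.** Within the winning partition padded by 64 px, the same
square-contour operator (size-unrestricted) finds the chart frame; its
bounding box is the tight crop. The pad is about half a window because an
accepted window may cover just over half the chart (training positives are
defined at ≥ 50% overlap) and the whole frame must be visible to the
contour search. When no contour closes — typically partial occlusion — the
bounding box of the dominant dark connected structure near the partition is
used instead (the frame remains the darkest large structure, and the
correctness criterion is one-sided, so a generous box is harmless); only on
structure-free regions does the crop fall back to the partition box itself.
The white (black) reference region is found by scanning a cell of one sixth
of the chart side over the tight box with an integral image and taking the
centroid of the brightest (darkest) tier of cells, shrunk to its central
50% to stay clear of patch borders.

## Post-processing

**Max-white balance.** Per channel, gain = 255 / mean over the white
region, computed on the original-resolution raster (the archival image is
what gets corrected); gains are clipped to (0, 8] and a zero-mean channel
is an error. The mean over the patch interior is used rather than a literal
per-pixel max for robustness to compression noise. Applying gains then
re-estimating them yields gains within 1% of unity (fixed point).

**Quadrant orientation.** The chart center's quadrant relative to the image
center determines the unique k × 90° counterclockwise rotation onto the
canonical quadrant (default SE — a user convention, configurable). Rotation
is lossless (`rot90`), conserving the pixel multiset exactly. A chart
center exactly on a center axis raises an ambiguity error.

## Synthetic data

The generator emulates the features of digitized herbarium sheets that this
pipeline is sensitive to: light noisy paper; dark plant-like blob and stem
clutter; white label rectangles with text-like line fill; colorful logo
blocks and ruler strips (the canonical failure modes of a pure
color-histogram ranker); and a chart rendered from a 5 × 5 patch-grid
template — exactly one pure-white and one pure-black patch, a gray ramp and
20 saturated/natural hues inside a dark frame — at 51–96 px rendered side.
30% of charts are skewed up to ±8°, and 10% are partially occluded (a blob
over one corner, under 20% of the area).

Capture augmentations: darkening (multiplier in [0.4, 1]), desaturation
(blend toward luminance, [0, 1]), a per-channel white-balance cast
([0.6, 1.4]), k × 90° sheet rotations, and wrong-size chart-like decoy
overlays (side below 40 px or above 140 px at working scale) on 20% of
sheets. Cast multipliers are normalized so the largest channel gain equals
the darkening factor: on an 8-bit render a gain above 1 clips the white
patch, destroying the information the max-white estimator needs — a real
mis-balanced capture is an attenuation, not a saturation. Ground truth
records the effective per-channel gains actually applied.

Training patches (125 × 125, balanced) are rendered directly: positives
contain a chart keeping ≥ 50% of its area in-window (overhang on one axis
only); negatives are clutter, labels, logos, and wrong-size decoys —
including windows across the *edges* of oversized decoys, which early
experiments showed to be the verifier's main blind spot. Per-patch
augmentation oversamples the hardest corner of the range (darkening ≤ 0.6
combined with desaturation ≥ 0.65; 35% of draws): under uniform sampling
that corner is rare, yet it is where chart appearance degenerates most.
Training, benchmark, white-balance and orientation streams draw from
disjoint seed namespaces of one user seed, and every output is a pure
function of its seed (byte-identical re-renders).

What passing does and does not show: the benchmark exercises small-object
search, color degradation, decoys, skew and occlusion, but its clutter is
schematic — no real leaf texture, camera noise profiles, JPEG artifacts,
shadows or lighting gradients — so accuracy here bounds the method's
mechanics, not its field performance on real archives.

## Experiment sizes and numerical choices

The standard recipe trains the ranker on 10,000 patches and the verifier on
8,000, evaluates on 200 held-out sheets at full working resolution under
both proposal modes, and runs 100-trial white-balance and orientation
studies; the whole cycle fits comfortably in the low tens of minutes on one
CPU. Correctness of a detection is mechanical: the reported box (tight crop
when present) must cover ≥ 80% of the chart's area — denominator the chart,
not the union — and contain both the white- and black-patch centers, a
machine-checkable version of "at least 80% of the chart with the whitest
and blackest parts visible". Ranking ties break by row-major partition
order; all RNG flows from explicit seeds; model containers are `.npz` files
with an embedded JSON architecture header, and loading refuses mismatched
shapes.

## Known limitations

* The verifier's reduced internal resolution (30 × 30) would blur the grid
  structure of charts much smaller than ~40 px; such charts are outside the
  proposal band anyway.
* Only the first confidently verified chart is reported; sheets bearing two
  valid charts return one of them.
* Occluded charts break the frame contour; the dark-component recovery
  usually, but not always, spans the full chart.
* The quadrant convention assumes institutions place charts in a corner;
  a chart near the image center yields an ambiguity error by design.
* White-balance correction is a single global per-channel gain; it does not
  model spatially varying illumination or nonlinear tone response.
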