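# Methods

This note documents the models and procedures implemented in `stickytrap`,
the defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical corner cases.

## Box geometry and suppression

Boxes are axis-aligned, continuous, 0-based and half-open
(`[x_min, x_max) × [y_min, y_max)`); zero-area boxes are rejected at
construction rather than silently scored. No integer rounding happens inside
geometry operations.

IoU is intersection area over union area. The DIoU penalty is
`R = ρ²(b_a, b_b) / c²` with `ρ` the Euclidean distance between box centres
and `c` the diagonal of the smallest axis-aligned rectangle enclosing both
boxes; `R ∈ [0, 1)`, is zero iff the centres coincide, and is invariant
under translation and uniform scaling. The DIoU regression loss is
`1 − IoU + R ∈ [0, 2)`.

Both suppressors are greedy: repeatedly keep the highest-scored unsuppressed
box `M` and discard every comparable box `B` with criterion ≥ ε, where the
criterion is `IoU(M, B)` for plain NMS and `IoU(M, B) − R(M, B)` for
DIoU-NMS. Design choices:

* **Tie-break**: equal scores break by lower class id, then lexicographic
  coordinates — suppression order is fully deterministic.
* **Threshold semantics**: suppression fires at criterion **≥ ε**
  (non-strict), so ε itself suppresses.
* **Defaults**: ε = 0.45 (common detection practice; exposed everywhere) and
  class-aware suppression (per-class de-duplication), both configurable.
* **Superset caveat**: against any single reference box, DIoU suppression is
  weaker than IoU suppression (`IoU − R ≤ IoU`), which is the mechanism that
  separates adjacent same-class insects. Over a full greedy run, however,
  the DIoU keep-set is *not* provably a superset of the IoU keep-set: a box
  rescued by the centre-distance term can itself suppress a lower-scored
  neighbour that plain NMS had kept. Random-instance experiments put such
  cascade escapes below 1% of instances; the test suite verifies that every
  observed escape is exactly of this rescued-suppressor form.

## Tile grids and merging

For image dimension `d` and tile size `t`, the planner uses
`n = ceil(d / t)` tiles per axis with uniform overlap
`o = (n·t − d) / (n − 1)` (0 when `n = 1`). Fractional remainders are
distributed one pixel each to the earliest gaps, keeping all origins
integral and the last tile flush with the image edge. This rule reproduces
the 6 × 5 grid with 64 / 134 px overlaps for a 3280 × 2464 frame at 600 px
tiles and generalises to any camera. Planning is pure and deterministic;
grids serialise to JSON.

Ground-truth clipping intersects each global box with each tile and keeps it
(in tile-local coordinates) iff the visible area fraction is at least
`min_visibility`. Two different thresholds are used deliberately:

* **Training-set construction**: `min_visibility = 0.25` — partially cut
  insects are still useful positives.
* **Inference-time oracle**: `min_visibility = 0.6`, with the score set to
  the visible fraction. Count-exact recovery after whole-image DIoU-NMS
  requires that (a) every retained duplicate view overlaps the fullest view
  by at least `ε + max R` so it gets suppressed, and (b) the fullest view
  wins the score comparison. For near-nested duplicate views `R ≲ 0.05`, so
  a retention threshold of 0.6 > 0.45 + 0.05 satisfies (a) with margin for
  every pest whose extent does not exceed the tile overlap by more than the
  catalogue allows, and visibility-scores satisfy (b). With uniform scores
  (plain clipped truth) the lexicographic tie-break may keep a partial view;
  the clip→merge round trip is then one-to-one at IoU ≥ 0.9 only when
  slivers below 0.9 visibility are dropped, which the tests exercise
  explicitly.

Merging translates tile-frame boxes by their origin, clips them to the image
extent, pools all tiles and runs a **single** whole-image DIoU-NMS pass (no
per-tile pre-suppression). DIoU rather than plain NMS is used at the merge
for consistency with the per-tile suppressor.

## Network-geometry calculator

`feature_map_sides` divides the input side by strides 32/16/8;
`cell_field` is the input-pixel footprint of one cell of the finest grid
(8 px at 608 input); `min_detectable_on_raw` back-projects that cell through
the whole-frame resize, `round_half_up(cell · raw / input)`, giving the
43 × 32 px floor for a 3280 × 2464 frame — and 8 × 8 px when 600 px tiles
are fed instead, a ~5.4× reduction that is the quantitative argument for
tiling. The 8 × 8 figure equals the stride of the finest map, not a traced
theoretical receptive field; the calculator implements the conventional
stride-based definition. Rounding is half-up so the 43.2 × 32.4 mapping
prints as 43 × 32. The module computes shapes only — no tensors.

## Synthetic scenes

The generator emulates a 20 × 25 cm yellow board imaged landscape at
3280 × 2464 px, i.e. **13.12 px/mm** (derived from board size and sensor
resolution; the scale is exposed because real rigs vary). At that scale a
0.5 mm thrips spans ~7 px — below the 43 × 32 whole-frame floor but above
the 8 px tile-level floor, so the simulated regime reproduces the
motivating size gap exactly.

Six classes with mm body-length bands and width/length aspects:
tobacco whitefly 1.0–1.5 (light tone; its body length is an assumption, not
a tabulated field value), thrips 0.5–2.0, winged aphid 1.8–2.6 (a nominal
2.2 mm widened for sampling variety), leaf miner 4–6, fruit fly 1.5–4,
housefly 5–8 (all dark). Relative frequencies follow a realistic imbalanced
trap catch (≈ 1024 : 857 : 1092 : 941 : 873 : 1013). Pests are rotated
ellipses with overlapping wing specks on a noisy yellow background with a
random illumination gradient; dust distractors are drawn below the thrips
size band (~30 per megapixel at clutter level 1). The truth box is the
bounding box of the rendered footprint, one per pest, scores 1.0.

Placement samples the catch first, then places the largest insects first by
rejection sampling; the default minimum centre separation keeps footprints
disjoint (the non-overlapping counting regime), and `separation=False`
enables adjacent/overlapping pairs for suppression experiments. A board too
small for the requested count raises rather than degrading silently.

Monitoring series are day-indexed scenes whose expected daily counts follow
a piecewise outbreak profile (quiet ~37/day start, a burst to ~325 a fifth
of the way in, decay to ~92, a sustained fluctuating 214–419 finish over 40
days), with Poisson day-to-day noise; scene seeds derive as `seed + day`.

**What the scenes do not emulate**: insect texture, wing venation,
translucency, glue glare, board wear, occlusion by the trap frame, or
capture-efficiency covariates. Passing tests demonstrate correctness of the
geometry, suppression, metric and counting machinery — not appearance-level
performance on real greenhouse imagery, for which a trained detector must
be plugged into the same contract.

## Reference and oracle detectors

The detector contract is a callable `(tile_raster, origin) → DetectionSet`
in tile-local coordinates. The **oracle** replays clipped ground truth as
described above and exists to validate the pipeline. The **reference
detector** is a deliberately classical baseline: per-tile median colour as
the board estimate, foreground where the RGB distance exceeds 60 (robust to
the ±18 illumination gradient and σ = 4 sensor noise), connected components
(8-connectivity), then per-blob filtering — components shorter than 0.45 mm
are dust; components touching an *interior* tile seam are cut views whose
complete view exists in a neighbouring tile and are dropped (insects wider
than the 64 px x-overlap that straddle a vertical seam can be lost this
way — a known ~1–2% recall cost on the largest classes). Classification
assigns the size band containing the blob's major-axis length, using tone
(light = whitefly) to disambiguate; the score is blob solidity times a
band-membership factor (0.5 when no band contains the length). The detector
exercises the pipeline and metrics; it is not calibrated to imitate any
learned model's accuracy, and its class confusion between size-overlapping
species is expected.

## Metrics

Matching is greedy: predictions in descending score order claim the
unclaimed truth of highest IoU ≥ threshold (same class unless
class-agnostic; IoU ties break toward the lower truth index). Default
matching threshold 0.5. P/R/F1 use the 0/0 → 0 convention. AP is the area
under the all-point-interpolated PR curve (monotone precision envelope) —
chosen over 11-point interpolation as the modern convention; mAP averages
over classes present in the truth only. The confusion matrix matches
class-agnostically so misclassifications populate off-diagonal cells;
missed truths go to the background column, spurious predictions to the
background row; row normalisation leaves empty rows at zero. Per-class
fixed-operating-point precision and per-class AP answer different
questions, so evaluation reports provide both.

## Augmentation

Mosaic stitches four jittered inputs around a random centre split point,
cropping overflow and padding shortfall with neutral gray. Rotation is
restricted to quarter-turns plus flips because axis-aligned boxes cannot
represent arbitrary rotation without re-fitting; brightness/hue jitter act
multiplicatively/additively in HSV. Boxes follow their patch, are clipped to
the pasted region, and are dropped below 4 px². All randomness flows through
one seeded generator — identical inputs and seed give bit-identical output.
Tile expansion writes every tile with clipped YOLO-txt labels (empty label
files kept as negatives) plus a provenance manifest; curation of
uninformative tiles is left to the user.

## Problem sizes in the shipped checks

The test suite and acceptance script size their simulations to run
comfortably on one CPU: 1000 random instances for the NMS brute-force and
superset checks; 50 (suite) / 20 (script) full-resolution boards of 30–200
non-overlapping pests for truth recovery and reference-detector quality; a
full 40-day season at native resolution for the monitoring identity. These
sizes were chosen once as adequate statistical coverage for the properties
asserted.

## Known limitations

* The reference detector assumes a roughly uniform board occupying the tile;
  heavy occupancy (> ~half the tile area covered by insects) would bias the
  median colour estimate.
* Count exactness through the tile pipeline is analysed for insects whose
  extent is at most `overlap + tile-fraction` margins described above;
  pathological objects larger than a tile are out of scope.
* YOLO-txt round trips are exact only to normalisation precision (9 decimal
  places — well below a thousandth of a pixel at these image sizes).
* The monitoring module counts per captured frame; converting board totals
  to daily arrivals (boards accumulate) is deliberately left to the analyst.
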