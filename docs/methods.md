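# Methods

## Pixel classification model

The classifier is a pair of deterministic RGB threshold rules applied
independently to every pixel; there is no spatial context, no color
deconvolution, and no learned component. The assumptions are those of
routine bright-field IHC scans: background is unstained glass (bright,
achromatic), all tissue carries hematoxylin counterstain (blue-dominant),
and positive signal is DAB chromogen (brown: red-dominant and dark).

Parameters, all exposed on `PixelClassParams`:

| parameter | default | units | role |
|---|---|---|---|
| `bg_min` | 230 | intensity | minimum channel value for background |
| `bg_uniformity` | 25 | intensity | maximum channel spread for background |
| `dark_threshold` | 125 | intensity | a stained pixel needs one channel below this |
| `alpha` | 1.00 | — | blue-dominance scale on R |
| `beta` | 1.25 | — | blue-dominance scale on G |

Numerical conventions, fixed once and tested at the boundaries:

- Background requires `min >= bg_min` (inclusive) and
  `max - min <= bg_uniformity` (inclusive). "Bright and consistent" has
  no canonical formula; min-channel plus spread was chosen because it
  penalizes chromatic (tissue) pixels even when bright, and both
  thresholds remain user-tunable.
- The darkness test is strict (`min < dark_threshold`).
- Blue dominance is the conjunction `B >= alpha*R and B >= beta*G`, with
  non-strict comparisons so that exact ties count as blue-dominant
  (unstained). Both choices bias against false-positive stain calls.
  The conjunction (rather than a disjunction) is required to reproduce
  the reference behavior on red-dominant pixels whose blue channel
  exceeds the red-scaled bound but not the green-scaled one.
- `is_stained` is total but only meaningful on non-background pixels;
  `classify_pixel` short-circuits background first.

The vectorized implementation is verified against a naive scalar loop
over the rule definitions (identical label rasters on random images);
the loop is the oracle and shares no code with the production path.

## ROI and whole-block processing

ROIs are classified in one pass. Whole-block images are partitioned by a
fixed grid (default 4 x 4); tile heights/widths are floor divisions and
the last row/column absorb remainders, which keeps the partition exact
for dimensions not divisible by the grid. Tiles are processed
sequentially with only one tile resident (paths are memory-mapped via
`tifffile` when the format allows), and tallies are accumulated as
integers — the tiled result equals the single-pass result exactly, which
is asserted property-style over random images and grid shapes. A region
with zero sample pixels reports an undefined stain fraction, never 0.

`normalize_by_max` rescales a measurement series by its maximum so that
independent measurement methods can be compared on a relative scale.

## TMA de-arraying

The grid design (`grid_rows x grid_cols`) is user-declared, never
inferred. Detection runs on a thumbnail: the tissue mask is closed with
a disk (radius defaulting to 5% of the design spacing, at least 3 px) to
merge fragmented cores, holes are filled, and connected components
outside an area window are discarded. The window defaults to
`[0.2, 2.5] * pi * r^2` with expected core radius `r = 0.8 * spacing/2`,
derived from the declared design so the defaults are
resolution-independent; both bounds are overridable.

Gridding proceeds in four steps:

1. **Spacing** is the median nearest-neighbor centroid distance (the
   median is robust to missing cores and to the occasional fragment).
2. **Walk.** The core with minimal `x + y` (ties: smaller y, then x)
   anchors a walk down the first column: accept the nearest centroid
   within `col_tolerance * spacing` (default 0.35) perpendicular offset
   and within `spacing_window * (k * spacing)` (default (0.5, 1.5))
   along the walk, expanding the gap `k` past missing cores up to
   `max_gap`. Because the windows for `k >= 2` overlap, the lattice step
   actually taken is `round(offset / spacing)`, not the search index.
   If the first column yields fewer than `baseline_min_fraction`
   (default 0.5) of its expected cores, the first row is used as the
   baseline instead. Each baseline core then anchors the same walk along
   its line. The 0.35 / (0.5, 1.5) tolerances admit ±10%-of-spacing
   jitter while rejecting diagonal neighbors (offset ≈ 1.41 spacing at
   45°).
3. **Registration.** The walk labels its anchor cell (0, 0), which is
   only correct when the array's top-left corner is populated. Each
   centroid's absolute lattice index is estimated independently as its
   offset from the extreme coordinate in units of the spacing, and the
   walked assignment is shifted by the modal difference. Without this
   step a missing corner core shifts every label by one.
4. **Reconciliation.** Centroids the walks could not reach (typically
   cores whose entire baseline anchor is absent) are placed into the
   nearest empty cell predicted from the assigned rows' and columns'
   median coordinates, under the same tolerance. Assignment injectivity
   (one core per cell) is maintained throughout.

Steps 3-4 extend the baseline-walk procedure; they are required for
correct absolute labels under realistic dropout and are exercised by the
parameter-recovery tests (5 x 5 arrays, ±10% jitter, 20% missing cores,
10 seeds, 100% correct assignment of surviving cores).

Row/column labels are optionally inverted (`invert_labels`, default on)
because scans are commonly oriented opposite to the pathologist's
numbering; the operation is an involution and is switchable off.
Centroids scale to the full image by per-axis size ratios, rounded
half-to-even; an aspect-ratio mismatch above 1% aborts (the images are
not the same scene). Each core is scored in a square window defaulting
to the spacing scaled to full resolution, so windows abut without
overlapping. No rotation correction is attempted: skew beyond the
tolerances is a documented failure mode, not silently absorbed.

Annotations join on exact `(row, col)`; duplicated annotation keys are
an error, unmatched keys on either side are logged. The canonical export
is CSV (an `.xlsx` suffix switches to a spreadsheet writer); undefined
stain fractions export as empty cells.

## Co-localization statistics

`PVI = ki67_fraction / cd31_fraction` per sample; samples with CD31 = 0
are excluded from ratio endpoints with a logged reason rather than
propagated as 0 or infinity. Grouping is Gleason <= 7 (low) versus >= 8
(high). The test is the classical pooled-variance two-sample t
(two-tailed, `df = n1 + n2 - 2`, alpha 0.05); an unequal-variance Welch
variant is available behind a flag for sensitivity analysis but is not
the default. No multiple-testing correction is applied — each endpoint
is reported per-comparison. Tests verify the implementation against an
independent closed-form pooled-variance computation, check label-swap
symmetry, and calibrate type-I error (within the exact binomial 99%
interval at alpha 0.05 over 1000 null replicates, n = 10 per group) and
power (> 0.8 at a 2-pooled-SD separation).

## Synthetic data generator

The generator exists so that every stage is testable with exact ground
truth and no external images. It emulates the *color statistics* of
IHC scans — near-white background (channels 240-255, spread <= 5),
hematoxylin-blue unstained tissue (`B >= 1.25 G`, `B >= R`), DAB-brown
stained tissue (R dominant, B < R, at least one channel below 125) — and
the *geometry* of TMAs: a lattice of circular cores with uniform
per-axis jitter, Bernoulli dropout, fragmentation into half-disks with a
3-px gap, and sub-threshold debris. Default study conditions for the
recovery experiments: 5 x 5 grid, spacing 100 px, core radius 30 px,
jitter 10% of spacing, 20% missing cores.

Two properties make the tests exact rather than statistical: every
emitted color is rejection-verified against the classifier at generation
time (generator labels and classifier labels agree by construction), and
target fractions are realized by placing exact pixel counts at shuffled
positions, so a recovered fraction differs from its target by at most
one pixel's worth of rounding. The full-resolution TMA image is an
integer pixel-replication upscale of the thumbnail, which preserves
per-core fractions exactly across scales.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: nuclear/glandular texture, stain gradients
and mixing at structure boundaries, scanner noise and compression
artifacts, tissue folds, and rotated or hex-packed TMA layouts. The
classifiers under test are pure color rules, so color statistics suffice
to verify the code paths; accuracy on real slides depends on threshold
choices that this package exposes but cannot validate synthetically.

Marker-pair simulation draws CD31 fractions from a fixed Uniform(0.02,
0.08) (typical vascular stain area), sets each sample's PVI to its group
mean times lognormal noise (`noise_sd` on the log scale), and derives
Ki-67 as `PVI * CD31` — so the group signal lives in the ratio while the
CD31 distribution is identical across groups, mirroring the structure of
a co-localization study in which vascularity is grade-invariant.

## Problem sizes and determinism

Test and acceptance runs use 64-100 px classification images, 512 px
whole-block fixtures, 5 x 5 TMAs at spacing 100 px (thumbnail ~600 px,
4x upscale), 1000 t-test replicates at n = 10 per group, and 10 TMA
seeds; these sizes keep every ground-truth identity exact while the
whole suite completes in well under a minute of compute. All randomness
flows from explicit seeds; identical specs and seeds yield byte-identical
images and CSVs.

## Known limitations

- Thresholds are scanner- and stain-protocol-dependent; the defaults
  suit typical 8-bit bright-field scans but should be checked against a
  manually scored field before production use.
- No color deconvolution: heavily mixed DAB/hematoxylin pixels are
  assigned by channel dominance alone.
- De-arraying assumes an axis-aligned grid; rotation or hex packing is
  out of scope.
- The ratio statistics treat each input row as an independent sample;
  when multiple blocks per subject are supplied, the unit of analysis is
  the block, and any subject-level correlation is ignored.
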