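# Methods

This note records the conventions, models and design choices behind
`dropsight`, the assumptions they rest on, and what the test suite does and
does not demonstrate.

## Coordinate and geometry conventions

One convention is used everywhere: 0-based indices, origin at the image's
top-left, `x` = column, `y` = row. Bounding boxes are half-open
(`[xmin, xmax) × [ymin, ymax)`). The pixel at row `r`, column `c` covers the
unit square with centre `(c + 0.5, r + 0.5)`.

**Rasterization.** A pixel is foreground iff its centre lies inside the
polygon, with points exactly on the boundary counting as inside, and
self-intersecting polygons filled by the even–odd rule. This rule was chosen
because it is unambiguous and oracle-checkable: the test suite re-derives
every rasterized mask with shapely's `covers` predicate at pixel centres and
requires exact agreement. The implementation is a vectorized crossing-number
test plus an explicit on-edge check (tolerance 1e-9, scaled by edge length);
polygons whose interior misses every pixel centre raise an empty-mask error
rather than returning an empty mask silently.

**Bounding boxes** are always the tight box of the mask; annotations and
detections validate this at construction.

## Preprocessing

Micrographs are downscaled by an integer factor (default 2, e.g.
3376×2704 → 1688×1352) and contrast-adjusted with CLAHE on a 12×12 tile grid.
The CLAHE clip limit is exposed in the OpenCV-style convention (default 2.0),
where the per-bin histogram ceiling is `clip × tile_area / 256`; it is
converted to scikit-image's normalized clip limit internally (`clip / 256`).
CLAHE cannot flatten a strictly two-valued histogram (any monotone intensity
map preserves the two atoms), so the flattening property is tested on a
two-mode pattern with within-mode spread, where the earth-mover distance to a
uniform histogram decreases.

## Synthetic scenes

The generator emulates the *geometry* of sitting-drop micrographs: one
quasi-elliptical drop per image, 0–N convex polygonal crystals (perturbed
regular polygons, convex-hulled, clipped to the drop when
`crystals_inside_drop` is set), a dark drop rim with an interior gradient,
bright/dark crystal fills and Gaussian noise. Defaults (256×320 frame,
drop semi-axes 120×95 px, 0–6 crystals of 10–40 px, noise σ = 8 grey levels)
were chosen once as plausible desk-scale stand-ins; the crystal-count
distribution of real drops is not characterized in the literature we follow,
so all of these are constructor parameters rather than constants.

Scores mirror the ten-point outcome system: scenes with ≥ 1 crystal draw a
score from {6..9} (the crystal classes), crystal-free scenes from {0..5},
under configurable weights — so the score's four-class mapping is
"Crystals" exactly when a crystal exists.

All randomness descends from a single seed through named
`numpy.random.SeedSequence` child streams (layout, rendering, scoring), so
scenes, tables, panels and mock detections are bit-reproducible.

What passing tests show: the downstream geometry, curation and metric code is
correct on inputs whose ground truth is known exactly. What they do not show:
robustness to photometric properties of real micrographs (glare, shadow,
focus) — the renderer makes no claim of visual realism, and nothing
downstream consumes the pixel values except the preprocessing contract tests.

**Expert panels** are simulated per-expert from 4×4 row-stochastic confusion
matrices applied to the true label. For uniform-error experts with accuracy
`a`, pairwise agreement has the closed form `a² + (1−a)²/3` and unanimous
three-expert agreement `a³ + (1−a)³/9`; simulations are required to match
these within 3 binomial standard errors at n = 2000.

**The mock detector** emits each ground-truth crystal mask with probability
`1 − drop_prob`, adds spurious small-polygon detections at a Poisson rate,
and assigns confidences by a pluggable score law (default constant 0.9). Its
corruption parameters give closed-form expectations for downstream recall and
for the image-level classification collapse, which the tests check.

## Curation rules

- **Score mapping**: 0 → Clear; {2,3} → Precipitate; {1,4,5} → Other;
  {6,7,8,9} → Crystals.
- **Subwell de-duplication**: "the second of these inspections" is read as
  the second-lowest *scored* inspection number, not inspection #2 literally —
  robust to missing inspections; a subwell with a single scored inspection
  contributes that image.
- **Split sizes**: train size is `round(fraction × N)`, which reproduces the
  published 11161/2790 partition of 13951 images at 80%. An optional flag
  stratifies the split per class (whether the original split was stratified
  is unstated; both behaviours are exposed).
- **Relabel flagging**: the `ceil(fraction × N)` highest-loss images; ties at
  the cut broken by ascending image id for determinism.
- **Consensus sets**: unanimous images enter both consensus sets; a strict
  majority (> n/2; for three experts, exactly two agreeing) enters only the
  mostly-unambiguous set with the modal label; the rest are discarded. The
  modal-label choice for majority images is implied but not stated by the
  source process; it is documented here as this package's rule.
- **Balancing weights**: item weight ∝ 1/count(class), normalized to sum
  to 1, making expected class frequencies uniform under weighted sampling
  with replacement.

## Targeting

- The distance transform is scipy's exact Euclidean EDT with the image
  border padded by background, so a drop touching the frame edge is not
  treated as infinitely clear there. An O(N²) brute-force minimum over
  background pixels serves as the oracle in tests (exact agreement required
  on 200 random masks up to 32×32).
- Dispense argmax ties are broken by smallest row, then column (first
  row-major index) — deterministic across platforms. Degenerate rectangles
  make whole segments tie; the tie-break picks the leftmost pixel of the
  first such row.
- Centroids are continuous pixel-centre coordinates; `inside_mask` records
  whether the containing pixel is foreground (false for ring-like crystals),
  surfacing the concave-crystal ambiguity instead of guessing a fallback.
- With multiple drop detections, the highest-probability one is used (one
  drop per image is the physical expectation). Crystals covering the entire
  drop leave no feasible point: `dispense_point` raises, while the
  `make_targets` composition reports the dispense target as absent.

## Evaluation

- Zero-denominator conventions: precision and recall are 0 when undefined;
  AP is undefined (`None`) where a (class, threshold, size-bin) cell has no
  ground truth, and undefined cells are excluded from all means. Classes
  absent from both truth and predictions are excluded from macro means.
- Matching is COCO-style greedy: detections in descending confidence, each
  taking the unmatched same-class ground truth of highest IoU if it reaches
  the threshold; every ground truth matches at most once.
- AP uses the 101-point interpolation (`max` precision at recall ≥ r over
  the grid 0, 0.01, …, 1), the standard COCO definition; thresholds default
  to 0.50:0.05:0.95 and size bins to all / ≤32² / (32², 96²] / >96² pixels,
  boundaries inclusive on the lower bin. Ground truth is binned by its own
  area (mask pixels or box area per geometry) and detections by theirs; the
  full COCO "ignore" machinery for out-of-bin matches is deliberately not
  reproduced — a documented simplification shared by most compact
  reimplementations, and the reason mAP checks are property-based (perfect
  detections → 1.0, erosion degrades strict thresholds first, hand-computed
  micro-benchmark) rather than tied to any published table.
- The classification collapse labels an image "Crystals" iff at least one
  crystal detection survives the probability threshold (default 0.6, the
  production operating point).

## Pipeline

Every command is deterministic given its config (seeds are explicit,
wall-clock seeding is not used); manifests record the config, its hash and
library versions. Exit codes: 0 success, 2 validation, 3 I/O, 4
predictor-contract violation. The `PredictorInterface` protocol is the seam
where a trained instance-segmentation model can replace the mock detector
without touching targeting or evaluation code.

## Problem sizes

The test suite and acceptance script run on desk-scale inputs chosen as the
package's own defaults: scenes of 96×112–256×320 px, 200 oracle masks up to
32×32, 100 dispense configurations at 32×40, 20-scene mAP sweeps, 2000-image
panels and 10⁵ sampler draws. Statistical checks use 3-standard-error bands
around closed-form expectations, so they are calibrated to their sample
sizes rather than tuned to outcomes.

## Known limitations

- No photometric realism in synthetic scenes; pixel-value-dependent code is
  only exercised through its contracts (dimensions, determinism, histogram
  flattening).
- mAP size-bin semantics are the simplified form described above.
- The Zooniverse dialect is frozen (columns `subject_ids`, `subject_data`,
  `annotations`); image dimensions are not part of the export and must be
  supplied by the caller. Multi-annotator duplicates for the same image are
  all kept — reconciliation policy is left to the caller.
- `pairwise_agreement` and the consensus builder assume complete panels; an
  image with a missing expert label is an error, not an imputation.
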