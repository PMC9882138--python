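# Methods

This note documents the models, conventions and design choices behind
`plaquekit`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Box geometry and merging

Boxes are 0-based, half-open pixel intervals `[x_min, x_max) × [y_min,
y_max)`, so `area = (x_max − x_min) · (y_max − y_min)` and two boxes that
merely share an edge have **zero** intersection. "Overlap" throughout the
toolkit means positive-area intersection; edge-touching boxes never merge
and never match. This resolves an ambiguity in box-merging descriptions
("overlapped" could include shared edges) in the direction that keeps the
arithmetic exact.

Merging builds, per class, the graph whose edges are positive-area
intersections, replaces each connected component by its minimal enclosing
rectangle, and repeats — an enclosing rectangle can newly overlap a third
box — until a fixpoint with no same-class overlap. Termination is
guaranteed because each productive round strictly decreases the box count.
The merged box's confidence is the **max** over constituents (the
strongest evidence should survive for confidence-ranked evaluation); its
source is the sorted concatenation of constituent sources. Output is
canonically sorted (class, then coordinates, then source/confidence), so
the result is independent of input order.

## Tiling

Slides are covered by `floor(W/1536) × floor(H/1536)` non-overlapping
tiles anchored top-left; right/bottom remainder strips are **dropped, not
padded** — padding would fabricate tissue pixels. Tiles are indexed
`(col, row)` and iterated row-major, making aggregation order
deterministic. 40× scans are normalized to 20× (≈0.5 µm/px) by 2×
area-averaging, the downsampling with the least aliasing for counting
purposes. No tissue-mask filtering is applied: background-only tiles are
processed like any other.

## Classical candidate extraction

Candidates are proposed in three stages, keyed to the brown DAB
chromogen:

1. **HSV gamut.** Hue uses the half-degree 0–179 convention and S/V the
   0–255 byte scale — the convention under which the stain presets were
   derived (a hue interval of (0, 40) is meaningless on a 0–360 scale for
   brown). Interval endpoints are inclusive. Presets: 4G8 and 6E10
   H (0, 40), S (10, 255), V (0, 220); NAB228 H (0, 100), S (1, 255),
   V (0, 250). Additional stains are registered via a YAML config.
2. **Smoothing.** Morphological close-then-open with a square structuring
   element, default side 5 px (~2.5 µm at 0.5 µm/px): closing bridges
   pores inside deposits, opening removes speckle. The exact smoothing
   operator is a package choice; it is deliberately mild and tunable.
3. **Watershed boxing.** Euclidean distance-transform watershed. Seeds
   are the *connected plateaus* where the distance transform reaches at
   least `seed_height` (default 0.7) of its peak within each connected
   component. Two touching compact blobs carry two separate near-maximum
   plateaus and are split; a curved or elongated deposit — a CAA vessel
   ring in particular — has one connected ridge and stays whole. (Seeding
   from isolated distance-transform maxima, the textbook recipe,
   fragments rings into arc pieces whose boxes under-cover the object;
   the plateau rule is the package's fix for that failure mode.) Regions
   smaller than `min_area` (default 200 px² ≈ 50 µm²) are discarded as
   noise. Each surviving region yields its tight bounding box.

Candidates are geometric proposals: class identity comes from a
downstream annotator or classifier, so `detect_candidates` stamps a
caller-chosen class label (default `cored`).

## Detector and classifier contracts

A detector is anything callable as `detector(tile_rgb, col=..., row=...)
→ BoxSet` with confidences in [0, 1]; the tile indices are optional
context (a trained network ignores them, the stub detectors use them to
look up planted ground truth). **Returned boxes must intersect the tile
but may overhang its edges** when the underlying object is only partially
visible. This overhang is load-bearing: an object straddling a tile
border is reported (in slide coordinates) by both adjacent tiles as
overlapping duplicates, which the final slide-level merge joins back into
one box. Strictly tile-clipped detections could only touch at the border
and would never re-merge under the positive-area rule.

Post-processing per image: optional raw-confidence cut (off by default —
whether the original pipelines thresholded raw detector output is
unknown, so the default changes nothing), same-class merging, then the
CAA filter: each CAA box is center-cropped to 256×256 (window clamped to
the image edge, never zero-padded, so the classifier never sees synthetic
black borders) and removed when the classifier score is strictly below
0.5 (`score < threshold → remove`, the strict reading of "confidence
< 0.5"). Cored boxes are never touched by the filter.

**Bootstrap label refinement** augments sparse labels with a model's own
predictions: detect, merge predictions, drop those the classifier scores
below 0.5, union with the existing labels, merge the union. With a null
detector this is the identity on merged labels; every original label box
ends up contained in an output box of its class.

## Evaluation

* **Matching** is greedy one-to-one: candidate pairs (same class, IOU ≥
  threshold, threshold inclusive) taken in descending IOU, ties broken by
  canonical box order. Greedy descending-IOU is the standard
  deterministic resolution of "each box in at most one pair".
* **Interrater accuracy** = congruous pairs / (|A| + |B| − pairs). The
  denominator is the *matched union* — the number of distinct pathologies
  either annotator marked; the raw sum |A| + |B| (which roughly halves
  accuracies) is available via `denominator="sum"`.
* **Consensus** clusters boxes greedily across annotators (seed box in
  canonical order; from each other annotator the highest-IOU unclustered
  box at IOU ≥ 0.5, at most one per annotator) and emits one box per
  cluster with support from ≥ 2 distinct annotators. The consensus box is
  the coordinate-wise mean of its members — unbiased toward any single
  annotator.
* **AP** uses all-point interpolation (the VOC 2010+ convention, chosen
  over 11-point and stated explicitly so results are reproducible).
  Detections rank by descending confidence with canonical tie-breaks;
  each is assigned the best still-unclaimed label at IOU ≥ threshold;
  duplicates of a claimed label are false positives. No labels → AP 0.
* **Expert baseline**: each annotator in turn is ground truth; every
  other annotator's precision against it is recorded (k·(k−1) ordered
  pairs; 12 for k = 4). A pair where the candidate has no boxes of the
  class has undefined precision and is excluded from the mean/sd
  (reported as NaN) rather than scored 0.
* **Field selection** walks the priority list — most model-predicted
  CAAs, most human CAAs, then the model-cored ranking — skipping
  already-selected fields until four distinct fields per WSI are chosen
  (ties by field id). When maximizers coincide, the cored ranking
  supplies the replacements.

## CERAD-like statistics

Slide score = count of slide-level merged cored detections. Between each
pair of burden categories a two-sided two-sample **pooled-variance**
t-test is run ("Student's" conventionally denotes pooled; Welch is a
flag). Significance uses α = 0.05 per pair with no multiplicity
correction by default (a Bonferroni flag exists). Post-hoc power is
computed from the observed standardized effect size d = |Δmean|/s_pooled
and the actual group sizes via the noncentral t distribution
(`statsmodels` `TTestIndPower`); at extreme effect sizes where the
noncentral t underflows, the normal approximation (exact in that limit)
is substituted. Power at d = 0 is reported as α, the size of the test.
Categories with fewer than two slides make a pair not-computable (NaN,
not significant). Degenerate zero-variance pairs are defined by their
means (equal → t = 0, p = 1; unequal → p = 0).

The test suite checks the t-test p-values against a 10,000-permutation
oracle. The two agree to within ≈0.05 in the mid-range and much tighter
in the tails: the residual gap is the t approximation to the exact
permutation null on skewed count data, which dominates the ≈0.005
Monte-Carlo error of the oracle itself.

## Synthetic fixtures

The generators emulate exactly the features the toolkit keys on, and no
more:

* **Fields**: beige textured background (HSV value 228–250, above the
  4G8 value cut of 220, so background never enters the gamut even after
  RGB round-off), cored plaques as brown discs with darker centres, CAAs
  as brown annuli, all colours drawn strictly inside the 4G8 gamut with
  wide margins. Objects are placed without overlap (bounded rejection
  sampling; infeasible packings raise). Ground-truth boxes are the tight
  pixel extents of the rendered objects. All fixture hues lie in the
  red–yellow sector (< 60°), where HSV→RGB has a cheap exact closed form;
  a post-render check repaints any out-of-gamut object pixel (unreachable
  at the default margins).
* **Annotators**: keep each true box with probability `recall`, jitter
  kept corners by ±`jitter` px, add Poisson(`fp_rate`·n) spurious boxes.
* **Stub detectors**: emit planted truth per tile (full extents, clipped
  only at the origin) with TP confidences ~ U(0.6, 1) stochastically
  dominating FP confidences ~ U(0, 0.5).
* **Cohorts**: Poisson cored counts with category means 2/15/60/150 at
  n = 10 per category — a burden gradient whose closest pair
  (none/sparse) mirrors the comparison that is marginal on real cohorts,
  while all other pairs separate decisively.

Everything is a pure function of its spec and a single integer seed; no
global random state is touched.

What the fixtures do **not** model: real tissue texture, diffuse plaques,
stain batch and scanner variation, color-normalization artifacts, tissue
folds, or annotator biases beyond i.i.d. jitter/drop/add noise. Passing
on fixtures therefore demonstrates that the *machinery* — geometry,
matching, scoring, aggregation — is correct, not that any particular
detector performs clinically.

## Problem sizes and determinism

The acceptance checks run at fixed sizes chosen to exercise the
asymptotics while staying desk-scale: 1,000 random box pairs against
exact pixel-counting, 500 merge collections of up to 30 boxes with 20
permutations each, 1,000 AP instances against brute-force enumeration,
100 consensus-recovery seeds, 20 full-size (1536²) synthetic fields for
candidate recall, and 20 cohort seeds for the CERAD statistics. All
randomness flows from explicit seeds; `scripts/acceptance.py` derives
every stream from its single `--seed`.

## Known limitations

* Pyramidal SVS reading requires an optional `openslide` dependency;
  plain/Big TIFF and PNG are the supported interchange formats.
* WSI color normalization is exposed only as a pre-processing hook
  (normalize before tiling); no implementation is bundled.
* Rotated boxes, polygon masks and sub-pixel mask geometry are out of
  scope; boxes are the only localization primitive.
* The CERAD module correlates counts with categories; it deliberately
  does not threshold counts *into* categories.
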