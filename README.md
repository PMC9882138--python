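# plaquekit

A detector-agnostic Python toolkit for quantifying amyloid-β pathology —
cored plaques and cerebral amyloid angiopathy (CAA) — on DAB-stained
immunohistochemistry whole-slide images (WSIs).

Deep object detectors for neuropathology are usually published as trained
weights plus a loose collection of scripts. Everything *around* the
network, however, is what makes the results reproducible: how candidate
objects are proposed, how overlapping boxes are merged, how multiple
expert annotators are reconciled, how average precision is scored, and how
slide-level counts are compared with semiquantitative CERAD-like scoring.
`plaquekit` implements that scaffolding as a library + CLI with a
pluggable detector/classifier contract, so any detector (or a bundled
stub) can be dropped in and evaluated end-to-end — including entirely on
synthetic data.

## What's in the box

| Module | Purpose |
| --- | --- |
| `plaquekit.geometry` | `Box`/`BoxSet`, IOU, iterative same-class merging to minimal superset boxes |
| `plaquekit.tiling` | deterministic 1536×1536 non-overlapping WSI tiling and coordinate mapping |
| `plaquekit.candidates` | classical candidate extraction: stain-specific HSV gamut → morphological smoothing → distance-transform watershed |
| `plaquekit.pipeline` | detector/classifier contracts, CAA center-crop filtering, bootstrap label refinement, tile-wise WSI detection |
| `plaquekit.evaluation` | congruous-pair interrater agreement, consensus-of-two annotation, PASCAL-VOC-style AP, expert-vs-expert baseline, prospective field selection |
| `plaquekit.cerad` | slide-level cored counts, pairwise Student's t-tests and post-hoc power across CERAD-like categories |
| `plaquekit.synthetic` | seeded generators: stained-looking fields with ground truth, multi-annotator sets, stub detectors, slide cohorts |
| `plaquekit.io` | lossless CSV/JSON box tables, PNG/TIFF rasters, tile manifests, stain configs |

## The core conventions

* **Boxes** are 0-based half-open pixel rectangles `[x_min, x_max) ×
  [y_min, y_max)` with a class (`cored` / `CAA`), optional confidence and
  provenance. Two boxes of the same class with positive-area intersection
  are iteratively replaced by their minimal enclosing rectangle until no
  overlap remains — the merging rule applied to labels, detections and
  bootstrap unions alike.
* **Congruous pair**: one box from each of two annotators, same class,
  IOU ≥ 0.50, each box in at most one pair. Interrater accuracy =
  pairs / (|A| + |B| − pairs).
* **AP** follows the PASCAL VOC convention: detections ranked by
  confidence, the highest-confidence detection of a label is its true
  positive and all later ones are false positives; all-point interpolated
  area under the precision–recall curve.
* **CERAD-like comparison**: two-sided pooled-variance t-tests between
  each pair of burden categories (none/sparse/moderate/frequent) at
  α = 0.05, with post-hoc power from the noncentral t distribution.

## Worked example

```python
import plaquekit as pk
from plaquekit.evaluation import ap_sweep, interrater_accuracy, build_consensus

# a synthetic 1536 px DAB-stained field with known ground truth
spec = pk.FixtureSpec(seed=42, tile_size=1536, n_cored=4, n_caa=2)
image, truth = pk.make_tile(spec)

# classical candidate extraction with the 4G8 stain gamut
candidates = pk.detect_candidates(image, "4G8")
print(f"planted objects: {len(truth)}  candidate boxes: {len(candidates)}")

# four simulated annotators, agreement and consensus
annotators = pk.make_annotators(truth, k=4, recall=0.85, fp_rate=0.2, jitter=4, seed=42)
acc = interrater_accuracy(annotators[0], annotators[1], "cored")
print(f"A1 vs A2 cored agreement: overlaps={acc.overlaps} total={acc.total} "
      f"accuracy={acc.accuracy:.2f}")
print(f"consensus-of-two cored boxes: {len(build_consensus(annotators, 'cored'))}")

# a noisy stub detector scored against the ground truth
detector = pk.make_stub_detector(truth, recall=0.9, fp_rate=0.3, jitter=5, seed=42)
for curve in ap_sweep(truth, detector(image), "cored", (0.5, 0.7, 0.9)):
    print(f"AP@IOU {curve.iou_threshold:.1f}: {curve.ap:.3f}")
```

prints

```
planted objects: 6  candidate boxes: 6
A1 vs A2 cored agreement: overlaps=4 total=8 accuracy=0.50
consensus-of-two cored boxes: 4
AP@IOU 0.5: 1.000
AP@IOU 0.7: 1.000
AP@IOU 0.9: 0.250
```

Every planted object was proposed as a candidate; two annotators with 85%
recall and jitter agree on half of the distinct objects they marked; the
jittered detector is perfect at the usual IOU 0.5 but collapses at the
near-pixel-exact 0.9 threshold — the qualitative behaviour expected of
box-level evaluation.

The same operations are available from the shell:

```bash
plaquekit synthesize tile --seed 42 --out demo/
plaquekit detect-candidates --stain 4G8 --in demo/tile_seed42.png --out demo/cand.csv
plaquekit evaluate agreement demo/a1.csv demo/a2.csv
plaquekit cerad compare --records cohort.csv --out matrix.csv
```

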