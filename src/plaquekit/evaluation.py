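"""Benchmark machinery for box annotations and detections.

Implements the evaluation conventions used throughout the toolkit:

* greedy one-to-one box matching at an inclusive IOU threshold (the
  "congruous pair" rule — same class, IOU >= 0.5, each box in at most one
  pair);
* interrater agreement accuracy = congruous pairs / matched union of the
  two annotators' boxes;
* consensus-of-k annotation building (a box is kept when independently
  supported by at least ``min_support`` annotators);
* PASCAL-VOC-style average precision with all-point interpolation, where
  for multiple detections of one label only the highest-confidence one is
  a true positive;
* the expert-vs-expert precision baseline (each annotator in turn as
  ground truth);
* prospective field selection by per-field pathology counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Box, BoxSet, canonical_key, iou

__all__ = [
    "MatchResult",
    "EvalCurve",
    "AgreementResult",
    "match_boxes",
    "interrater_accuracy",
    "build_consensus",
    "average_precision",
    "ap_sweep",
    "expert_baseline",
    "select_fields",
]


@dataclass
class MatchResult:
    """One-to-one matching between a label set and a detection set."""

    pairs: list[tuple[Box, Box, float]]
    unmatched_labels: list[Box]
    unmatched_detections: list[Box]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


@dataclass
class EvalCurve:
    """Precision/recall points and AP for one class at one IOU threshold."""

    class_label: str
    iou_threshold: float
    precision: np.ndarray
    recall: np.ndarray
    ap: float


@dataclass
class AgreementResult:
    """Interrater agreement between two annotators for one class."""

    annotator_a: str
    annotator_b: str
    class_label: str
    overlaps: int
    total: int
    accuracy: float


def match_boxes(
    labels: BoxSet,
    detections: BoxSet,
    iou_threshold: float,
    class_label: str,
) -> MatchResult:
    """Greedy one-to-one matching of same-class boxes at IOU >= threshold.

    Candidate pairs are considered in descending IOU (ties broken by the
    canonical box order on each side); once matched, a box takes part in no
    further pair.  The threshold is inclusive.
    """
    if not (0 < iou_threshold <= 1):
        raise ValueError("iou_threshold must lie in (0, 1]")
    lab = labels.of_class(class_label)
    det = detections.of_class(class_label)
    candidates = []
    for li, lb in enumerate(lab):
        for di, db in enumerate(det):
            v = iou(lb, db)
            if v >= iou_threshold:
                candidates.append((v, li, di))
    candidates.sort(key=lambda t: (-t[0], canonical_key(lab[t[1]]), canonical_key(det[t[2]])))
    used_l: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for v, li, di in candidates:
        if li in used_l or di in used_d:
            continue
        used_l.add(li)
        used_d.add(di)
        pairs.append((lab[li], det[di], v))
    return MatchResult(
        pairs=pairs,
        unmatched_labels=[b for i, b in enumerate(lab) if i not in used_l],
        unmatched_detections=[b for i, b in enumerate(det) if i not in used_d],
    )


def interrater_accuracy(
    a: BoxSet,
    b: BoxSet,
    class_label: str,
    iou_threshold: float = 0.5,
    denominator: str = "union",
) -> AgreementResult:
    """Agreement accuracy between two annotators' box sets for one class.

    ``overlaps`` counts congruous pairs (same class, IOU >= threshold,
    one-to-one).  The default denominator ``total = |a| + |b| - overlaps``
    is the matched union — the number of distinct pathologies either
    annotator marked; ``denominator="sum"`` uses the raw ``|a| + |b|``
    instead.  Accuracy = overlaps / total (0 when total is 0) and is
    symmetric in the two annotators.
    """
    if a.image_id != b.image_id:
        raise ValueError(
            f"annotations refer to different images: {a.image_id!r} vs {b.image_id!r}"
        )
    overlaps = match_boxes(a, b, iou_threshold, class_label).n_matched
    na, nb = len(a.of_class(class_label)), len(b.of_class(class_label))
    if denominator == "union":
        total = na + nb - overlaps
    elif denominator == "sum":
        total = na + nb
    else:
        raise ValueError("denominator must be 'union' or 'sum'")
    accuracy = overlaps / total if total else 0.0
    return AgreementResult(
        annotator_a=_annotator_id(a, "A1"),
        annotator_b=_annotator_id(b, "A2"),
        class_label=class_label,
        overlaps=overlaps,
        total=total,
        accuracy=accuracy,
    )


def _annotator_id(bs: BoxSet, fallback: str) -> str:
    sources = {b.source for b in bs.boxes if b.source}
    return sources.pop() if len(sources) == 1 else fallback


def build_consensus(
    annotations: list[BoxSet],
    class_label: str,
    iou_threshold: float = 0.5,
    min_support: int = 2,
) -> BoxSet:
    """Consensus annotation: boxes independently supported by >= min_support
    annotators.

    Boxes of the class are clustered greedily: each still-unclustered box
    (canonical order) seeds a cluster, and from every *other* annotator the
    unclustered box with the highest IOU >= threshold to the seed joins (at
    most one per annotator).  Clusters spanning >= ``min_support`` distinct
    annotators emit one consensus box whose coordinates are the
    coordinate-wise mean of the members.
    """
    if not annotations:
        raise ValueError("at least one annotation set required")
    image_id = annotations[0].image_id
    ids = []
    for i, bs in enumerate(annotations):
        if bs.image_id != image_id:
            raise ValueError("all annotation sets must share one image_id")
        ids.append(_annotator_id(bs, f"annotator{i + 1}"))
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate annotator ids: {ids}")

    entries = []  # (annotator index, box)
    for ai, bs in enumerate(annotations):
        for b in bs.of_class(class_label):
            entries.append((ai, b))
    entries.sort(key=lambda t: (canonical_key(t[1]), t[0]))
    clustered = [False] * len(entries)
    consensus: list[Box] = []
    for idx, (seed_ai, seed) in enumerate(entries):
        if clustered[idx]:
            continue
        clustered[idx] = True
        members = [(seed_ai, seed, idx)]
        for other_ai in range(len(annotations)):
            if other_ai == seed_ai:
                continue
            best = None
            for jdx, (ai, b) in enumerate(entries):
                if clustered[jdx] or ai != other_ai:
                    continue
                v = iou(seed, b)
                if v >= iou_threshold and (best is None or v > best[0]):
                    best = (v, jdx, b)
            if best is not None:
                clustered[best[1]] = True
                members.append((other_ai, best[2], best[1]))
        if len({ai for ai, _, _ in members}) >= min_support:
            boxes = [b for _, b, _ in members]
            consensus.append(
                Box(
                    class_label,
                    float(np.mean([b.x_min for b in boxes])),
                    float(np.mean([b.y_min for b in boxes])),
                    float(np.mean([b.x_max for b in boxes])),
                    float(np.mean([b.y_max for b in boxes])),
                    source="consensus",
                )
            )
    return BoxSet(image_id, annotations[0].width, annotations[0].height, consensus)


def _interpolated_ap(precision: np.ndarray, recall: np.ndarray) -> float:
    """All-point interpolated area under the PR curve (monotone precision
    envelope, summed over recall increments)."""
    if len(precision) == 0:
        return 0.0
    mrec = np.concatenate(([0.0], recall))
    mpre = np.concatenate(([0.0], precision))
    # envelope: precision at recall r = max precision at any recall >= r
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    steps = np.nonzero(np.diff(mrec))[0]
    return float(np.sum((mrec[steps + 1] - mrec[steps]) * mpre[steps + 1]))


def average_precision(
    labels: BoxSet,
    detections: BoxSet,
    class_label: str,
    iou_threshold: float,
) -> EvalCurve:
    """PASCAL-VOC-style AP for one class at one IOU threshold.

    Detections are ranked by descending confidence (canonical order on
    ties) and each is greedily assigned the unclaimed same-class label with
    the highest IOU >= threshold.  The highest-confidence detection of a
    label is the true positive; any later detection of an already-claimed
    label, or of no label, is a false positive.  AP is the all-point
    interpolated area under the accumulated precision-recall curve.
    """
    lab = labels.of_class(class_label)
    det = detections.of_class(class_label)
    if any(d.confidence is None for d in det):
        raise ValueError("every detection must carry a confidence for AP")
    det = sorted(det, key=lambda d: (-d.confidence, canonical_key(d)))
    claimed = [False] * len(lab)
    tp = np.zeros(len(det))
    for rank, d in enumerate(det):
        best = None
        for li, lb in enumerate(lab):
            if claimed[li]:
                continue
            v = iou(lb, d)
            if v >= iou_threshold and (best is None or v > best[0]):
                best = (v, li)
        if best is not None:
            claimed[best[1]] = True
            tp[rank] = 1.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(det) + 1) if len(det) else np.array([])
    recall = cum_tp / len(lab) if lab and len(det) else np.array([])
    ap = _interpolated_ap(precision, recall) if lab else 0.0
    return EvalCurve(class_label, iou_threshold, precision, recall, ap)


def ap_sweep(
    labels: BoxSet,
    detections: BoxSet,
    class_label: str,
    thresholds,
) -> list[EvalCurve]:
    """AP at each IOU threshold (stricter thresholds never increase AP)."""
    return [
        average_precision(labels, detections, class_label, t) for t in thresholds
    ]


def expert_baseline(
    annotations: list[BoxSet],
    class_label: str,
    iou_threshold: float = 0.5,
) -> dict:
    """Expert-vs-expert precision ceiling.

    Each annotator A in turn is fixed as ground truth and every other
    annotator B's boxes are matched against it; the pair's precision is
    matched(B) / |B|.  For k annotators this yields k*(k-1) ordered-pair
    values; a pair where B has no boxes of the class is undefined (NaN) and
    excluded from the mean/sd.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two annotators")
    rows = []
    for i, truth in enumerate(annotations):
        for j, cand in enumerate(annotations):
            if i == j:
                continue
            n_cand = len(cand.of_class(class_label))
            if n_cand == 0:
                prec = float("nan")
            else:
                matched = match_boxes(truth, cand, iou_threshold, class_label).n_matched
                prec = matched / n_cand
            rows.append(
                {
                    "truth": _annotator_id(truth, f"annotator{i + 1}"),
                    "candidate": _annotator_id(cand, f"annotator{j + 1}"),
                    "precision": prec,
                }
            )
    values = np.array([r["precision"] for r in rows])
    finite = values[np.isfinite(values)]
    return {
        "per_pair": rows,
        "mean_precision": float(np.mean(finite)) if len(finite) else float("nan"),
        "sd_precision": float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0,
    }


def select_fields(per_field_stats: pd.DataFrame) -> pd.DataFrame:
    """Select prospective-validation fields per WSI by pathology counts.

    Per WSI the priority order is: (1) the field with the most
    model-predicted CAAs, (2) the field with the most human-annotated CAAs,
    (3) the fields with the most model-predicted cored plaques — walking
    down the cored ranking past already-selected fields until four distinct
    fields are chosen.  Ties break by ``field_id`` order.

    Expects columns ``wsi_id, field_id, model_caa, human_caa, model_cored``;
    returns rows ``wsi_id, field_id, criterion``.
    """
    required = {"wsi_id", "field_id", "model_caa", "human_caa", "model_cored"}
    missing = required - set(per_field_stats.columns)
    if missing:
        raise ValueError(f"per-field table is missing columns: {sorted(missing)}")
    out_rows = []
    for wsi_id, group in per_field_stats.groupby("wsi_id", sort=False):
        g = group.sort_values("field_id", kind="stable").reset_index(drop=True)
        if len(g) < 4:
            warnings.warn(
                f"WSI {wsi_id!r} has only {len(g)} candidate fields (< 4)",
                stacklevel=2,
            )
        ranked_cored = g.sort_values(
            ["model_cored", "field_id"], ascending=[False, True], kind="stable"
        )["field_id"].tolist()
        priority = [
            (g.loc[g["model_caa"].idxmax(), "field_id"], "max_model_caa"),
            (g.loc[g["human_caa"].idxmax(), "field_id"], "max_human_caa"),
        ] + [(f, "top_cored") for f in ranked_cored]
        chosen: list[tuple[str, str]] = []
        seen = set()
        for field_id, criterion in priority:
            if len(chosen) == 4:
                break
            if field_id in seen:
                continue
            seen.add(field_id)
            chosen.append((field_id, criterion))
        for field_id, criterion in chosen:
            out_rows.append(
                {"wsi_id": wsi_id, "field_id": field_id, "criterion": criterion}
            )
    return pd.DataFrame(out_rows, columns=["wsi_id", "field_id", "criterion"])
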