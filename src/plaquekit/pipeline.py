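"""Detector/classifier contracts and detection post-processing.

The object detector itself is pluggable: anything callable as
``detector(tile_rgb, col=..., row=...) -> BoxSet`` (the tile indices are
optional context a detector may ignore) satisfies the contract, from a
trained network wrapper to the bundled stub detectors.  Returned boxes must
carry confidences and intersect the tile; a box may overhang the tile edge
when the underlying object is only partially visible, which is what lets
slide-level merging re-join objects straddling tile borders.

The classifier contract is ``classifier(crop_rgb, class_label) -> float``
in [0, 1], deterministic for fixed input; it stands behind the CAA
crop-classification filter and bootstrap label refinement.
"""

from __future__ import annotations

import inspect
from typing import Callable, Iterable, Protocol

import numpy as np

from .geometry import CAA, Box, BoxSet, merge_same_class
from .tiling import TileGrid, extract_tiles

__all__ = [
    "Detector",
    "Classifier",
    "center_crop",
    "postprocess",
    "bootstrap_labels",
    "detect_wsi",
    "ConstantClassifier",
    "GamutClassifier",
    "null_detector",
]


class Detector(Protocol):
    def __call__(self, image: np.ndarray, col: int = ..., row: int = ...) -> BoxSet: ...


class Classifier(Protocol):
    def __call__(self, crop: np.ndarray, class_label: str) -> float: ...


def _accepts_tile_context(detector: Callable) -> bool:
    try:
        params = inspect.signature(detector).parameters
    except (TypeError, ValueError):
        return False
    if any(p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()):
        return True
    return "col" in params and "row" in params


def _call_detector(detector: Callable, tile: np.ndarray, col: int, row: int) -> BoxSet:
    if _accepts_tile_context(detector):
        return detector(tile, col=col, row=row)
    return detector(tile)


def center_crop(image: np.ndarray, box: Box, size: int = 256) -> np.ndarray:
    """A ``size x size`` crop centered on the box center.

    When the window would exceed the image bounds it is shifted (clamped to
    the edge) rather than zero-padded, so the output is always exactly
    ``size x size`` and contains only real pixels.
    """
    if size <= 0:
        raise ValueError("crop size must be positive")
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {w} x {h} is smaller than crop size {size}")
    cx, cy = box.center
    x0 = int(round(cx - size / 2))
    y0 = int(round(cy - size / 2))
    x0 = min(max(x0, 0), w - size)
    y0 = min(max(y0, 0), h - size)
    return image[y0 : y0 + size, x0 : x0 + size]


def postprocess(
    detections: BoxSet,
    image: np.ndarray,
    classifier: Classifier | None = None,
    caa_threshold: float = 0.5,
    min_confidence: float = 0.0,
    crop_size: int = 256,
) -> BoxSet:
    """Merge raw detections, then classifier-filter the CAA boxes.

    Steps: (1) optional raw confidence cut at ``min_confidence`` (default
    off); (2) same-class merging; (3) each CAA box is center-cropped to
    ``crop_size`` and scored by the classifier — boxes scoring strictly
    below ``caa_threshold`` are removed.  Cored boxes pass step 3
    untouched.  Never increases the box count.
    """
    boxes = list(detections.boxes)
    if min_confidence > 0:
        boxes = [
            b for b in boxes
            if b.confidence is not None and b.confidence >= min_confidence
        ]
    merged = merge_same_class(boxes)
    if any(b.class_label == CAA for b in merged) and classifier is None:
        raise ValueError("CAA detections present but no classifier supplied")
    kept = []
    for b in merged:
        if b.class_label == CAA:
            score = classifier(center_crop(image, b, crop_size), CAA)
            if score < caa_threshold:
                continue
        kept.append(b)
    return BoxSet(detections.image_id, detections.width, detections.height, kept, check=False)


def bootstrap_labels(
    training_images: Iterable[tuple[np.ndarray, BoxSet]],
    detector: Detector,
    classifier: Classifier | None = None,
    conf_cut: float = 0.5,
    crop_size: int = 256,
) -> list[BoxSet]:
    """Refine sparse training labels with a model's own filtered predictions.

    Per image: run the detector, merge its predictions per class, drop
    merged predictions whose classifier score on a center crop is strictly
    below ``conf_cut`` (no classifier -> no filtering), union the survivors
    with the existing labels, and merge the union.  Every original label
    box ends up contained in some output box of its class, and the output
    has no same-class overlaps.
    """
    refined = []
    for image, labels in training_images:
        try:
            preds = _call_detector(detector, image, 0, 0)
            merged_preds = merge_same_class(preds.boxes)
            if classifier is not None:
                merged_preds = [
                    b for b in merged_preds
                    if classifier(center_crop(image, b, crop_size), b.class_label)
                    >= conf_cut
                ]
        except Exception as exc:
            raise RuntimeError(
                f"bootstrap refinement failed on image {labels.image_id!r}"
            ) from exc
        union = merge_same_class(list(labels.boxes) + merged_preds)
        refined.append(
            BoxSet(labels.image_id, labels.width, labels.height, union, check=False)
        )
    return refined


def detect_wsi(
    wsi: np.ndarray,
    grid: TileGrid,
    detector: Detector,
    classifier: Classifier | None = None,
    caa_threshold: float = 0.5,
    min_confidence: float = 0.0,
) -> BoxSet:
    """Run tile-wise detection over a whole slide and aggregate.

    Each tile is detected and post-processed independently, detections are
    translated into slide coordinates (clipped to the slide extent), and a
    final slide-level merge joins same-class boxes that overlap — including
    duplicated detections of one object seen from adjacent tiles.
    """
    all_boxes: list[Box] = []
    for col, row, tile in extract_tiles(wsi, grid):
        try:
            dets = _call_detector(detector, tile, col, row)
            # tiles can be smaller than crop_size in tests; fall back to tile edge
            crop = min(256, grid.tile_size)
            processed = postprocess(
                dets, tile, classifier,
                caa_threshold=caa_threshold,
                min_confidence=min_confidence,
                crop_size=crop,
            )
        except Exception as exc:
            raise RuntimeError(f"detection failed on tile (col={col}, row={row})") from exc
        dx, dy = grid.offset(col, row)
        for b in processed.boxes:
            clipped = b.translate(dx, dy).clip(grid.width, grid.height)
            if clipped is not None:
                all_boxes.append(clipped)
    return BoxSet(
        grid.wsi_id, grid.width, grid.height,
        merge_same_class(all_boxes), check=False,
    )


class ConstantClassifier:
    """Classifier stub returning a fixed score for every crop."""

    def __init__(self, value: float):
        if not 0.0 <= value <= 1.0:
            raise ValueError("classifier score must lie in [0, 1]")
        self.value = float(value)

    def __call__(self, crop: np.ndarray, class_label: str) -> float:
        return self.value


class GamutClassifier:
    """Heuristic classifier stub: score = fraction of crop pixels inside a
    stain's HSV gamut.

    A crude but image-grounded stand-in for a trained CNN — crops over
    stained deposits score high, crops over bare background score ~0.
    """

    def __init__(self, stain: str = "4G8"):
        from .candidates import STAIN_PRESETS

        self.hsv_range = STAIN_PRESETS[stain]

    def __call__(self, crop: np.ndarray, class_label: str) -> float:
        from .candidates import hsv_mask

        return float(hsv_mask(crop, self.hsv_range).mean())


def null_detector(image: np.ndarray, col: int = 0, row: int = 0) -> BoxSet:
    """Detector stub that never detects anything."""
    h, w = image.shape[:2]
    return BoxSet("null", w, h, [])
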