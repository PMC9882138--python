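"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import colorsys

import numpy as np
import pytest

from plaquekit.geometry import Box, BoxSet, canonical_key


# ---------------------------------------------------------------- oracles

def rasterized_iou(a: Box, b: Box) -> float:
    """IOU by brute-force pixel counting on integer-coordinate boxes."""
    extent_x = int(max(a.x_max, b.x_max))
    extent_y = int(max(a.y_max, b.y_max))
    ga = np.zeros((extent_y, extent_x), dtype=bool)
    gb = np.zeros((extent_y, extent_x), dtype=bool)
    ga[int(a.y_min) : int(a.y_max), int(a.x_min) : int(a.x_max)] = True
    gb[int(b.y_min) : int(b.y_max), int(b.x_min) : int(b.x_max)] = True
    inter = int((ga & gb).sum())
    union = int((ga | gb).sum())
    return inter / union


def colorsys_hsv(pixel: np.ndarray) -> tuple[float, float, float]:
    """One pixel's HSV on the 0-180 / 0-255 / 0-255 scales via stdlib."""
    r, g, b = (float(c) / 255.0 for c in pixel)
    h, s, v = colorsys.rgb_to_hsv(r, g, b)
    return h * 180.0, s * 255.0, v * 255.0


def brute_force_ap(labels, detections, class_label, iou_threshold) -> float:
    """AP by explicit enumeration of the ranked confusion table.

    Independent of the library implementation: ranks detections by
    confidence, walks the ranking assigning each detection the best
    still-free label at IOU >= threshold, and integrates the interpolated
    precision over every achieved recall level.
    """
    from plaquekit.geometry import iou as box_iou

    lab = [b for b in labels.boxes if b.class_label == class_label]
    det = [b for b in detections.boxes if b.class_label == class_label]
    det = sorted(det, key=lambda d: (-d.confidence, canonical_key(d)))
    free = set(range(len(lab)))
    flags = []
    for d in det:
        scored = sorted(
            ((box_iou(lab[i], d), i) for i in free),
            key=lambda t: -t[0],
        )
        if scored and scored[0][0] >= iou_threshold:
            free.discard(scored[0][1])
            flags.append(1)
        else:
            flags.append(0)
    if not lab:
        return 0.0
    n_tp = 0
    points = []  # (recall, precision) after each rank
    for rank, f in enumerate(flags, start=1):
        n_tp += f
        points.append((n_tp / len(lab), n_tp / rank))
    ap = 0.0
    prev_recall = 0.0
    for recall in sorted({r for r, _ in points}):
        best = max(p for r, p in points if r >= recall)
        ap += (recall - prev_recall) * best
        prev_recall = recall
    return ap


def random_boxset(
    rng: np.random.Generator,
    image_id: str = "img",
    size: float = 1536.0,
    n: int | None = None,
    with_confidence: bool = False,
    source: str | None = None,
) -> BoxSet:
    """A BoxSet of random boxes of both classes."""
    if n is None:
        n = int(rng.integers(0, 9))
    boxes = []
    for _ in range(n):
        w = float(rng.integers(10, 120))
        h = float(rng.integers(10, 120))
        x0 = float(rng.uniform(0, size - w))
        y0 = float(rng.uniform(0, size - h))
        boxes.append(
            Box(
                "cored" if rng.random() < 0.5 else "CAA",
                x0, y0, x0 + w, y0 + h,
                confidence=float(rng.uniform(0, 1)) if with_confidence else None,
                source=source,
            )
        )
    return BoxSet(image_id, size, size, boxes)


def random_int_box(rng: np.random.Generator, limit: int = 100, class_label="cored") -> Box:
    x0, y0 = int(rng.integers(0, limit - 1)), int(rng.integers(0, limit - 1))
    w, h = int(rng.integers(1, limit - x0)), int(rng.integers(1, limit - y0))
    return Box(class_label, float(x0), float(y0), float(x0 + w), float(y0 + h))


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_field():
    """A 512 px synthetic stained field with its ground truth (session-wide)."""
    import plaquekit as pk

    spec = pk.FixtureSpec(seed=11, tile_size=512, n_cored=3, n_caa=1)
    return pk.make_tile(spec)
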