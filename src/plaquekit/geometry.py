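"""Axis-aligned bounding-box arithmetic.

Boxes are the universal currency of the toolkit: human annotations,
classical candidate proposals, and detector outputs are all expressed as
:class:`Box` objects grouped per image into a :class:`BoxSet`.

Coordinates are 0-based, half-open pixel intervals ``[x_min, x_max) x
[y_min, y_max)``, so ``area = (x_max - x_min) * (y_max - y_min)`` and two
boxes that merely share an edge have zero intersection.  That convention
drives the merging rule: boxes of the same class with *positive-area*
intersection are iteratively replaced by their minimal enclosing rectangle
until no same-class pair overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, InitVar, replace
from typing import Iterable, Sequence

__all__ = [
    "CLASS_LABELS",
    "CORED",
    "CAA",
    "Box",
    "BoxSet",
    "iou",
    "intersection_area",
    "merge_same_class",
    "contains",
    "canonical_key",
    "sort_canonical",
]

CORED = "cored"
CAA = "CAA"
#: The two pathology classes handled by the toolkit.
CLASS_LABELS = (CORED, CAA)


@dataclass(frozen=True)
class Box:
    """A classed, axis-aligned rectangle in pixel coordinates.

    Parameters
    ----------
    class_label
        One of ``"cored"`` (dense-core amyloid plaque) or ``"CAA"``
        (cerebral amyloid angiopathy).
    x_min, y_min, x_max, y_max
        Half-open pixel extents; must satisfy ``x_min < x_max`` and
        ``y_min < y_max`` with finite, non-negative coordinates.
    confidence
        Optional detection score in ``[0, 1]``.
    source
        Optional provenance tag (annotator id or ``"model"``).
    """

    class_label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"box coordinates must be finite, got {coords}")
        if min(coords) < 0:
            raise ValueError(f"box coordinates must be >= 0, got {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"box must have positive area: "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def translate(self, dx: float, dy: float) -> "Box":
        """Return the box shifted by ``(dx, dy)``."""
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def clip(self, width: float, height: float) -> "Box | None":
        """Intersect the box with ``[0, width) x [0, height)``.

        Returns ``None`` when nothing with positive area remains.
        """
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)


def intersection_area(a: Box, b: Box) -> float:
    """Area of the rectangle intersection of ``a`` and ``b`` (0 if disjoint)."""
    w = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    h = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if w <= 0 or h <= 0:
        return 0.0
    return w * h


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes, ignoring class labels.

    Symmetric, bounded in ``[0, 1]``; exactly 0 for boxes that are disjoint
    or only share an edge.  Both boxes must have positive area (guaranteed
    by the :class:`Box` invariants).
    """
    inter = intersection_area(a, b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def contains(outer: Box, inner: Box) -> bool:
    """True iff ``inner``'s extent lies within ``outer`` on both axes."""
    return (
        outer.x_min <= inner.x_min
        and outer.y_min <= inner.y_min
        and inner.x_max <= outer.x_max
        and inner.y_max <= outer.y_max
    )


def canonical_key(box: Box):
    """Deterministic sort key used for tie-breaking throughout the toolkit."""
    return (
        box.class_label,
        box.x_min,
        box.y_min,
        box.x_max,
        box.y_max,
        box.source or "",
        -1.0 if box.confidence is None else box.confidence,
    )


def sort_canonical(boxes: Iterable[Box]) -> list[Box]:
    return sorted(boxes, key=canonical_key)


def _enclosing(boxes: Sequence[Box]) -> Box:
    """Minimal superset rectangle of a same-class group.

    Confidence is the max over constituents (strongest evidence survives for
    confidence-ranked evaluation); sources are concatenated sorted.
    """
    confs = [b.confidence for b in boxes if b.confidence is not None]
    sources = sorted({b.source for b in boxes if b.source is not None})
    return Box(
        class_label=boxes[0].class_label,
        x_min=min(b.x_min for b in boxes),
        y_min=min(b.y_min for b in boxes),
        x_max=max(b.x_max for b in boxes),
        y_max=max(b.y_max for b in boxes),
        confidence=max(confs) if confs else None,
        source=";".join(sources) if sources else None,
    )


def _merge_round(boxes: list[Box]) -> list[Box]:
    """One round: connected components of the positive-intersection graph,
    each replaced by its enclosing rectangle (singletons pass unchanged)."""
    n = len(boxes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if intersection_area(boxes[i], boxes[j]) > 0:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, list[Box]] = {}
    for i, b in enumerate(boxes):
        groups.setdefault(find(i), []).append(b)
    out = []
    for members in groups.values():
        out.append(members[0] if len(members) == 1 else _enclosing(members))
    return out


def merge_same_class(boxes: Iterable[Box]) -> list[Box]:
    """Iteratively merge overlapping same-class boxes to minimal supersets.

    Within each class, any two boxes with positive-area intersection are
    replaced by their minimal enclosing rectangle; because an enclosing
    rectangle may newly overlap a third box, the replacement repeats until a
    fixpoint where no same-class pair overlaps.  Different classes never
    merge.  The result is sorted canonically, so it is independent of input
    order, and every input box is contained in exactly one output box of its
    class.
    """
    by_class: dict[str, list[Box]] = {}
    for b in boxes:
        by_class.setdefault(b.class_label, []).append(b)
    out: list[Box] = []
    for group in by_class.values():
        current = group
        while True:
            merged = _merge_round(current)
            if len(merged) == len(current):
                break
            current = merged
        out.extend(current)
    return sort_canonical(out)


@dataclass
class BoxSet:
    """All boxes attached to one image (labels, detections, or one
    annotator's annotations).

    Every box must lie within ``[0, width) x [0, height)``; construction
    with ``check=False`` skips that containment check (used internally for
    detector outputs that may overhang a tile edge).
    """

    image_id: str
    width: float
    height: float
    boxes: list[Box] = field(default_factory=list)
    check: InitVar[bool] = True

    def __post_init__(self, check: bool) -> None:
        if not self.image_id:
            raise ValueError("image_id must be non-empty")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        self.boxes = list(self.boxes)
        if check:
            for b in self.boxes:
                if b.x_min < 0 or b.y_min < 0 or b.x_max > self.width or b.y_max > self.height:
                    raise ValueError(
                        f"box {b} exceeds image extent "
                        f"{self.width} x {self.height} of {self.image_id!r}"
                    )

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)

    def of_class(self, class_label: str) -> list[Box]:
        return [b for b in self.boxes if b.class_label == class_label]

    def merged(self) -> "BoxSet":
        """A copy with same-class overlapping boxes merged to supersets."""
        return BoxSet(
            self.image_id, self.width, self.height, merge_same_class(self.boxes),
            check=False,
        )
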