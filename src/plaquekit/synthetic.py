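"""Seeded generators of synthetic test data.

Everything the toolkit's tests and examples need is generated here from a
single integer seed: DAB-stained-looking tissue fields with planted
pathologies and exact ground-truth boxes, multi-annotator box sets with
controlled recall/false-positive/jitter behaviour, stub detectors
honouring the detector contract, and CERAD-like slide cohorts with a
plaque-burden gradient.

The image fixtures emulate the geometry and colour statistics the
classical candidate extractor keys on — beige tissue background (too
bright for the 4G8 gamut), brown cored-plaque discs with darker centres,
and brown CAA rings, all drawn strictly inside the 4G8 HSV gamut.  They do
not emulate real tissue texture, diffuse plaques, stain batch variation or
scanner artefacts, so passing on fixtures demonstrates the machinery, not
clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import hsv2rgb

from .cerad import CeradRecord
from .geometry import CAA, CORED, Box, BoxSet
from .candidates import STAIN_PRESETS, hsv_mask

__all__ = [
    "FixtureSpec",
    "make_tile",
    "make_annotators",
    "make_stub_detector",
    "StubDetector",
    "make_cerad_cohort",
]

#: default Poisson means for the CERAD cohort generator: a burden gradient
#: where the none/sparse pair is by far the closest (the comparison that is
#: marginal on real cohorts) and all other pairs separate decisively.
DEFAULT_CERAD_MEANS = (2.0, 15.0, 60.0, 150.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one synthetic stained field.

    Colours are specified in OpenCV-convention HSV (hue 0-179, saturation
    and value 0-255).  Plaque colours sit well inside the 4G8 preset gamut
    and the background sits outside it (value > 220), with margins wide
    enough to survive HSV->RGB->HSV round-off.
    """

    seed: int
    tile_size: int = 1536
    n_cored: int = 3
    n_caa: int = 2
    cored_radius_range: tuple[int, int] = (20, 40)
    caa_radius_range: tuple[int, int] = (28, 48)
    caa_thickness_range: tuple[int, int] = (12, 16)
    #: (h, s, v) intervals for plaque/ring pixels — inside the 4G8 gamut
    plaque_hsv: tuple[tuple[float, float], ...] = ((8.0, 25.0), (90.0, 190.0), (80.0, 170.0))
    #: (h, s, v) intervals for background pixels — value above the 4G8 cut
    background_hsv: tuple[tuple[float, float], ...] = ((12.0, 28.0), (15.0, 55.0), (228.0, 250.0))
    jitter: int = 3


def _hsv_to_rgb8(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """HSV (0-180 / 0-255 / 0-255 scales) to 8-bit RGB.

    All fixture colours live in the red-yellow hue sector (H < 60 deg),
    where the conversion has the closed form R=V, G=V*(1-S*(1-H/60)),
    B=V*(1-S); it is applied directly in float32, which is much cheaper
    than a general full-frame conversion.  Hues outside the sector fall
    back to the general routine.
    """
    h = np.asarray(h, dtype=np.float32)
    s = np.asarray(s, dtype=np.float32) / 255.0
    v = np.asarray(v, dtype=np.float32)
    if np.any(h * 2.0 >= 60.0):
        hsv = np.stack([h / 180.0, s, v / 255.0], axis=-1)
        return np.clip(np.rint(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    frac = (h * 2.0) / 60.0
    out = np.empty(h.shape + (3,), dtype=np.uint8)
    out[..., 0] = np.rint(v)
    out[..., 1] = np.rint(v * (1.0 - s * (1.0 - frac)))
    out[..., 2] = np.rint(v * (1.0 - s))
    return out


def _fill_hsv(rng, shape, intervals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    (h0, h1), (s0, s1), (v0, v1) = intervals
    return (
        rng.uniform(h0, h1, shape),
        rng.uniform(s0, s1, shape),
        rng.uniform(v0, v1, shape),
    )


def _place_objects(rng, spec: FixtureSpec) -> list[tuple[str, int, int, int, int]]:
    """Non-overlapping (class, cx, cy, r_outer, thickness) placements."""
    placements: list[tuple[str, int, int, int, int]] = []
    requests = [(CORED, spec.cored_radius_range, (0, 0))] * spec.n_cored + [
        (CAA, spec.caa_radius_range, spec.caa_thickness_range)
    ] * spec.n_caa
    margin = 6  # min gap between object extents so candidate boxes stay apart
    for class_label, (r_lo, r_hi), thick_range in requests:
        for _ in range(1000):
            r = int(rng.integers(r_lo, r_hi + 1))
            thickness = (
                int(rng.integers(thick_range[0], thick_range[1] + 1))
                if thick_range != (0, 0)
                else 0
            )
            cx = int(rng.integers(r + 1, spec.tile_size - r - 1))
            cy = int(rng.integers(r + 1, spec.tile_size - r - 1))
            ok = True
            for _, px, py, pr, _ in placements:
                if (
                    abs(cx - px) < r + pr + margin
                    and abs(cy - py) < r + pr + margin
                ):
                    ok = False
                    break
            if ok:
                placements.append((class_label, cx, cy, r, thickness))
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cored} cored + {spec.n_caa} CAA objects "
                f"of the requested radii in a {spec.tile_size} px tile"
            )
    return placements


def make_tile(spec: FixtureSpec) -> tuple[np.ndarray, BoxSet]:
    """Render one synthetic stained field with exact ground-truth boxes.

    Cored plaques are filled brown discs with darker centres; CAAs are
    brown annuli (vessel-wall rings).  Ground-truth boxes are the tight
    pixel extents of the rendered objects.  Bit-identical output for
    identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    ts = spec.tile_size
    h, s, v = _fill_hsv(rng, (ts, ts), spec.background_hsv)
    placements = _place_objects(rng, spec)
    boxes = []
    object_mask = np.zeros((ts, ts), dtype=bool)
    for class_label, cx, cy, r, thickness in placements:
        # work on the object's local window only
        x0, x1 = cx - r, cx + r + 1
        y0, y1 = cy - r, cy + r + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        if class_label == CORED:
            mask = d2 <= r * r
            core = d2 <= (r / 3.0) ** 2
        else:
            r_in = max(r - thickness, 2)
            mask = (d2 <= r * r) & (d2 >= r_in * r_in)
            core = np.zeros_like(mask)
        win = (slice(y0, y1), slice(x0, x1))
        ph, ps, pv = _fill_hsv(rng, (int(mask.sum()),), spec.plaque_hsv)
        h[win][mask], s[win][mask], v[win][mask] = ph, ps, pv
        if core.any():
            # dense core: darker (lower value), still inside the gamut
            v[win][core] = rng.uniform(60.0, 90.0, int(core.sum()))
        object_mask[win] |= mask
        ys, xs = np.nonzero(mask)
        boxes.append(
            Box(
                class_label,
                float(x0 + xs.min()), float(y0 + ys.min()),
                float(x0 + xs.max() + 1), float(y0 + ys.max() + 1),
            )
        )
    image = _hsv_to_rgb8(h, s, v)
    # round-off insurance: any object pixel that fell out of the 4G8 gamut
    # is repainted with the gamut midpoint colour
    obj_pixels = image[object_mask][None, :, :]
    gamut = hsv_mask(obj_pixels, STAIN_PRESETS["4G8"])[0]
    if not gamut.all():  # pragma: no cover - margins make this unreachable
        (h0, h1), (s0, s1), (v0, v1) = spec.plaque_hsv
        n_bad = int((~gamut).sum())
        mid = _hsv_to_rgb8(
            np.full(n_bad, (h0 + h1) / 2),
            np.full(n_bad, (s0 + s1) / 2),
            np.full(n_bad, (v0 + v1) / 2),
        )
        flat = image[object_mask]
        flat[~gamut] = mid
        image[object_mask] = flat
    truth = BoxSet(f"synthetic-{spec.seed}", ts, ts, boxes)
    return image, truth


def _jitter_box(rng, box: Box, jitter: int, width: float, height: float, source: str) -> Box:
    if jitter <= 0:
        return Box(box.class_label, box.x_min, box.y_min, box.x_max, box.y_max, source=source)
    dx0, dy0, dx1, dy1 = rng.integers(-jitter, jitter + 1, size=4)
    x0 = min(max(box.x_min + dx0, 0.0), width - 2)
    y0 = min(max(box.y_min + dy0, 0.0), height - 2)
    x1 = max(min(box.x_max + dx1, width), x0 + 1)
    y1 = max(min(box.y_max + dy1, height), y0 + 1)
    return Box(box.class_label, x0, y0, x1, y1, source=source)


def _random_box(rng, width: float, height: float, source=None, confidence=None) -> Box:
    w = float(rng.integers(20, 81))
    h = float(rng.integers(20, 81))
    x0 = float(rng.uniform(0, width - w))
    y0 = float(rng.uniform(0, height - h))
    cls = CORED if rng.random() < 0.5 else CAA
    return Box(cls, x0, y0, x0 + w, y0 + h, confidence=confidence, source=source)


def make_annotators(
    ground_truth: BoxSet,
    k: int = 4,
    recall: float = 1.0,
    fp_rate: float = 0.0,
    jitter: int = 3,
    seed: int = 0,
) -> list[BoxSet]:
    """Simulate ``k`` independent annotators of one field.

    Each annotator keeps every true box with probability ``recall``,
    perturbs kept corners by up to ``jitter`` px, and adds
    ``Poisson(fp_rate * n_true)`` spurious boxes of random class, size and
    position.  Annotator ids A1..Ak are stamped into the boxes' sources.
    """
    if not (0 <= recall <= 1 and fp_rate >= 0):
        raise ValueError("recall must lie in [0, 1] and fp_rate must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    w, h = ground_truth.width, ground_truth.height
    for i in range(k):
        source = f"A{i + 1}"
        boxes = []
        for b in ground_truth.boxes:
            if rng.random() < recall:
                boxes.append(_jitter_box(rng, b, jitter, w, h, source))
        n_fp = rng.poisson(fp_rate * len(ground_truth.boxes))
        for _ in range(n_fp):
            boxes.append(_random_box(rng, w, h, source=source))
        out.append(BoxSet(ground_truth.image_id, w, h, boxes))
    return out


class StubDetector:
    """Detector stub emitting perturbed ground truth plus noise.

    Holds a ground-truth :class:`~plaquekit.geometry.BoxSet` in the frame
    it will be called on (a field, or a whole slide when used with
    ``detect_wsi``).  On each call it selects the truth boxes intersecting
    the current tile window — emitting the *full* extent of
    boundary-straddling objects, so adjacent tiles see duplicated boxes
    that slide-level merging re-joins — keeps each with probability
    ``recall``, jitters, and adds false positives.  True positives draw
    confidences from ``conf_tp`` and false positives from ``conf_fp`` so
    TPs stochastically dominate.  Deterministic per (seed, col, row).
    """

    def __init__(
        self,
        ground_truth: BoxSet,
        recall: float = 1.0,
        fp_rate: float = 0.0,
        jitter: int = 0,
        conf_tp: tuple[float, float] = (0.6, 1.0),
        conf_fp: tuple[float, float] = (0.0, 0.5),
        seed: int = 0,
    ):
        self.truth = ground_truth
        self.recall = recall
        self.fp_rate = fp_rate
        self.jitter = jitter
        self.conf_tp = conf_tp
        self.conf_fp = conf_fp
        self.seed = seed

    def __call__(self, image: np.ndarray, col: int = 0, row: int = 0) -> BoxSet:
        th, tw = image.shape[:2]
        x0, y0 = col * tw, row * th
        rng = np.random.default_rng([self.seed, col, row])
        boxes = []
        for b in self.truth.boxes:
            # positive-area intersection with this tile's slide-space window
            if (
                min(b.x_max, x0 + tw) - max(b.x_min, x0) <= 0
                or min(b.y_max, y0 + th) - max(b.y_min, y0) <= 0
            ):
                continue
            if rng.random() >= self.recall:
                continue
            # full local extent, clipped only at the non-negative origin; the
            # positive-side overhang is what lets adjacent tiles' duplicates
            # overlap in slide space and merge back to one object
            local = Box(
                b.class_label,
                max(b.x_min - x0, 0.0), max(b.y_min - y0, 0.0),
                b.x_max - x0, b.y_max - y0,
            )
            if self.jitter > 0:
                local = _jitter_box(rng, local, self.jitter, tw * 2.0, th * 2.0, "model")
            boxes.append(
                Box(
                    local.class_label,
                    local.x_min, local.y_min, local.x_max, local.y_max,
                    confidence=float(rng.uniform(*self.conf_tp)),
                    source="model",
                )
            )
        n_fp = rng.poisson(self.fp_rate * max(len(boxes), 1))
        for _ in range(n_fp):
            boxes.append(
                _random_box(rng, tw, th, source="model",
                            confidence=float(rng.uniform(*self.conf_fp)))
            )
        return BoxSet(self.truth.image_id, tw, th, boxes, check=False)


def make_stub_detector(
    ground_truth: BoxSet,
    recall: float = 1.0,
    fp_rate: float = 0.0,
    jitter: int = 0,
    conf_tp: tuple[float, float] = (0.6, 1.0),
    conf_fp: tuple[float, float] = (0.0, 0.5),
    seed: int = 0,
) -> StubDetector:
    """Build a :class:`StubDetector` over the given ground truth."""
    return StubDetector(ground_truth, recall, fp_rate, jitter, conf_tp, conf_fp, seed)


def make_cerad_cohort(
    means: tuple[float, float, float, float] = DEFAULT_CERAD_MEANS,
    n_per_group: int = 10,
    seed: int = 0,
) -> list[CeradRecord]:
    """Synthetic slide cohort: Poisson cored counts per CERAD-like category.

    Category means default to a burden gradient (2/15/60/150); none/sparse
    is the closest pair at ``n_per_group=10``.
    """
    from .cerad import CATEGORIES

    if len(means) != len(CATEGORIES):
        raise ValueError(f"need one mean per category {CATEGORIES}")
    if any(m < 0 for m in means):
        raise ValueError("Poisson means must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for category, mean in zip(CATEGORIES, means):
        counts = rng.poisson(mean, n_per_group)
        for i, c in enumerate(counts):
            records.append(CeradRecord(f"wsi-{category}-{i + 1}", category, int(c)))
    return records
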