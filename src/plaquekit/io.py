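"""Reading and writing the toolkit's table and raster formats.

Box tables use a fixed schema (CSV header or JSON object keys)::

    image_id,class,x_min,y_min,x_max,y_max,confidence,source

Empty ``confidence``/``source`` fields are allowed and round-trip to
``None``.  Coordinates round-trip losslessly (written with full ``repr``
precision; integers stay integers).

Rasters: PNG and plain/Big TIFF are supported everywhere (tifffile,
imageio); pyramidal SVS only when ``openslide`` happens to be importable.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .geometry import Box, BoxSet

__all__ = [
    "write_boxes_csv",
    "read_boxes_csv",
    "write_boxes_json",
    "read_boxes_json",
    "read_image",
    "write_image",
    "read_wsi",
    "load_stain_config",
]

_SCHEMA = ("image_id", "class", "x_min", "y_min", "x_max", "y_max", "confidence", "source")


def _num(value: float) -> str:
    # integers without trailing .0 so integer boxes stay readable; floats at
    # full repr precision so round-trips are lossless
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _box_row(image_id: str, b: Box) -> dict[str, str]:
    return {
        "image_id": image_id,
        "class": b.class_label,
        "x_min": _num(b.x_min),
        "y_min": _num(b.y_min),
        "x_max": _num(b.x_max),
        "y_max": _num(b.y_max),
        "confidence": "" if b.confidence is None else repr(float(b.confidence)),
        "source": "" if b.source is None else b.source,
    }


def _as_boxsets(boxsets: BoxSet | Iterable[BoxSet]) -> list[BoxSet]:
    if isinstance(boxsets, BoxSet):
        return [boxsets]
    return list(boxsets)


def write_boxes_csv(boxsets: BoxSet | Iterable[BoxSet], path: str | Path) -> None:
    """Write one or more BoxSets to a CSV box table."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_SCHEMA)
        writer.writeheader()
        for bs in _as_boxsets(boxsets):
            for b in bs.boxes:
                writer.writerow(_box_row(bs.image_id, b))


def _parse_row(row: Mapping[str, object]) -> tuple[str, Box]:
    conf = row.get("confidence")
    if conf in ("", None):
        conf = None
    else:
        conf = float(conf)
    source = row.get("source")
    if source in ("", None):
        source = None
    box = Box(
        class_label=str(row["class"]),
        x_min=float(row["x_min"]),
        y_min=float(row["y_min"]),
        x_max=float(row["x_max"]),
        y_max=float(row["y_max"]),
        confidence=conf,
        source=source,
    )
    return str(row["image_id"]), box


def _group(
    rows: Iterable[tuple[str, Box]],
    image_sizes: Mapping[str, tuple[float, float]] | None,
    default_size: tuple[float, float],
) -> dict[str, BoxSet]:
    grouped: dict[str, list[Box]] = {}
    for image_id, box in rows:
        grouped.setdefault(image_id, []).append(box)
    out: dict[str, BoxSet] = {}
    for image_id, boxes in grouped.items():
        w, h = (image_sizes or {}).get(image_id, default_size)
        out[image_id] = BoxSet(image_id, w, h, boxes)
    return out


def read_boxes_csv(
    path: str | Path,
    image_sizes: Mapping[str, tuple[float, float]] | None = None,
    default_size: tuple[float, float] = (1536, 1536),
) -> dict[str, BoxSet]:
    """Read a CSV box table, grouping rows into BoxSets by image_id.

    The schema carries no image dimensions, so sizes come from
    ``image_sizes`` (keyed by image_id) or ``default_size`` (the standard
    1536 px field).
    """
    with open(path, newline="") as fh:
        rows = [_parse_row(row) for row in csv.DictReader(fh)]
    return _group(rows, image_sizes, default_size)


def write_boxes_json(boxsets: BoxSet | Iterable[BoxSet], path: str | Path) -> None:
    """Write BoxSets as a JSON list of objects (same keys as the CSV)."""
    records = []
    for bs in _as_boxsets(boxsets):
        for b in bs.boxes:
            records.append(
                {
                    "image_id": bs.image_id,
                    "class": b.class_label,
                    "x_min": b.x_min,
                    "y_min": b.y_min,
                    "x_max": b.x_max,
                    "y_max": b.y_max,
                    "confidence": b.confidence,
                    "source": b.source,
                }
            )
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def read_boxes_json(
    path: str | Path,
    image_sizes: Mapping[str, tuple[float, float]] | None = None,
    default_size: tuple[float, float] = (1536, 1536),
) -> dict[str, BoxSet]:
    with open(path) as fh:
        records = json.load(fh)
    return _group([_parse_row(r) for r in records], image_sizes, default_size)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as a numpy array (RGB images as HxWx3 uint8)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image)
        return
    import imageio.v3 as iio

    iio.imwrite(path, image)


def read_wsi(path: str | Path, target_mpp: float = 0.5) -> np.ndarray:
    """Read a whole-slide image.

    Plain/Big TIFF and PNG are read directly.  Pyramidal SVS requires the
    optional ``openslide`` dependency; when present, the pyramid level with
    resolution closest to ``target_mpp`` microns/pixel is read.
    """
    path = Path(path)
    if path.suffix.lower() != ".svs":
        return read_image(path)
    try:
        import openslide  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading pyramidal SVS requires the optional 'openslide' package; "
            "convert the slide to plain TIFF instead"
        ) from exc
    slide = openslide.OpenSlide(str(path))  # pragma: no cover
    mpp = float(slide.properties.get("openslide.mpp-x", target_mpp))
    levels = [mpp * d for d in slide.level_downsamples]
    level = int(np.argmin([abs(m - target_mpp) for m in levels]))
    w, h = slide.level_dimensions[level]
    region = slide.read_region((0, 0), level, (w, h)).convert("RGB")
    return np.asarray(region)


def load_stain_config(path: str | Path) -> dict:
    """Load a YAML stain configuration.

    Expected structure::

        kernel: 5
        min_area: 200
        stains:
          4G8: {h: [0, 40], s: [10, 255], v: [0, 220]}

    Returns a dict with keys ``stains`` (name -> HSVRange), ``kernel`` and
    ``min_area`` (absent keys fall back to the built-in defaults).
    """
    from .candidates import HSVRange

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    stains = {}
    for name, rng in (raw.get("stains") or {}).items():
        stains[name] = HSVRange(
            stain=name,
            h_min=rng["h"][0], h_max=rng["h"][1],
            s_min=rng["s"][0], s_max=rng["s"][1],
            v_min=rng["v"][0], v_max=rng["v"][1],
        )
    return {
        "stains": stains,
        "kernel": raw.get("kernel"),
        "min_area": raw.get("min_area"),
    }
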