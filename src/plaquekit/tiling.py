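"""Deterministic tiling of whole-slide images into non-overlapping fields.

A slide of ``width x height`` pixels is covered by a grid of
``floor(width/tile_size) x floor(height/tile_size)`` tiles anchored at the
top-left corner; right/bottom remainder strips narrower than one tile are
dropped rather than padded, so no tissue pixels are fabricated.  Tiles are
indexed ``(col, row)`` and iterated row-major (row outer, col inner).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .geometry import Box

__all__ = [
    "TileGrid",
    "make_grid",
    "tile_to_slide",
    "slide_to_tile",
    "extract_tiles",
    "downsample_half",
    "write_tile_manifest",
]


@dataclass(frozen=True)
class TileGrid:
    """Mapping between slide pixel space and tile indices."""

    wsi_id: str
    width: int
    height: int
    tile_size: int = 1536

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.n_cols == 0 or self.n_rows == 0:
            raise ValueError(
                f"image {self.width} x {self.height} is smaller than one "
                f"{self.tile_size} px tile; the grid would be empty"
            )

    @property
    def n_cols(self) -> int:
        return self.width // self.tile_size

    @property
    def n_rows(self) -> int:
        return self.height // self.tile_size

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    def offset(self, col: int, row: int) -> tuple[int, int]:
        """Slide-space pixel offset of tile ``(col, row)``'s top-left corner."""
        self._check_index(col, row)
        return col * self.tile_size, row * self.tile_size

    def _check_index(self, col: int, row: int) -> None:
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise IndexError(
                f"tile ({col}, {row}) outside grid {self.n_cols} x {self.n_rows}"
            )

    def iter_tiles(self) -> Iterator[tuple[int, int]]:
        """Yield (col, row) pairs in row-major order."""
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield col, row


def make_grid(width: int, height: int, tile_size: int = 1536, wsi_id: str = "wsi") -> TileGrid:
    """Build the tile grid for a slide of the given pixel dimensions.

    Raises ``ValueError`` when the slide is smaller than one tile.
    """
    return TileGrid(wsi_id=wsi_id, width=int(width), height=int(height), tile_size=int(tile_size))


def tile_to_slide(grid: TileGrid, col: int, row: int, box: Box) -> Box:
    """Translate a tile-coordinate box into slide coordinates.

    The box must lie within the tile's ``[0, tile_size)^2`` extent; use
    :meth:`Box.translate` directly for detector outputs that overhang.
    """
    ts = grid.tile_size
    if box.x_min < 0 or box.y_min < 0 or box.x_max > ts or box.y_max > ts:
        raise ValueError(f"box {box} exceeds tile bounds [0, {ts})^2")
    dx, dy = grid.offset(col, row)
    return box.translate(dx, dy)


def slide_to_tile(grid: TileGrid, col: int, row: int, box: Box) -> Box:
    """Inverse of :func:`tile_to_slide`: slide coordinates to tile-local."""
    dx, dy = grid.offset(col, row)
    ts = grid.tile_size
    if box.x_min < dx or box.y_min < dy or box.x_max > dx + ts or box.y_max > dy + ts:
        raise ValueError(f"box {box} does not lie within tile ({col}, {row})")
    return box.translate(-dx, -dy)


def extract_tiles(image: np.ndarray, grid: TileGrid) -> Iterator[tuple[int, int, np.ndarray]]:
    """Yield ``(col, row, tile)`` views over the image in row-major order.

    The raster's spatial dimensions must match the grid's; tile pixels are
    views into the source (bit-identical, no copies).
    """
    h, w = image.shape[:2]
    if (w, h) != (grid.width, grid.height):
        raise ValueError(
            f"raster is {w} x {h} but grid expects {grid.width} x {grid.height}"
        )
    ts = grid.tile_size
    for col, row in grid.iter_tiles():
        x0, y0 = col * ts, row * ts
        yield col, row, image[y0 : y0 + ts, x0 : x0 + ts]


def downsample_half(image: np.ndarray) -> np.ndarray:
    """2x area-averaging downsample (40x -> 20x resolution normalization).

    Odd trailing rows/columns are cropped.  Integer inputs are rounded back
    to their original dtype.
    """
    h, w = image.shape[:2]
    img = image[: h - h % 2, : w - w % 2]
    if img.ndim == 2:
        img = img[:, :, None]
        squeeze = True
    else:
        squeeze = False
    hh, ww, c = img.shape
    block = img.reshape(hh // 2, 2, ww // 2, 2, c).astype(np.float64)
    out = block.mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).astype(image.dtype)
    else:
        out = out.astype(image.dtype)
    return out[:, :, 0] if squeeze else out


def write_tile_manifest(grid: TileGrid, path: str | Path) -> None:
    """Write the tile layout as CSV: wsi_id,col,row,x_offset,y_offset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wsi_id", "col", "row", "x_offset", "y_offset"])
        for col, row in grid.iter_tiles():
            x0, y0 = grid.offset(col, row)
            writer.writerow([grid.wsi_id, col, row, x0, y0])
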