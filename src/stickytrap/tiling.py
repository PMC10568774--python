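"""Deterministic overlapping tile grids for tiny-object inference.

A full trap-board frame (e.g. 3280 x 2464 px) is far larger than a detector's
input, and resizing the whole frame destroys insects only a few pixels long.
Cropping the frame into fixed-size tiles that overlap by enough to contain a
whole insect lets every insect appear uncut in at least one tile; detections
from all tiles are then translated back to the frame and de-duplicated with a
single whole-image DIoU-NMS pass.

The default geometry tiles a 3280 x 2464 frame with 600 px tiles into a 6 x 5
grid with 64 px horizontal and 134 px vertical overlaps (30 tiles).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import Box, DetectionSet, diou_nms

__all__ = [
    "TileGrid",
    "plan_grid",
    "crop_tiles",
    "clip_annotations",
    "merge_detections",
    "tile_name",
]

_FRAME_RE = re.compile(r"^tile:(\d+),(\d+)$")


@dataclass(frozen=True)
class TileGrid:
    """Overlapping crop layout for one image size.

    ``x_origins``/``y_origins`` are the left/top pixel of each tile column/row;
    the last tile along each axis ends exactly at the image edge.  When the
    uniform overlap is fractional, the remainder pixels are added to the
    earliest overlaps so every origin stays integral.
    """

    image_width: int
    image_height: int
    tile_size: int
    x_origins: tuple[int, ...]
    y_origins: tuple[int, ...]

    @property
    def nx(self) -> int:
        return len(self.x_origins)

    @property
    def ny(self) -> int:
        return len(self.y_origins)

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    @property
    def overlap_x(self) -> int:
        """Base horizontal overlap in px (0 for a single column)."""
        if self.nx < 2:
            return 0
        return min(
            self.x_origins[i] + self.tile_size - self.x_origins[i + 1]
            for i in range(self.nx - 1)
        )

    @property
    def overlap_y(self) -> int:
        if self.ny < 2:
            return 0
        return min(
            self.y_origins[i] + self.tile_size - self.y_origins[i + 1]
            for i in range(self.ny - 1)
        )

    @property
    def origins(self) -> list[tuple[int, int]]:
        """Row-major (x0, y0) per tile."""
        return [(x0, y0) for y0 in self.y_origins for x0 in self.x_origins]

    def tile_extent(self, row: int, col: int) -> tuple[int, int, int, int]:
        x0, y0 = self.x_origins[col], self.y_origins[row]
        return x0, y0, x0 + self.tile_size, y0 + self.tile_size

    def origin_index(self, origin: tuple[int, int]) -> tuple[int, int]:
        """(row, col) of a tile origin; raises if it is not on the grid."""
        x0, y0 = origin
        try:
            return self.y_origins.index(y0), self.x_origins.index(x0)
        except ValueError:
            raise ValueError(f"origin {origin} not on grid") from None

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_width": self.image_width,
                "image_height": self.image_height,
                "tile_size": self.tile_size,
                "x_origins": list(self.x_origins),
                "y_origins": list(self.y_origins),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        d = json.loads(text)
        return cls(
            image_width=d["image_width"],
            image_height=d["image_height"],
            tile_size=d["tile_size"],
            x_origins=tuple(d["x_origins"]),
            y_origins=tuple(d["y_origins"]),
        )


def _axis_origins(dim: int, tile: int) -> tuple[int, ...]:
    if tile > dim:
        raise ValueError(f"tile size {tile} exceeds image dimension {dim}")
    n = math.ceil(dim / tile)
    if n == 1:
        return (0,)
    total_overlap = n * tile - dim
    base, rem = divmod(total_overlap, n - 1)
    # Distribute fractional remainder to the earliest gaps (deterministic).
    overlaps = [base + 1] * rem + [base] * (n - 1 - rem)
    origins = [0]
    for o in overlaps:
        origins.append(origins[-1] + tile - o)
    return tuple(origins)


def plan_grid(image_width: int, image_height: int, tile_size: int) -> TileGrid:
    """Plan the minimal overlapping grid of ``tile_size`` tiles covering the image.

    Per axis ``n = ceil(dim / tile_size)`` tiles share a uniform overlap
    ``(n * tile_size - dim) / (n - 1)``; fractional remainders go to the first
    gaps as one extra pixel each.
    """
    return TileGrid(
        image_width=image_width,
        image_height=image_height,
        tile_size=tile_size,
        x_origins=_axis_origins(image_width, tile_size),
        y_origins=_axis_origins(image_height, tile_size),
    )


def tile_name(image_id: str, row: int, col: int, ext: str = "png") -> str:
    return f"{image_id}_r{row}_c{col}.{ext}"


def crop_tiles(
    image: np.ndarray, grid: TileGrid
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Cut the image into ``(tile raster, (x0, y0))`` pairs, row-major."""
    h, w = image.shape[:2]
    if (w, h) != (grid.image_width, grid.image_height):
        raise ValueError(
            f"image is {w}x{h} but grid expects {grid.image_width}x{grid.image_height}"
        )
    t = grid.tile_size
    return [
        (image[y0 : y0 + t, x0 : x0 + t], (x0, y0))
        for y0 in grid.y_origins
        for x0 in grid.x_origins
    ]


def clip_annotations(
    truth: DetectionSet,
    grid: TileGrid,
    min_visibility: float = 0.25,
) -> list[DetectionSet]:
    """Intersect global-frame boxes with every tile.

    A box is retained in a tile (in tile-local coordinates) iff the
    intersected area is at least ``min_visibility`` times its original area;
    boxes sitting inside an overlap strip therefore appear in several tiles.
    Returns one DetectionSet per tile, row-major, frames tagged ``tile:r,c``.
    """
    if not 0.0 < min_visibility <= 1.0:
        raise ValueError(f"min_visibility {min_visibility} outside (0, 1]")
    if truth.frame != "global":
        raise ValueError(f"expected global-frame truth, got {truth.frame!r}")
    out: list[DetectionSet] = []
    for r in range(grid.ny):
        for c in range(grid.nx):
            x0, y0, x1, y1 = grid.tile_extent(r, c)
            kept: list[Box] = []
            for b in truth.boxes:
                clip = b.clipped(x0, y0, x1, y1)
                if clip is None or clip.area < min_visibility * b.area:
                    continue
                kept.append(clip.shifted(-x0, -y0))
            out.append(DetectionSet(truth.image_id, tuple(kept), frame=f"tile:{r},{c}"))
    return out


def merge_detections(
    per_tile: Sequence[DetectionSet],
    grid: TileGrid,
    epsilon: float = 0.45,
    class_aware: bool = True,
) -> DetectionSet:
    """Remap tile-frame detections to the global frame and de-duplicate.

    Boxes are translated by their tile origin, clipped to the image extent,
    pooled, and passed once through whole-image DIoU-NMS.
    """
    pooled: list[Box] = []
    image_id = per_tile[0].image_id if per_tile else "image"
    for dets in per_tile:
        m = _FRAME_RE.match(dets.frame)
        if m is None:
            raise ValueError(f"unknown tile frame tag {dets.frame!r}")
        r, c = int(m.group(1)), int(m.group(2))
        if not (0 <= r < grid.ny and 0 <= c < grid.nx):
            raise ValueError(f"tile {dets.frame!r} outside {grid.ny}x{grid.nx} grid")
        x0, y0 = grid.x_origins[c], grid.y_origins[r]
        for b in dets.boxes:
            g = b.shifted(x0, y0).clipped(0, 0, grid.image_width, grid.image_height)
            if g is not None:
                pooled.append(g)
    merged = DetectionSet(image_id, tuple(pooled), frame="global")
    return diou_nms(merged, epsilon=epsilon, class_aware=class_aware)
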