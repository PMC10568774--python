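"""Per-tile detector contract, a classical reference detector, and box I/O.

A detector is any callable ``(tile_raster, origin) -> DetectionSet`` in the
tile's local frame.  Two implementations ship with the package:

* :class:`OracleDetector` replays clipped ground truth per tile — the ideal
  detector used to validate the tiling/merging machinery in isolation.
* :class:`ReferenceDetector` is a classical colour-segmentation detector for
  synthetic boards: it segments anything far from the yellow board colour,
  extracts connected blobs, rejects dust below the smallest pest size band,
  and assigns a class from mm body-length bands and tone.  It exists so the
  whole pipeline runs and can be evaluated without trained weights; it is not
  calibrated to match any learned model's accuracy.

I/O covers the two common plain-text box dialects: YOLO-txt (one
``class cx cy w h [score]`` line per box, normalised to image size) and a
single-image COCO-style JSON with absolute ``[x, y, w, h]`` boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import yaml
from skimage.measure import label, regionprops

from .boxes import Box, DetectionSet
from .synthgen import DEFAULT_PX_PER_MM, PestSpec, class_names, default_catalog
from .tiling import TileGrid, crop_tiles, merge_detections

__all__ = [
    "Detector",
    "OracleDetector",
    "ReferenceDetector",
    "ReferenceParams",
    "run_pipeline",
    "read_detections",
    "write_detections",
    "read_class_map",
    "write_class_map",
]


class Detector(Protocol):
    """Callable detection contract: tile raster + tile origin -> tile-frame boxes."""

    def __call__(
        self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> DetectionSet: ...


class OracleDetector:
    """Replays clipped ground truth for each tile of a known grid.

    A truth box is reported in a tile iff its visible fraction there is at
    least ``min_visibility``, and its score is that fraction — so whole-image
    suppression always prefers the fullest view of a pest.  The default
    threshold of 0.6 sits above the suppression threshold plus the worst-case
    centre-distance penalty of near-nested duplicate views, which makes the
    merged output count-exact (see the methods note).
    """

    def __init__(
        self,
        truth: DetectionSet,
        grid: TileGrid,
        min_visibility: float = 0.6,
    ) -> None:
        if not 0.0 < min_visibility <= 1.0:
            raise ValueError(f"min_visibility {min_visibility} outside (0, 1]")
        self.truth = truth
        self.grid = grid
        self.min_visibility = min_visibility

    def __call__(
        self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> DetectionSet:
        r, c = self.grid.origin_index(origin)
        x0, y0, x1, y1 = self.grid.tile_extent(r, c)
        kept = []
        for b in self.truth.boxes:
            clip = b.clipped(x0, y0, x1, y1)
            if clip is None:
                continue
            vis = clip.area / b.area
            if vis < self.min_visibility:
                continue
            kept.append(
                Box(
                    clip.x_min - x0,
                    clip.y_min - y0,
                    clip.x_max - x0,
                    clip.y_max - y0,
                    class_id=b.class_id,
                    score=min(vis, 1.0),
                )
            )
        return DetectionSet(self.truth.image_id, tuple(kept), frame=f"tile:{r},{c}")


@dataclass
class ReferenceParams:
    """Tunables of the classical reference detector."""

    px_per_mm: float = DEFAULT_PX_PER_MM
    color_threshold: float = 60.0  # RGB distance from the tile's median colour
    min_length_mm: float = 0.45  # below the thrips band -> dust, rejected
    light_tone_value: float = 200.0  # mean brightness separating light pests


class ReferenceDetector:
    """Colour-blob detector for yellow-board imagery.

    Pixels whose RGB distance from the tile's median (board) colour exceeds a
    threshold are foreground; connected components become candidate boxes.
    Components shorter than the smallest pest band are discarded as dust, and
    components touching an interior tile edge are discarded as cut views (the
    complete view lives in a neighbouring tile whenever the insect is smaller
    than the overlap).  The class is the size band containing the blob's
    major-axis length, tone-filtered; the score is blob solidity times a
    band-membership factor.
    """

    def __init__(
        self,
        catalog: Sequence[PestSpec] | None = None,
        params: ReferenceParams | None = None,
        grid: TileGrid | None = None,
    ) -> None:
        self.catalog = tuple(default_catalog() if catalog is None else catalog)
        self.params = params or ReferenceParams()
        self.grid = grid  # enables interior-edge rejection when known

    def _interior_edges(
        self, origin: tuple[int, int], tile_h: int, tile_w: int
    ) -> tuple[bool, bool, bool, bool]:
        """(left, top, right, bottom) edges that are interior seams of the grid."""
        if self.grid is None:
            return (False, False, False, False)
        x0, y0 = origin
        return (
            x0 > 0,
            y0 > 0,
            x0 + tile_w < self.grid.image_width,
            y0 + tile_h < self.grid.image_height,
        )

    def _classify(self, length_mm: float, light: bool) -> tuple[int, float]:
        """(class_id, band-membership factor) for a blob length and tone."""
        candidates = [
            s
            for s in self.catalog
            if (s.tone == "light") == light
            and s.length_mm[0] <= length_mm <= s.length_mm[1]
        ]
        membership = 1.0
        if not candidates:
            # Tone mismatch or out-of-band: fall back to the nearest band centre.
            candidates = list(self.catalog)
            membership = 0.5
        best = min(
            candidates,
            key=lambda s: abs(length_mm - (s.length_mm[0] + s.length_mm[1]) / 2.0),
        )
        return best.class_id, membership

    def __call__(
        self, tile: np.ndarray, origin: tuple[int, int] = (0, 0)
    ) -> DetectionSet:
        if tile.ndim != 3 or tile.shape[2] < 3:
            raise ValueError("reference detector requires a color raster")
        h, w = tile.shape[:2]
        pixels = tile[..., :3].astype(np.float32)
        board = np.median(pixels.reshape(-1, 3), axis=0)
        dist = np.sqrt(((pixels - board) ** 2).sum(axis=-1))
        mask = dist > self.params.color_threshold
        left, top, right, bottom = self._interior_edges(origin, h, w)

        boxes: list[Box] = []
        for region in regionprops(label(mask, connectivity=2)):
            r0, c0, r1, c1 = region.bbox
            length_px = max(region.axis_major_length, r1 - r0, c1 - c0)
            length_mm = length_px / self.params.px_per_mm
            if length_mm < self.params.min_length_mm:
                continue  # dust speck
            if (
                (left and c0 <= 0)
                or (top and r0 <= 0)
                or (right and c1 >= w)
                or (bottom and r1 >= h)
            ):
                continue  # cut view across an interior seam
            blob = pixels[region.slice][region.image]
            light = float(blob.mean()) > self.params.light_tone_value
            class_id, membership = self._classify(length_mm, light)
            score = min(max(region.solidity * membership, 0.0), 1.0)
            boxes.append(Box(c0, r0, c1, r1, class_id=class_id, score=score))
        frame = "tile:0,0"
        if self.grid is not None:
            try:
                r, c = self.grid.origin_index(origin)
                frame = f"tile:{r},{c}"
            except ValueError:
                pass
        return DetectionSet("tile", tuple(boxes), frame=frame)


def run_pipeline(
    image: np.ndarray,
    grid: TileGrid,
    detector: Detector,
    epsilon: float = 0.45,
    class_aware: bool = True,
    image_id: str = "image",
) -> DetectionSet:
    """Crop -> detect per tile -> remap and DIoU-NMS over the whole image."""
    per_tile: list[DetectionSet] = []
    for (tile, origin), (r, c) in zip(
        crop_tiles(image, grid),
        ((r, c) for r in range(grid.ny) for c in range(grid.nx)),
    ):
        dets = detector(tile, origin)
        per_tile.append(DetectionSet(image_id, dets.boxes, frame=f"tile:{r},{c}"))
    return merge_detections(per_tile, grid, epsilon=epsilon, class_aware=class_aware)


# ---------------------------------------------------------------------------
# Box file I/O


def write_detections(
    dets: DetectionSet,
    path: str | Path,
    dialect: str = "yolo-txt",
    image_size: tuple[int, int] | None = None,
) -> None:
    """Write boxes in YOLO-txt (needs ``image_size``) or COCO-JSON."""
    path = Path(path)
    if dialect == "yolo-txt":
        if image_size is None:
            raise ValueError("image_size required for the yolo-txt dialect")
        w, h = image_size
        lines = []
        for b in dets.boxes:
            cx, cy = b.center
            lines.append(
                f"{b.class_id} {cx / w:.9f} {cy / h:.9f} "
                f"{b.width / w:.9f} {b.height / h:.9f} {b.score:.9f}"
            )
        path.write_text("".join(line + "\n" for line in lines))
    elif dialect == "coco-json":
        payload = {
            "images": [{"id": 0, "file_name": dets.image_id}],
            "annotations": [
                {
                    "id": i,
                    "image_id": 0,
                    "category_id": b.class_id,
                    "bbox": [b.x_min, b.y_min, b.width, b.height],
                    "score": b.score,
                    "area": b.area,
                }
                for i, b in enumerate(dets.boxes)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_detections(
    path: str | Path,
    dialect: str = "yolo-txt",
    image_size: tuple[int, int] | None = None,
    image_id: str | None = None,
    frame: str = "global",
) -> DetectionSet:
    """Read boxes written by :func:`write_detections` (lossless round trip)."""
    path = Path(path)
    image_id = image_id or path.stem
    if dialect == "yolo-txt":
        if image_size is None:
            raise ValueError("image_size required for the yolo-txt dialect")
        w, h = image_size
        boxes = []
        for ln, raw in enumerate(path.read_text().splitlines(), start=1):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{ln}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                cx, cy, bw, bh = (float(v) for v in parts[1:5])
                score = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed line: {raw!r}") from exc
            boxes.append(
                Box(
                    (cx - bw / 2) * w,
                    (cy - bh / 2) * h,
                    (cx + bw / 2) * w,
                    (cy + bh / 2) * h,
                    class_id=cid,
                    score=score,
                )
            )
        return DetectionSet(image_id, tuple(boxes), frame=frame)
    if dialect == "coco-json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: malformed JSON at line {exc.lineno}") from exc
        boxes = []
        for rec in payload.get("annotations", []):
            x, y, bw, bh = rec["bbox"]
            boxes.append(
                Box(
                    x, y, x + bw, y + bh,
                    class_id=int(rec["category_id"]),
                    score=float(rec.get("score", 1.0)),
                )
            )
        if payload.get("images"):
            image_id = payload["images"][0].get("file_name", image_id)
        return DetectionSet(image_id, tuple(boxes), frame=frame)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_class_map(path: str | Path, catalog: Sequence[PestSpec] | None = None) -> None:
    """Serialise the id -> name class map as YAML."""
    names = class_names(catalog)
    Path(path).write_text(yaml.safe_dump({i: n for i, n in enumerate(names)}))


def read_class_map(path: str | Path) -> dict[int, str]:
    data = yaml.safe_load(Path(path).read_text())
    return {int(k): str(v) for k, v in data.items()}
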