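"""Training-set construction: mosaic stitching and tile-based expansion.

Mosaic augmentation stitches four annotated images around a random centre
split point into one canvas, after jittering each input (axis-aligned 90-degree
rotations and flips, scaling, brightness/hue shifts).  Rotation is restricted
to multiples of 90 degrees because axis-aligned boxes cannot represent an
arbitrary rotation without re-fitting; flips cover the remaining orientation
variety.

Tile expansion ("copy-pasting") turns a handful of high-resolution annotated
frames into a large set of small training images by cropping every frame into
its overlapping tile grid and clipping annotations into each tile.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

from .boxes import Box, DetectionSet
from .detector import write_detections
from .tiling import clip_annotations, crop_tiles, plan_grid, tile_name

__all__ = ["AugmentConfig", "mosaic", "build_tile_training_set"]

_PAD_GRAY = 114  # canvas fill outside pasted patches


@dataclass(frozen=True)
class AugmentConfig:
    """Mosaic/jitter parameters; all randomness flows through ``seed``."""

    output_size: int = 1200
    scale_range: tuple[float, float] = (0.75, 1.25)
    flip_prob: float = 0.5
    rot90: bool = True
    brightness_jitter: tuple[float, float] = (0.8, 1.2)  # multiplicative on V
    hue_jitter: tuple[float, float] = (-0.03, 0.03)  # additive on H (cyclic)
    center_range: tuple[float, float] = (0.25, 0.75)  # split point, canvas fractions
    min_box_area: float = 4.0  # px^2; smaller survivors are dropped
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob outside [0, 1]")
        for name in ("scale_range", "brightness_jitter", "hue_jitter", "center_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"empty interval for {name}")


def _rot90_box(b: Box, k: int, w: float, h: float) -> Box:
    """Box under np.rot90(image, k) (counter-clockwise quarter turns)."""
    for _ in range(k % 4):
        b = Box(b.y_min, w - b.x_max, b.y_max, w - b.x_min, b.class_id, b.score)
        w, h = h, w
    return b


def _flip_box(b: Box, w: float) -> Box:
    return Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max, b.class_id, b.score)


def _jitter_colors(img: np.ndarray, rng: np.random.Generator, cfg: AugmentConfig) -> np.ndarray:
    hsv = rgb2hsv(img[..., :3].astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + rng.uniform(*cfg.hue_jitter)) % 1.0
    hsv[..., 2] = np.clip(hsv[..., 2] * rng.uniform(*cfg.brightness_jitter), 0.0, 1.0)
    return (hsv2rgb(hsv) * 255.0).astype(np.uint8)


def _transform_one(
    img: np.ndarray,
    dets: DetectionSet,
    rng: np.random.Generator,
    cfg: AugmentConfig,
) -> tuple[np.ndarray, list[Box]]:
    boxes = list(dets.boxes)
    h, w = img.shape[:2]
    if cfg.rot90:
        k = int(rng.integers(0, 4))
        if k:
            img = np.rot90(img, k)
            boxes = [_rot90_box(b, k, w, h) for b in boxes]
            if k % 2:
                w, h = h, w
    if rng.random() < cfg.flip_prob:
        img = img[:, ::-1]
        boxes = [_flip_box(b, w) for b in boxes]
    img = _jitter_colors(img, rng, cfg)
    s = float(rng.uniform(*cfg.scale_range))
    if s != 1.0:
        nw, nh = max(int(round(w * s)), 1), max(int(round(h * s)), 1)
        img = np.asarray(
            Image.fromarray(img).resize((nw, nh), Image.Resampling.BILINEAR)
        )
        sx, sy = nw / w, nh / h
        boxes = [
            Box(b.x_min * sx, b.y_min * sy, b.x_max * sx, b.y_max * sy,
                b.class_id, b.score)
            for b in boxes
        ]
    return np.ascontiguousarray(img), boxes


def mosaic(
    images_with_truth: Sequence[tuple[np.ndarray, DetectionSet]],
    cfg: AugmentConfig | None = None,
) -> tuple[np.ndarray, DetectionSet]:
    """Stitch four annotated images into one mosaic canvas.

    Each input is jittered, then pasted into one quadrant around a random
    centre split point; overflow is cropped, shortfall padded gray.  Boxes
    follow their patch and are clipped to the pasted region; survivors below
    ``min_box_area`` are dropped.  Identical inputs, config and seed give a
    bit-identical result.
    """
    cfg = cfg or AugmentConfig()
    if len(images_with_truth) != 4:
        raise ValueError(f"mosaic needs exactly 4 annotated images, got {len(images_with_truth)}")
    rng = np.random.default_rng(cfg.seed)
    s = cfg.output_size
    canvas = np.full((s, s, 3), _PAD_GRAY, dtype=np.uint8)
    cx = int(round(rng.uniform(*cfg.center_range) * s))
    cy = int(round(rng.uniform(*cfg.center_range) * s))
    cx, cy = min(max(cx, 1), s - 1), min(max(cy, 1), s - 1)

    out_boxes: list[Box] = []
    for k, (img, dets) in enumerate(images_with_truth):
        patch, boxes = _transform_one(np.asarray(img), dets, rng, cfg)
        ph, pw = patch.shape[:2]
        if k == 0:  # top-left: anchor the patch's bottom-right corner at (cx, cy)
            x1a, y1a, x2a, y2a = max(cx - pw, 0), max(cy - ph, 0), cx, cy
            x1b, y1b = pw - (x2a - x1a), ph - (y2a - y1a)
        elif k == 1:  # top-right
            x1a, y1a, x2a, y2a = cx, max(cy - ph, 0), min(cx + pw, s), cy
            x1b, y1b = 0, ph - (y2a - y1a)
        elif k == 2:  # bottom-left
            x1a, y1a, x2a, y2a = max(cx - pw, 0), cy, cx, min(cy + ph, s)
            x1b, y1b = pw - (x2a - x1a), 0
        else:  # bottom-right
            x1a, y1a, x2a, y2a = cx, cy, min(cx + pw, s), min(cy + ph, s)
            x1b, y1b = 0, 0
        canvas[y1a:y2a, x1a:x2a] = patch[y1b : y1b + (y2a - y1a), x1b : x1b + (x2a - x1a)]
        dx, dy = x1a - x1b, y1a - y1b
        for b in boxes:
            shifted = b.shifted(dx, dy)
            clip = shifted.clipped(x1a, y1a, x2a, y2a)
            if clip is not None and clip.area >= cfg.min_box_area:
                out_boxes.append(clip)

    image_id = f"mosaic_{cfg.seed}"
    return canvas, DetectionSet(image_id, tuple(out_boxes), frame="global")


def build_tile_training_set(
    annotated_images: Sequence[tuple[str, np.ndarray, DetectionSet]],
    out_dir: str | Path,
    tile_size: int = 600,
    min_visibility: float = 0.25,
) -> Path:
    """Expand annotated frames into a tile dataset on disk.

    For every input frame the overlapping grid is planned, each tile is saved
    as ``{image_id}_r{row}_c{col}.png`` with a YOLO-txt label file of the same
    stem (empty files are kept as negatives), and a ``manifest.csv`` records
    tile provenance.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    labels_dir = out_dir / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["tile", "source_image", "row", "col", "x0", "y0", "tile_size", "n_boxes"]
        )
        for image_id, image, truth in annotated_images:
            h, w = np.asarray(image).shape[:2]
            grid = plan_grid(w, h, tile_size)
            tiles = crop_tiles(np.asarray(image), grid)
            clipped = clip_annotations(truth, grid, min_visibility=min_visibility)
            for idx, ((tile, (x0, y0)), dets) in enumerate(zip(tiles, clipped)):
                r, c = divmod(idx, grid.nx)
                name = tile_name(image_id, r, c)
                try:
                    Image.fromarray(tile).save(images_dir / name)
                    write_detections(
                        dets,
                        labels_dir / f"{Path(name).stem}.txt",
                        dialect="yolo-txt",
                        image_size=(tile_size, tile_size),
                    )
                except OSError as exc:
                    raise OSError(f"failed writing tile {images_dir / name}: {exc}") from exc
                writer.writerow([name, image_id, r, c, x0, y0, tile_size, len(dets)])
    return manifest_path
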