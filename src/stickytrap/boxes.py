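"""Axis-aligned box geometry, IoU/DIoU measures and greedy suppression.

Boxes use continuous 0-based pixel coordinates with half-open extents: a box
covers ``[x_min, x_max) x [y_min, y_max)``.  The distance-IoU (DIoU) measure
penalises IoU by the squared distance between box centres, normalised by the
squared diagonal of the smallest rectangle enclosing both boxes.  DIoU-based
suppression keeps overlapping boxes whose centres are clearly displaced —
exactly the regime of two insects stuck side by side on a trap board, which
plain IoU suppression collapses into one detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Box",
    "DetectionSet",
    "iou",
    "diou_penalty",
    "diou_loss",
    "greedy_nms",
    "diou_nms",
]


@dataclass(frozen=True)
class Box:
    """One detection or annotation: geometry, class label and confidence.

    Ground-truth boxes conventionally carry ``score=1.0``.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int = 0
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: [{self.x_min},{self.y_min},{self.x_max},{self.y_max}]"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.class_id < 0:
            raise ValueError(f"negative class_id {self.class_id}")

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
        return (self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def clipped(self, x0: float, y0: float, x1: float, y1: float) -> "Box | None":
        """Intersect with a rectangle; ``None`` if nothing of positive area is left."""
        nx0, ny0 = max(self.x_min, x0), max(self.y_min, y0)
        nx1, ny1 = min(self.x_max, x1), min(self.y_max, y1)
        if nx0 >= nx1 or ny0 >= ny1:
            return None
        return replace(self, x_min=nx0, y_min=ny0, x_max=nx1, y_max=ny1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class DetectionSet:
    """Boxes of one image expressed in one coordinate frame.

    ``frame`` is ``"global"`` for full-image coordinates or ``"tile:r,c"`` for
    coordinates local to the tile at grid row ``r``, column ``c``.
    """

    image_id: str
    boxes: tuple[Box, ...] = ()
    frame: str = "global"

    def __post_init__(self) -> None:
        object.__setattr__(self, "boxes", tuple(self.boxes))

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self) -> Iterator[Box]:
        return iter(self.boxes)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n, 4) coordinates, (n,) scores, (n,) class ids."""
        if not self.boxes:
            return (
                np.empty((0, 4), dtype=float),
                np.empty(0, dtype=float),
                np.empty(0, dtype=int),
            )
        coords = np.array([b.as_tuple() for b in self.boxes], dtype=float)
        scores = np.array([b.score for b in self.boxes], dtype=float)
        classes = np.array([b.class_id for b in self.boxes], dtype=int)
        return coords, scores, classes

    def with_boxes(self, boxes: Iterable[Box], frame: str | None = None) -> "DetectionSet":
        return DetectionSet(self.image_id, tuple(boxes), frame or self.frame)

    def counts_by_class(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for b in self.boxes:
            out[b.class_id] = out.get(b.class_id, 0) + 1
        return out


def iou(a: Box, b: Box) -> float:
    """Intersection area over union area; 0 for disjoint boxes; symmetric."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def diou_penalty(a: Box, b: Box) -> float:
    """Centre-distance penalty: rho^2 / c^2.

    ``rho`` is the Euclidean distance between box centres and ``c`` the
    diagonal of the smallest axis-aligned rectangle covering both boxes.
    Zero iff the centres coincide; always strictly below one.
    """
    (ax, ay), (bx, by) = a.center, b.center
    rho2 = (ax - bx) ** 2 + (ay - by) ** 2
    cw = max(a.x_max, b.x_max) - min(a.x_min, b.x_min)
    ch = max(a.y_max, b.y_max) - min(a.y_min, b.y_min)
    return rho2 / (cw * cw + ch * ch)


def diou_loss(a: Box, b: Box) -> float:
    """Distance-IoU regression loss: ``1 - IoU + rho^2/c^2``, in [0, 2)."""
    return 1.0 - iou(a, b) + diou_penalty(a, b)


def _sort_key(b: Box) -> tuple:
    # Deterministic greedy order: score desc, then class, then coordinates.
    return (-b.score, b.class_id, b.x_min, b.y_min, b.x_max, b.y_max)


def _nms(
    dets: DetectionSet,
    epsilon: float,
    class_aware: bool,
    use_diou: bool,
) -> DetectionSet:
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon {epsilon} outside (0, 1)")
    boxes = sorted(dets.boxes, key=_sort_key)
    n = len(boxes)
    if n == 0:
        return dets.with_boxes(())

    coords = np.array([b.as_tuple() for b in boxes], dtype=float)
    classes = np.array([b.class_id for b in boxes], dtype=int)
    x0, y0, x1, y1 = coords.T
    areas = (x1 - x0) * (y1 - y0)

    alive = np.ones(n, dtype=bool)
    keep: list[int] = []
    for i in range(n):
        if not alive[i]:
            continue
        keep.append(i)
        alive[i] = False
        rest = np.nonzero(alive)[0]
        if rest.size == 0:
            break
        ix = np.minimum(x1[i], x1[rest]) - np.maximum(x0[i], x0[rest])
        iy = np.minimum(y1[i], y1[rest]) - np.maximum(y0[i], y0[rest])
        inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
        crit = inter / (areas[i] + areas[rest] - inter)
        if use_diou:
            cxs = (x0 + x1) / 2.0
            cys = (y0 + y1) / 2.0
            rho2 = (cxs[i] - cxs[rest]) ** 2 + (cys[i] - cys[rest]) ** 2
            cw = np.maximum(x1[i], x1[rest]) - np.minimum(x0[i], x0[rest])
            ch = np.maximum(y1[i], y1[rest]) - np.minimum(y0[i], y0[rest])
            crit = crit - rho2 / (cw * cw + ch * ch)
        suppress = crit >= epsilon
        if class_aware:
            suppress &= classes[rest] == classes[i]
        alive[rest[suppress]] = False

    return dets.with_boxes(boxes[i] for i in keep)


def greedy_nms(
    dets: DetectionSet, epsilon: float = 0.45, class_aware: bool = True
) -> DetectionSet:
    """Plain greedy NMS: suppress B when ``IoU(M, B) >= epsilon``."""
    return _nms(dets, epsilon, class_aware, use_diou=False)


def diou_nms(
    dets: DetectionSet, epsilon: float = 0.45, class_aware: bool = True
) -> DetectionSet:
    """DIoU-NMS: suppress B when ``IoU(M, B) - rho^2/c^2 >= epsilon``.

    The centre-distance term rescues overlapping boxes with displaced centres:
    against any single reference box, DIoU suppression is strictly weaker than
    plain IoU suppression at equal ``epsilon``.  (Over a whole greedy run the
    keep-set is almost always a superset of :func:`greedy_nms`, but not
    provably so: a rescued box can itself suppress a lower-scored neighbour
    that plain NMS would have kept.)
    """
    return _nms(dets, epsilon, class_aware, use_diou=True)
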