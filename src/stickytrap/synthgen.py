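"""Synthetic yellow sticky-trap scenes with exact ground truth.

The generator emulates a 20 x 25 cm yellow trap board imaged by a fixed camera
at full-frame resolution (3280 x 2464 px by default, i.e. ~13.1 px/mm).  Six
greenhouse pest classes are drawn as rotated dark (or, for the tobacco
whitefly, whitish) ellipses with wing specks, with body lengths in millimetres
matching the field sizes of each species and class frequencies matching a
realistic, imbalanced trap catch.  Dust-like distractors below the smallest
pest size band can be sprinkled on top.  Every rendered pest yields exactly
one ground-truth box (the bounding box of its rendered footprint), which makes
the scenes a test substrate for tiling, suppression, detection and counting
code without any trained weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.draw import disk, ellipse

from .boxes import Box, DetectionSet

__all__ = [
    "PestSpec",
    "SceneTruth",
    "default_catalog",
    "class_names",
    "render_scene",
    "render_series",
    "default_outbreak_profile",
    "series_manifest",
    "BOARD_MM",
    "DEFAULT_BOARD_PX",
    "DEFAULT_PX_PER_MM",
]

# Board is 20 x 25 cm, imaged landscape: 250 mm across the image width.
BOARD_MM = (250.0, 200.0)
DEFAULT_BOARD_PX = (3280, 2464)
DEFAULT_PX_PER_MM = DEFAULT_BOARD_PX[0] / BOARD_MM[0]  # ~13.12

_BOARD_YELLOW = np.array([231.0, 206.0, 46.0])
_DUST_COLOR = np.array([150.0, 142.0, 118.0])


@dataclass(frozen=True)
class PestSpec:
    """Catalog entry for one pest class."""

    class_id: int
    name: str
    length_mm: tuple[float, float]  # body length interval
    aspect: tuple[float, float]  # body width / length interval
    tone: str  # "dark" or "light"
    winged: bool
    frequency: float  # relative abundance, catalog sums to 1

    def __post_init__(self) -> None:
        lo, hi = self.length_mm
        if not 0 < lo <= hi:
            raise ValueError(f"bad length interval {self.length_mm}")
        if self.tone not in ("dark", "light"):
            raise ValueError(f"tone must be dark/light, got {self.tone!r}")


# Relative frequencies follow a realistic imbalanced trap catch
# (whitefly:thrips:aphid:leafminer:fruitfly:housefly ~ 1024:857:1092:941:873:1013).
_RAW_FREQ = (1024, 857, 1092, 941, 873, 1013)
_FREQ = tuple(c / sum(_RAW_FREQ) for c in _RAW_FREQ)


def default_catalog() -> tuple[PestSpec, ...]:
    """The six default pest classes with mm body-length bands.

    Whitefly body length is not a tabulated field value; 1.0-1.5 mm with a
    light tone is assumed.  The aphid's nominal 2.2 mm is widened to
    1.8-2.6 mm for sampling variety.
    """
    return (
        PestSpec(0, "tobacco_whitefly", (1.0, 1.5), (0.45, 0.65), "light", True, _FREQ[0]),
        PestSpec(1, "thrips", (0.5, 2.0), (0.25, 0.40), "dark", False, _FREQ[1]),
        PestSpec(2, "winged_aphid", (1.8, 2.6), (0.40, 0.55), "dark", True, _FREQ[2]),
        PestSpec(3, "leaf_miner", (4.0, 6.0), (0.40, 0.55), "dark", True, _FREQ[3]),
        PestSpec(4, "fruit_fly", (1.5, 4.0), (0.40, 0.60), "dark", True, _FREQ[4]),
        PestSpec(5, "housefly", (5.0, 8.0), (0.40, 0.55), "dark", True, _FREQ[5]),
    )


def class_names(catalog: Sequence[PestSpec] | None = None) -> list[str]:
    cat = default_catalog() if catalog is None else catalog
    return [spec.name for spec in sorted(cat, key=lambda s: s.class_id)]


@dataclass
class SceneTruth:
    """A rendered board image together with its exact annotation."""

    image: np.ndarray  # H x W x 3 uint8
    truth: DetectionSet  # global frame, scores all 1.0
    px_per_mm: float
    seed: int
    day: int | None = None


def _background(rng: np.random.Generator, width: int, height: int) -> np.ndarray:
    theta = rng.uniform(0, 2 * math.pi)
    x = np.linspace(0.0, 1.0, width, dtype=np.float32) * np.float32(math.cos(theta))
    y = np.linspace(0.0, 1.0, height, dtype=np.float32) * np.float32(math.sin(theta))
    ramp = x[None, :] + y[:, None]
    grad = 18.0 * (ramp - ramp.mean())
    img = rng.standard_normal((height, width, 3), dtype=np.float32)
    img *= 4.0  # sensor noise
    img += grad[..., None]
    img += _BOARD_YELLOW.astype(np.float32)
    return img


def _paint(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, color: np.ndarray,
           rng: np.random.Generator, noise: float = 6.0) -> None:
    img[rr, cc] = color + rng.normal(0.0, noise, size=(rr.size, 3)).astype(np.float32)


def _draw_pest(
    img: np.ndarray,
    rng: np.random.Generator,
    spec: PestSpec,
    cx: float,
    cy: float,
    half_len: float,
    angle: float,
) -> tuple[int, int, int, int]:
    """Render one pest; return its pixel-footprint bbox (x0, y0, x1, y1), half-open."""
    h, w = img.shape[:2]
    aspect = rng.uniform(*spec.aspect)
    a = half_len
    b = max(half_len * aspect, 0.6)
    if spec.tone == "dark":
        body = np.array([62.0, 48.0, 34.0]) + rng.uniform(-14, 14, 3)
        wing = np.array([172.0, 172.0, 158.0]) + rng.uniform(-10, 10, 3)
    else:
        body = np.array([244.0, 243.0, 235.0]) + rng.uniform(-6, 6, 3)
        wing = np.array([232.0, 233.0, 228.0]) + rng.uniform(-6, 6, 3)

    all_r: list[np.ndarray] = []
    all_c: list[np.ndarray] = []
    if spec.winged and a >= 2.0:
        # Two wing specks overlapping the body flanks, drawn first.
        for side in (-1.0, 1.0):
            wx = cx + side * b * 0.8 * math.cos(angle + math.pi / 2)
            wy = cy + side * b * 0.8 * math.sin(angle + math.pi / 2)
            rr, cc = ellipse(
                wy, wx, max(a * 0.45, 1.0), max(a * 0.28, 0.8),
                shape=(h, w), rotation=angle + side * 0.35,
            )
            if rr.size:
                _paint(img, rr, cc, wing, rng)
                all_r.append(rr)
                all_c.append(cc)
    rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=angle)
    _paint(img, rr, cc, body, rng)
    all_r.append(rr)
    all_c.append(cc)
    rs = np.concatenate(all_r)
    cs = np.concatenate(all_c)
    return int(cs.min()), int(rs.min()), int(cs.max()) + 1, int(rs.max()) + 1


def render_scene(
    n_pests: int,
    catalog: Sequence[PestSpec] | None = None,
    board_px: tuple[int, int] = DEFAULT_BOARD_PX,
    px_per_mm: float | None = None,
    clutter_level: float = 1.0,
    separation: bool | float = True,
    seed: int = 0,
    image_id: str | None = None,
    day: int | None = None,
) -> SceneTruth:
    """Render one board with ``n_pests`` pests and exact ground truth.

    ``separation=True`` enforces a minimum centre distance so pest footprints
    never touch (the summed per-pest clearance radii, bodies plus wings);
    pass ``False`` to allow adjacent/overlapping pairs, or a float to scale
    the clearance directly.
    ``clutter_level`` scales the density of dust specks (~30 per megapixel at
    level 1), all smaller than the thrips size band.
    """
    if n_pests < 0:
        raise ValueError("n_pests must be nonnegative")
    cat = tuple(default_catalog() if catalog is None else catalog)
    width, height = board_px
    ppm = board_px[0] / BOARD_MM[0] if px_per_mm is None else float(px_per_mm)
    rng = np.random.default_rng(seed)
    img = _background(rng, width, height)

    if separation is True:
        sep_factor: float = 1.0
    elif separation is False:
        sep_factor = 0.0
    else:
        sep_factor = float(separation)

    freqs = np.array([s.frequency for s in cat], dtype=float)
    freqs = freqs / freqs.sum()
    max_half = max(s.length_mm[1] for s in cat) * ppm / 2.0
    if n_pests > 0 and (width < 4 * max_half or height < 4 * max_half):
        raise ValueError(f"board {board_px} too small for pests at {ppm} px/mm")

    # Sample the catch first, then place the largest insects first — greatly
    # improves the success rate of rejection sampling at outbreak densities.
    draws = []
    for _ in range(n_pests):
        spec = cat[int(rng.choice(len(cat), p=freqs))]
        draws.append((spec, rng.uniform(*spec.length_mm) * ppm))
    draws.sort(key=lambda d: -d[1])

    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance radius)
    boxes: list[Box] = []
    for spec, length in draws:
        a = length / 2.0
        margin = a * 1.3 + 3.0  # body + wing specks + a little slack
        ok = False
        for _try in range(1500):
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
            if sep_factor <= 0 or all(
                math.hypot(cx - px, cy - py) >= sep_factor * (margin + pa)
                for px, py, pa in placed
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {n_pests} pests on {board_px} at separation "
                f"factor {sep_factor}"
            )
        angle = rng.uniform(0, math.pi)
        x0, y0, x1, y1 = _draw_pest(img, rng, spec, cx, cy, a, angle)
        placed.append((cx, cy, margin))
        boxes.append(Box(x0, y0, x1, y1, class_id=spec.class_id, score=1.0))

    # Dust distractors: all below the smallest (thrips) size band.
    n_dust = int(round(clutter_level * 30.0 * width * height / 1e6))
    for _ in range(n_dust):
        dx = rng.uniform(2, width - 2)
        dy = rng.uniform(2, height - 2)
        rr, cc = disk((dy, dx), rng.uniform(0.8, 2.0), shape=(height, width))
        if rr.size:
            _paint(img, rr, cc, _DUST_COLOR + rng.uniform(-15, 15, 3), rng)

    if image_id is None:
        image_id = f"scene_{seed:05d}" if day is None else f"day_{day:03d}"
    truth = DetectionSet(image_id, tuple(boxes), frame="global")
    return SceneTruth(
        image=np.clip(img, 0, 255).astype(np.uint8),
        truth=truth,
        px_per_mm=ppm,
        seed=seed,
        day=day,
    )


def default_outbreak_profile(days: int = 40) -> np.ndarray:
    """Expected daily pest counts with an early outbreak burst.

    The shape mimics observed greenhouse dynamics: a quiet start, a sharp
    burst (tens to hundreds within a day) around a fifth of the way in, a
    decay, and a sustained high, fluctuating late period.
    """
    if days < 1:
        raise ValueError("days must be positive")
    anchors_t = np.array([0.0, 0.20, 0.225, 0.47, 0.62, 0.75, 0.90, 1.0])
    anchors_n = np.array([37.0, 37.0, 325.0, 92.0, 300.0, 214.0, 419.0, 380.0])
    t = np.linspace(0.0, 1.0, days)
    return np.interp(t, anchors_t, anchors_n)


def render_series(
    days: int = 40,
    profile: Sequence[float] | np.ndarray | None = None,
    catalog: Sequence[PestSpec] | None = None,
    board_px: tuple[int, int] = DEFAULT_BOARD_PX,
    px_per_mm: float | None = None,
    clutter_level: float = 1.0,
    separation: bool | float = True,
    noise: bool = True,
    seed: int = 0,
) -> list[SceneTruth]:
    """Render a day-indexed monitoring series (days numbered from 1).

    ``profile`` gives the expected pest count per day (defaults to
    :func:`default_outbreak_profile`); with ``noise`` the realised count is
    Poisson around it, otherwise it is the rounded expectation.  Scene seeds
    are derived as ``seed + day`` so each day is independently reproducible.
    """
    prof = (
        default_outbreak_profile(days)
        if profile is None
        else np.asarray(profile, dtype=float)
    )
    if len(prof) != days:
        raise ValueError(f"profile length {len(prof)} != days {days}")
    rng = np.random.default_rng(seed)
    scenes: list[SceneTruth] = []
    for d in range(1, days + 1):
        mean = float(prof[d - 1])
        n = int(rng.poisson(mean)) if noise else int(round(mean))
        scenes.append(
            render_scene(
                n,
                catalog=catalog,
                board_px=board_px,
                px_per_mm=px_per_mm,
                clutter_level=clutter_level,
                separation=separation,
                seed=seed + d,
                day=d,
            )
        )
    return scenes


def series_manifest(scenes: Sequence[SceneTruth],
                    catalog: Sequence[PestSpec] | None = None):
    """Per-day truth counts as a tidy DataFrame (day, image_id, one column per class, total)."""
    import pandas as pd

    names = class_names(catalog)
    rows = []
    for sc in scenes:
        counts = sc.truth.counts_by_class()
        row = {"day": sc.day, "image_id": sc.truth.image_id}
        for cid, name in enumerate(names):
            row[name] = counts.get(cid, 0)
        row["total"] = len(sc.truth)
        rows.append(row)
    return pd.DataFrame(rows)
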