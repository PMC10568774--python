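"""Shape and receptive-field arithmetic for a three-scale detection network.

These little calculators quantify why whole-frame inference misses tiny
insects: a 608 px network input produces 19/38/76-cell detection grids, the
finest of which resolves 8 x 8 px of the network input per cell.  Mapped back
to a 3280 x 2464 raw frame that cell covers roughly 43 x 32 raw pixels — an
insect smaller than that is invisible to the detector unless the frame is
tiled so each crop is fed at (almost) native resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NetGeometry",
    "feature_map_sides",
    "cell_field",
    "min_detectable_on_raw",
    "focus_output_shape",
    "geometry_report",
]

STRIDES = (32, 16, 8)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def feature_map_sides(input_side: int) -> tuple[int, int, int]:
    """Grid sides at strides 32/16/8 (coarse to fine)."""
    if input_side % 32 != 0:
        raise ValueError(f"input side {input_side} not divisible by 32")
    return tuple(input_side // s for s in STRIDES)  # type: ignore[return-value]


def cell_field(input_side: int, finest_grid_side: int) -> int:
    """Input pixels covered by one cell of the finest detection grid."""
    if input_side % finest_grid_side != 0:
        raise ValueError(
            f"grid side {finest_grid_side} does not divide input {input_side}"
        )
    return input_side // finest_grid_side


def min_detectable_on_raw(
    raw_width: int, raw_height: int, input_side: int, cell_px: int
) -> tuple[int, int]:
    """Smallest resolvable object footprint on the raw frame, in raw pixels.

    The network cell of ``cell_px`` input pixels back-projects through the
    resize from ``raw`` to ``input_side`` as ``cell_px * raw / input_side``
    per axis (rounded half-up).  Objects smaller than this are lost when the
    whole frame is resized into the network.
    """
    return (
        _round_half_up(cell_px * raw_width / input_side),
        _round_half_up(cell_px * raw_height / input_side),
    )


def focus_output_shape(
    input_width: int, input_height: int, input_channels: int, out_channels: int
) -> tuple[int, int, int]:
    """Output shape of a 2x2 space-to-channel slicing stem (width, height, channels)."""
    if input_width % 2 or input_height % 2:
        raise ValueError("slicing stem requires even input sides")
    return input_width // 2, input_height // 2, out_channels


@dataclass(frozen=True)
class NetGeometry:
    """Raw-frame and network-input geometry bundled for reporting."""

    raw_width: int = 3280
    raw_height: int = 2464
    input_side: int = 608
    tile_size: int = 600

    def report(self) -> dict:
        return geometry_report(
            self.raw_width, self.raw_height, self.input_side, self.tile_size
        )


def geometry_report(
    raw_width: int,
    raw_height: int,
    input_side: int = 608,
    tile_size: int | None = None,
) -> dict:
    """All derived geometry for a camera/network pairing, JSON-friendly."""
    sides = feature_map_sides(input_side)
    cell = cell_field(input_side, sides[-1])
    whole = min_detectable_on_raw(raw_width, raw_height, input_side, cell)
    out = {
        "raw_size": [raw_width, raw_height],
        "input_side": input_side,
        "feature_map_sides": list(sides),
        "cell_field_px": cell,
        "min_detectable_whole_frame": list(whole),
        "focus_output": list(focus_output_shape(input_side, input_side, 1, 32)),
    }
    if tile_size is not None:
        out["tile_size"] = tile_size
        out["min_detectable_tiled"] = list(
            min_detectable_on_raw(tile_size, tile_size, input_side, cell)
        )
    return out
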