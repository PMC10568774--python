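from __future__ import annotations

import pytest

from stickytrap import (
    OracleDetector,
    plan_grid,
    render_scene,
)


@pytest.fixture(scope="session")
def small_scene():
    """A small board (1312 x 984 px, same px/mm as the full camera) with 40 pests."""
    return render_scene(
        40, board_px=(1312, 984), px_per_mm=13.12, clutter_level=1.0, seed=7
    )


@pytest.fixture(scope="session")
def small_grid(small_scene):
    h, w = small_scene.image.shape[:2]
    return plan_grid(w, h, 600)


@pytest.fixture(scope="session")
def small_oracle(small_scene, small_grid):
    return OracleDetector(small_scene.truth, small_grid)
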