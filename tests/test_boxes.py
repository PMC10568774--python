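"""Box geometry, IoU/DIoU measures and the two greedy suppressors."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stickytrap import (
    Box,
    DetectionSet,
    diou_loss,
    diou_nms,
    diou_penalty,
    greedy_nms,
    iou,
)

from _reference import random_records, ref_nms


def _boxes_strategy():
    coord = st.floats(0, 500, allow_nan=False, allow_infinity=False, width=32)
    size = st.floats(0.5, 200, allow_nan=False, allow_infinity=False, width=32)
    return st.builds(
        lambda x, y, w, h: Box(x, y, x + w, y + h),
        coord, coord, size, size,
    )


class TestBoxValidity:
    def test_degenerate_boxes_rejected(self):
        with pytest.raises(ValueError):
            Box(0, 0, 0, 2)
        with pytest.raises(ValueError):
            Box(0, 5, 2, 5)
        with pytest.raises(ValueError):
            Box(3, 0, 1, 2)

    def test_score_and_class_bounds(self):
        with pytest.raises(ValueError):
            Box(0, 0, 1, 1, score=1.5)
        with pytest.raises(ValueError):
            Box(0, 0, 1, 1, class_id=-1)

    def test_derived_fields(self):
        b = Box(1, 2, 4, 8)
        assert (b.width, b.height, b.area) == (3, 6, 18)
        assert b.center == (2.5, 5.0)


class TestIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Box(0, 0, 2, 2), Box(0, 0, 2, 2), 1.0),
            (Box(0, 0, 2, 2), Box(5, 5, 7, 7), 0.0),
            (Box(0, 0, 2, 2), Box(1, 0, 3, 2), 1 / 3),  # inter 2, union 6
        ],
    )
    def test_values(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected)

    @given(_boxes_strategy(), _boxes_strategy())
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))

    @given(_boxes_strategy())
    @settings(max_examples=50, deadline=None)
    def test_self_iou_is_one(self, a):
        assert iou(a, a) == pytest.approx(1.0)


class TestDIoU:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Box(0, 0, 2, 2), Box(0, 0, 2, 2), 0.0),
            # rho^2 = 100, enclosing [0,0,12,2] -> c^2 = 144 + 4 = 148
            (Box(0, 0, 2, 2), Box(10, 0, 12, 2), 100 / 148),
            # concentric boxes of different size: coincident centres
            (Box(0, 0, 4, 4), Box(1, 1, 3, 3), 0.0),
        ],
    )
    def test_penalty_values(self, a, b, expected):
        assert diou_penalty(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Box(0, 0, 2, 2), Box(0, 0, 2, 2), 0.0),
            (Box(0, 0, 2, 2), Box(10, 0, 12, 2), 1 + 100 / 148),
            # 1 - 1/3 + rho^2/c^2 with rho = 1, c^2 = 13
            (Box(0, 0, 2, 2), Box(1, 0, 3, 2), 1 - 1 / 3 + 1 / 13),
        ],
    )
    def test_loss_values(self, a, b, expected):
        assert diou_loss(a, b) == pytest.approx(expected)

    @given(_boxes_strategy(), _boxes_strategy())
    @settings(max_examples=200, deadline=None)
    def test_penalty_bounds(self, a, b):
        v = diou_penalty(a, b)
        assert 0.0 <= v < 1.0
        assert 0.0 <= diou_loss(a, b) < 2.0

    @given(
        _boxes_strategy(),
        _boxes_strategy(),
        st.floats(-50, 50, width=32),
        st.floats(-50, 50, width=32),
        st.floats(0.125, 8.0, width=32),
    )
    @settings(max_examples=100, deadline=None)
    def test_penalty_translation_and_scale_invariant(self, a, b, dx, dy, s):
        base = diou_penalty(a, b)
        assert diou_penalty(a.shifted(dx, dy), b.shifted(dx, dy)) == pytest.approx(
            base, abs=1e-5
        )
        scale = lambda bx: Box(
            bx.x_min * s, bx.y_min * s, bx.x_max * s, bx.y_max * s
        )
        assert diou_penalty(scale(a), scale(b)) == pytest.approx(base, abs=1e-5)


def _to_set(records):
    return DetectionSet(
        "t",
        tuple(Box(*r[:4], class_id=r[4], score=r[5]) for r in records),
    )


def _keys(dets):
    return {(b.x_min, b.y_min, b.x_max, b.y_max, b.class_id, b.score) for b in dets}


class TestNMS:
    def test_single_box_kept(self):
        d = _to_set([(0, 0, 2, 2, 0, 0.7)])
        assert len(diou_nms(d)) == 1
        assert len(greedy_nms(d)) == 1

    def test_identical_pair_collapses(self):
        d = _to_set([(0, 0, 2, 2, 0, 0.9), (0, 0, 2, 2, 0, 0.8)])
        for eps in (0.1, 0.5, 0.9):
            kept = diou_nms(d, epsilon=eps)
            assert len(kept) == 1 and kept.boxes[0].score == 0.9

    def test_empty_input(self):
        d = DetectionSet("t", ())
        assert len(diou_nms(d)) == 0

    def test_epsilon_validated(self):
        d = _to_set([(0, 0, 2, 2, 0, 0.9)])
        for eps in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                diou_nms(d, epsilon=eps)

    def test_disjoint_boxes_all_kept(self):
        d = _to_set([(0, 0, 2, 2, 0, 0.9), (10, 10, 12, 12, 0, 0.2)])
        assert len(greedy_nms(d, epsilon=0.3)) == 2

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("use_diou", [False, True])
    def test_matches_bruteforce_reference(self, seed, use_diou):
        rng = np.random.default_rng(seed)
        records = random_records(rng, 20)
        eps = float(rng.uniform(0.2, 0.7))
        class_aware = bool(seed % 2)
        expect = ref_nms(records, eps, class_aware, use_diou)
        fn = diou_nms if use_diou else greedy_nms
        got = fn(_to_set(records), epsilon=eps, class_aware=class_aware)
        assert _keys(got) == {tuple(r) for r in expect}

    @pytest.mark.parametrize("seed", range(8))
    def test_diou_suppression_weaker_per_reference_box(self, seed):
        """Against the same kept reference box, DIoU suppression never fires
        where IoU suppression would not: every box DIoU-NMS discards overlaps
        some kept box by at least epsilon in plain IoU."""
        rng = np.random.default_rng(100 + seed)
        d = _to_set(random_records(rng, 25))
        eps = float(rng.uniform(0.2, 0.7))
        for aware in (False, True):
            kept = diou_nms(d, eps, aware)
            dropped = _keys(d) - _keys(kept)
            for rec in dropped:
                box = Box(*rec[:4], class_id=rec[4], score=rec[5])
                suppressors = [
                    k for k in kept
                    if (not aware or k.class_id == box.class_id)
                    and iou(k, box) - diou_penalty(k, box) >= eps
                ]
                assert suppressors
                assert all(iou(k, box) >= eps for k in suppressors)

    def test_diou_keepset_superset_except_rescue_cascade(self):
        """The DIoU keep-set contains the plain-IoU keep-set on almost every
        instance; the only escape is a box rescued by the centre-distance term
        that then suppresses a neighbour plain NMS had kept."""
        violations = 0
        for seed in range(300):
            rng = np.random.default_rng(100 + seed)
            d = _to_set(random_records(rng, 25))
            eps = float(rng.uniform(0.2, 0.7))
            for aware in (False, True):
                kept_iou = _keys(greedy_nms(d, eps, aware))
                kept_diou = _keys(diou_nms(d, eps, aware))
                escaped = kept_iou - kept_diou
                if not escaped:
                    continue
                violations += 1
                for rec in escaped:
                    box = Box(*rec[:4], class_id=rec[4], score=rec[5])
                    rescuers = [
                        Box(*k[:4], class_id=k[4], score=k[5])
                        for k in kept_diou - kept_iou
                    ]
                    assert any(
                        (not aware or r.class_id == box.class_id)
                        and iou(r, box) - diou_penalty(r, box) >= eps
                        for r in rescuers
                    )
        assert violations <= 6  # cascade escapes are rare (<1% of instances)

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(200 + seed)
        d = _to_set(random_records(rng, 25))
        once = diou_nms(d, 0.45)
        assert _keys(diou_nms(once, 0.45)) == _keys(once)
        once_g = greedy_nms(d, 0.45)
        assert _keys(greedy_nms(once_g, 0.45)) == _keys(once_g)

    def test_adjacent_pair_separated_only_by_diou(self):
        """Two overlapping same-class boxes with displaced centres (two insects
        stuck side by side): plain IoU suppression merges them, the
        centre-distance term keeps both."""
        a = Box(0, 0, 10, 10, class_id=0, score=0.9)
        b = Box(4, 0, 14, 10, class_id=0, score=0.8)
        d = DetectionSet("t", (a, b))
        v = iou(a, b)
        crit = v - diou_penalty(a, b)
        eps = (crit + v) / 2  # between the two criteria
        assert len(greedy_nms(d, epsilon=eps)) == 1
        assert len(diou_nms(d, epsilon=eps)) == 2
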