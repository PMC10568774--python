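"""Independent brute-force references used as oracles by the test suite.

Everything here is written in plain Python over coordinate tuples, on purpose:
it shares no code with the package so it can serve as an independent check of
the vectorised implementations.
"""

from __future__ import annotations


def ref_iou(a, b):
    """IoU of two (x0, y0, x1, y1) tuples."""
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def ref_diou_penalty(a, b):
    """Centre-distance penalty of two (x0, y0, x1, y1) tuples."""
    ax, ay = (a[0] + a[2]) / 2, (a[1] + a[3]) / 2
    bx, by = (b[0] + b[2]) / 2, (b[1] + b[3]) / 2
    rho2 = (ax - bx) ** 2 + (ay - by) ** 2
    cw = max(a[2], b[2]) - min(a[0], b[0])
    ch = max(a[3], b[3]) - min(a[1], b[1])
    return rho2 / (cw * cw + ch * ch)


def ref_nms(records, epsilon, class_aware, use_diou):
    """O(n^2) greedy suppression over (x0, y0, x1, y1, class_id, score) tuples.

    Returns the kept records in greedy order.  Ties in score break by lower
    class id then lexicographic coordinates, matching the package contract.
    """
    remaining = list(records)
    kept = []
    while remaining:
        m = min(
            remaining,
            key=lambda r: (-r[5], r[4], r[0], r[1], r[2], r[3]),
        )
        kept.append(m)
        remaining.remove(m)
        survivors = []
        for r in remaining:
            if class_aware and r[4] != m[4]:
                survivors.append(r)
                continue
            crit = ref_iou(m[:4], r[:4])
            if use_diou:
                crit -= ref_diou_penalty(m[:4], r[:4])
            if crit < epsilon:
                survivors.append(r)
        remaining = survivors
    return kept


def ref_greedy_match(preds, truths, iou_thresh, class_agnostic):
    """Greedy matcher over (x0, y0, x1, y1, class_id, score) tuples.

    Predictions in score order (index tie-break) claim the unclaimed truth of
    highest IoU >= threshold; returns (tp, fp, fn).
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][5], i))
    claimed = [False] * len(truths)
    tp = 0
    for pi in order:
        p = preds[pi]
        best_j, best_v = -1, iou_thresh - 1e-12
        for j, t in enumerate(truths):
            if claimed[j]:
                continue
            if not class_agnostic and t[4] != p[4]:
                continue
            v = ref_iou(p[:4], t[:4])
            if v >= iou_thresh and v > best_v:
                best_j, best_v = j, v
        if best_j >= 0:
            claimed[best_j] = True
            tp += 1
    return tp, len(preds) - tp, len(truths) - tp


def random_records(rng, n, span=100.0, classes=3):
    """Random valid (x0, y0, x1, y1, class_id, score) tuples."""
    out = []
    for _ in range(n):
        x0 = rng.uniform(0, span)
        y0 = rng.uniform(0, span)
        w = rng.uniform(1.0, span / 3)
        h = rng.uniform(1.0, span / 3)
        out.append(
            (
                round(x0, 3),
                round(y0, 3),
                round(x0 + w, 3),
                round(y0 + h, 3),
                int(rng.integers(0, classes)),
                round(float(rng.uniform(0.05, 1.0)), 4),
            )
        )
    return out
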