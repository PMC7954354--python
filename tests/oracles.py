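"""Independent brute-force reference implementations used only by tests.

Everything here is written the slow, obvious way (explicit loops,
exhaustive all-pairs matching) and never calls into the package's own
implementations of the same quantity.
"""

import math

import numpy as np


def conv2d_loop(x, w, b=None, padding=(0, 0), dilation=(1, 1), groups=1):
    """Direct quadruple-loop stride-1 cross-correlation, NCHW."""
    n, c, h, wd_ = x.shape
    co, cg, kh, kw = w.shape
    ph, pw = padding
    dh, dw = dilation
    xp = np.zeros((n, c, h + 2 * ph, wd_ + 2 * pw), dtype=np.float64)
    xp[:, :, ph:ph + h, pw:pw + wd_] = x
    ho = h + 2 * ph - (dh * (kh - 1) + 1) + 1
    wo = wd_ + 2 * pw - (dw * (kw - 1) + 1) + 1
    out = np.zeros((n, co, ho, wo), dtype=np.float64)
    cpg = c // groups
    opg = co // groups
    for b_i in range(n):
        for o in range(co):
            g = o // opg
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(cg):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (w[o, ci, u, v] *
                                        xp[b_i, g * cpg + ci,
                                           i + u * dh, j + v * dw])
                    out[b_i, o, i, j] = acc
            if b is not None:
                out[b_i, o] += b[o]
    return out


def region_metrics_loop(pred, truth):
    """Confusion counts by double loop, then the six formulas.

    Degenerate 0/0 ratios: 1 when the relevant sets are empty on both
    sides, else 0.
    """
    tp = fp = fn = tn = 0
    h, w = pred.shape
    for i in range(h):
        for j in range(w):
            p, t = int(pred[i, j]), int(truth[i, j])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1

    def ratio(num, den, both_empty):
        if den == 0:
            return 1.0 if both_empty else 0.0
        return num / den

    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn, fp == 0),
        "specificity": ratio(tn, tn + fp, fn == 0),
        "precision": ratio(tp, tp + fp, fn == 0),
        "dice": ratio(2 * tp, 2 * tp + fp + fn, True),
        "jaccard": ratio(tp, tp + fn + fp, True),
    }


def boundary_loop(mask, connectivity=4):
    """Foreground pixels with a background (or out-of-image) neighbour."""
    h, w = mask.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                   if (di, dj) != (0, 0)]
    pts = set()
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in offsets:
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    pts.add((i, j))
                    break
    return pts


def bf_score_allpairs(pred, truth, theta=2.0, connectivity=4):
    """Exhaustive all-pairs boundary matching."""
    bp = boundary_loop(pred, connectivity)
    bt = boundary_loop(truth, connectivity)
    if not bp and not bt:
        return 1.0
    if not bp or not bt:
        return 0.0

    def matched(points, others):
        count = 0
        for p in points:
            best = min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in others)
            if best <= theta:
                count += 1
        return count

    precision = matched(bp, bt) / len(bp)
    recall = matched(bt, bp) / len(bt)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def bce_loop(pred, target, eps=1e-7):
    """Element-wise binary cross-entropy mean, accumulated by loop."""
    total = 0.0
    flat_p = np.asarray(pred, dtype=np.float64).ravel()
    flat_t = np.asarray(target, dtype=np.float64).ravel()
    for p, t in zip(flat_p, flat_t):
        p = min(max(p, eps), 1 - eps)
        total += -(t * math.log(p) + (1 - t) * math.log(1 - p))
    return total / flat_p.size
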