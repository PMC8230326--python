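"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own overlap-table machinery:
everything is computed by explicit loops over instance ids and boolean
mask algebra, so they can serve as oracles for the vectorised versions.
"""

from __future__ import annotations

import numpy as np


def instance_ids(mask: np.ndarray) -> list[int]:
    return sorted(int(v) for v in set(mask.ravel()) - {0})


def brute_dice(S: np.ndarray, G: np.ndarray) -> float:
    s, g = S > 0, G > 0
    if s.sum() + g.sum() == 0:
        return 1.0
    return 2.0 * float((s & g).sum()) / float(s.sum() + g.sum())


def brute_aji(G: np.ndarray, S: np.ndarray) -> float:
    """Aggregated Jaccard index by direct per-GT argmax over predictions."""
    gt_ids, pr_ids = instance_ids(G), instance_ids(S)
    if not gt_ids:
        return 1.0 if not pr_ids else 0.0
    num = den = 0
    used: set[int] = set()
    for gi in gt_ids:
        g = G == gi
        best_j, best_iou = None, -1.0
        for sj in pr_ids:  # ascending: ties keep the lowest label
            s = S == sj
            inter = int((g & s).sum())
            if inter == 0:
                continue
            iou = inter / int((g | s).sum())
            if iou > best_iou:
                best_iou, best_j = iou, sj
        if best_j is None:
            den += int(g.sum())
        else:
            s = S == best_j
            num += int((g & s).sum())
            den += int((g | s).sum())
            used.add(best_j)
    for sj in pr_ids:
        if sj not in used:
            den += int((S == sj).sum())
    return num / den if den else 0.0


def brute_pq(G: np.ndarray, S: np.ndarray) -> float:
    """Panoptic quality by exhaustive IoU > 0.5 matching."""
    gt_ids, pr_ids = instance_ids(G), instance_ids(S)
    ious = []
    matched_g: set[int] = set()
    matched_s: set[int] = set()
    for gi in gt_ids:
        g = G == gi
        for sj in pr_ids:
            s = S == sj
            inter = int((g & s).sum())
            if inter == 0:
                continue
            iou = inter / int((g | s).sum())
            if iou > 0.5:
                ious.append(iou)
                matched_g.add(gi)
                matched_s.add(sj)
    tp = len(ious)
    fn = len(gt_ids) - len(matched_g)
    fp = len(pr_ids) - len(matched_s)
    if tp == 0:
        return 1.0 if fn + fp == 0 else 0.0
    return (2.0 * tp / (2.0 * tp + fn + fp)) * (sum(ious) / tp)


def brute_edt(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel, O(n^2)."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for y, x in np.argwhere(mask):
        d2 = ((bg - (y, x)) ** 2).sum(axis=1)
        out[y, x] = np.sqrt(d2.min()) if len(d2) else np.inf
    return out


def random_label_pair(rng: np.random.Generator, shape=(32, 32), max_instances=5):
    """A (GT, prediction) pair of random rectangle instances with partial
    overlaps, exercising matched, split, merged and spurious cases."""

    def one(n):
        m = np.zeros(shape, dtype=np.int32)
        for k in range(1, n + 1):
            h = int(rng.integers(3, 10))
            w = int(rng.integers(3, 10))
            y = int(rng.integers(0, shape[0] - h))
            x = int(rng.integers(0, shape[1] - w))
            m[y : y + h, x : x + w] = k
        return m

    G = one(int(rng.integers(0, max_instances + 1)))
    if rng.random() < 0.3:
        S = one(int(rng.integers(0, max_instances + 1)))
    else:  # jittered copy of GT plus possible extra instance
        S = np.zeros(shape, dtype=np.int32)
        for k in instance_ids(G):
            shift = rng.integers(-2, 3, size=2)
            coords = np.clip(np.argwhere(G == k) + shift, 0, np.array(shape) - 1)
            S[coords[:, 0], coords[:, 1]] = k
        if rng.random() < 0.5:
            extra = one(1)
            S[extra > 0] = S.max() + 1
    return G, S
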