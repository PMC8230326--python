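"""Instance-segmentation evaluation: Dice, AJI and PQ.

Dice measures semantic overlap, 2|S∩G| / (|S| + |G|).

The aggregated Jaccard index (AJI) matches each ground-truth instance G_i
with the prediction maximising the Jaccard index against it, then scores

    AJI = Σ_i |G_i ∩ S̃(i)|  /  ( Σ_i |G_i ∪ S̃(i)| + Σ_{l∈U} |S_l| )

where U indexes predictions never used by any match.  Per the original
formulation, one prediction may be the argmax of several ground-truth
instances and is then counted in each pair; ties go to the lowest
prediction label.

Panoptic quality (PQ) matches instances at IoU > 0.5 (which makes matches
provably unique) and multiplies detection quality by segmentation quality:

    PQ = 2·TP / (2·TP + FN + FP)  ×  mean IoU over matched pairs.

Degenerate conventions: an empty ground truth against a non-empty
prediction scores 0 on all three indices; two empty masks score 1 and are
flagged, so study summaries can report such images separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult",
    "MetricsRecord",
    "dice",
    "match_instances",
    "aji",
    "pq",
    "evaluate",
]


@dataclass
class MatchResult:
    """GT↔prediction correspondence with overlap statistics.

    pairs are (gt_label, pred_label, IoU); pred_label may be 0 in
    ``aji_maxmatch`` mode when a GT instance overlaps no prediction.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_gt: list[int]
    unmatched_pred: list[int]
    mode: str
    intersections: dict = field(default_factory=dict, repr=False)
    areas_gt: dict = field(default_factory=dict, repr=False)
    areas_pred: dict = field(default_factory=dict, repr=False)


@dataclass
class MetricsRecord:
    dice: float
    aji: float
    pq: float
    n_gt: int
    n_pred: int
    degenerate_flag: bool = False


def _check_shapes(G: np.ndarray, S: np.ndarray) -> None:
    if G.shape != S.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {S.shape}")


def dice(S: np.ndarray, G: np.ndarray) -> float:
    """Dice coefficient of two binary masks (any nonzero pixel counts)."""
    S, G = np.asarray(S), np.asarray(G)
    _check_shapes(G, S)
    s, g = S > 0, G > 0
    ns, ng = int(s.sum()), int(g.sum())
    if ns + ng == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / (ns + ng)


def _overlap_table(G: np.ndarray, S: np.ndarray):
    """Sparse pairwise intersection areas and per-instance areas."""
    G = np.asarray(G).astype(np.int64)
    S = np.asarray(S).astype(np.int64)
    gt_ids, gt_areas = np.unique(G[G > 0], return_counts=True)
    pr_ids, pr_areas = np.unique(S[S > 0], return_counts=True)
    areas_gt = dict(zip(gt_ids.tolist(), gt_areas.tolist()))
    areas_pred = dict(zip(pr_ids.tolist(), pr_areas.tolist()))
    both = (G > 0) & (S > 0)
    key = G[both] * (S.max() + 1) + S[both]
    uk, counts = np.unique(key, return_counts=True)
    inter = {}
    for k, c in zip(uk.tolist(), counts.tolist()):
        gi, sj = divmod(k, int(S.max()) + 1)
        inter[(gi, sj)] = c
    return inter, areas_gt, areas_pred


def match_instances(G: np.ndarray, S: np.ndarray, mode: str = "aji_maxmatch") -> MatchResult:
    """Build the GT↔prediction correspondence.

    ``aji_maxmatch``: every GT instance is paired with the prediction of
    maximal Jaccard (ties → lowest prediction label; no overlap → pred 0);
    predictions left unused form the unmatched set.  ``pq_iou_half``:
    pairs are exactly those with IoU strictly above 0.5.
    """
    G, S = np.asarray(G), np.asarray(S)
    _check_shapes(G, S)
    if mode not in ("aji_maxmatch", "pq_iou_half"):
        raise ValueError(f"unknown matching mode {mode!r}")
    inter, areas_gt, areas_pred = _overlap_table(G, S)
    overlaps_by_gt: dict[int, list[tuple[int, int]]] = {}
    for (gi, sj), c in inter.items():
        overlaps_by_gt.setdefault(gi, []).append((sj, c))

    pairs: list[tuple[int, int, float]] = []
    used_preds: set[int] = set()
    matched_gt: set[int] = set()

    if mode == "aji_maxmatch":
        for gi in sorted(areas_gt):
            best_j, best_iou = 0, -1.0
            for sj, c in sorted(overlaps_by_gt.get(gi, [])):
                iou = c / (areas_gt[gi] + areas_pred[sj] - c)
                if iou > best_iou:  # ties keep the lowest label (sorted order)
                    best_j, best_iou = sj, iou
            if best_j > 0:
                pairs.append((gi, best_j, best_iou))
                used_preds.add(best_j)
                matched_gt.add(gi)
            else:
                pairs.append((gi, 0, 0.0))
    else:
        for (gi, sj), c in inter.items():
            iou = c / (areas_gt[gi] + areas_pred[sj] - c)
            if iou > 0.5:
                pairs.append((gi, sj, iou))
                used_preds.add(sj)
                matched_gt.add(gi)
        pairs.sort()

    return MatchResult(
        pairs=pairs,
        unmatched_gt=sorted(set(areas_gt) - matched_gt),
        unmatched_pred=sorted(set(areas_pred) - used_preds),
        mode=mode,
        intersections=inter,
        areas_gt=areas_gt,
        areas_pred=areas_pred,
    )


def aji(G: np.ndarray, S: np.ndarray) -> float:
    """Aggregated Jaccard index.

    A GT instance with no overlapping prediction contributes 0 to the
    numerator and its own area to the denominator; unused predictions add
    their areas to the denominator.
    """
    m = match_instances(G, S, mode="aji_maxmatch")
    if not m.areas_gt:
        return 1.0 if not m.areas_pred else 0.0
    num = 0
    den = 0
    for gi, sj, _ in m.pairs:
        if sj > 0:
            c = m.intersections[(gi, sj)]
            num += c
            den += m.areas_gt[gi] + m.areas_pred[sj] - c
        else:
            den += m.areas_gt[gi]
    den += sum(m.areas_pred[l] for l in m.unmatched_pred)
    return num / den if den > 0 else 0.0


def pq(G: np.ndarray, S: np.ndarray) -> float:
    """Panoptic quality with the strict IoU > 0.5 matching rule."""
    m = match_instances(G, S, mode="pq_iou_half")
    tp = len(m.pairs)
    fn, fp = len(m.unmatched_gt), len(m.unmatched_pred)
    if tp == 0:
        return 1.0 if fn + fp == 0 else 0.0
    dq = 2.0 * tp / (2.0 * tp + fn + fp)
    sq = sum(iou for _, _, iou in m.pairs) / tp
    return dq * sq


def evaluate(G: np.ndarray, S: np.ndarray) -> MetricsRecord:
    """Dice, AJI and PQ for one GT/prediction mask pair."""
    G, S = np.asarray(G), np.asarray(S)
    _check_shapes(G, S)
    n_gt = int(np.count_nonzero(np.unique(G)))
    n_pred = int(np.count_nonzero(np.unique(S)))
    return MetricsRecord(
        dice=dice(S, G),
        aji=aji(G, S),
        pq=pq(G, S),
        n_gt=n_gt,
        n_pred=n_pred,
        degenerate_flag=(n_gt == 0 or n_pred == 0),
    )
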