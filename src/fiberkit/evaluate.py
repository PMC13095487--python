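"""Detection and segmentation scoring against ground truth or another grader.

Fibers are compared as pixel sets: centerlines dilated by the 3 px
annotation stroke radius, so predictions are commensurate with hand-traced
strokes.  Detections are matched one-to-one by greedy descent over IoU,
accepting a pair only when its IoU strictly exceeds the threshold (0.5 by
default).  Mask quality uses the multiclass Dice score; grader agreement
uses mutual skeleton proximity (a fiber pair is "common" when at least a
minimum fraction of each skeleton lies within 5 px of the other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

DEFAULT_STROKE_RADIUS = 3.0


@dataclass
class MatchResult:
    matches: list[tuple[int, int, float]]  # (pred id, gt id, IoU)
    unmatched_pred: list[int]  # false positives
    unmatched_gt: list[int]  # false negatives

    @property
    def tp(self) -> int:
        return len(self.matches)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)


def dilate_skeleton(
    path: np.ndarray, shape: tuple[int, int], radius: float = DEFAULT_STROKE_RADIUS
) -> np.ndarray:
    """Flat indices of the stroke obtained by dilating a centerline path."""
    mask = np.zeros(shape, dtype=bool)
    path = np.asarray(path, dtype=int)
    mask[path[:, 0], path[:, 1]] = True
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disc = (yy**2 + xx**2) <= radius**2
    return np.flatnonzero(ndimage.binary_dilation(mask, structure=disc))


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.intersect1d(a, b, assume_unique=True).size
    if inter == 0:
        return 0.0
    union = a.size + b.size - inter
    return inter / union


def match_detections(
    pred_sets: list[np.ndarray],
    gt_sets: list[np.ndarray],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """One-to-one greedy IoU matching between predicted and reference fibers.

    Candidate pairs are sorted by decreasing IoU (ties broken by (pred id,
    gt id)); a pair is accepted when both ids are unused and IoU strictly
    exceeds the threshold.
    """
    candidates = []
    for pi, p in enumerate(pred_sets):
        for gi, g in enumerate(gt_sets):
            iou = _iou(np.asarray(p), np.asarray(g))
            if iou > iou_threshold:
                candidates.append((iou, pi, gi))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    matches = []
    for iou, pi, gi in candidates:
        if pi in used_p or gi in used_g:
            continue
        matches.append((pi, gi, iou))
        used_p.add(pi)
        used_g.add(gi)
    return MatchResult(
        matches=matches,
        unmatched_pred=[i for i in range(len(pred_sets)) if i not in used_p],
        unmatched_gt=[i for i in range(len(gt_sets)) if i not in used_g],
    )


def detection_prf(match: MatchResult) -> tuple[float, float, float]:
    """Precision, recall, and their harmonic mean from a match result."""
    tp, fp, fn = match.tp, match.fp, match.fn
    if tp + fp == 0:
        warnings.warn("no predictions; precision undefined, returning 0")
        p = 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no reference fibers; recall undefined, returning 0")
        r = 0.0
    else:
        r = tp / (tp + fn)
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def multiclass_dice(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Mean Dice over foreground classes; classes absent from both are skipped."""
    pred_mask = np.asarray(pred_mask)
    gt_mask = np.asarray(gt_mask)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("mask shapes differ")
    scores = []
    for cls in (1, 2):
        a = pred_mask == cls
        b = gt_mask == cls
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            continue
        scores.append(2.0 * int((a & b).sum()) / (na + nb))
    return float(np.mean(scores)) if scores else float("nan")


def skeleton_agreement(
    fibers_a: list[np.ndarray],
    fibers_b: list[np.ndarray],
    dist: float = 5.0,
    min_fraction: float = 0.5,
) -> list[tuple[int, int]]:
    """Pairs of fibers the two graders have in common.

    ``fibers_*`` are skeleton pixel coordinate arrays (N, 2).  A pair is
    common when at least ``min_fraction`` (inclusive) of each skeleton's
    pixels lie within ``dist`` of the other skeleton.
    """
    trees_b = [cKDTree(np.asarray(b, dtype=float)) for b in fibers_b]
    trees_a = [cKDTree(np.asarray(a, dtype=float)) for a in fibers_a]
    pairs = []
    for ia, a in enumerate(fibers_a):
        a = np.asarray(a, dtype=float)
        for ib, b in enumerate(fibers_b):
            b = np.asarray(b, dtype=float)
            da, _ = trees_b[ib].query(a, k=1)
            if (da <= dist).mean() < min_fraction:
                continue
            db, _ = trees_a[ia].query(b, k=1)
            if (db <= dist).mean() < min_fraction:
                continue
            pairs.append((ia, ib))
    return pairs


def found_by_histogram(
    all_graders: list[list[np.ndarray]],
    dist: float = 5.0,
    min_fraction: float = 0.5,
) -> dict[int, list[int]]:
    """For each grader, count each fiber's occurrence among the other graders.

    Returns, per grader index, a list giving for each of their fibers the
    number of other graders who also found it.
    """
    out: dict[int, list[int]] = {}
    for gi, fibers in enumerate(all_graders):
        counts = [0] * len(fibers)
        for gj, others in enumerate(all_graders):
            if gj == gi:
                continue
            common = skeleton_agreement(fibers, others, dist, min_fraction)
            for ia in {a for a, _ in common}:
                counts[ia] += 1
        out[gi] = counts
    return out
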