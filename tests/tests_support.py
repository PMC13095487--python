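"""Brute-force reference implementations shared across test modules.

Each oracle recomputes a library result by the most literal method
available (explicit loops, exhaustive enumeration) and stays independent
of the code paths it checks.
"""

import itertools

import numpy as np


def brute_force_single_linkage(points, threshold):
    """Merge the two closest clusters until the single-linkage distance
    exceeds the threshold; return rounded centroids, sorted."""
    clusters = [[tuple(p)] for p in points]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = min(
                np.hypot(a[0] - b[0], a[1] - b[1])
                for a in clusters[i]
                for b in clusters[j]
            )
            if best is None or d < best[0]:
                best = (d, i, j)
        if best[0] > threshold:
            break
        _, i, j = best
        clusters[i] += clusters[j]
        del clusters[j]
    return sorted(tuple(np.rint(np.mean(c, axis=0)).astype(int)) for c in clusters)


def brute_force_greedy(pred_sets, gt_sets, threshold):
    """Sorted-pair greedy IoU acceptance simulated with python sets."""
    cands = []
    for pi, p in enumerate(pred_sets):
        for gi, g in enumerate(gt_sets):
            ps, gs = set(np.asarray(p).tolist()), set(np.asarray(g).tolist())
            inter = len(ps & gs)
            iou = inter / len(ps | gs) if inter else 0.0
            if iou > threshold:
                cands.append((iou, pi, gi))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_g, matches = set(), set(), []
    for _, pi, gi in cands:
        if pi not in used_p and gi not in used_g:
            matches.append((pi, gi))
            used_p.add(pi)
            used_g.add(gi)
    return matches


def brute_force_delta(x, y):
    """Cliff's delta by full pair enumeration."""
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))
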