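"""Junction disentanglement: from a class mask to individual labeled fibers.

The pipeline mirrors how a microscopist untangles crossing fibers:

1. thin each connected component of the mask to a 1-px centerline, keeping
   the per-pixel analog label and estimating the fiber stroke width;
2. find branch points (skeleton pixels whose 8-neighborhood splits into
   three or more directions) and merge nearby ones into junctions by
   single-linkage clustering at a 10 px threshold;
3. erase a disc around each junction (radius proportional to fiber width),
   splitting the skeleton into simple branches; drop tiny fragments;
4. estimate each branch endpoint's direction by tracing 15 px inward, then
   match endpoints across each junction with a weighted cost combining
   spatial proximity, collinearity (directions ~180 degrees apart) and
   analog-color consistency; crossings (4 endpoints) take the cheapest of
   the three perfect pairings, T-junctions pair the best two and tie the
   leftover tip back to the junction center;
5. draw straight reconnection paths (labeled with the second analog when
   the joined branches disagree), group branches into fibers via the
   connected components of the pairing graph, and discard fibers that are
   single-label or shorter than 15 px;
6. final cleaning keeps bicolor fibers with 2-3 segments that stay clear of
   the image border.

All tie-breaks use lowest (row, col) lexicographic order so runs are
bit-reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize as _sk_skeletonize

from .core import LABEL_ANALOG2, path_step_length

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)
# 8-neighborhood ring in clockwise order starting north
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class SkeletonGraph:
    """1-px centerlines of a class mask with per-pixel labels and width."""

    skeleton: np.ndarray  # bool (H, W)
    labels: np.ndarray  # uint8 (H, W); analog label on skeleton pixels, else 0
    fiber_width: float  # 2 x median distance-transform value on the skeleton

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape


@dataclass
class Branch:
    """A simple 8-connected skeleton path with per-pixel analog labels."""

    path: np.ndarray  # (N, 2) int
    labels: np.ndarray  # (N,) uint8

    @property
    def length_px(self) -> float:
        return path_step_length(self.path)

    @property
    def n_px(self) -> int:
        return len(self.path)

    @property
    def dominant_label(self) -> int:
        vals, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        if len(vals) == 0:
            return 0
        # ties resolve to the lower label id
        return int(vals[np.argmax(counts)])

    def endpoint(self, end: int) -> tuple[int, int]:
        p = self.path[0] if end == 0 else self.path[-1]
        return int(p[0]), int(p[1])

    def endpoint_label(self, end: int, trace_px: int = 15) -> int:
        seg = self.labels[:trace_px] if end == 0 else self.labels[-trace_px:]
        seg = seg[seg > 0]
        if len(seg) == 0:
            return self.dominant_label
        vals, counts = np.unique(seg, return_counts=True)
        return int(vals[np.argmax(counts)])


@dataclass(frozen=True)
class EndpointRef:
    branch_id: int
    end: int  # 0 = path start, 1 = path end
    pos: tuple[int, int]
    angle: float
    label: int


@dataclass
class Junction:
    center: tuple[int, int]
    endpoints: list[EndpointRef] = field(default_factory=list)

    @property
    def topology(self) -> str:
        n = len(self.endpoints)
        return {2: "continuation", 3: "t_junction", 4: "crossing"}.get(n, f"complex_{n}")


@dataclass
class Fiber:
    """An ordered centerline path with per-pixel labels and validity flags."""

    path: np.ndarray  # (N, 2) int, ordered end to end
    labels: np.ndarray  # (N,) uint8
    branch_ids: tuple[int, ...] = ()
    border_touching: bool = False
    valid: bool = True
    # per-end length correction (px): how far the source mask reaches past
    # the skeleton tip beyond the expected rounded-cap radius
    tip_extension: tuple[float, float] = (0.0, 0.0)

    @property
    def length_px(self) -> float:
        return path_step_length(self.path)

    @property
    def n_px(self) -> int:
        return len(self.path)

    def segment_runs(self, min_segment_px: int = 4) -> list[tuple[int, int, int]]:
        """Maximal constant-label runs as (label, start, stop) index triples.

        Runs shorter than ``min_segment_px`` pixels are merged into the
        longer adjacent run (a guard against 1-2 px label flicker where the
        skeleton grazes a transition); background-labeled stretches (from
        reconnections through erased regions) join the following run.
        """
        labs = [int(l) for l in self.labels]
        runs: list[list[int]] = []  # [label, start, stop)
        for i, l in enumerate(labs):
            if runs and runs[-1][0] == l:
                runs[-1][2] = i + 1
            else:
                runs.append([l, i, i + 1])
        # fold background runs into the nearest analog run (next, else previous)
        cleaned: list[list[int]] = []
        pending_start = None
        for run in runs:
            if run[0] == 0:
                if pending_start is None:
                    pending_start = run[1]
                continue
            if pending_start is not None:
                run = [run[0], pending_start, run[2]]
                pending_start = None
            if cleaned and cleaned[-1][0] == run[0]:
                cleaned[-1][2] = run[2]
            else:
                cleaned.append(run)
        if pending_start is not None and cleaned:
            cleaned[-1][2] = len(labs)
        runs = cleaned
        # merge sub-minimal runs into their longer neighbor
        changed = True
        while changed and len(runs) > 1:
            changed = False
            sizes = [r[2] - r[1] for r in runs]
            order = sorted(range(len(runs)), key=lambda i: (sizes[i], i))
            for i in order:
                if sizes[i] >= min_segment_px:
                    continue
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i < len(runs) - 1 else None
                if left is None and right is None:
                    continue
                if right is None or (
                    left is not None and (left[2] - left[1]) >= (right[2] - right[1])
                ):
                    left[2] = runs[i][2]
                else:
                    right[1] = runs[i][1]
                del runs[i]
                changed = True
                break
            # re-merge equal-label neighbors created by a deletion
            j = 0
            while j < len(runs) - 1:
                if runs[j][0] == runs[j + 1][0]:
                    runs[j][2] = runs[j + 1][2]
                    del runs[j + 1]
                else:
                    j += 1
        return [(r[0], r[1], r[2]) for r in runs]

    def segments(self, min_segment_px: int = 4) -> list[tuple[int, float]]:
        """Ordered (label, length_px) segments along the fiber.

        Segment lengths partition the total path length: the step joining
        two runs is attributed to the later run.
        """
        runs = self.segment_runs(min_segment_px)
        steps = np.concatenate(
            [[0.0], _step_lengths(self.path)]
        ).cumsum() if len(self.path) > 1 else np.zeros(1)
        out = []
        for k, (label, start, stop) in enumerate(runs):
            s0 = steps[runs[k - 1][2] - 1] if k > 0 else steps[start]
            s1 = steps[stop - 1]
            out.append((label, float(s1 - s0)))
        return out

    @property
    def distinct_labels(self) -> set[int]:
        return set(int(l) for l in np.unique(self.labels) if l > 0)


def _step_lengths(path: np.ndarray) -> np.ndarray:
    d = np.abs(np.diff(np.asarray(path, dtype=int), axis=0))
    return np.where(d.sum(axis=1) == 2, np.sqrt(2.0), d.sum(axis=1).astype(float))


# ---------------------------------------------------------------------------
# 1. Skeletonization
# ---------------------------------------------------------------------------


def skeletonize(mask: np.ndarray) -> SkeletonGraph:
    """Thin each connected component of the mask to its centerline.

    Skeleton pixels inherit the analog label of the mask at their location.
    The fiber stroke width is estimated as twice the median Euclidean
    distance-transform value over skeleton pixels.
    """
    mask = np.asarray(mask)
    fg = mask > 0
    skel = np.zeros_like(fg)
    if fg.any():
        comp, n = ndimage.label(fg, structure=_EIGHT)
        objects = ndimage.find_objects(comp)
        for idx, sl in enumerate(objects, start=1):
            sub = comp[sl] == idx
            skel[sl] |= _sk_skeletonize(sub)
    labels = np.where(skel, mask, 0).astype(np.uint8)
    if skel.any():
        dist = ndimage.distance_transform_edt(fg)
        width = float(2.0 * np.median(dist[skel]))
    else:
        width = 0.0
    return SkeletonGraph(skeleton=skel, labels=labels, fiber_width=width)


# ---------------------------------------------------------------------------
# 2. Junction detection and clustering
# ---------------------------------------------------------------------------


def _build_branch_point_lut() -> np.ndarray:
    """Truth table over the 256 8-neighborhood configurations.

    A skeleton pixel is a branch point when its occupied neighbors form at
    least three connected groups around the 8-neighborhood ring, i.e. the
    skeleton leaves the pixel in three or more distinct directions.  The
    table plays the role of a bank of hit-and-miss intersection templates,
    evaluated for all configurations at once.
    """
    lut = np.zeros(256, dtype=bool)
    for code in range(256):
        ring = [(code >> b) & 1 for b in range(8)]
        groups = sum(
            1 for i in range(8) if ring[i] == 1 and ring[(i - 1) % 8] == 0
        )
        lut[code] = groups >= 3
    return lut


_BRANCH_LUT = _build_branch_point_lut()


def detect_junctions(sk: SkeletonGraph) -> np.ndarray:
    """Branch-point pixels of the skeleton as an (N, 2) array, sorted.

    Two template families fire: ring templates (the occupied 8-neighborhood
    splits into >= 3 directional groups) and filled 2x2 blocks, which
    thinning only leaves where strokes cross and whose pixels read as plain
    corners to the ring test.
    """
    skel = sk.skeleton.astype(np.uint8)
    padded = np.pad(skel, 1)
    code = np.zeros_like(padded, dtype=np.uint16)
    for bit, (dr, dc) in enumerate(_RING):
        code += (np.roll(np.roll(padded, -dr, axis=0), -dc, axis=1) << bit).astype(
            np.uint16
        )
    hits = _BRANCH_LUT[code[1:-1, 1:-1]] & sk.skeleton
    s = sk.skeleton
    anchor = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
    block = np.zeros_like(s)
    block[:-1, :-1] |= anchor
    block[1:, :-1] |= anchor
    block[:-1, 1:] |= anchor
    block[1:, 1:] |= anchor
    hits |= block
    pts = np.argwhere(hits)
    return pts[np.lexsort((pts[:, 1], pts[:, 0]))] if len(pts) else pts


def cluster_junctions(pixels: np.ndarray, threshold: float = 10.0) -> list[tuple[int, int]]:
    """Merge branch-point pixels into junction centers.

    Single-linkage agglomeration: pixels joined by a chain of steps each at
    most ``threshold`` apart share a junction; the center is the centroid
    rounded to the nearest pixel.  Centers are returned in lexicographic
    order.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if len(pixels) == 0:
        return []
    if len(pixels) == 1:
        r, c = np.rint(pixels[0]).astype(int)
        return [(int(r), int(c))]
    z = linkage(pixels, method="single")
    assignment = fcluster(z, t=threshold, criterion="distance")
    centers = []
    for cid in np.unique(assignment):
        centroid = pixels[assignment == cid].mean(axis=0)
        r, c = np.rint(centroid).astype(int)
        centers.append((int(r), int(c)))
    centers.sort()
    return centers


# ---------------------------------------------------------------------------
# 3. Junction erasure and branch extraction
# ---------------------------------------------------------------------------


def _neighbors(p: tuple[int, int], pixel_set: set[tuple[int, int]]):
    r, c = p
    for dr, dc in _RING:
        q = (r + dr, c + dc)
        if q in pixel_set:
            yield q


def _trace_component(pixels: np.ndarray) -> np.ndarray:
    """Order a skeleton component into a simple path.

    Components are expected to be simple arcs after junction erasure.  If
    small spurs remain, the longest endpoint-to-endpoint path is taken and
    spur pixels are dropped; pure loops are opened at the lexicographically
    smallest pixel.
    """
    pts = [tuple(int(v) for v in p) for p in pixels]
    pixel_set = set(pts)
    degree = {p: sum(1 for _ in _neighbors(p, pixel_set)) for p in pts}
    endpoints = sorted(p for p, d in degree.items() if d <= 1)

    def walk(start: tuple[int, int]) -> list[tuple[int, int]]:
        path = [start]
        seen = {start}
        cur = start
        while True:
            nxt = sorted(q for q in _neighbors(cur, pixel_set) if q not in seen)
            if not nxt:
                return path
            cur = nxt[0]
            path.append(cur)
            seen.add(cur)

    if len(endpoints) == 0:  # loop
        path = walk(min(pts))
        return np.array(path, dtype=int)
    if len(endpoints) <= 2:
        return np.array(walk(endpoints[0]), dtype=int)
    # spurred component: use graph shortest paths between the two most
    # distant endpoints (path length in steps)
    g = nx.Graph()
    for p in pts:
        for q in _neighbors(p, pixel_set):
            g.add_edge(p, q, weight=float(np.hypot(p[0] - q[0], p[1] - q[1])))
    best = None
    for a, b in itertools.combinations(endpoints, 2):
        try:
            length = nx.dijkstra_path_length(g, a, b)
        except nx.NetworkXNoPath:
            continue
        key = (-length, a, b)
        if best is None or key < best[0]:
            best = (key, a, b)
    if best is None:
        return np.array(walk(endpoints[0]), dtype=int)
    path = nx.dijkstra_path(g, best[1], best[2])
    return np.array(path, dtype=int)


def erase_and_split(
    sk: SkeletonGraph,
    junction_centers: list[tuple[int, int]],
    radius_factor: float = 1.5,
    min_branch_px: int = 5,
) -> list[Branch]:
    """Erase a disc around each junction and split the rest into branches.

    The erasure radius is ``radius_factor`` times the estimated fiber
    width (at least 2 px).  Remaining components shorter than
    ``min_branch_px`` pixels are discarded.
    """
    remaining = sk.skeleton.copy()
    if junction_centers:
        radius = max(radius_factor * sk.fiber_width, 2.0)
        rows, cols = sk.shape
        r_int = int(np.ceil(radius))
        for (jr, jc) in junction_centers:
            r0, r1 = max(0, jr - r_int), min(rows, jr + r_int + 1)
            c0, c1 = max(0, jc - r_int), min(cols, jc + r_int + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            disc = (rr - jr) ** 2 + (cc - jc) ** 2 <= radius**2
            remaining[r0:r1, c0:c1] &= ~disc
    branches: list[Branch] = []
    if not remaining.any():
        return branches
    comp, n = ndimage.label(remaining, structure=_EIGHT)
    for idx in range(1, n + 1):
        pix = np.argwhere(comp == idx)
        if len(pix) < min_branch_px:
            continue
        path = _trace_component(pix)
        if len(path) < min_branch_px:
            continue
        labels = sk.labels[path[:, 0], path[:, 1]]
        branches.append(Branch(path=path, labels=labels))
    branches.sort(key=lambda b: (tuple(b.path[0]), tuple(b.path[-1])))
    return branches


# ---------------------------------------------------------------------------
# 4. Endpoint directions and junction matching
# ---------------------------------------------------------------------------


def endpoint_direction(branch: Branch, end: int, trace_px: int = 15) -> float:
    """Outward direction angle at a branch endpoint, in (-pi, pi].

    The angle is that of the vector from the point ``trace_px`` path pixels
    inward (or the far end on shorter branches) to the endpoint, measured in
    (row, col) image coordinates: 0 points along +col, +pi/2 along +row.
    """
    path = branch.path
    if len(path) < 2:
        raise ValueError("branch must contain at least 2 pixels")
    if end == 0:
        tip = path[0].astype(float)
        inner = path[min(trace_px, len(path) - 1)].astype(float)
    else:
        tip = path[-1].astype(float)
        inner = path[max(len(path) - 1 - trace_px, 0)].astype(float)
    d = tip - inner
    return float(np.arctan2(d[0], d[1]))


@dataclass(frozen=True)
class MatchWeights:
    """Endpoint-matching cost weights.

    Collinearity carries the largest weight: endpoints of a genuine
    continuation sit a full erased-disc diameter apart (about the maximum
    matching distance), so a heavily weighted proximity term would favor
    pairing same-side arms at acute crossings.
    """

    distance: float = 0.2
    angle: float = 0.6
    color: float = 0.2


def pair_cost(
    e1: EndpointRef, e2: EndpointRef, max_dist: float, weights: MatchWeights = MatchWeights()
) -> float:
    """Weighted matching cost: proximity + collinearity + color consistency.

    The angular term vanishes when the endpoint directions are exactly
    opposed (collinear continuation) and reaches 1 when they coincide.
    """
    dist = float(np.hypot(e1.pos[0] - e2.pos[0], e1.pos[1] - e2.pos[1]))
    diff = abs(
        float(np.arctan2(np.sin(e1.angle - e2.angle), np.cos(e1.angle - e2.angle)))
    )
    angular = (np.pi - diff) / np.pi
    color = 1.0 if e1.label != e2.label else 0.0
    return (
        weights.distance * (dist / max_dist)
        + weights.angle * angular
        + weights.color * color
    )


def match_endpoints(
    junction: Junction,
    max_dist: float,
    weights: MatchWeights = MatchWeights(),
) -> tuple[list[tuple[EndpointRef, EndpointRef]], list[EndpointRef]]:
    """Pair branch endpoints across one junction.

    Returns (pairings, unmatched tips).  Two endpoints pair directly; three
    take the cheapest pair and leave one tip; four evaluate the three
    perfect matchings and keep the cheapest total; five or more are matched
    greedily by ascending pairwise cost (with a warning), any odd leftover
    becoming a tip.
    """
    eps = [
        e
        for e in junction.endpoints
        if np.hypot(e.pos[0] - junction.center[0], e.pos[1] - junction.center[1])
        <= max_dist
    ]
    eps.sort(key=lambda e: (e.pos, e.branch_id, e.end))
    n = len(eps)
    if n == 0:
        return [], []
    if n == 1:
        return [], [eps[0]]

    def cost(i: int, j: int) -> float:
        # a branch never continues into itself across a junction
        if eps[i].branch_id == eps[j].branch_id:
            return float("inf")
        return pair_cost(eps[i], eps[j], max_dist, weights)

    if n == 2:
        if np.isfinite(cost(0, 1)):
            return [(eps[0], eps[1])], []
        return [], eps
    if n == 3:
        pairs = list(itertools.combinations(range(3), 2))
        costs = [cost(i, j) for i, j in pairs]
        if not np.isfinite(min(costs)):
            return [], eps
        i, j = pairs[int(np.argmin(costs))]
        leftover = [eps[k] for k in range(3) if k not in (i, j)]
        return [(eps[i], eps[j])], leftover
    if n == 4:
        matchings = [
            ((0, 1), (2, 3)),
            ((0, 2), (1, 3)),
            ((0, 3), (1, 2)),
        ]
        totals = [sum(cost(a, b) for a, b in m) for m in matchings]
        if np.isfinite(min(totals)):
            best = matchings[int(np.argmin(totals))]
            return [(eps[a], eps[b]) for a, b in best], []
        # fall through to greedy when every perfect matching self-pairs
    else:
        logger.warning(
            "junction at %s has %d incident endpoints; matching greedily",
            junction.center,
            n,
        )
    ranked = sorted(
        (cost(i, j), i, j) for i, j in itertools.combinations(range(n), 2)
    )
    used: set[int] = set()
    out = []
    for c, i, j in ranked:
        if not np.isfinite(c) or i in used or j in used:
            continue
        out.append((eps[i], eps[j]))
        used.update((i, j))
    leftovers = [eps[k] for k in range(n) if k not in used]
    return out, leftovers


def assign_endpoints_to_junctions(
    branches: list[Branch],
    centers: list[tuple[int, int]],
    max_dist: float,
    trace_px: int = 15,
    color_px: int = 5,
) -> list[Junction]:
    """Attach each branch endpoint to its nearest junction center in range."""
    junctions = [Junction(center=c) for c in centers]
    if not junctions:
        return []
    carr = np.array(centers, dtype=float)
    for bid, branch in enumerate(branches):
        for end in (0, 1):
            pos = branch.endpoint(end)
            d = np.hypot(carr[:, 0] - pos[0], carr[:, 1] - pos[1])
            k = int(np.argmin(d))
            if d[k] <= max_dist:
                junctions[k].endpoints.append(
                    EndpointRef(
                        branch_id=bid,
                        end=end,
                        pos=pos,
                        angle=endpoint_direction(branch, end, trace_px),
                        label=branch.endpoint_label(end, color_px),
                    )
                )
    return junctions


# ---------------------------------------------------------------------------
# 5. Reconnection and grouping
# ---------------------------------------------------------------------------


def _line_path(a: tuple[int, int], b: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_line(a[0], a[1], b[0], b[1])
    return np.stack([rr, cc], axis=1)


def reconnect_and_group(
    branches: list[Branch],
    junctions: list[Junction],
    max_dist: float,
    weights: MatchWeights = MatchWeights(),
    min_fiber_px: int = 15,
) -> list[Fiber]:
    """Match endpoints at every junction, reconnect, and group into fibers.

    Reconnection paths are straight lines between matched endpoints and take
    the second-analog label when the joined ends disagree, otherwise the
    shared label.  Unmatched T-junction tips are tied to the junction center
    with their own label.  Fibers are the connected components of the branch
    pairing graph; components with a single analog label or fewer than
    ``min_fiber_px`` path pixels are discarded.
    """
    used: set[tuple[int, int]] = set()
    pairings: list[tuple[EndpointRef, EndpointRef, np.ndarray, int]] = []
    tip_extensions: dict[tuple[int, int], tuple[np.ndarray, int]] = {}
    for junction in sorted(junctions, key=lambda j: j.center):
        fresh = Junction(
            center=junction.center,
            endpoints=[
                e for e in junction.endpoints if (e.branch_id, e.end) not in used
            ],
        )
        pairs, tips = match_endpoints(fresh, max_dist, weights)
        for e1, e2 in pairs:
            label = (
                LABEL_ANALOG2 if e1.label != e2.label else (e1.label or LABEL_ANALOG2)
            )
            pairings.append((e1, e2, _line_path(e1.pos, e2.pos), label))
            used.add((e1.branch_id, e1.end))
            used.add((e2.branch_id, e2.end))
        for tip in tips:
            tip_extensions[(tip.branch_id, tip.end)] = (
                _line_path(tip.pos, junction.center),
                tip.label,
            )
            used.add((tip.branch_id, tip.end))

    graph = nx.Graph()
    graph.add_nodes_from(range(len(branches)))
    link: dict[tuple[int, int], tuple[EndpointRef, EndpointRef, np.ndarray, int]] = {}
    for e1, e2, path, label in pairings:
        graph.add_edge(e1.branch_id, e2.branch_id)
        link[(e1.branch_id, e1.end)] = (e1, e2, path, label)
        link[(e2.branch_id, e2.end)] = (e2, e1, path[::-1].copy(), label)

    fibers: list[Fiber] = []
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        fiber = _assemble_component(branches, comp, link, tip_extensions)
        if fiber is None:
            continue
        if len(fiber.distinct_labels) < 2:
            continue
        if fiber.n_px < min_fiber_px:
            continue
        fibers.append(fiber)
    fibers.sort(key=lambda f: tuple(f.path[0]))
    return fibers


def _assemble_component(
    branches: list[Branch],
    comp: list[int],
    link: dict,
    tip_extensions: dict,
) -> Fiber | None:
    """Walk a pairing-graph component into one ordered path with labels."""
    # find a free (unpaired) branch end to start from, lexicographic first
    starts = []
    for bid in comp:
        for end in (0, 1):
            if (bid, end) not in link:
                starts.append((branches[bid].endpoint(end), bid, end))
    if not starts:
        logger.warning("cyclic branch component %s skipped", comp)
        return None
    starts.sort()
    _, bid, end = starts[0]
    coords: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    def extend(path: np.ndarray, labs: np.ndarray) -> None:
        if coords and len(path) and np.array_equal(coords[-1][-1], path[0]):
            path, labs = path[1:], labs[1:]
        if len(path):
            coords.append(path)
            labels.append(labs)

    # leading tip extension (points from tip outward to junction center):
    ext = tip_extensions.get((bid, end))
    if ext is not None:
        path, label = ext
        extend(path[::-1].copy(), np.full(len(path), label, dtype=np.uint8))

    visited = set()
    cur_bid, cur_end = bid, end
    while True:
        if cur_bid in visited:
            logger.warning("branch revisit in component %s; skipped", comp)
            return None
        visited.add(cur_bid)
        branch = branches[cur_bid]
        bpath = branch.path if cur_end == 0 else branch.path[::-1]
        blabs = branch.labels if cur_end == 0 else branch.labels[::-1]
        extend(bpath.copy(), blabs.copy())
        far_end = 1 - cur_end
        nxt = link.get((cur_bid, far_end))
        if nxt is None:
            ext = tip_extensions.get((cur_bid, far_end))
            if ext is not None:
                path, label = ext
                extend(path.copy(), np.full(len(path), label, dtype=np.uint8))
            break
        _, partner, conn_path, conn_label = nxt
        extend(conn_path.copy(), np.full(len(conn_path), conn_label, dtype=np.uint8))
        cur_bid, cur_end = partner.branch_id, partner.end
    if len(visited) != len(comp):
        logger.warning("branch component %s not a simple chain; skipped", comp)
        return None
    path = np.concatenate(coords)
    labs = np.concatenate(labels)
    return Fiber(path=path, labels=labs, branch_ids=tuple(comp))


# ---------------------------------------------------------------------------
# 6. Final cleaning
# ---------------------------------------------------------------------------


def clean_fibers(
    fibers: list[Fiber],
    image_size: tuple[int, int],
    border_margin: int = 1,
    min_segment_px: int = 4,
) -> list[Fiber]:
    """Keep bicolor fibers with 2-3 segments that avoid the image border."""
    rows, cols = image_size
    kept = []
    for fiber in fibers:
        runs = fiber.segment_runs(min_segment_px)
        run_labels = {label for label, _, _ in runs}
        r = fiber.path[:, 0]
        c = fiber.path[:, 1]
        touches = bool(
            (r < border_margin).any()
            or (c < border_margin).any()
            or (r >= rows - border_margin).any()
            or (c >= cols - border_margin).any()
        )
        fiber.border_touching = touches
        if touches:
            continue
        if len(run_labels) != 2:
            continue
        if not 2 <= len(runs) <= 3:
            continue
        kept.append(fiber)
    return kept


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReconstructionParams:
    cluster_threshold: float = 10.0
    radius_factor: float = 1.5
    max_dist_factor: float = 3.0
    min_branch_px: int = 5
    trace_px: int = 15
    color_px: int = 5
    weights: MatchWeights = MatchWeights()
    min_fiber_px: int = 15
    border_margin: int = 1
    min_segment_px: int = 4


def reconstruct_fibers(
    mask: np.ndarray, params: ReconstructionParams = ReconstructionParams()
) -> list[Fiber]:
    """Run the full disentanglement chain on a class mask."""
    sk = skeletonize(mask)
    if not sk.skeleton.any():
        return []
    junction_pixels = detect_junctions(sk)
    centers = cluster_junctions(junction_pixels, params.cluster_threshold)
    # junctions whose erasure discs overlap are one intersection region:
    # consolidate them so endpoint matching sees all arms together
    erase_radius = max(params.radius_factor * sk.fiber_width, 2.0)
    if len(centers) > 1:
        centers = cluster_junctions(np.array(centers, dtype=float), 2.0 * erase_radius)
    branches = erase_and_split(
        sk, centers, params.radius_factor, params.min_branch_px
    )
    max_dist = max(params.max_dist_factor * max(sk.fiber_width, 1.0), 4.0)
    junctions = assign_endpoints_to_junctions(
        branches, centers, max_dist, params.trace_px, params.color_px
    )
    fibers = reconnect_and_group(
        branches, junctions, max_dist, params.weights, params.min_fiber_px
    )
    cleaned = clean_fibers(
        fibers, mask.shape, params.border_margin, params.min_segment_px
    )
    _measure_tip_extensions(cleaned, mask, sk.fiber_width / 2.0, params.trace_px)
    return cleaned


def _measure_tip_extensions(
    fibers: list[Fiber], mask: np.ndarray, cap_radius: float, trace_px: int
) -> None:
    """Estimate per-end skeleton recession inside the mask.

    Thinning usually ends centerlines at the stroke's cap center, but on
    oblique or curved strokes the tip can recede a few pixels inward or
    overshoot into the rounded cap.  When the tip sits exactly at the
    underlying curve's end, the mask reaches one cap radius ahead of it;
    any deviation from that (clamped to one cap radius either way) is
    recorded as a signed length correction.
    """
    fg = mask > 0
    rows, cols = fg.shape
    reach = int(np.ceil(cap_radius)) + 5
    for fiber in fibers:
        exts = []
        for end in (0, 1):
            tip = fiber.path[0 if end == 0 else -1].astype(float)
            k = min(trace_px, len(fiber.path) - 1)
            inner = fiber.path[k if end == 0 else -1 - k].astype(float)
            d = tip - inner
            norm = float(np.hypot(*d))
            if norm == 0:
                exts.append(0.0)
                continue
            d /= norm
            ahead = 0
            for t in range(1, reach + 1):
                q = np.rint(tip + t * d).astype(int)
                if not (0 <= q[0] < rows and 0 <= q[1] < cols) or not fg[q[0], q[1]]:
                    break
                ahead = t
            # negative deviations mix true overshoot with cap erosion from
            # thresholding dim stroke ends, so they are only half-trusted
            exts.append(
                float(np.clip(ahead - cap_radius, -cap_radius / 2.0, cap_radius))
            )
        fiber.tip_extension = (exts[0], exts[1])
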