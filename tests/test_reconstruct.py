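"""Skeletonization, junction handling, endpoint matching, cleaning."""

import numpy as np
import pytest

from fiberkit.core import LABEL_ANALOG1, LABEL_ANALOG2
from fiberkit.reconstruct import (
    Branch,
    EndpointRef,
    Fiber,
    Junction,
    MatchWeights,
    clean_fibers,
    cluster_junctions,
    detect_junctions,
    endpoint_direction,
    erase_and_split,
    match_endpoints,
    pair_cost,
    reconnect_and_group,
    reconstruct_fibers,
    skeletonize,
)
from fiberkit.synthetic import (
    generate_crossing_pair,
    rasterize_stroke,
    render_mask_only,
)


def horizontal_mask(length=50, radius=3, shape=(31, 70), label=1):
    poly = np.array([[15.0, 8.0], [15.0, 8.0 + length]])
    mask = rasterize_stroke(poly, radius, shape).astype(np.uint8) * label
    return mask


def make_fiber(points, labels):
    return Fiber(path=np.array(points, dtype=int), labels=np.array(labels, dtype=np.uint8))


def straight_fiber(n, labels_fn, row=20, col0=5):
    pts = [(row, col0 + i) for i in range(n)]
    labs = [labels_fn(i) for i in range(n)]
    return make_fiber(pts, labs)


class TestSkeletonize:
    def test_straight_stroke_gives_single_path_of_matching_length(self):
        sk = skeletonize(horizontal_mask(length=50))
        pts = np.argwhere(sk.skeleton)
        span = pts[:, 1].max() - pts[:, 1].min()
        assert abs(span - 50) <= 2
        assert sk.fiber_width == pytest.approx(6.0, abs=2.0)

    def test_empty_mask_gives_empty_graph(self):
        sk = skeletonize(np.zeros((20, 20), dtype=np.uint8))
        assert not sk.skeleton.any()
        assert sk.fiber_width == 0.0

    def test_filled_disc_degenerates_to_few_pixels(self):
        from skimage.morphology import disk

        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[5:16, 5:16] = disk(5).astype(np.uint8)
        sk = skeletonize(mask)
        assert 1 <= sk.skeleton.sum() <= 3

    def test_labels_inherited_from_mask(self):
        mask = horizontal_mask(label=2)
        sk = skeletonize(mask)
        assert set(np.unique(sk.labels[sk.skeleton])) == {2}


def brute_force_branch_points(skel):
    """Oracle: count connected direction-groups of occupied 8-neighbors by
    walking the ring explicitly per pixel; >= 3 groups marks a branch point.
    Filled 2x2 blocks also count (crossing signature of thinning)."""
    ring = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    rows, cols = skel.shape
    out = set()
    for r in range(rows):
        for c in range(cols):
            if not skel[r, c]:
                continue
            occ = []
            for dr, dc in ring:
                rr, cc = r + dr, c + dc
                occ.append(bool(0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]))
            groups = sum(
                1 for i in range(8) if occ[i] and not occ[(i - 1) % 8]
            )
            if groups >= 3:
                out.add((r, c))
            for dr, dc in ((0, 0), (0, -1), (-1, 0), (-1, -1)):
                r0, c0 = r + dr, c + dc
                if 0 <= r0 < rows - 1 and 0 <= c0 < cols - 1:
                    if skel[r0 : r0 + 2, c0 : c0 + 2].all():
                        out.add((r, c))
    return out


class TestDetectJunctions:
    def test_straight_line_has_no_junctions(self):
        sk = skeletonize(horizontal_mask())
        assert len(detect_junctions(sk)) == 0

    def test_plus_crossing_detected_near_center(self):
        skel = np.zeros((21, 21), dtype=bool)
        skel[10, :] = True
        skel[:, 10] = True
        sk_obj = skeletonize(skel.astype(np.uint8))
        # use the raw cross directly as a skeleton
        from fiberkit.reconstruct import SkeletonGraph

        sk = SkeletonGraph(skeleton=skel, labels=skel.astype(np.uint8), fiber_width=2.0)
        pts = detect_junctions(sk)
        assert len(pts) >= 1
        assert all(np.hypot(p[0] - 10, p[1] - 10) <= 1.0 for p in pts)

    def test_t_junction_matches_brute_force_oracle(self):
        from fiberkit.reconstruct import SkeletonGraph

        skel = np.zeros((15, 15), dtype=bool)
        skel[7, 2:13] = True
        skel[8:13, 7] = True
        sk = SkeletonGraph(skeleton=skel, labels=skel.astype(np.uint8), fiber_width=2.0)
        got = {tuple(p) for p in detect_junctions(sk)}
        assert got == brute_force_branch_points(skel)
        assert (7, 7) in got

    def test_random_skeletons_match_oracle(self, rng):
        from fiberkit.reconstruct import SkeletonGraph
        from skimage.morphology import skeletonize as thin

        for _ in range(10):
            blob = rng.random((40, 40)) < 0.35
            skel = thin(blob)
            sk = SkeletonGraph(
                skeleton=skel, labels=skel.astype(np.uint8), fiber_width=2.0
            )
            got = {tuple(p) for p in detect_junctions(sk)}
            assert got == brute_force_branch_points(skel)


from tests_support import brute_force_single_linkage


class TestClusterJunctions:
    def test_two_close_pixels_merge(self):
        centers = cluster_junctions(np.array([[10, 10], [10, 15]]), threshold=10)
        assert len(centers) == 1

    def test_two_far_pixels_stay_separate(self):
        centers = cluster_junctions(np.array([[10, 10], [10, 30]]), threshold=10)
        assert len(centers) == 2

    def test_chain_links_through_intermediates(self):
        # 5 pixels spaced 8 px apart span 32 px but chain into one cluster
        pts = np.array([[5, 5 + 8 * k] for k in range(5)])
        centers = cluster_junctions(pts, threshold=10)
        assert centers == [(5, 21)]

    def test_matches_brute_force_agglomeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 12))
            pts = rng.uniform(0, 60, (n, 2)).round(1)
            got = sorted(
                (int(r), int(c)) for r, c in cluster_junctions(pts, threshold=10)
            )
            assert got == brute_force_single_linkage(pts, 10)

    def test_empty_input(self):
        assert cluster_junctions(np.empty((0, 2))) == []


class TestEraseAndSplit:
    def test_line_without_junctions_is_one_branch(self):
        sk = skeletonize(horizontal_mask(length=50))
        branches = erase_and_split(sk, [])
        assert len(branches) == 1
        assert branches[0].n_px >= 45

    def test_x_crossing_splits_into_four_branches(self):
        gt = generate_crossing_pair(80.0, seed=2, image_size=(200, 200))
        mask, _ = render_mask_only(gt, (200, 200))
        sk = skeletonize(mask)
        centers = cluster_junctions(detect_junctions(sk))
        assert len(centers) >= 1
        branches = erase_and_split(sk, centers[:1])
        assert len(branches) == 4

    def test_short_branches_dropped(self):
        sk = skeletonize(horizontal_mask(length=50))
        # huge erasure radius leaves only fragments below the minimum
        centers = [(15, 35)]
        branches = erase_and_split(sk, centers, radius_factor=2.0, min_branch_px=25)
        assert all(b.n_px >= 25 for b in branches)


class TestEndpointDirection:
    def test_horizontal_branch_right_endpoint_angle_zero(self):
        b = Branch(
            path=np.array([(10, c) for c in range(5, 30)]),
            labels=np.ones(25, dtype=np.uint8),
        )
        assert endpoint_direction(b, end=1) == pytest.approx(0.0, abs=1e-6)
        assert abs(endpoint_direction(b, end=0)) == pytest.approx(np.pi, abs=1e-6)

    def test_vertical_branch_top_endpoint(self):
        b = Branch(
            path=np.array([(r, 10) for r in range(30, 5, -1)]),
            labels=np.ones(25, dtype=np.uint8),
        )
        # moving toward decreasing row: angle is -pi/2 in (row, col) convention
        assert endpoint_direction(b, end=1) == pytest.approx(-np.pi / 2, abs=1e-6)

    def test_quarter_circle_endpoint_matches_chord_direction(self):
        r0 = 40.0
        thetas = np.linspace(0, np.pi / 2, 200)
        pts = np.unique(
            np.rint(
                np.stack([50 - r0 * np.sin(thetas), 10 + r0 * np.cos(thetas)], axis=1)
            ).astype(int),
            axis=0,
        )
        # order points along the arc by angle
        order = np.argsort(np.arctan2(50 - pts[:, 0], pts[:, 1] - 10))
        path = pts[order]
        b = Branch(path=path, labels=np.ones(len(path), dtype=np.uint8))
        tip = path[-1].astype(float)
        inner = path[-16].astype(float)
        expected = np.arctan2(tip[0] - inner[0], tip[1] - inner[1])
        assert endpoint_direction(b, end=1, trace_px=15) == pytest.approx(expected)


def ep(branch_id, pos, angle_deg, label, end=0):
    return EndpointRef(
        branch_id=branch_id, end=end, pos=pos, angle=np.deg2rad(angle_deg), label=label
    )


class TestMatchEndpoints:
    def test_two_endpoints_always_pair(self):
        j = Junction(
            center=(50, 50),
            endpoints=[ep(0, (45, 50), 90, 1), ep(1, (55, 50), -90, 2)],
        )
        pairs, tips = match_endpoints(j, max_dist=20.0)
        assert len(pairs) == 1 and not tips

    def test_crossing_pairs_collinear_over_cross_color(self):
        # red fiber running north-south, green fiber east-west, equal arm
        # distances: the angular term must enforce collinear continuation
        j = Junction(
            center=(50, 50),
            endpoints=[
                ep(0, (40, 50), 90, 1, end=1),   # red from north, points south
                ep(1, (60, 50), -90, 1, end=0),  # red from south, points north
                ep(2, (50, 40), 0, 2, end=1),    # green from west, points east
                ep(3, (50, 60), 180, 2, end=0),  # green from east, points west
            ],
        )
        pairs, tips = match_endpoints(j, max_dist=20.0)
        got = {frozenset((a.branch_id, b.branch_id)) for a, b in pairs}
        assert got == {frozenset((0, 1)), frozenset((2, 3))}

    def test_four_endpoint_matching_equals_exhaustive_enumeration(self, rng):
        for _ in range(50):
            eps = [
                ep(
                    k,
                    tuple(int(v) for v in rng.integers(40, 61, 2)),
                    float(rng.uniform(-180, 180)),
                    int(rng.integers(1, 3)),
                )
                for k in range(4)
            ]
            j = Junction(center=(50, 50), endpoints=eps)
            pairs, _ = match_endpoints(j, max_dist=40.0)
            got_cost = sum(pair_cost(a, b, 40.0, MatchWeights()) for a, b in pairs)
            best = min(
                sum(
                    pair_cost(eps[a], eps[b], 40.0, MatchWeights())
                    for a, b in m
                )
                for m in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            )
            assert got_cost == pytest.approx(best)

    def test_pair_cost_hand_arithmetic(self):
        # dist = 10, maxdist = 20 -> 0.5; angles 0 and 180 -> angular 0;
        # different labels -> color 1. cost = 0.2*0.5 + 0.6*0 + 0.2*1 = 0.3
        a = ep(0, (50, 45), 0, 1)
        b = ep(1, (50, 55), 180, 2)
        assert pair_cost(a, b, 20.0, MatchWeights()) == pytest.approx(0.3)

    def test_three_endpoints_leave_one_tip(self):
        j = Junction(
            center=(50, 50),
            endpoints=[
                ep(0, (42, 50), 90, 1),
                ep(1, (58, 50), -90, 1),
                ep(2, (50, 42), 0, 2),
            ],
        )
        pairs, tips = match_endpoints(j, max_dist=20.0)
        assert len(pairs) == 1 and len(tips) == 1
        assert {pairs[0][0].branch_id, pairs[0][1].branch_id} == {0, 1}
        assert tips[0].branch_id == 2

    def test_out_of_range_endpoints_excluded(self):
        j = Junction(
            center=(50, 50),
            endpoints=[ep(0, (45, 50), 90, 1), ep(1, (90, 50), -90, 1)],
        )
        pairs, tips = match_endpoints(j, max_dist=10.0)
        assert not pairs and len(tips) == 1


class TestReconnectAndGroup:
    def _two_branch_setup(self, lab1, lab2):
        b0 = Branch(
            path=np.array([(50, c) for c in range(10, 45)]),
            labels=np.full(35, lab1, dtype=np.uint8),
        )
        b1 = Branch(
            path=np.array([(50, c) for c in range(55, 90)]),
            labels=np.full(35, lab2, dtype=np.uint8),
        )
        j = Junction(
            center=(50, 50),
            endpoints=[
                EndpointRef(0, 1, (50, 44), 0.0, lab1),
                EndpointRef(1, 0, (50, 55), np.pi, lab2),
            ],
        )
        return [b0, b1], [j]

    def test_cross_label_reconnection_is_second_analog(self):
        branches, junctions = self._two_branch_setup(LABEL_ANALOG1, LABEL_ANALOG2)
        fibers = reconnect_and_group(branches, junctions, max_dist=20.0)
        assert len(fibers) == 1
        fiber = fibers[0]
        conn = (fiber.path[:, 1] > 44) & (fiber.path[:, 1] < 55)
        assert (fiber.labels[conn] == LABEL_ANALOG2).all()

    def test_same_label_reconnection_keeps_label(self):
        branches, junctions = self._two_branch_setup(LABEL_ANALOG1, LABEL_ANALOG1)
        # single-label component is discarded entirely
        assert reconnect_and_group(branches, junctions, max_dist=20.0) == []

    def test_isolated_bicolor_branch_survives(self):
        b = Branch(
            path=np.array([(30, c) for c in range(10, 50)]),
            labels=np.array([1] * 20 + [2] * 20, dtype=np.uint8),
        )
        fibers = reconnect_and_group([b], [], max_dist=10.0)
        assert len(fibers) == 1

    def test_short_fiber_discarded(self):
        b = Branch(
            path=np.array([(30, c) for c in range(10, 24)]),  # 14 px
            labels=np.array([1] * 7 + [2] * 7, dtype=np.uint8),
        )
        assert reconnect_and_group([b], [], max_dist=10.0) == []

    def test_single_label_long_branch_discarded(self):
        b = Branch(
            path=np.array([(30, c) for c in range(10, 110)]),
            labels=np.full(100, 1, dtype=np.uint8),
        )
        assert reconnect_and_group([b], [], max_dist=10.0) == []


class TestCleanFibers:
    def test_four_segment_fiber_removed(self):
        f = straight_fiber(48, lambda i: 1 + (i // 12) % 2)
        assert clean_fibers([f], (64, 64)) == []

    def test_centered_bicolor_fiber_kept(self):
        f = straight_fiber(40, lambda i: 1 if i < 20 else 2)
        assert clean_fibers([f], (64, 64)) == [f]

    def test_border_touching_fiber_removed(self):
        f = make_fiber(
            [(0, c) for c in range(5, 45)],
            [1 if c < 25 else 2 for c in range(5, 45)],
        )
        assert clean_fibers([f], (64, 64)) == []
        assert f.border_touching

    def test_three_segment_bicolor_kept(self):
        f = straight_fiber(45, lambda i: 2 if i < 15 or i >= 30 else 1)
        assert clean_fibers([f], (64, 64)) == [f]


class TestFullChain:
    def test_two_planted_crossing_fibers_recovered(self):
        gt = generate_crossing_pair(70.0, seed=9, image_size=(220, 220))
        mask, _ = render_mask_only(gt, (220, 220))
        fibers = reconstruct_fibers(mask)
        assert len(fibers) == 2
        for fiber, planted in zip(
            sorted(fibers, key=lambda f: tuple(f.path[0])), gt
        ):
            assert len(fiber.distinct_labels) == 2

    def test_empty_mask_gives_no_fibers(self):
        assert reconstruct_fibers(np.zeros((50, 50), dtype=np.uint8)) == []

    def test_segment_runs_match_walked_labels(self):
        f = straight_fiber(60, lambda i: 1 if i < 25 else 2)
        runs = f.segment_runs(min_segment_px=4)
        assert [lab for lab, _, _ in runs] == [1, 2]
        assert runs[0][2] - runs[0][1] == 25
        assert runs[1][2] - runs[1][1] == 35
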