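"""Generator invariants: determinism, geometry, and exact rasterization."""

import numpy as np
import pytest

from fiberkit.core import LABEL_ANALOG1, LABEL_ANALOG2
from fiberkit.synthetic import (
    GeometryParams,
    GroundTruthFiber,
    RenderParams,
    generate_crossing_pair,
    generate_fiber_set,
    rasterize_stroke,
    render,
    render_mask_only,
)


def brute_force_stroke(polyline, radius, shape):
    """Independent disc-swept rasterizer: per-pixel min distance to every
    polyline segment, computed with explicit loops."""
    out = np.zeros(shape, dtype=bool)
    poly = np.asarray(polyline, dtype=float)
    for r in range(shape[0]):
        for c in range(shape[1]):
            p = np.array([r, c], dtype=float)
            best = np.inf
            for a, b in zip(poly[:-1], poly[1:]):
                v = b - a
                vv = v @ v
                t = 0.0 if vv == 0 else np.clip((p - a) @ v / vv, 0.0, 1.0)
                best = min(best, np.linalg.norm(p - (a + t * v)))
            out[r, c] = best <= radius
    return out


class TestGenerateFiberSet:
    def test_zero_fibers_gives_empty_list(self):
        assert generate_fiber_set(0, GeometryParams(), seed=0) == []

    def test_identical_seed_replays_bitwise(self):
        params = GeometryParams(image_size=(256, 256), length_range=(40.0, 80.0))
        a = generate_fiber_set(10, params, seed=42)
        b = generate_fiber_set(10, params, seed=42)
        assert len(a) == len(b) == 10
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.polyline, fb.polyline)
            assert fa.segments == fb.segments

    def test_different_seeds_differ(self):
        params = GeometryParams(image_size=(256, 256))
        a = generate_fiber_set(5, params, seed=1)
        b = generate_fiber_set(5, params, seed=2)
        assert not np.array_equal(a[0].polyline, b[0].polyline)

    def test_fixed_ratio_one_two_segment_gives_equal_fractions(self):
        params = GeometryParams(
            image_size=(512, 512),
            segment_count_probs=(0.0, 1.0, 0.0),
            ratio_median=1.0,
            ratio_sigma=0.0,
        )
        fibers = generate_fiber_set(100, params, seed=7)
        for f in fibers:
            fracs = [frac for _, frac in f.segments]
            assert fracs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="min > max"):
            GeometryParams(length_range=(100.0, 50.0))

    def test_min_separation_respected(self):
        params = GeometryParams(
            image_size=(512, 512),
            length_range=(40.0, 70.0),
            min_separation=15.0,
        )
        fibers = generate_fiber_set(15, params, seed=3)
        from scipy.spatial import cKDTree

        for i, fi in enumerate(fibers):
            for fj in fibers[i + 1 :]:
                d, _ = cKDTree(fj.polyline).query(fi.polyline)
                assert d.min() > 10.0  # vertex-sampled bound near the 15 px target

    def test_segment_fractions_sum_to_one(self):
        fibers = generate_fiber_set(50, GeometryParams(image_size=(400, 400)), seed=9)
        for f in fibers:
            assert sum(frac for _, frac in f.segments) == pytest.approx(1.0, abs=1e-9)
            assert 1 <= len(f.segments) <= 3


class TestGroundTruthFiber:
    def test_arc_length_equals_segment_sum(self):
        fibers = generate_fiber_set(30, GeometryParams(image_size=(400, 400)), seed=5)
        for f in fibers:
            assert f.segment_lengths_px().sum() == pytest.approx(
                f.arc_length_px, rel=1e-6
            )

    def test_bad_fractions_rejected(self):
        poly = np.array([[0.0, 0.0], [0.0, 10.0]])
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruthFiber(poly, ((LABEL_ANALOG1, 0.6), (LABEL_ANALOG2, 0.6)))

    def test_too_many_segments_rejected(self):
        poly = np.array([[0.0, 0.0], [0.0, 10.0]])
        segs = ((1, 0.25), (2, 0.25), (1, 0.25), (2, 0.25))
        with pytest.raises(ValueError, match="1-3 segments"):
            GroundTruthFiber(poly, segs)

    def test_ratio_of_equal_halves_is_one(self):
        poly = np.array([[0.0, 0.0], [0.0, 100.0]])
        f = GroundTruthFiber(poly, ((LABEL_ANALOG1, 0.5), (LABEL_ANALOG2, 0.5)))
        assert f.ratio == pytest.approx(1.0)


class TestRender:
    def test_stroke_matches_brute_force_rasterizer(self):
        poly = np.array([[12.0, 5.0], [14.0, 40.0], [20.0, 52.0]])
        shape = (32, 60)
        fast = rasterize_stroke(poly, 3.0, shape)
        slow = brute_force_stroke(poly, 3.0, shape)
        np.testing.assert_array_equal(fast, slow)

    def test_straight_fiber_mask_pixel_count_matches_oracle(self):
        poly = np.array([[15.0, 8.0], [15.0, 48.0]])
        fiber = GroundTruthFiber(poly, ((LABEL_ANALOG1, 0.5), (LABEL_ANALOG2, 0.5)))
        params = RenderParams(
            image_size=(31, 60), psf_sigma=0.0, noise_sigma=0.0,
            illumination_gradient=0.0,
        )
        _, seg, _ = render([fiber], params)
        oracle = brute_force_stroke(poly, 3.0, (31, 60))
        assert (seg > 0).sum() == oracle.sum()

    def test_empty_ground_truth_renders_background_only(self):
        params = RenderParams(image_size=(64, 64), noise_sigma=0.0, psf_sigma=0.0)
        img, seg, inst = render([], params)
        assert (seg == 0).all() and (inst == 0).all()
        assert np.allclose(
            img.channels, params.background_level * np.ones((2, 64, 64)), atol=1e-5
        ) or img.channels.std() < params.background_level  # illumination ramp only

    def test_crossing_pair_has_two_instance_ids(self):
        gt = generate_crossing_pair(90.0, seed=1)
        seg, inst = render_mask_only(gt, (256, 256))
        assert set(np.unique(inst)) == {0, 1, 2}

    def test_transition_pixels_assigned_to_second_analog(self):
        # pixels within one stroke radius of the analog2 sub-curve are analog2
        poly = np.array([[15.0, 5.0], [15.0, 55.0]])
        fiber = GroundTruthFiber(poly, ((LABEL_ANALOG1, 0.5), (LABEL_ANALOG2, 0.5)))
        seg, _ = render_mask_only([fiber], (31, 64))
        boundary_col = 30  # transition at col 30: analog2 occupies cols >= 27
        assert (seg[15, boundary_col - 2 : boundary_col + 1] == LABEL_ANALOG2).all()
        assert seg[15, boundary_col - 4] == LABEL_ANALOG1

    def test_mask_intensity_consistency_without_noise(self):
        fibers = generate_fiber_set(
            8, GeometryParams(image_size=(256, 256)), seed=11
        )
        params = RenderParams(
            image_size=(256, 256), psf_sigma=0.0, noise_sigma=0.0,
            illumination_gradient=0.0,
        )
        img, seg, _ = render(fibers, params)
        for ch, label in ((0, LABEL_ANALOG1), (1, LABEL_ANALOG2)):
            sel = seg == label
            assert (
                img.channels[ch][sel] >= params.fiber_intensity[ch] - 1e-6
            ).all()

    def test_render_determinism(self):
        fibers = generate_fiber_set(5, GeometryParams(image_size=(128, 128)), seed=2)
        params = RenderParams(image_size=(128, 128), seed=13)
        img1, seg1, inst1 = render(fibers, params)
        img2, seg2, inst2 = render(fibers, params)
        np.testing.assert_array_equal(img1.channels, img2.channels)
        np.testing.assert_array_equal(seg1, seg2)
        np.testing.assert_array_equal(inst1, inst2)

    def test_later_fiber_wins_instance_overlap(self):
        gt = generate_crossing_pair(90.0, seed=4)
        _, inst = render_mask_only(gt, (256, 256))
        crossing = np.array([128, 128])
        # the crossing belongs to the later-drawn fiber (id 2)
        assert inst[tuple(crossing)] == 2

    def test_zero_size_image_rejected(self):
        with pytest.raises(ValueError, match="zero-size"):
            RenderParams(image_size=(0, 100))
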