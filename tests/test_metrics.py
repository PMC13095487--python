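"""Fiber measurement, classification, features and error filtering."""

import numpy as np
import pytest

from fiberkit.core import LABEL_ANALOG1, LABEL_ANALOG2, FluorImage
from fiberkit.metrics import (
    RECORD_COLUMNS_V1,
    RuleScorer,
    apply_filter,
    classify,
    extract_features,
    measure,
    records_to_dataframe,
    smoothed_path_cumlength,
)
from fiberkit.reconstruct import Fiber


def make_fiber(points, labels):
    return Fiber(path=np.array(points, dtype=int), labels=np.array(labels, dtype=np.uint8))


def uniform_image(shape, v1=100.0, v2=150.0):
    data = np.stack([np.full(shape, v1), np.full(shape, v2)])
    return FluorImage(data, pixel_size=0.26)


class TestMeasure:
    def test_equal_halves_give_ratio_one(self):
        f = make_fiber(
            [(10, 5 + i) for i in range(101)],
            [1] * 50 + [2] * 51,
        )
        rec = measure(f, pixel_size=0.26)
        assert rec.ratio == pytest.approx(1.0, abs=0.05)
        for _, length in rec.segments:
            assert length == pytest.approx(50 * 0.26, abs=0.26)
        assert rec.type == "ongoing_fork"

    def test_diagonal_run_uses_euclidean_metric(self):
        n = 60
        f = make_fiber(
            [(5 + i, 5 + i) for i in range(n + 1)],
            [1] * 30 + [2] * 31,
        )
        rec = measure(f, pixel_size=0.26)
        assert rec.total_length_um == pytest.approx(n * np.sqrt(2) * 0.26, rel=0.01)

    def test_planted_fiber_total_length_within_3_percent(self, clean_slide, config):
        from fiberkit.evaluate import dilate_skeleton, match_detections
        from fiberkit.pipeline import analyze_fluorimage
        from fiberkit.synthetic import rasterize_stroke

        img, gt = clean_slide
        fibers, records, _ = analyze_fluorimage(img, config)
        shape = img.shape
        match = match_detections(
            [dilate_skeleton(f.path, shape) for f in fibers],
            [
                np.flatnonzero(rasterize_stroke(g.polyline, g.stroke_radius, shape))
                for g in gt
            ],
        )
        assert match.tp == len(gt)
        for pi, gi, _ in match.matches:
            truth = gt[gi].arc_length_px * 0.26
            assert records[pi].total_length_um == pytest.approx(truth, rel=0.03)

    def test_transition_shift_moves_length_between_analogs(self):
        f = make_fiber([(10, i) for i in range(100)], [1] * 50 + [2] * 50)
        plain = measure(f)
        shifted = measure(f, transition_shift_px=3.0)
        assert shifted.analog1_length_um > plain.analog1_length_um
        assert shifted.total_length_um == pytest.approx(plain.total_length_um)

    def test_smoothed_length_unbiased_on_oblique_lines(self):
        from skimage.draw import line

        rr, cc = line(0, 0, 80, 200)
        cum = smoothed_path_cumlength(np.stack([rr, cc], axis=1))
        assert cum[-1] == pytest.approx(np.hypot(80, 200), rel=0.005)


class TestClassify:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ((LABEL_ANALOG1, LABEL_ANALOG2), "ongoing_fork"),
            ((LABEL_ANALOG2, LABEL_ANALOG1), "ongoing_fork"),
            ((LABEL_ANALOG2, LABEL_ANALOG1, LABEL_ANALOG2), "divergent_origin"),
            ((LABEL_ANALOG1, LABEL_ANALOG2, LABEL_ANALOG1), "convergent_fork"),
            ((LABEL_ANALOG1,), "invalid"),
            ((LABEL_ANALOG1, LABEL_ANALOG1), "invalid"),
            ((LABEL_ANALOG2, LABEL_ANALOG2, LABEL_ANALOG1), "invalid"),
        ],
    )
    def test_structure_catalogue(self, pattern, expected):
        assert classify(pattern) == expected


class TestFeatures:
    def test_straight_fiber_tortuosity_one_curvature_zero(self):
        f = make_fiber([(10, 5 + i) for i in range(60)], [1] * 30 + [2] * 30)
        rec = extract_features(f, uniform_image((64, 80)), measure(f))
        assert rec.tortuosity == pytest.approx(1.0, abs=1e-6)
        assert rec.mean_curvature == pytest.approx(0.0, abs=1e-6)

    def test_half_circle_tortuosity_is_pi_over_two(self):
        r0 = 30.0
        thetas = np.linspace(0, np.pi, 400)
        pts = np.unique(
            np.rint(np.stack([40 - r0 * np.sin(thetas), 40 + r0 * np.cos(thetas)], 1)).astype(int),
            axis=0,
        )
        order = np.argsort(np.arctan2(40 - pts[:, 0], pts[:, 1] - 40))
        f = make_fiber(pts[order], [1] * len(pts))
        rec = extract_features(f, uniform_image((80, 80)), measure(f))
        assert rec.tortuosity == pytest.approx(np.pi / 2, rel=0.06)

    def test_uniform_channel_mean_intensity(self):
        f = make_fiber([(10, 5 + i) for i in range(40)], [1] * 40)
        rec = extract_features(f, uniform_image((32, 64), v1=77.0, v2=42.0), measure(f))
        assert rec.mean_intensity == pytest.approx((77.0, 42.0))

    def test_closed_loop_gets_infinite_tortuosity_and_rejection(self):
        thetas = np.linspace(0, 2 * np.pi, 300)
        pts = np.unique(
            np.rint(np.stack([30 + 15 * np.sin(thetas), 30 + 15 * np.cos(thetas)], 1)).astype(int),
            axis=0,
        )
        # order around the circle and close it
        order = np.argsort(np.arctan2(pts[:, 0] - 30, pts[:, 1] - 30))
        path = np.vstack([pts[order], pts[order][:1]])
        f = make_fiber(path, [1] * len(path))
        rec = extract_features(f, uniform_image((64, 64)), measure(f))
        assert rec.tortuosity == np.inf
        assert not rec.valid
        assert RuleScorer()(rec) == 1.0


class TestFilter:
    def _records(self):
        straight = make_fiber([(10, 5 + i) for i in range(50)], [1] * 25 + [2] * 25)
        # large sawtooth (half-wavelength 24 rows, 3 rows per column):
        # a nonlinear artifact no real stretched fiber resembles
        pts, r, c, dr = [], 10, 5, 1
        for i in range(240):
            pts.append((r, c))
            r += dr
            if i % 3 == 2:
                c += 1
            if r >= 34 or r <= 10:
                dr = -dr
        zig = make_fiber(pts, [1] * 120 + [2] * 120)
        img = uniform_image((64, 110))
        return [
            extract_features(straight, img, measure(straight, fiber_id=1)),
            extract_features(zig, img, measure(zig, fiber_id=2)),
        ]

    def test_zigzag_scores_strictly_higher_than_straight(self):
        recs = self._records()
        scorer = RuleScorer()
        assert recs[1].tortuosity > 2.0
        assert scorer(recs[1]) > scorer(recs[0])

    def test_threshold_one_rejects_nothing(self):
        recs = apply_filter(self._records(), threshold=1.0)
        assert all(r.valid for r in recs)

    def test_lower_threshold_rejects_superset(self):
        rej_05 = {
            r.fiber_id for r in apply_filter(self._records(), threshold=0.5) if not r.valid
        }
        rej_03 = {
            r.fiber_id for r in apply_filter(self._records(), threshold=0.3) if not r.valid
        }
        assert rej_05 <= rej_03


class TestExport:
    def test_dataframe_schema_is_stable(self):
        recs = apply_filter(TestFilter()._records())
        df = records_to_dataframe(recs)
        assert list(df.columns) == RECORD_COLUMNS_V1
        assert len(df) == 2

    def test_empty_records_give_empty_frame_with_schema(self):
        df = records_to_dataframe([])
        assert list(df.columns) == RECORD_COLUMNS_V1
        assert df.empty
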