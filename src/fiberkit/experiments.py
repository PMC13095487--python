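"""Reference experiment protocols on synthetic slides.

These drivers fix the study conditions for validating the pipeline without
any external data: slide composition, cut grids, degradation series and
the crossing-disentanglement benchmark.  They are used by the test suite,
the CLI and the reproduction script alike, so the conditions are defined
once.

Problem sizes: the standard validation slide carries 200 two-segment
fibers of 80-160 px at 0.26 um/px on a 1280 x 1280 raster (about 10%
stroke coverage, comparable to a well-populated field of view); the
crossing benchmark uses small two-fiber images so each trial isolates one
junction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FluorImage
from .evaluate import detection_prf, dilate_skeleton, match_detections
from .insilico import (
    CutSpec,
    DegradationSpec,
    expected_ratio,
    run_cut_experiment,
    run_degradation_experiment,
)
from .pipeline import PipelineConfig, analyze_fluorimage, make_analyzer
from .synthetic import (
    GeometryParams,
    GroundTruthFiber,
    RenderParams,
    generate_crossing_pair,
    generate_fiber_set,
    render,
    rasterize_stroke,
)


def default_config() -> PipelineConfig:
    """Pipeline configuration used throughout the synthetic experiments."""
    return PipelineConfig()


def make_ratio_one_slide(
    n_fibers: int = 200,
    image_size: tuple[int, int] = (1280, 1280),
    seed: int = 0,
    min_separation: float | None = None,
) -> tuple[FluorImage, list[GroundTruthFiber]]:
    """Slide of two-segment fibers built with ratio exactly 1."""
    geom = GeometryParams(
        image_size=image_size,
        segment_count_probs=(0.0, 1.0, 0.0),
        ratio_median=1.0,
        ratio_sigma=0.0,
        min_separation=min_separation,
    )
    gt = generate_fiber_set(n_fibers, geom, seed=seed)
    img, _, _ = render(gt, RenderParams(image_size=image_size, seed=seed))
    return img, gt


def make_clean_slide(
    n_fibers: int = 50,
    image_size: tuple[int, int] = (768, 768),
    seed: int = 0,
) -> tuple[FluorImage, list[GroundTruthFiber]]:
    """Noiseless, crossing-free slide of ratio-1 two-segment fibers.

    The exact-recovery reference condition: both analog tracks are 40-80 px
    (10-20 um), long enough that single-pixel boundary quantization stays
    well inside a few percent of the segment length.
    """
    geom = GeometryParams(
        image_size=image_size,
        segment_count_probs=(0.0, 1.0, 0.0),
        ratio_median=1.0,
        ratio_sigma=0.0,
        min_separation=12.0,
    )
    gt = generate_fiber_set(n_fibers, geom, seed=seed)
    img, _, _ = render(
        gt,
        RenderParams(
            image_size=image_size,
            psf_sigma=0.0,
            noise_sigma=0.0,
            illumination_gradient=0.0,
            seed=seed,
        ),
    )
    return img, gt


def planted_recovery_experiment(
    n_fibers: int = 50,
    image_size: tuple[int, int] = (768, 768),
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Detection and length accuracy on a clean crossing-free slide.

    Returns precision/recall at IoU 0.5 plus the worst relative error of
    matched per-segment lengths against planted truth.
    """
    config = config or default_config()
    img, gt = make_clean_slide(n_fibers, image_size, seed)
    fibers, records, _ = analyze_fluorimage(img, config)
    shape = image_size
    pred_sets = [dilate_skeleton(f.path, shape) for f in fibers]
    gt_sets = [
        np.flatnonzero(rasterize_stroke(f.polyline, f.stroke_radius, shape))
        for f in gt
    ]
    match = match_detections(pred_sets, gt_sets, 0.5)
    precision, recall, f1 = detection_prf(match)
    px = config.target_pixel_size
    seg_errors = []
    for pi, gi, _ in match.matches:
        planted = sorted(
            (lab, ln * px) for (lab, _), ln in zip(gt[gi].segments, gt[gi].segment_lengths_px())
        )
        measured = sorted(records[pi].segments)
        for (lab_a, la), (lab_b, lb) in zip(planted, measured):
            if lab_a == lab_b and la > 0:
                seg_errors.append(abs(lb - la) / la)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_planted": len(gt),
        "n_detected": len(fibers),
        "max_segment_rel_error": float(max(seg_errors)) if seg_errors else float("nan"),
        "n_segments_checked": len(seg_errors),
    }


def crossing_experiment(
    n_images: int = 50,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Two-fiber X-crossing benchmark over angles drawn from 45-90 degrees.

    Each trial renders one crossing, runs the pipeline, and counts success
    when both planted fibers are recovered with total length within 10% of
    truth.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    px = config.target_pixel_size
    both_recovered = 0
    lengths_ok = 0
    worst_len_err = 0.0
    for k in range(n_images):
        angle = float(rng.uniform(45.0, 90.0))
        gt = generate_crossing_pair(angle, seed=int(rng.integers(2**31)))
        img, _, _ = render(
            gt,
            RenderParams(
                image_size=(256, 256),
                psf_sigma=0.5,
                noise_sigma=2.0,
                illumination_gradient=0.0,
                seed=k,
            ),
        )
        fibers, records, _ = analyze_fluorimage(img, config)
        shape = (256, 256)
        pred_sets = [dilate_skeleton(f.path, shape) for f in fibers]
        gt_sets = [
            np.flatnonzero(rasterize_stroke(f.polyline, f.stroke_radius, shape))
            for f in gt
        ]
        match = match_detections(pred_sets, gt_sets, 0.5)
        if match.tp < 2:
            continue
        both_recovered += 1
        errs = []
        for pi, gi, _ in match.matches:
            truth_um = gt[gi].arc_length_px * px
            errs.append(abs(records[pi].total_length_um - truth_um) / truth_um)
        worst = max(errs)
        worst_len_err = max(worst_len_err, worst)
        if worst <= 0.10:
            lengths_ok += 1
    return {
        "n_images": n_images,
        "both_recovered_fraction": both_recovered / n_images,
        "recovered_with_lengths_fraction": lengths_ok / n_images,
        "worst_recovered_length_rel_error": worst_len_err,
    }


def cut_grid_experiment(
    n_fibers: int = 200,
    image_size: tuple[int, int] = (1280, 1280),
    fractions: list[float] = (0.0, 0.2, 0.4),
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full cut-grid protocol on a ratio-1 slide.

    Builds the slide, applies every (c_r, c_g) combination of the given
    fractions, re-analyses, and returns the tabulated medians together with
    the analytic expectation and relative errors of the common-set median.
    """
    config = config or default_config()
    img, gt = make_ratio_one_slide(n_fibers, image_size, seed=seed)
    grid = [CutSpec(c_r=cr, c_g=cg) for cr in fractions for cg in fractions]
    table = run_cut_experiment(img, gt, grid, make_analyzer(config), seed=seed)
    table["expected_ratio"] = [
        expected_ratio(1.0, row.c_r, row.c_g) for row in table.itertuples()
    ]
    table["rel_error_common"] = (
        table["median_ratio_common"] - table["expected_ratio"]
    ).abs() / table["expected_ratio"]
    return table


def blur_series_experiment(
    n_fibers: int = 200,
    image_size: tuple[int, int] = (1600, 1600),
    sigmas: list[float] = (0.0, 3.0, 6.0, 9.0, 12.0),
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Gaussian-blur robustness protocol on a crossing-free ratio-1 slide.

    The raster is larger than the cut-grid slide so that 200 fibers fit at
    a 26 px spacing (strokes blurred to sigma 12 stay distinguishable).
    """
    config = config or default_config()
    img, gt = make_ratio_one_slide(
        n_fibers, image_size, seed=seed, min_separation=26.0
    )
    specs = [DegradationSpec("gaussian_blur", s) for s in sigmas]
    return run_degradation_experiment(img, gt, specs, make_analyzer(config))


def noise_series_experiment(
    n_fibers: int = 200,
    image_size: tuple[int, int] = (1280, 1280),
    sds: list[float] = (0.0, 5.0, 10.0, 20.0, 40.0),
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Additive-noise robustness protocol (sd on the 8-bit intensity scale)."""
    config = config or default_config()
    img, gt = make_ratio_one_slide(
        n_fibers, image_size, seed=seed, min_separation=26.0
    )
    specs = [DegradationSpec("additive_noise", s, seed=seed + i) for i, s in enumerate(sds)]
    return run_degradation_experiment(img, gt, specs, make_analyzer(config))
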