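"""Controlled in-silico experiments: fiber shortening and image degradation.

Fiber shortening emulates biological track-length changes (e.g. nucleolytic
degradation of the second-analog track) by cutting a chosen fraction of an
analog's length off a planted fiber and inpainting the removed stroke with
pixels sampled from the surrounding background.  For a starting ratio
``alpha`` and cut fractions ``c_r`` (first analog) and ``c_g`` (second),
the measured second/first ratio is expected to move to

    alpha * (1 - c_g) / (1 - c_r)

so re-analysing a cut slide tests the whole pipeline against an analytic
target.  Degradation applies Gaussian blur or additive Gaussian noise to
probe how detection count and the population ratio respond to image
quality.

Cuts remove the terminal end of the targeted segment (the end away from
the color transition), preserving the bicolor structure; this is
configurable via ``CutSpec.cut_from``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LABEL_ANALOG1, FluorImage
from .synthetic import GroundTruthFiber, rasterize_stroke


def expected_ratio(alpha: float, c_r: float, c_g: float) -> float:
    """Analytic post-cut ratio: alpha * (1 - c_g) / (1 - c_r)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    for c in (c_r, c_g):
        if not 0.0 <= c < 1.0:
            raise ValueError("cut fractions must lie in [0, 1)")
    return alpha * (1.0 - c_g) / (1.0 - c_r)


@dataclass(frozen=True)
class CutSpec:
    """Cut fractions per analog: c_r for the first, c_g for the second."""

    c_r: float = 0.0
    c_g: float = 0.0
    cut_from: str = "terminal"  # terminal end of the targeted segment

    def __post_init__(self) -> None:
        for c in (self.c_r, self.c_g):
            if not 0.0 <= c < 1.0:
                raise ValueError("cut fractions must lie in [0, 1)")

    @property
    def target(self) -> str:
        if self.c_r > 0 and self.c_g > 0:
            return "both"
        if self.c_r > 0:
            return "analog1"
        if self.c_g > 0:
            return "analog2"
        return "none"


@dataclass(frozen=True)
class DegradationSpec:
    kind: str  # "gaussian_blur" | "additive_noise"
    level: float  # sigma in px, or noise sd in intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_blur", "additive_noise"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("level must be >= 0")


# ---------------------------------------------------------------------------
# Fiber shortening
# ---------------------------------------------------------------------------


def _arc_cumlen(poly: np.ndarray) -> np.ndarray:
    return np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))]
    )


def _point_at(poly: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    s = min(max(s, 0.0), cum[-1])
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(poly) - 2)
    span = cum[i + 1] - cum[i]
    t = 0.0 if span == 0 else (s - cum[i]) / span
    return poly[i] + t * (poly[i + 1] - poly[i])


def _sub_polyline(poly: np.ndarray, s0: float, s1: float) -> np.ndarray:
    cum = _arc_cumlen(poly)
    inner = poly[(cum > s0 + 1e-9) & (cum < s1 - 1e-9)]
    return np.vstack([_point_at(poly, cum, s0), inner, _point_at(poly, cum, s1)])


def cut_fiber(
    img: FluorImage,
    fiber: GroundTruthFiber,
    spec: CutSpec,
    rng: np.random.Generator,
    protect_mask: np.ndarray | None = None,
    min_remaining_px: float = 2.0,
) -> tuple[FluorImage, GroundTruthFiber]:
    """Shorten the targeted analog segments of one fiber and inpaint the image.

    Each targeted segment loses the fraction given by the spec, taken from
    the fiber end it touches (interior segments, which lack a free end, are
    left unchanged with a warning).  Removed stroke pixels are replaced per
    channel by values sampled i.i.d. from an annulus around the fiber
    stroke, excluding any other fiber given via ``protect_mask``.  Returns
    the modified image and the updated ground truth.
    """
    total = fiber.arc_length_px
    cum_fracs = np.concatenate([[0.0], np.cumsum([f for _, f in fiber.segments])])
    cut_windows: list[tuple[float, float]] = []  # arc ranges to remove
    new_bounds = [cum_fracs[k] * total for k in range(len(cum_fracs))]
    for k, (label, frac) in enumerate(fiber.segments):
        c = spec.c_r if label == LABEL_ANALOG1 else spec.c_g
        if c <= 0:
            continue
        s0, s1 = cum_fracs[k] * total, cum_fracs[k + 1] * total
        seg_len = s1 - s0
        if seg_len * (1 - c) < min_remaining_px:
            warnings.warn(
                f"cut would leave segment {k} under {min_remaining_px} px; skipped"
            )
            continue
        if k == 0:  # free end at the fiber start
            cut_windows.append((s0, s0 + c * seg_len))
            new_bounds[0] = s0 + c * seg_len
        elif k == len(fiber.segments) - 1:  # free end at the fiber end
            cut_windows.append((s1 - c * seg_len, s1))
            new_bounds[-1] = s1 - c * seg_len
        else:
            warnings.warn("interior segment has no free end; cut skipped")
    if not cut_windows:
        return img, fiber

    rows, cols = img.shape
    radius = fiber.stroke_radius
    w = int(np.ceil(radius))
    # all geometry happens inside the fiber's bounding window
    margin = 2 * w + 10
    r0 = max(0, int(np.floor(fiber.polyline[:, 0].min())) - margin)
    r1 = min(rows, int(np.ceil(fiber.polyline[:, 0].max())) + margin + 1)
    c0 = max(0, int(np.floor(fiber.polyline[:, 1].min())) - margin)
    c1 = min(cols, int(np.ceil(fiber.polyline[:, 1].max())) + margin + 1)
    crop_shape = (r1 - r0, c1 - c0)
    shift = np.array([r0, c0], dtype=float)

    cut_mask = np.zeros(crop_shape, dtype=bool)
    for s0, s1 in cut_windows:
        cut_mask |= rasterize_stroke(
            _sub_polyline(fiber.polyline, s0, s1) - shift, radius + 2.0, crop_shape
        )
    # protect exactly the kept stroke (its natural rounded cap included);
    # a wider guard would leave a stub of original paint past the cut
    keep_stroke = rasterize_stroke(
        _sub_polyline(fiber.polyline, new_bounds[0], new_bounds[-1]) - shift,
        radius,
        crop_shape,
    )
    cut_mask &= ~keep_stroke

    # sampling annulus: a ring around the full original stroke, clear of fibers
    full_stroke = rasterize_stroke(fiber.polyline - shift, radius, crop_shape)
    ring = ndimage.binary_dilation(full_stroke, iterations=w + 6) & ~ndimage.binary_dilation(
        full_stroke, iterations=w + 2
    )
    if protect_mask is not None:
        ring &= ~protect_mask[r0:r1, c0:c1]
    ring_idx = np.flatnonzero(ring)
    out = img.channels.astype(np.float32, copy=True)
    tgt_idx = np.flatnonzero(cut_mask)
    if len(ring_idx) and len(tgt_idx):
        tr, tc = np.unravel_index(tgt_idx, crop_shape)
        for ch in range(2):
            crop = np.ascontiguousarray(img.channels[ch, r0:r1, c0:c1])
            samples = crop.ravel()[rng.choice(ring_idx, size=len(tgt_idx), replace=True)]
            out[ch, r0 + tr, c0 + tc] = samples

    # updated ground truth: truncated polyline, recomputed fractions
    new_poly = _sub_polyline(fiber.polyline, new_bounds[0], new_bounds[-1])
    seg_lengths = np.diff(new_bounds)
    new_total = float(seg_lengths.sum())
    segments = tuple(
        (label, float(ln / new_total))
        for (label, _), ln in zip(fiber.segments, seg_lengths)
    )
    # renormalize against float drift
    fracs = np.array([f for _, f in segments])
    fracs = fracs / fracs.sum()
    segments = tuple((lab, float(f)) for (lab, _), f in zip(segments, fracs))
    new_fiber = GroundTruthFiber(new_poly, segments, stroke_radius=radius)
    return replace(img, channels=out), new_fiber


def cut_slide(
    img: FluorImage,
    gt: list[GroundTruthFiber],
    spec: CutSpec,
    seed: int = 0,
) -> tuple[FluorImage, list[GroundTruthFiber]]:
    """Apply the same cut spec to every fiber on a slide."""
    rng = np.random.default_rng(seed)
    if spec.c_r == 0 and spec.c_g == 0:
        return img, list(gt)
    protect = np.zeros(img.shape, dtype=bool)
    for fiber in gt:
        protect |= rasterize_stroke(fiber.polyline, fiber.stroke_radius + 1.0, img.shape)
    out = img
    new_gt = []
    for fiber in gt:
        out, nf = cut_fiber(out, fiber, spec, rng, protect_mask=protect)
        new_gt.append(nf)
    return out, new_gt


# ---------------------------------------------------------------------------
# Image degradation
# ---------------------------------------------------------------------------


def degrade(img: FluorImage, spec: DegradationSpec) -> FluorImage:
    """Blur or add noise to the intensity channels; level 0 is the identity."""
    if spec.level == 0:
        return img
    data = img.channels.astype(np.float32, copy=True)
    if spec.kind == "gaussian_blur":
        for ch in range(2):
            data[ch] = ndimage.gaussian_filter(data[ch], spec.level)
    else:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.level, size=data.shape).astype(np.float32)
    if np.issubdtype(img.channels.dtype, np.integer):
        info = np.iinfo(img.channels.dtype)
        data = np.clip(np.rint(data), info.min, info.max).astype(img.channels.dtype)
    else:
        data = np.clip(data, 0.0, None)
    return replace(img, channels=data)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------


def _detect_and_measure(img, gt, analyzer, stroke_radius=3.0):
    """Run the analyzer and match detections to planted fibers by IoU."""
    from .evaluate import dilate_skeleton, match_detections

    fibers, records = analyzer(img)
    shape = img.shape
    pred_sets = [dilate_skeleton(f.path, shape, stroke_radius) for f in fibers]
    gt_sets = [
        np.flatnonzero(rasterize_stroke(f.polyline, f.stroke_radius, shape))
        for f in gt
    ]
    match = match_detections(pred_sets, gt_sets, iou_threshold=0.5)
    ratios = {}
    for pi, gi, _ in match.matches:
        rec = records[pi]
        if rec.valid and np.isfinite(rec.ratio):
            ratios[gi] = rec.ratio
    return ratios, len(fibers)


def run_cut_experiment(
    img: FluorImage,
    gt: list[GroundTruthFiber],
    grid: list[CutSpec],
    analyzer,
    seed: int = 0,
) -> pd.DataFrame:
    """Cut, re-analyse and tabulate the slide for every grid point.

    ``analyzer`` maps a FluorImage to ``(fibers, records)``.  The returned
    table holds, per (c_r, c_g): the number of detected fibers, the median
    measured ratio over all planted fibers recovered at that level, and the
    median over the *common* set of fibers recovered at every grid level
    (which removes detection-dropout bias from the comparison).
    """
    per_level: list[dict[int, float]] = []
    counts: list[int] = []
    for spec in grid:
        cut_img, cut_gt = cut_slide(img, gt, spec, seed=seed)
        ratios, n = _detect_and_measure(cut_img, cut_gt, analyzer)
        per_level.append(ratios)
        counts.append(n)
    common = set.intersection(*(set(r) for r in per_level)) if per_level else set()
    rows = []
    for spec, ratios, n in zip(grid, per_level, counts):
        rows.append(
            {
                "c_r": spec.c_r,
                "c_g": spec.c_g,
                "n_detected": n,
                "n_matched": len(ratios),
                "median_ratio": float(np.median(list(ratios.values())))
                if ratios
                else float("nan"),
                "median_ratio_common": float(
                    np.median([ratios[i] for i in common])
                )
                if common
                else float("nan"),
                "n_common": len(common),
            }
        )
    return pd.DataFrame(rows)


def run_degradation_experiment(
    img: FluorImage,
    gt: list[GroundTruthFiber],
    specs: list[DegradationSpec],
    analyzer,
) -> pd.DataFrame:
    """Degrade, re-analyse and tabulate counts and median ratios per level."""
    per_level: list[dict[int, float]] = []
    counts: list[int] = []
    for spec in specs:
        ratios, n = _detect_and_measure(degrade(img, spec), gt, analyzer)
        per_level.append(ratios)
        counts.append(n)
    common = set.intersection(*(set(r) for r in per_level)) if per_level else set()
    rows = []
    for spec, ratios, n in zip(specs, per_level, counts):
        rows.append(
            {
                "kind": spec.kind,
                "level": spec.level,
                "n_detected": n,
                "n_matched": len(ratios),
                "median_ratio": float(np.median(list(ratios.values())))
                if ratios
                else float("nan"),
                "median_ratio_common": float(
                    np.median([ratios[i] for i in common])
                )
                if common
                else float("nan"),
                "n_common": len(common),
            }
        )
    return pd.DataFrame(rows)
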