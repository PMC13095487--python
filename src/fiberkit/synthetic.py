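"""Synthetic two-analog fiber slides with exact planted ground truth.

Emulates spread-DNA fluorescence images: sparse, bright, gently curved
strokes of ~3 px half-width on a dark noisy background.  Each fiber is a
smooth polyline carrying 1-3 consecutive single-analog segments; rendering
adds Gaussian blur, additive noise and a smooth illumination gradient.
Masks and polylines are exact, so every downstream stage can be scored
against planted truth.

Conventions
-----------
* Coordinates are 0-based ``(row, col)`` floats; pixel centers sit at
  integer coordinates; all geometry stays in pixel units until measurement
  applies the micrometer scale.
* A pixel belongs to a stroke iff its center lies within ``stroke_radius``
  of the polyline (the disc-swept area of the curve).
* At the transition between two analogs, ambiguous pixels are assigned to
  the *second* analog, matching how annotators label mixed-color pixels.
* Overlapping fibers: intensities are max-composited per channel; the class
  and instance masks are overwritten in draw order (later fiber wins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import (
    DEFAULT_PIXEL_SIZE_UM,
    LABEL_ANALOG1,
    LABEL_ANALOG2,
    FluorImage,
    polyline_arc_length,
    write_image,
    write_mask,
)

# Two-segment fibers are ongoing forks; three-segment fibers are bidirectional
# origins (green-red-green) or fork terminations (red-green-red).
PATTERN_ONGOING = (LABEL_ANALOG1, LABEL_ANALOG2)
PATTERN_DIVERGENT = (LABEL_ANALOG2, LABEL_ANALOG1, LABEL_ANALOG2)
PATTERN_CONVERGENT = (LABEL_ANALOG1, LABEL_ANALOG2, LABEL_ANALOG1)


@dataclass(frozen=True)
class GroundTruthFiber:
    """A planted fiber: smooth polyline plus ordered analog segments.

    ``segments`` lists ``(label, fraction)`` pairs in order along the
    polyline; fractions are arc-length fractions and must sum to 1.
    """

    polyline: np.ndarray
    segments: tuple[tuple[int, float], ...]
    stroke_radius: float = 3.0

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
            raise ValueError("polyline must be an (N>=2, 2) array")
        object.__setattr__(self, "polyline", poly)
        segs = tuple((int(l), float(f)) for l, f in self.segments)
        if not 1 <= len(segs) <= 3:
            raise ValueError("fibers carry 1-3 segments")
        if any(l not in (LABEL_ANALOG1, LABEL_ANALOG2) for l, _ in segs):
            raise ValueError("segment labels must be analog1/analog2")
        total = sum(f for _, f in segs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment fractions must sum to 1, got {total}")
        object.__setattr__(self, "segments", segs)

    @property
    def arc_length_px(self) -> float:
        return polyline_arc_length(self.polyline)

    def segment_lengths_px(self) -> np.ndarray:
        return self.arc_length_px * np.array([f for _, f in self.segments])

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(l for l, _ in self.segments)

    @property
    def is_bicolor(self) -> bool:
        return len(set(self.labels)) == 2

    @property
    def ratio(self) -> float:
        """Second-analog over first-analog total length (inf if no analog1)."""
        lengths = self.segment_lengths_px()
        a1 = sum(ln for (l, _), ln in zip(self.segments, lengths) if l == LABEL_ANALOG1)
        a2 = sum(ln for (l, _), ln in zip(self.segments, lengths) if l == LABEL_ANALOG2)
        return float(a2 / a1) if a1 > 0 else float("inf")


@dataclass(frozen=True)
class GeometryParams:
    """Shape of the planted fiber population.

    Fibers are random smooth polylines: the heading performs a bounded
    random walk (at most ``max_turn_deg`` per ``step_px`` advance), so the
    default fibers are nearly straight, like well-stretched spread DNA.
    Segment-count probabilities default to the mix observed in annotated
    slides (~9% single, ~78% double, ~13% triple); ratios are log-normal
    around a median of 1.2 unless ``ratio_sigma`` is zero.
    """

    image_size: tuple[int, int] = (1024, 1024)
    length_range: tuple[float, float] = (80.0, 160.0)
    max_turn_deg: float = 3.0
    step_px: float = 4.0
    segment_count_probs: tuple[float, float, float] = (0.09, 0.78, 0.13)
    ratio_median: float = 1.2
    ratio_sigma: float = 0.4
    stroke_radius: float = 3.0
    margin_px: float = 8.0
    min_separation: float | None = None
    max_tries_per_fiber: int = 200

    def __post_init__(self) -> None:
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range: min > max")
        if self.length_range[0] <= 0:
            raise ValueError("length_range must be positive")
        if self.max_turn_deg < 0 or self.step_px <= 0:
            raise ValueError("invalid curvature parameters")
        if abs(sum(self.segment_count_probs) - 1.0) > 1e-9:
            raise ValueError("segment_count_probs must sum to 1")
        if self.ratio_median <= 0 or self.ratio_sigma < 0:
            raise ValueError("invalid ratio distribution")


@dataclass(frozen=True)
class RenderParams:
    """Acquisition model for rendering: blur, noise, uneven illumination."""

    image_size: tuple[int, int] = (1024, 1024)
    background_level: float = 10.0
    illumination_gradient: float = 0.1
    psf_sigma: float = 1.0
    noise_sigma: float = 4.0
    fiber_intensity: tuple[float, float] = (180.0, 180.0)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("zero-size image")
        for v in (
            self.background_level,
            self.illumination_gradient,
            self.psf_sigma,
            self.noise_sigma,
            *self.fiber_intensity,
        ):
            if v < 0:
                raise ValueError("render parameters must be non-negative")


def _sample_segments(rng: np.random.Generator, params: GeometryParams):
    """Sample an ordered (label, fraction) tuple consistent with a ratio draw."""
    n_seg = 1 + rng.choice(3, p=params.segment_count_probs)
    if params.ratio_sigma > 0:
        ratio = float(
            np.exp(np.log(params.ratio_median) + params.ratio_sigma * rng.normal())
        )
    else:
        ratio = params.ratio_median
    if n_seg == 1:
        label = LABEL_ANALOG1 if rng.random() < 0.5 else LABEL_ANALOG2
        return ((label, 1.0),)
    g = ratio / (1.0 + ratio)  # analog2 arc-length fraction
    r = 1.0 - g
    if n_seg == 2:
        return ((LABEL_ANALOG1, r), (LABEL_ANALOG2, g))
    if rng.random() < 0.5:  # divergent origin: green-red-green
        return (
            (LABEL_ANALOG2, g / 2),
            (LABEL_ANALOG1, r),
            (LABEL_ANALOG2, g / 2),
        )
    return (  # convergent forks: red-green-red
        (LABEL_ANALOG1, r / 2),
        (LABEL_ANALOG2, g),
        (LABEL_ANALOG1, r / 2),
    )


def _sample_polyline(rng: np.random.Generator, params: GeometryParams) -> np.ndarray:
    """Heading-random-walk polyline fully inside the margin box, or None."""
    rows, cols = params.image_size
    length = rng.uniform(*params.length_range)
    n_steps = max(1, int(round(length / params.step_px)))
    start = np.array(
        [
            rng.uniform(params.margin_px, rows - 1 - params.margin_px),
            rng.uniform(params.margin_px, cols - 1 - params.margin_px),
        ]
    )
    heading = rng.uniform(-np.pi, np.pi)
    max_turn = np.deg2rad(params.max_turn_deg)
    turns = rng.uniform(-max_turn, max_turn, size=n_steps)
    pts = [start]
    for k in range(n_steps):
        heading += turns[k]
        step = params.step_px * np.array([np.sin(heading), np.cos(heading)])
        pts.append(pts[-1] + step)
    poly = np.array(pts)
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    if (
        lo[0] < params.margin_px
        or lo[1] < params.margin_px
        or hi[0] > rows - 1 - params.margin_px
        or hi[1] > cols - 1 - params.margin_px
    ):
        return None
    return poly


def _densify(polyline: np.ndarray, spacing: float = 2.0) -> np.ndarray:
    """Resample a polyline at roughly uniform spacing for proximity queries."""
    out = [polyline[0]]
    for p, q in zip(polyline[:-1], polyline[1:]):
        seg = np.linalg.norm(q - p)
        n = max(1, int(np.ceil(seg / spacing)))
        for t in np.linspace(0, 1, n + 1)[1:]:
            out.append(p + t * (q - p))
    return np.array(out)


def generate_fiber_set(
    n_fibers: int,
    params: GeometryParams = GeometryParams(),
    seed: int = 0,
) -> list[GroundTruthFiber]:
    """Sample ``n_fibers`` planted fibers; identical (params, seed) replays exactly.

    With ``params.min_separation`` set, candidate fibers closer than that
    distance to an already-accepted fiber are rejected, producing a slide
    without crossings.
    """
    if n_fibers < 0:
        raise ValueError("n_fibers must be >= 0")
    rng = np.random.default_rng(seed)
    fibers: list[GroundTruthFiber] = []
    occupied: list[np.ndarray] = []
    tree: cKDTree | None = None
    for _ in range(n_fibers):
        for _try in range(params.max_tries_per_fiber):
            poly = _sample_polyline(rng, params)
            if poly is None:
                continue
            if params.min_separation is not None and tree is not None:
                dense = _densify(poly)
                d, _ = tree.query(dense, k=1)
                if d.min() < params.min_separation:
                    continue
            segments = _sample_segments(rng, params)
            fibers.append(
                GroundTruthFiber(poly, segments, stroke_radius=params.stroke_radius)
            )
            if params.min_separation is not None:
                occupied.append(_densify(poly))
                tree = cKDTree(np.concatenate(occupied))
            break
        else:
            raise RuntimeError(
                "could not place fiber; loosen geometry or separation constraints"
            )
    return fibers


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _split_polyline(fiber: GroundTruthFiber) -> list[tuple[int, np.ndarray]]:
    """Split the polyline at segment arc-length boundaries.

    Returns ordered (label, sub-polyline) pairs; boundary points are
    interpolated so sub-polylines share endpoints exactly.
    """
    poly = fiber.polyline
    seg_vec = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]

    def point_at(s: float) -> np.ndarray:
        s = min(max(s, 0.0), total)
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(seg_len) - 1)
        t = 0.0 if seg_len[i] == 0 else (s - cum[i]) / seg_len[i]
        return poly[i] + t * seg_vec[i]

    pieces = []
    s0 = 0.0
    for label, frac in fiber.segments:
        s1 = s0 + frac * total
        inner = poly[(cum > s0 + 1e-9) & (cum < s1 - 1e-9)]
        sub = np.vstack([point_at(s0), inner, point_at(s1)])
        pieces.append((label, sub))
        s0 = s1
    return pieces


def rasterize_stroke(
    polyline: np.ndarray, radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean disc-swept stroke: pixel centers within ``radius`` of the curve.

    Exact point-to-segment distances, evaluated per polyline segment on its
    bounding box only.
    """
    rows, cols = shape
    out = np.zeros(shape, dtype=bool)
    poly = np.asarray(polyline, dtype=float)
    r_ceil = int(np.ceil(radius)) + 1
    for p, q in zip(poly[:-1], poly[1:]):
        r0 = max(0, int(np.floor(min(p[0], q[0]))) - r_ceil)
        r1 = min(rows - 1, int(np.ceil(max(p[0], q[0]))) + r_ceil)
        c0 = max(0, int(np.floor(min(p[1], q[1]))) - r_ceil)
        c1 = min(cols - 1, int(np.ceil(max(p[1], q[1]))) + r_ceil)
        if r1 < r0 or c1 < c0:
            continue
        rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        pr = np.stack([rr, cc], axis=-1).astype(float)
        v = q - p
        vv = float(v @ v)
        if vv == 0:
            d = np.linalg.norm(pr - p, axis=-1)
        else:
            t = np.clip(((pr - p) @ v) / vv, 0.0, 1.0)
            proj = p + t[..., None] * v
            d = np.linalg.norm(pr - proj, axis=-1)
        out[r0 : r1 + 1, c0 : c1 + 1] |= d <= radius
    return out


def render(
    gt: list[GroundTruthFiber], params: RenderParams = RenderParams()
) -> tuple[FluorImage, np.ndarray, np.ndarray]:
    """Render planted fibers to (image, class mask, instance map).

    The class mask and instance map are exact (never blurred or noised).
    Within a fiber, analog1 discs are stamped before analog2 discs, so
    transition pixels resolve to the second analog.  Across fibers, the
    later-drawn fiber overwrites masks; intensities are max-composited.
    Acquisition effects apply to intensities in the order blur, noise,
    illumination gradient.
    """
    shape = params.image_size
    seg_mask = np.zeros(shape, dtype=np.uint8)
    inst_map = np.zeros(shape, dtype=np.int32)
    signal = np.zeros((2, *shape), dtype=np.float32)
    clipped = False
    for fid, fiber in enumerate(gt, start=1):
        lo = fiber.polyline.min(axis=0)
        hi = fiber.polyline.max(axis=0)
        if lo.min() < 0 or hi[0] > shape[0] - 1 or hi[1] > shape[1] - 1:
            clipped = True
        fiber_labels = np.zeros(shape, dtype=np.uint8)
        pieces = _split_polyline(fiber)
        # analog1 first, analog2 second: second analog wins ambiguous pixels
        for target in (LABEL_ANALOG1, LABEL_ANALOG2):
            for label, sub in pieces:
                if label != target:
                    continue
                stroke = rasterize_stroke(sub, fiber.stroke_radius, shape)
                fiber_labels[stroke] = label
        on = fiber_labels > 0
        seg_mask[on] = fiber_labels[on]
        inst_map[on] = fid
        for ch, label in ((0, LABEL_ANALOG1), (1, LABEL_ANALOG2)):
            sel = fiber_labels == label
            np.maximum(
                signal[ch],
                np.where(sel, params.fiber_intensity[ch], 0.0),
                out=signal[ch],
            )
    if clipped:
        import warnings

        warnings.warn("some polylines extend beyond the image and were clipped")

    rng = np.random.default_rng(params.seed)
    img = signal + params.background_level
    if params.psf_sigma > 0:
        for ch in range(2):
            img[ch] = ndimage.gaussian_filter(img[ch], params.psf_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    if params.illumination_gradient > 0:
        theta = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        ramp = (rr / max(shape[0] - 1, 1) - 0.5) * np.cos(theta) + (
            cc / max(shape[1] - 1, 1) - 0.5
        ) * np.sin(theta)
        img = img * (1.0 + params.illumination_gradient * ramp)
    img = np.clip(img, 0.0, None).astype(np.float32)
    return FluorImage(img, pixel_size=params.pixel_size), seg_mask, inst_map


def render_mask_only(
    gt: list[GroundTruthFiber], image_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Exact class mask and instance map without the intensity model."""
    params = RenderParams(
        image_size=image_size,
        background_level=0.0,
        illumination_gradient=0.0,
        psf_sigma=0.0,
        noise_sigma=0.0,
    )
    _, seg, inst = render(gt, params)
    return seg, inst


def generate_crossing_pair(
    angle_deg: float,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    length_px: float = 110.0,
    stroke_radius: float = 3.0,
) -> list[GroundTruthFiber]:
    """Two straight bicolor fibers crossing at ``angle_deg`` (45-90 degrees).

    The crossing point sits at ~35% of each fiber's arc length so it stays
    clear of the color transition at midlength.
    """
    rng = np.random.default_rng(seed)
    center = np.array(image_size, dtype=float) / 2.0
    base = rng.uniform(0, np.pi)
    fibers = []
    for theta in (base, base + np.deg2rad(angle_deg)):
        d = np.array([np.sin(theta), np.cos(theta)])
        start = center - 0.35 * length_px * d
        end = center + 0.65 * length_px * d
        poly = np.linspace(start, end, 12)
        fibers.append(
            GroundTruthFiber(
                poly,
                ((LABEL_ANALOG1, 0.5), (LABEL_ANALOG2, 0.5)),
                stroke_radius=stroke_radius,
            )
        )
    return fibers


# ---------------------------------------------------------------------------
# On-disk artifacts
# ---------------------------------------------------------------------------


def ground_truth_table(
    gt: list[GroundTruthFiber], pixel_size: float = DEFAULT_PIXEL_SIZE_UM
) -> pd.DataFrame:
    """One row per planted segment: fiber id, label, lengths in px and um."""
    rows = []
    for fid, fiber in enumerate(gt, start=1):
        for (label, _), ln in zip(fiber.segments, fiber.segment_lengths_px()):
            rows.append(
                {
                    "fiber_id": fid,
                    "segment_label": LABEL_NAMES_SHORT[label],
                    "length_px": ln,
                    "length_um": ln * pixel_size,
                }
            )
    return pd.DataFrame(rows, columns=["fiber_id", "segment_label", "length_px", "length_um"])


LABEL_NAMES_SHORT = {LABEL_ANALOG1: "analog1", LABEL_ANALOG2: "analog2"}


def write_ground_truth(
    out_dir: str | Path,
    gt: list[GroundTruthFiber],
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ground_truth_table(gt, pixel_size).to_csv(out_dir / "ground_truth.csv", index=False)
    payload = [
        {
            "fiber_id": fid,
            "stroke_radius": fiber.stroke_radius,
            "polyline": fiber.polyline.tolist(),
            "segments": [
                {"label": LABEL_NAMES_SHORT[l], "fraction": f}
                for l, f in fiber.segments
            ],
        }
        for fid, fiber in enumerate(gt, start=1)
    ]
    (out_dir / "polylines.json").write_text(json.dumps(payload, indent=1))


def write_slide(
    out_dir: str | Path,
    img: FluorImage,
    seg_mask: np.ndarray,
    inst_map: np.ndarray,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(out_dir / "image.tiff", img)
    write_mask(out_dir / "class_mask.tiff", seg_mask)
    write_mask(out_dir / "instance_map.tiff", inst_map)
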