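"""End-to-end driver: configuration, single-image analysis, batch analysis.

The analysis chain is: load -> standardize pixel size -> normalize ->
segment (pluggable backend, tiled inference, optional TTA) -> argmax mask
-> junction disentanglement -> measurement + feature extraction -> error
filter -> per-fiber records.  ``PipelineConfig`` captures every knob and
round-trips through YAML; unknown keys are rejected so stale config files
fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DEFAULT_PIXEL_SIZE_UM, FluorImage, read_image
from .metrics import (
    FiberRecord,
    RuleScorer,
    apply_filter,
    extract_features,
    measure,
    records_to_dataframe,
)
from .prep import PrepParams, normalize, rescale_to_pixel_size
from .reconstruct import (
    Fiber,
    MatchWeights,
    ReconstructionParams,
    reconstruct_fibers,
)
from .segmentation import (
    ThresholdBackend,
    TileSpec,
    ensemble_inference,
    mask_from_probs,
    tiled_inference,
    tta_inference,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every analytical parameter of the pipeline, serializable to YAML."""

    # image interpretation
    pixel_size: float | None = None  # raw image scale; None = already standardized
    target_pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    swap_channels: bool = False  # set when the first analog is in channel 1
    # preprocessing
    clarity: float = 1.0
    skip_normalize: bool = False
    # segmentation
    backend: str = "threshold"  # "threshold" or "model:<path>"
    threshold: str | float = "otsu"
    smooth_sigma: float = 1.0
    tile: int = 1024
    overlap_fraction: float = 0.10
    blend_sigma: float = 0.125
    tta: bool = False
    ensemble_size: int = 1
    # reconstruction
    cluster_threshold: float = 10.0
    radius_factor: float = 1.5
    max_dist_factor: float = 3.0
    min_branch_px: int = 5
    trace_px: int = 15
    weight_distance: float = 0.2
    weight_angle: float = 0.6
    weight_color: float = 0.2
    min_fiber_px: int = 15
    border_margin: int = 1
    min_segment_px: int = 4
    # measurement: annotation stroke radius; also the transition de-bias
    # (the thinned centerline keeps the polyline extent at rounded caps, so
    # no end-cap correction is applied by default)
    stroke_radius_px: float = 3.0
    end_extension_px: float = 0.0
    # error filter
    apply_error_filter: bool = True
    error_threshold: float = 0.5
    max_tortuosity: float = 1.5
    max_curvature: float = 0.3
    min_intensity: float = 0.0
    # reproducibility
    seed: int = 0

    def prep_params(self) -> PrepParams:
        return PrepParams(target_pixel_size=self.target_pixel_size, clarity=self.clarity)

    def tile_spec(self) -> TileSpec:
        return TileSpec(
            tile=self.tile,
            overlap_fraction=self.overlap_fraction,
            blend_sigma=self.blend_sigma,
        )

    def reconstruction_params(self) -> ReconstructionParams:
        return ReconstructionParams(
            cluster_threshold=self.cluster_threshold,
            radius_factor=self.radius_factor,
            max_dist_factor=self.max_dist_factor,
            min_branch_px=self.min_branch_px,
            trace_px=self.trace_px,
            weights=MatchWeights(
                distance=self.weight_distance,
                angle=self.weight_angle,
                color=self.weight_color,
            ),
            min_fiber_px=self.min_fiber_px,
            border_margin=self.border_margin,
            min_segment_px=self.min_segment_px,
        )

    def scorer(self) -> RuleScorer:
        return RuleScorer(
            max_tortuosity=self.max_tortuosity,
            max_curvature=self.max_curvature,
            min_intensity=self.min_intensity,
        )

    def make_backend(self):
        if self.backend == "threshold":
            return ThresholdBackend(
                threshold=self.threshold, smooth_sigma=self.smooth_sigma
            )
        if self.backend.startswith("model:"):
            raise NotImplementedError(
                "learned backends plug in programmatically: pass any callable "
                "patch -> (3, h, w) probability map to the segmentation API"
            )
        raise ValueError(f"unknown backend {self.backend!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def segment_image(img: FluorImage, config: PipelineConfig) -> np.ndarray:
    """Probability map for a prepared image under the configured backend."""
    backend = config.make_backend()
    spec = config.tile_spec()
    if config.ensemble_size > 1:
        return ensemble_inference(
            [backend] * config.ensemble_size, img, spec=spec, tta=config.tta
        )
    if config.tta:
        return tta_inference(backend, img, spec=spec)
    return tiled_inference(backend, img, spec)


def analyze_fluorimage(
    img: FluorImage, config: PipelineConfig | None = None
) -> tuple[list[Fiber], list[FiberRecord], np.ndarray]:
    """Run the full chain on an in-memory image.

    Returns the cleaned fibers, their records (with features and filter
    decisions), and the class probability map.
    """
    config = config or PipelineConfig()
    if img.pixel_size is None:
        img = FluorImage(img.channels, pixel_size=config.target_pixel_size)
    work = rescale_to_pixel_size(img, config.prep_params())
    if not config.skip_normalize:
        work = normalize(work, config.prep_params())
    probs = segment_image(work, config)
    mask = mask_from_probs(probs)
    fibers = reconstruct_fibers(mask, config.reconstruction_params())
    records = []
    for fid, fiber in enumerate(fibers, start=1):
        rec = measure(
            fiber,
            pixel_size=config.target_pixel_size,
            fiber_id=fid,
            min_segment_px=config.min_segment_px,
            transition_shift_px=config.stroke_radius_px,
            end_extension_px=config.end_extension_px,
        )
        rec = extract_features(fiber, work, rec, stroke_radius=config.stroke_radius_px)
        records.append(rec)
    if config.apply_error_filter:
        apply_filter(records, config.scorer(), config.error_threshold)
    return fibers, records, probs


def make_analyzer(config: PipelineConfig | None = None):
    """Closure ``image -> (fibers, records)`` for the experiment drivers."""
    config = config or PipelineConfig()

    def analyzer(img: FluorImage):
        fibers, records, _ = analyze_fluorimage(img, config)
        return fibers, records

    return analyzer


def overlay_image(
    img: FluorImage, fibers: list[Fiber], records: list[FiberRecord]
) -> np.ndarray:
    """QC overlay: grayscale composite with fibers colored by analog class.

    Valid fibers are drawn as solid strokes (analog1 red, analog2 green);
    invalid fibers as dashed blue strokes.
    """
    base = img.channels.astype(float)
    lum = base.mean(axis=0)
    if lum.max() > 0:
        lum = lum / lum.max() * 180.0
    rgb = np.stack([lum, lum, lum], axis=-1).astype(np.uint8)
    for fiber, rec in zip(fibers, records):
        pts = fiber.path
        if rec.valid:
            colors = np.where(
                fiber.labels[:, None] == 1, [255, 64, 64], [64, 255, 64]
            )
            rgb[pts[:, 0], pts[:, 1]] = colors
        else:
            dash = (np.arange(len(pts)) // 4) % 2 == 0
            rgb[pts[dash, 0], pts[dash, 1]] = [96, 96, 255]
    return rgb


def analyze_image(
    path: str | Path,
    config: PipelineConfig | None = None,
    second_path: str | Path | None = None,
    out_csv: str | Path | None = None,
    out_overlay: str | Path | None = None,
) -> pd.DataFrame:
    """Analyze one image file and optionally write the CSV and QC overlay."""
    config = config or PipelineConfig()
    img = read_image(
        path,
        second_path=second_path,
        pixel_size=config.pixel_size,
        swap_channels=config.swap_channels,
    )
    if img.pixel_size is None:  # assume already standardized
        img = FluorImage(img.channels, pixel_size=config.target_pixel_size)
    fibers, records, _ = analyze_fluorimage(img, config)
    df = records_to_dataframe(records)
    logger.info(
        "analyzed %s: %d fibers (%d valid); config %s seed %d",
        path,
        len(records),
        int(df["valid"].sum()) if len(df) else 0,
        config.config_hash(),
        config.seed,
    )
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_overlay is not None:
        import imageio.v3 as iio

        work = rescale_to_pixel_size(img, config.prep_params())
        iio.imwrite(out_overlay, overlay_image(work, fibers, records))
    return df


def batch_analyze(
    paths: list[str | Path],
    config: PipelineConfig | None = None,
    conditions: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Analyze many files; failures are recorded and skipped, not fatal.

    ``conditions`` maps file name to condition label; by default the stem up
    to the last underscore groups replicates of one condition.
    """
    config = config or PipelineConfig()
    frames = []
    failures = []
    for path in paths:
        path = Path(path)
        try:
            df = analyze_image(path, config)
        except Exception as exc:  # noqa: BLE001 - batch must survive bad files
            logger.error("failed to analyze %s: %s", path, exc)
            failures.append(f"{path}: {exc}")
            continue
        if conditions and path.name in conditions:
            cond = conditions[path.name]
        else:
            stem = path.stem
            cond = stem.rsplit("_", 1)[0] if "_" in stem else stem
        df.insert(0, "source", path.name)
        df.insert(0, "condition", cond)
        frames.append(df)
    if frames:
        combined = pd.concat(frames, ignore_index=True)
    else:
        combined = pd.DataFrame(
            columns=["condition", "source", *records_to_dataframe([]).columns]
        )
    return combined, failures
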