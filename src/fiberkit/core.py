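"""Core containers and image I/O for two-analog DNA fiber images.

A fiber image holds two fluorescence channels: channel 0 carries the first
nucleoside analog ("analog1", conventionally CldU, shown red) and channel 1
the second analog ("analog2", conventionally IdU, shown green).  Per-pixel
class masks use the fixed coding 0 = background, 1 = analog1, 2 = analog2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

LABEL_BACKGROUND = 0
LABEL_ANALOG1 = 1
LABEL_ANALOG2 = 2

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_ANALOG1: "analog1",
    LABEL_ANALOG2: "analog2",
}

#: Default physical scale every image is standardized to before analysis.
DEFAULT_PIXEL_SIZE_UM = 0.26


@dataclass
class FluorImage:
    """Two-channel fluorescence raster with a physical pixel size.

    Parameters
    ----------
    channels:
        Array of shape ``(2, rows, cols)``; channel 0 = analog1, channel 1 =
        analog2.  Any numeric dtype.
    pixel_size:
        Physical scale in micrometers per pixel, or ``None`` when unknown.
    """

    channels: np.ndarray
    pixel_size: float | None = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels)
        if arr.ndim != 3 or arr.shape[0] != 2:
            raise ValueError(
                f"channels must have shape (2, rows, cols), got {arr.shape}"
            )
        if arr.shape[1] == 0 or arr.shape[2] == 0:
            raise ValueError("image must have nonzero size")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.channels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def astype(self, dtype) -> "FluorImage":
        return replace(self, channels=self.channels.astype(dtype))

    def copy(self) -> "FluorImage":
        return replace(self, channels=self.channels.copy())


def _load_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return iio.imread(path)


def read_image(
    path: str | Path,
    second_path: str | Path | None = None,
    pixel_size: float | None = None,
    swap_channels: bool = False,
) -> FluorImage:
    """Read a fiber image from a dual-channel file or two single-channel files.

    Accepts TIFF or PNG/JPEG.  Dual-channel files may be channel-first
    ``(2, H, W)`` or channel-last ``(H, W, 2..4)``; for RGB(A) input the red
    and green planes are taken.  ``swap_channels`` flips which channel is
    treated as the first analog.
    """
    if second_path is not None:
        ch1 = np.asarray(_load_raster(path), dtype=np.float32)
        ch2 = np.asarray(_load_raster(second_path), dtype=np.float32)
        if ch1.ndim != 2 or ch2.ndim != 2:
            raise ValueError("per-channel files must be single-channel 2-D images")
        if ch1.shape != ch2.shape:
            raise ValueError("channel images must have identical shapes")
        data = np.stack([ch1, ch2])
    else:
        raw = np.asarray(_load_raster(path))
        if raw.ndim == 2:
            raise ValueError(
                "single-channel image: supply the second channel via second_path"
            )
        if raw.ndim != 3:
            raise ValueError(f"unsupported image shape {raw.shape}")
        if raw.shape[0] in (2, 3, 4) and raw.shape[0] < min(raw.shape[1:]):
            data = raw[:2].astype(np.float32)
        elif raw.shape[-1] in (2, 3, 4):
            data = np.moveaxis(raw, -1, 0)[:2].astype(np.float32)
        else:
            raise ValueError(f"cannot infer channel axis for shape {raw.shape}")
    if swap_channels:
        data = data[::-1]
    return FluorImage(data, pixel_size=pixel_size)


def write_image(path: str | Path, img: FluorImage) -> None:
    """Write a two-channel image as a channel-first TIFF."""
    path = Path(path)
    arr = img.channels
    if arr.dtype.kind == "f":
        arr = np.clip(arr, 0, 65535).astype(np.float32)
    tifffile.imwrite(path, arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an indexed class/instance mask (PNG or TIFF)."""
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask)
    else:
        if mask.max() > 255:
            raise ValueError("PNG masks limited to 255 labels; use TIFF")
        iio.imwrite(path, mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(_load_raster(path))


def path_step_length(path: np.ndarray) -> float:
    """Length of an 8-connected pixel path: 1 per axial step, sqrt(2) per diagonal."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    d = np.abs(np.diff(path, axis=0))
    return float(np.where(d.sum(axis=1) == 2, np.sqrt(2.0), d.sum(axis=1)).sum())


def polyline_arc_length(polyline: np.ndarray) -> float:
    """Euclidean arc length of a polyline given as (N, 2) float points."""
    polyline = np.asarray(polyline, dtype=float)
    if len(polyline) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum())
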