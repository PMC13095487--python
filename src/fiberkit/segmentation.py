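"""Per-pixel 3-class segmentation with a pluggable backend.

A backend is any callable mapping a two-channel patch ``(2, h, w)`` to a
per-class probability map ``(3, h, w)`` over {background, analog1, analog2},
summing to 1 at every pixel.  The module supplies:

* a transparent channel-dominance threshold backend (fixed or Otsu
  thresholds, optional smoothing, softmax-style probabilities);
* tiled whole-image inference with Gaussian center-weighted blending of
  overlapping patches;
* test-time augmentation over the dihedral transform group;
* pixel-wise ensembling of several backends.

A trained model can be plugged in by wrapping it in the same callable
contract; nothing downstream depends on how probabilities are produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import FluorImage

ProbMap = np.ndarray  # (3, H, W), simplex along axis 0


@runtime_checkable
class SegBackend(Protocol):
    def __call__(self, patch: np.ndarray) -> ProbMap: ...


@dataclass(frozen=True)
class TileSpec:
    """Sliding-window geometry: 1024-px tiles with 10% overlap by default."""

    tile: int = 1024
    overlap_fraction: float = 0.10
    blend_sigma: float = 0.125  # fraction of tile size

    def __post_init__(self) -> None:
        if self.tile <= 0:
            raise ValueError("tile must be positive")
        if not 0.0 <= self.overlap_fraction < 0.5:
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if self.blend_sigma <= 0:
            raise ValueError("blend_sigma must be positive")


@dataclass(frozen=True)
class ThresholdBackend:
    """Channel-dominance backend: a desk-scale reference segmenter.

    A pixel is foreground when either (optionally smoothed) channel exceeds
    its threshold, and takes the class of the dominant channel.
    Probabilities are a softmax over ``[threshold, ch1, ch2] / temperature``,
    which reproduces exactly that rule at the argmax while staying on the
    probability simplex.  With ``smooth_sigma = 0`` and fixed thresholds the
    backend is purely pixel-wise.
    """

    threshold: float | tuple[float, float] | str = "otsu"
    smooth_sigma: float = 1.0
    temperature: float = 8.0

    def _thresholds(self, channels: np.ndarray) -> tuple[float, float]:
        if self.threshold == "otsu":
            out = []
            for ch in range(2):
                vals = channels[ch]
                try:
                    out.append(float(threshold_otsu(vals)))
                except ValueError:  # constant channel: everything background
                    out.append(float(vals.max()) + 1.0)
            return tuple(out)
        if np.isscalar(self.threshold):
            return float(self.threshold), float(self.threshold)
        t1, t2 = self.threshold
        return float(t1), float(t2)

    def __call__(self, patch: np.ndarray) -> ProbMap:
        channels = np.asarray(patch, dtype=np.float64)
        if self.smooth_sigma > 0:
            channels = np.stack(
                [ndimage.gaussian_filter(channels[ch], self.smooth_sigma) for ch in range(2)]
            )
        t1, t2 = self._thresholds(channels)
        logits = np.stack(
            [np.full(channels.shape[1:], 0.5 * (t1 + t2)), channels[0], channels[1]]
        )
        logits = logits / self.temperature
        logits -= logits.max(axis=0, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=0, keepdims=True)
        return p


def _as_channels(img: FluorImage | np.ndarray) -> np.ndarray:
    if isinstance(img, FluorImage):
        return np.asarray(img.channels, dtype=np.float64)
    return np.asarray(img, dtype=np.float64)


def _tile_positions(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    pos = list(range(0, extent - tile + 1, stride))
    if pos[-1] != extent - tile:
        pos.append(extent - tile)
    return pos


def _gaussian_weight(tile: int, sigma_frac: float) -> np.ndarray:
    sigma = sigma_frac * tile
    ax = np.arange(tile) - (tile - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return np.maximum(w, 1e-6)  # strictly positive everywhere


def tiled_inference(
    backend: SegBackend,
    img: FluorImage | np.ndarray,
    spec: TileSpec = TileSpec(),
) -> ProbMap:
    """Whole-image inference by overlapping tiles with Gaussian blending.

    Images smaller than one tile are reflect-padded up to the tile size and
    cropped back afterwards.  Overlapping predictions are combined by a
    weighted average whose weights peak at each tile center, so predictions
    near patch borders contribute less.
    """
    channels = _as_channels(img)
    _, rows, cols = channels.shape
    tile = spec.tile
    pad_r = max(0, tile - rows)
    pad_c = max(0, tile - cols)
    if pad_r or pad_c:
        channels = np.pad(
            channels, ((0, 0), (0, pad_r), (0, pad_c)), mode="reflect"
        )
    _, prow, pcol = channels.shape
    stride = max(1, int(round(tile * (1.0 - spec.overlap_fraction))))
    weight = _gaussian_weight(tile, spec.blend_sigma)
    acc = np.zeros((3, prow, pcol), dtype=np.float64)
    wacc = np.zeros((prow, pcol), dtype=np.float64)
    for r0 in _tile_positions(prow, tile, stride):
        for c0 in _tile_positions(pcol, tile, stride):
            patch = channels[:, r0 : r0 + tile, c0 : c0 + tile]
            probs = np.asarray(backend(patch), dtype=np.float64)
            acc[:, r0 : r0 + tile, c0 : c0 + tile] += probs * weight
            wacc[r0 : r0 + tile, c0 : c0 + tile] += weight
    out = acc / wacc
    out = out[:, :rows, :cols]
    out /= out.sum(axis=0, keepdims=True)
    return out


# (forward, inverse) pairs acting on (C, H, W) arrays
_D4_TRANSFORMS: list[tuple[Callable, Callable]] = []
for k in range(4):
    for flip in (False, True):

        def fwd(a, k=k, flip=flip):
            a = np.rot90(a, k=k, axes=(1, 2))
            return a[:, :, ::-1] if flip else a

        def inv(a, k=k, flip=flip):
            a = a[:, :, ::-1] if flip else a
            return np.rot90(a, k=-k, axes=(1, 2))

        _D4_TRANSFORMS.append((fwd, inv))

_FLIP_TRANSFORMS = [
    (lambda a: a, lambda a: a),
    (lambda a: a[:, :, ::-1], lambda a: a[:, :, ::-1]),
    (lambda a: a[:, ::-1, :], lambda a: a[:, ::-1, :]),
    (lambda a: a[:, ::-1, ::-1], lambda a: a[:, ::-1, ::-1]),
]


def tta_inference(
    backend: SegBackend,
    img: FluorImage | np.ndarray,
    spec: TileSpec | None = None,
) -> ProbMap:
    """Average predictions over geometric transforms of the input.

    Square images use the full 8-element dihedral group (flips and 90-degree
    rotations); non-square images use flips and the 180-degree rotation only,
    since quarter rotations would change the raster shape.  When ``spec`` is
    given each transformed image runs through tiled inference.
    """
    channels = _as_channels(img)
    square = channels.shape[1] == channels.shape[2]
    transforms = _D4_TRANSFORMS if square else _FLIP_TRANSFORMS
    run = (lambda a: tiled_inference(backend, a, spec)) if spec else backend
    acc = None
    for fwd, inv in transforms:
        pred = inv(np.asarray(run(np.ascontiguousarray(fwd(channels))), dtype=np.float64))
        acc = pred.copy() if acc is None else acc + pred
    out = acc / len(transforms)
    out /= out.sum(axis=0, keepdims=True)
    return out


def ensemble_inference(
    backends: Sequence[SegBackend],
    img: FluorImage | np.ndarray,
    spec: TileSpec | None = None,
    tta: bool = False,
) -> ProbMap:
    """Unweighted pixel-wise mean of the member backends' probability maps."""
    if len(backends) == 0:
        raise ValueError("ensemble requires at least one backend")
    channels = _as_channels(img)

    def run_one(b: SegBackend) -> ProbMap:
        if tta:
            return tta_inference(b, channels, spec)
        if spec is not None:
            return tiled_inference(b, channels, spec)
        return np.asarray(b(channels), dtype=np.float64)

    acc = None
    for b in backends:
        pred = run_one(b)
        acc = pred.copy() if acc is None else acc + pred
    out = acc / len(backends)
    out /= out.sum(axis=0, keepdims=True)
    return out


def mask_from_probs(probs: ProbMap) -> np.ndarray:
    """Argmax class mask in {0, 1, 2} from a probability map."""
    return np.argmax(probs, axis=0).astype(np.uint8)
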