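"""Bottom-up image saliency front end.

Per frame, 24 feature maps are computed — {motion, four oriented-edge
energies (0°, 45°, 90°, 135°), luminance, red–green and blue–yellow
colour opponency} at three spatial scales obtained by successively
blurring the image — each min–max scaled to [0, 1].  Their sum is
block-averaged down to a 40x30 grid and normalized by the mean of its
100 largest values, so a value of 1 marks "maximally salient" cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stimulus import FrameStack

__all__ = [
    "FeatureMaps",
    "SaliencyMap",
    "SaliencyMapSeq",
    "compute_feature_maps",
    "compute_saliency_map",
    "compute_saliency_sequence",
    "saliency_at",
    "GRID_W",
    "GRID_H",
    "CELL_PX",
]

GRID_W = 40
GRID_H = 30
CELL_PX = 12  # 480/40 == 360/30

_LUM = np.array([0.299, 0.587, 0.114])
_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)
_CHANNELS = ("motion", "edge_0", "edge_45", "edge_90", "edge_135",
             "luminance", "rg", "by")


@dataclass(frozen=True)
class FeatureMaps:
    """24 per-frame feature maps (8 channels x 3 scales), each in [0, 1]."""

    maps: np.ndarray          # (24, H, W)
    names: tuple[str, ...]    # e.g. "motion@s0"

    def __post_init__(self) -> None:
        if self.maps.shape[0] != len(self.names):
            raise ValueError("names/maps length mismatch")


@dataclass(frozen=True)
class SaliencyMap:
    """A 40x30 (w x h) non-negative saliency grid for one frame."""

    grid: np.ndarray  # (GRID_H, GRID_W), row-major (y, x)
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.grid.shape != (GRID_H, GRID_W):
            raise ValueError(f"saliency grid must be {GRID_H}x{GRID_W} (h x w)")
        if np.any(self.grid < 0):
            raise ValueError("saliency values must be non-negative")


@dataclass(frozen=True)
class SaliencyMapSeq:
    """Saliency maps for every frame of a display cycle (cyclic indexing)."""

    maps: np.ndarray  # (T, GRID_H, GRID_W)

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    def grid(self, t: int) -> np.ndarray:
        return self.maps[int(t) % self.n_frames]

    def at(self, t: int, x_px: float, y_px: float) -> float:
        return saliency_at(SaliencyMap(self.grid(t), int(t) % self.n_frames), x_px, y_px)


def _minmax(m: np.ndarray) -> np.ndarray:
    lo = m.min()
    hi = m.max()
    if hi <= lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def _scale_channels(frame: np.ndarray, sigma: float):
    """Blurred luminance and signed opponency planes at one scale.

    Blur and the channel combinations are both linear, so blurring the
    combined planes equals combining blurred RGB channels.
    """
    lum = frame @ _LUM
    rg = frame[..., 0] - frame[..., 1]
    by = frame[..., 2] - 0.5 * (frame[..., 0] + frame[..., 1])
    return (ndi.gaussian_filter(lum, sigma),
            ndi.gaussian_filter(rg, sigma),
            ndi.gaussian_filter(by, sigma))


def compute_feature_maps(frame: np.ndarray, prev_frame: np.ndarray | None = None,
                         scales: int = 3, base_sigma: float = 2.0) -> FeatureMaps:
    """Compute the 24 normalized feature maps for one RGB frame.

    ``prev_frame`` feeds the frame-difference motion channel; if absent
    (first frame) the motion maps are all zero.  The three scales use
    Gaussian blurs with doubling sigma (sigma, 2 sigma, 4 sigma); edge
    energy is Sobel-derived oriented gradient magnitude on the blurred
    luminance.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be (H, W, 3)")
    if prev_frame is not None:
        prev_frame = np.asarray(prev_frame, dtype=float)
        if prev_frame.shape != frame.shape:
            raise ValueError("prev_frame shape mismatch")

    maps = []
    names = []
    for s in range(scales):
        sigma = base_sigma * (2.0 ** s)
        lum, rg, by = _scale_channels(frame, sigma)
        if prev_frame is None:
            motion = np.zeros_like(lum)
        else:
            prev_lum = ndi.gaussian_filter(prev_frame @ _LUM, sigma)
            motion = np.abs(lum - prev_lum)
        gx = ndi.sobel(lum, axis=1)
        gy = ndi.sobel(lum, axis=0)
        edges = [np.abs(np.cos(np.deg2rad(a)) * gx + np.sin(np.deg2rad(a)) * gy)
                 for a in _ANGLES_DEG]
        for name, m in zip(_CHANNELS,
                           (motion, *edges, lum, np.abs(rg), np.abs(by))):
            maps.append(_minmax(m))
            names.append(f"{name}@s{s}")
    return FeatureMaps(maps=np.stack(maps), names=tuple(names))


def compute_saliency_map(fm: FeatureMaps, frame_index: int = 0) -> SaliencyMap:
    """Sum the 24 feature maps, downscale to 40x30, normalize by top-100 mean."""
    total = fm.maps.sum(axis=0)
    h, w = total.shape
    if h % GRID_H or w % GRID_W:
        raise ValueError("frame size must be an integer multiple of the grid")
    by, bx = h // GRID_H, w // GRID_W
    down = total.reshape(GRID_H, by, GRID_W, bx).mean(axis=(1, 3))
    top = np.sort(down, axis=None)[-100:]
    denom = top.mean()
    if denom > 0:
        down = down / denom
    return SaliencyMap(grid=down, frame_index=frame_index)


def compute_saliency_sequence(frames: FrameStack, scales: int = 3,
                              base_sigma: float = 2.0) -> SaliencyMapSeq:
    """Saliency maps for every frame of the stack (motion map zero at t=0)."""
    out = np.empty((len(frames), GRID_H, GRID_W))
    prev = None
    for t in range(len(frames)):
        fm = compute_feature_maps(frames.frame(t), prev, scales=scales,
                                  base_sigma=base_sigma)
        out[t] = compute_saliency_map(fm, frame_index=t).grid
        prev = frames.frame(t)
    return SaliencyMapSeq(maps=out)


def saliency_at(smap: SaliencyMap, x_px: float, y_px: float) -> float:
    """Saliency of the 12x12-px grid cell containing pixel (x, y)."""
    if not (0 <= x_px < GRID_W * CELL_PX and 0 <= y_px < GRID_H * CELL_PX):
        raise ValueError(f"coordinates ({x_px}, {y_px}) outside the display")
    return float(smap.grid[int(y_px) // CELL_PX, int(x_px) // CELL_PX])
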