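"""Center-of-gaze (COG) sample extraction.

Each fixation of a gaze record becomes one grayscale patch, sampled from
the display frame on which the fixation started, centred at the fixation
point.  The default 41x41-px patch subtends about 1.8 degrees of visual
angle under the original viewing geometry (60 cm from a 76-cm, 1280x1024
monitor), i.e. roughly the foveal field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimulus import FrameStack
from .synthetic_gaze import GazeRecord

__all__ = ["COGSequence", "extract_cog_sequence", "visual_angle_deg"]

_LUM = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class COGSequence:
    """Ordered foveal samples: grayscale patches plus normalized coordinates."""

    patches: np.ndarray        # (L, P, P) grayscale in [0, 1]
    coords: np.ndarray         # (L, 2) fixation (x, y) normalized to [0, 1]
    frame_indices: np.ndarray  # (L,) source frame of each sample
    observer_id: str = ""

    def __post_init__(self) -> None:
        p = self.patches
        if p.ndim != 3 or p.shape[1] != p.shape[2]:
            raise ValueError("patches must be (L, P, P)")
        if self.coords.shape != (p.shape[0], 2):
            raise ValueError("coords must be (L, 2)")
        if np.any(self.coords < 0) or np.any(self.coords > 1):
            raise ValueError("coords must be normalized to [0, 1]")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]


def extract_cog_sequence(frames: FrameStack, gaze: GazeRecord,
                         patch_size: int = 41) -> COGSequence:
    """Map a gaze record to its COG sample sequence.

    The frame for each sample is the fixation's onset frame modulo the
    cycle length; the frame is converted to luminance grayscale
    (0.299 R + 0.587 G + 0.114 B) and a ``patch_size`` square centred at
    the rounded fixation pixel is cut out, edge-replicating beyond the
    display border.  Fixation coordinates are attached normalized by the
    display width/height.
    """
    if gaze.n_fixations == 0:
        raise ValueError("empty gaze record")
    if patch_size % 2 != 1:
        raise ValueError("patch_size must be odd")
    cfg = frames.config
    if (np.any(gaze.x < 0) or np.any(gaze.x >= cfg.width_px)
            or np.any(gaze.y < 0) or np.any(gaze.y >= cfg.height_px)):
        raise ValueError("gaze coordinates outside the display")

    gray = frames.frames @ _LUM  # (T, H, W)
    half = patch_size // 2
    onsets = gaze.onset_frames(cfg.frame_ms) % cfg.n_frames
    L = gaze.n_fixations
    patches = np.empty((L, patch_size, patch_size), dtype=float)
    for i in range(L):
        cx = int(round(float(gaze.x[i])))
        cy = int(round(float(gaze.y[i])))
        rows = np.clip(np.arange(cy - half, cy + half + 1), 0, cfg.height_px - 1)
        cols = np.clip(np.arange(cx - half, cx + half + 1), 0, cfg.width_px - 1)
        patches[i] = gray[onsets[i]][np.ix_(rows, cols)]
    coords = np.column_stack([gaze.x / cfg.width_px, gaze.y / cfg.height_px])
    return COGSequence(patches=patches, coords=coords,
                       frame_indices=onsets.astype(int),
                       observer_id=gaze.observer_id)


def visual_angle_deg(n_px: float, viewing_distance_cm: float = 60.0,
                     screen_diag_cm: float = 76.0,
                     screen_res: tuple[int, int] = (1280, 1024)) -> float:
    """Visual angle subtended by ``n_px`` monitor pixels.

    Defaults reproduce the original viewing geometry: a 76-cm monitor at
    1280x1024 viewed from 60 cm, for which the 41-px COG patch subtends
    about 1.8 degrees.
    """
    diag_px = math.hypot(*screen_res)
    cm = n_px * screen_diag_cm / diag_px
    return math.degrees(2.0 * math.atan(cm / (2.0 * viewing_distance_cm)))
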