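"""Synthetic occluded-rod display.

Renders the classic perceptual-completion stimulus: a vertical rod that
translates horizontally behind a static horizontal occluding box, on a
textured background.  One full motion cycle (far right -> far left -> far
right) spans ``n_frames`` frames; frame indices are cyclic, so frame ``t``
always refers to ``t mod n_frames``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["DisplayConfig", "FrameStack", "rod_position", "render_occluded_rod"]


@dataclass(frozen=True)
class DisplayConfig:
    """Geometry, timing and appearance of the occluded-rod display.

    Defaults give a 480x360 pixel display, 117 frames at 30 fps (one full
    rod cycle), a vertical green rod sweeping behind a horizontal blue
    occluder, and a static seeded dot texture on the background.
    """

    width_px: int = 480
    height_px: int = 360
    n_frames: int = 117
    frame_ms: float = 100.0 / 3.0

    rod_length_px: int = 280
    rod_width_px: int = 8
    rod_color: tuple[float, float, float] = (0.10, 0.75, 0.20)

    occluder_x: int = 90
    occluder_y: int = 130
    occluder_w: int = 300
    occluder_h: int = 100
    occluder_color: tuple[float, float, float] = (0.35, 0.50, 0.85)

    background_color: tuple[float, float, float] = (0.25, 0.25, 0.25)
    texture_dots: bool = True
    n_dots: int = 180
    dot_color: tuple[float, float, float] = (0.85, 0.85, 0.85)
    texture_seed: int = 7

    rod_center_x: float = 240.0
    motion_amplitude_px: float = 180.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) <= 0:
            raise ValueError("width_px, height_px and n_frames must be positive")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")
        if self.motion_amplitude_px < 0:
            raise ValueError("motion_amplitude_px must be non-negative")
        half = self.rod_width_px / 2
        if (self.rod_center_x - self.motion_amplitude_px - half < 0
                or self.rod_center_x + self.motion_amplitude_px + half >= self.width_px):
            raise ValueError("rod trajectory leaves the canvas")
        if self.rod_length_px > self.height_px:
            raise ValueError("rod longer than the canvas")
        if (self.occluder_x < 0 or self.occluder_y < 0
                or self.occluder_x + self.occluder_w > self.width_px
                or self.occluder_y + self.occluder_h > self.height_px):
            raise ValueError("occluder outside the canvas")

    @property
    def x_right(self) -> float:
        """Far-right extreme of the rod center's trajectory."""
        return self.rod_center_x + self.motion_amplitude_px

    @property
    def x_left(self) -> float:
        """Far-left extreme of the rod center's trajectory."""
        return self.rod_center_x - self.motion_amplitude_px

    @property
    def rod_y0(self) -> int:
        return (self.height_px - self.rod_length_px) // 2

    @property
    def rod_y1(self) -> int:
        return self.rod_y0 + self.rod_length_px

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DisplayConfig":
        d = dict(d)
        for key in ("rod_color", "occluder_color", "background_color", "dot_color"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class FrameStack:
    """Ordered RGB frames of one display cycle, values in [0, 1].

    ``frame(t)`` applies the cyclic indexing contract (t mod n_frames).
    """

    frames: np.ndarray  # (n_frames, height, width, 3)
    config: DisplayConfig

    def __post_init__(self) -> None:
        f = self.frames
        c = self.config
        if f.shape != (c.n_frames, c.height_px, c.width_px, 3):
            raise ValueError(f"frame stack shape {f.shape} inconsistent with config")

    def __len__(self) -> int:
        return self.config.n_frames

    def frame(self, t: int) -> np.ndarray:
        return self.frames[int(t) % self.config.n_frames]


def rod_position(t, config: DisplayConfig):
    """Horizontal rod-center position (px) at frame ``t``.

    The trajectory is a constant-speed triangle wave with period
    ``n_frames``: the rod starts at the far-right extreme at t=0, reaches
    the far-left extreme at the half cycle, and returns to the start at
    t=n_frames.  ``t`` may be fractional and is taken modulo the period.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("frame index must be finite")
    if np.any(t < 0):
        raise ValueError("frame index must be non-negative")
    phase = np.mod(t, config.n_frames) / config.n_frames
    tri = 1.0 - np.abs(1.0 - 2.0 * phase)  # 0 at cycle ends, 1 at half cycle
    pos = config.x_right - 2.0 * config.motion_amplitude_px * tri
    return float(pos) if pos.ndim == 0 else pos


def _paint_rect(img: np.ndarray, x0: int, y0: int, x1: int, y1: int, color) -> None:
    img[y0:y1, x0:x1] = color


def render_occluded_rod(config: DisplayConfig | None = None) -> FrameStack:
    """Render the display into a :class:`FrameStack`.

    Deterministic given the config (including the texture seed).  The rod
    is painted first, the occluder last, so rod pixels never overwrite the
    occluder.
    """
    cfg = config if config is not None else DisplayConfig()
    h, w = cfg.height_px, cfg.width_px

    background = np.empty((h, w, 3), dtype=np.float32)
    background[:] = cfg.background_color
    if cfg.texture_dots and cfg.n_dots > 0:
        rng = np.random.default_rng(cfg.texture_seed)
        xs = rng.integers(0, w - 1, size=cfg.n_dots)
        ys = rng.integers(0, h - 1, size=cfg.n_dots)
        for x, y in zip(xs, ys):  # 2x2 px dots
            background[y:y + 2, x:x + 2] = cfg.dot_color

    frames = np.empty((cfg.n_frames, h, w, 3), dtype=np.float32)
    half = cfg.rod_width_px / 2
    for t in range(cfg.n_frames):
        img = background.copy()
        cx = rod_position(t, cfg)
        x0 = int(round(cx - half))
        x1 = x0 + cfg.rod_width_px
        if x0 < 0 or x1 > w:
            raise ValueError("rod outside the canvas during rendering")
        _paint_rect(img, x0, cfg.rod_y0, x1, cfg.rod_y1, cfg.rod_color)
        _paint_rect(img, cfg.occluder_x, cfg.occluder_y,
                    cfg.occluder_x + cfg.occluder_w, cfg.occluder_y + cfg.occluder_h,
                    cfg.occluder_color)
        frames[t] = img
    return FrameStack(frames=frames, config=cfg)
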