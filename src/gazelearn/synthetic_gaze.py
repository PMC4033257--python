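"""Synthetic reference gaze records.

Generates fixation sequences with infant-like kinematics (fixation
durations and gaze-shift distances drawn from truncated normals matched
to published 3-month-old group statistics) and controllable temporal
structure: gaze alternating among a small set of anchor regions under a
first-order Markov transition matrix, or fully random scanning.

These records stand in for eye-tracking data as the *reference* observers
to which the artificial observers are yoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .stimulus import DisplayConfig, rod_position

__all__ = [
    "GazeRecord",
    "Anchor",
    "GazeStyleParams",
    "generate_gaze",
    "INFANT_FIXATION_MS",
    "INFANT_FIXATION_SD_MS",
    "INFANT_SHIFT_PX",
    "INFANT_SHIFT_SD_PX",
]

# Published 3-month-old group kinematics used as generator defaults:
# fixation duration 339.38 (96.03) ms, gaze-shift distance 59.20 (18.82) px.
INFANT_FIXATION_MS = 339.38
INFANT_FIXATION_SD_MS = 96.03
INFANT_SHIFT_PX = 59.20
INFANT_SHIFT_SD_PX = 18.82


@dataclass(frozen=True)
class GazeRecord:
    """An ordered fixation sequence: positions (px) and dwell times (ms)."""

    observer_id: str
    x: np.ndarray
    y: np.ndarray
    duration_ms: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "duration_ms", np.asarray(self.duration_ms, dtype=float))
        if not (self.x.shape == self.y.shape == self.duration_ms.shape):
            raise ValueError("x, y and duration_ms must have equal length")
        if self.x.ndim != 1 or self.x.size == 0:
            raise ValueError("a gaze record needs at least one fixation")
        if np.any(self.duration_ms <= 0):
            raise ValueError("fixation durations must be positive")

    @property
    def n_fixations(self) -> int:
        return self.x.size

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) fixation positions."""
        return np.column_stack([self.x, self.y])

    def onset_frames(self, frame_ms: float = 100.0 / 3.0) -> np.ndarray:
        """Frame index at which each fixation starts (cumulative ms // frame)."""
        starts = np.concatenate([[0.0], np.cumsum(self.duration_ms)[:-1]])
        return np.floor(starts / frame_ms).astype(int)

    def shift_distances(self) -> np.ndarray:
        """Euclidean distance between successive fixations (n-1 values)."""
        return np.hypot(np.diff(self.x), np.diff(self.y))


@dataclass(frozen=True)
class Anchor:
    """A gaze anchor region; ``track_rod`` ties its x to the rod position."""

    x: float
    y: float
    track_rod: bool = False

    def position(self, frame: int, config: DisplayConfig) -> np.ndarray:
        x = rod_position(frame, config) if self.track_rod else self.x
        return np.array([x, self.y], dtype=float)


def _default_infant_anchors() -> tuple[Anchor, ...]:
    # A compact cluster over the upper rod path / occluder edge, spaced so
    # that inter-anchor hops land near the target ~59 px shift distance.
    return (Anchor(215.0, 120.0), Anchor(265.0, 120.0), Anchor(240.0, 175.0))


@dataclass(frozen=True)
class GazeStyleParams:
    """Parameters of the synthetic gaze generator.

    styles
      ``infant_like``      anchors + Markov transitions, distances matched
                           to a truncated-normal target via best-of-M
                           proposal selection
      ``scripted_regions`` anchors + Markov transitions, positions placed
                           at the (jittered) anchor itself
      ``uniform_random``   positions uniform over the display
    """

    style: str = "infant_like"
    n_fixations: int = 61
    duration_mean_ms: float = INFANT_FIXATION_MS
    duration_sd_ms: float = INFANT_FIXATION_SD_MS
    shift_mean_px: float = INFANT_SHIFT_PX
    shift_sd_px: float = INFANT_SHIFT_SD_PX
    anchors: tuple[Anchor, ...] = field(default_factory=_default_infant_anchors)
    transition: np.ndarray | None = None  # rows sum to 1; default: uniform off-diagonal
    jitter_sd_px: float = 18.0
    n_proposals: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in ("infant_like", "scripted_regions", "uniform_random"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.n_fixations < 2:
            raise ValueError("need at least 2 fixations")
        if min(self.duration_mean_ms, self.duration_sd_ms,
               self.shift_mean_px, self.shift_sd_px) <= 0:
            raise ValueError("distribution parameters must be positive")
        if self.jitter_sd_px < 0:
            raise ValueError("jitter_sd_px must be non-negative")
        if self.transition is not None:
            m = np.asarray(self.transition, dtype=float)
            if m.shape != (len(self.anchors), len(self.anchors)):
                raise ValueError("transition matrix shape must match anchor count")
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must be non-negative and sum to 1")
            object.__setattr__(self, "transition", m)

    def transition_matrix(self) -> np.ndarray:
        if self.transition is not None:
            return self.transition
        k = len(self.anchors)
        if k == 1:
            return np.ones((1, 1))
        m = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(m, 0.0)
        return m

    @classmethod
    def infant_like(cls, seed: int = 0, n_fixations: int = 61, **kw) -> "GazeStyleParams":
        return cls(style="infant_like", seed=seed, n_fixations=n_fixations, **kw)

    @classmethod
    def scripted(cls, anchors: Sequence[Anchor], transition, seed: int = 0,
                 n_fixations: int = 40, jitter_sd_px: float = 4.0, **kw) -> "GazeStyleParams":
        return cls(style="scripted_regions", anchors=tuple(anchors),
                   transition=np.asarray(transition, dtype=float), seed=seed,
                   n_fixations=n_fixations, jitter_sd_px=jitter_sd_px, **kw)

    @classmethod
    def uniform(cls, seed: int = 0, n_fixations: int = 61, **kw) -> "GazeStyleParams":
        return cls(style="uniform_random", seed=seed, n_fixations=n_fixations, **kw)


def _truncnorm_sample(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _clip_into(p: np.ndarray, config: DisplayConfig) -> np.ndarray:
    eps = 1e-9
    p = np.atleast_2d(p)
    out = p.copy()
    out[:, 0] = np.clip(out[:, 0], 0.0, config.width_px - 1 - eps)
    out[:, 1] = np.clip(out[:, 1], 0.0, config.height_px - 1 - eps)
    return out


def generate_gaze(params: GazeStyleParams, config: DisplayConfig | None = None,
                  observer_id: str | None = None) -> GazeRecord:
    """Generate one synthetic gaze record; deterministic given the seed.

    Durations are truncated-normal (lower bound one frame).  For the
    anchored styles, successive fixation regions follow the transition
    matrix; ``infant_like`` additionally draws a target shift distance
    from its truncated normal and keeps, out of ``n_proposals`` jittered
    candidate points around the chosen anchor, the one whose realized
    shift distance is closest to the target.
    """
    cfg = config if config is not None else DisplayConfig()
    rng = np.random.default_rng(params.seed)
    n = params.n_fixations

    durations = _truncnorm_sample(rng, params.duration_mean_ms, params.duration_sd_ms,
                                  cfg.frame_ms, n)
    onsets = np.floor(np.concatenate([[0.0], np.cumsum(durations)[:-1]]) / cfg.frame_ms)
    onsets = onsets.astype(int)

    if params.style == "uniform_random":
        xs = rng.uniform(0, cfg.width_px, size=n)
        ys = rng.uniform(0, cfg.height_px, size=n)
        pos = _clip_into(np.column_stack([xs, ys]), cfg)
    else:
        anchors = params.anchors
        for a in anchors:
            probe = a.position(0, cfg)
            if not (0 <= probe[0] < cfg.width_px and 0 <= probe[1] < cfg.height_px):
                raise ValueError(f"anchor {a} outside the display")
        trans = params.transition_matrix()
        k = len(anchors)
        region = 0
        p0 = anchors[0].position(onsets[0], cfg)
        if params.jitter_sd_px > 0:
            p0 = p0 + rng.normal(0.0, params.jitter_sd_px, size=2)
        pos = np.empty((n, 2))
        pos[0] = _clip_into(p0, cfg)[0]

        if params.style == "scripted_regions":
            for i in range(1, n):
                region = int(rng.choice(k, p=trans[region]))
                p = anchors[region].position(onsets[i], cfg)
                if params.jitter_sd_px > 0:
                    p = p + rng.normal(0.0, params.jitter_sd_px, size=2)
                pos[i] = _clip_into(p, cfg)[0]
        else:  # infant_like: distance-matched proposals around the next anchor
            targets = _truncnorm_sample(rng, params.shift_mean_px, params.shift_sd_px,
                                        1.0, n - 1)
            m = params.n_proposals
            for i in range(1, n):
                region = int(rng.choice(k, p=trans[region]))
                center = anchors[region].position(onsets[i], cfg)
                proposals = center + rng.normal(0.0, max(params.jitter_sd_px, 1e-6),
                                                size=(m, 2))
                proposals = _clip_into(proposals, cfg)
                d = np.hypot(proposals[:, 0] - pos[i - 1, 0],
                             proposals[:, 1] - pos[i - 1, 1])
                pos[i] = proposals[np.argmin(np.abs(d - targets[i - 1]))]

    name = observer_id if observer_id is not None else f"{params.style}-{params.seed}"
    return GazeRecord(observer_id=name, x=pos[:, 0], y=pos[:, 1], duration_ms=durations)
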