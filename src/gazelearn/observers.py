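"""Yoked artificial observers: image-saliency and random-gaze models.

Both observers are yoked to a reference gaze record on four dimensions —
first fixation location, number of fixations, per-fixation duration
(quantized to whole frames), and gaze-shift distance.  The saliency
observer picks each next fixation from the top-500 cells of a fixation
map (cumulative saliency over the dwell minus a decaying
inhibition-of-return map), choosing the candidate whose distance from
the current point is closest to the yoked distance; the random observer
picks uniformly on the circle of the yoked radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .saliency import CELL_PX, GRID_H, GRID_W, SaliencyMapSeq
from .stimulus import DisplayConfig
from .synthetic_gaze import GazeRecord

__all__ = [
    "YokeSpec",
    "make_yoke",
    "step_inhibition",
    "select_next_fixation",
    "simulate_saliency_observer",
    "simulate_random_observer",
    "INHIBITION_DECAY",
    "INHIBITION_SPAN_PX",
    "N_CANDIDATES",
]

INHIBITION_DECAY = 0.9      # multiplicative, per 33-ms frame
INHIBITION_SPAN_PX = 92     # Gaussian support, ~2x a COG sample
N_CANDIDATES = 500

_FRAME_MS = 100.0 / 3.0


@dataclass(frozen=True)
class YokeSpec:
    """The four equated dimensions extracted from a reference record."""

    first_xy: tuple[float, float]
    durations_frames: np.ndarray  # whole frames, >= 1
    distances_px: np.ndarray      # len == n_fixations - 1

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_frames, dtype=int)
        s = np.asarray(self.distances_px, dtype=float)
        if np.any(d < 1):
            raise ValueError("yoked durations must be at least one frame")
        if s.size != d.size - 1:
            raise ValueError("need n_fixations - 1 gaze-shift distances")
        object.__setattr__(self, "durations_frames", d)
        object.__setattr__(self, "distances_px", s)

    @property
    def n_fixations(self) -> int:
        return self.durations_frames.size


def make_yoke(ref: GazeRecord, frame_ms: float = _FRAME_MS) -> YokeSpec:
    """Extract the yoked dimensions; durations round to whole frames (min 1)."""
    if ref.n_fixations < 2:
        raise ValueError("reference record needs at least 2 fixations")
    frames = np.maximum(1, np.rint(ref.duration_ms / frame_ms).astype(int))
    return YokeSpec(first_xy=(float(ref.x[0]), float(ref.y[0])),
                    durations_frames=frames,
                    distances_px=ref.shift_distances())


def _cell_of(x_px: float, y_px: float) -> tuple[int, int]:
    return int(y_px) // CELL_PX, int(x_px) // CELL_PX


def _gaussian_surface(row: int, col: int, peak: float) -> np.ndarray:
    """2D Gaussian centred on a grid cell; sigma = span/4 so the surface
    is effectively zero at the edge of its 92x92-px support."""
    sigma_cells = INHIBITION_SPAN_PX / CELL_PX / 4.0
    rr, cc = np.ogrid[:GRID_H, :GRID_W]
    return peak * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma_cells ** 2))


def step_inhibition(inhib: np.ndarray, fixation: tuple[float, float] | None = None,
                    smap_grid: np.ndarray | None = None,
                    add: bool = False) -> np.ndarray:
    """Advance the inhibition map by one frame.

    If ``add``, a Gaussian surface centred at the fixation's cell with
    peak equal to the saliency value at that cell is added first; then
    every value decays by 10%.
    """
    out = np.asarray(inhib, dtype=float)
    if out.shape != (GRID_H, GRID_W):
        raise ValueError("inhibition map must be 30x40")
    if add:
        if fixation is None or smap_grid is None:
            raise ValueError("adding requires a fixation and a saliency grid")
        row, col = _cell_of(*fixation)
        if not (0 <= row < GRID_H and 0 <= col < GRID_W):
            raise ValueError("fixation outside the display")
        out = out + _gaussian_surface(row, col, float(smap_grid[row, col]))
    return out * INHIBITION_DECAY


def _cell_centers() -> tuple[np.ndarray, np.ndarray]:
    cols, rows = np.meshgrid(np.arange(GRID_W), np.arange(GRID_H))
    return cols * CELL_PX + (CELL_PX - 1) / 2.0, rows * CELL_PX + (CELL_PX - 1) / 2.0


def select_next_fixation(fixmap: np.ndarray, current: tuple[float, float],
                         target_distance: float, rng: np.random.Generator
                         ) -> tuple[float, float]:
    """Pick the next fixation from the top-500 cells of the fixation map.

    Among the candidates the cell (addressed by its pixel centre) whose
    distance from ``current`` is closest to ``target_distance`` wins;
    exact ties — in candidate ordering or in distance error — are broken
    uniformly at random.
    """
    fixmap = np.asarray(fixmap, dtype=float)
    if fixmap.shape != (GRID_H, GRID_W):
        raise ValueError("fixation map must be 30x40")
    if np.any(fixmap < 0):
        raise ValueError("fixation map must be non-negative")
    flat = fixmap.ravel()
    pool = np.flatnonzero(flat > 0)  # zero cells are fully inhibited, not targets
    if pool.size == 0:
        pool = np.arange(flat.size)
    perm = rng.permutation(pool)  # randomize ordering ties at the cutoff
    order = perm[np.argsort(-flat[perm], kind="stable")]
    top = order[:N_CANDIDATES]

    cx, cy = _cell_centers()
    dist = np.hypot(cx.ravel()[top] - current[0], cy.ravel()[top] - current[1])
    err = np.abs(dist - target_distance)
    winners = top[err <= err.min() + 1e-9]
    pick = int(winners[rng.integers(winners.size)]) if winners.size > 1 else int(winners[0])
    row, col = divmod(pick, GRID_W)
    return (col * CELL_PX + (CELL_PX - 1) / 2.0, row * CELL_PX + (CELL_PX - 1) / 2.0)


def simulate_saliency_observer(smaps: SaliencyMapSeq, yoke: YokeSpec,
                               seed: int = 0, frame_ms: float = _FRAME_MS,
                               observer_id: str = "saliency") -> GazeRecord:
    """Simulate the saliency-driven observer under a yoke.

    Per fixation: hold for the yoked frame count while accumulating the
    saliency maps spanning those frames (cyclic frame indexing) and
    decaying the inhibition map each frame; the inhibition Gaussian is
    added once at fixation onset; at fixation end the fixation map is
    max(0, cumulative saliency - inhibition) and the next location is the
    yoked-distance-matched top-500 candidate.
    """
    if smaps.maps.shape[1:] != (GRID_H, GRID_W):
        raise ValueError("saliency map sequence has the wrong grid shape")
    rng = np.random.default_rng(seed)
    n = yoke.n_fixations
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = yoke.first_xy

    inhib = np.zeros((GRID_H, GRID_W))
    t = 0  # global frame clock
    for k in range(n):
        cumulative = np.zeros((GRID_H, GRID_W))
        dur = int(yoke.durations_frames[k])
        for f in range(dur):
            grid = smaps.grid(t)
            inhib = step_inhibition(inhib, (xs[k], ys[k]), grid, add=(f == 0))
            cumulative += grid
            t += 1
        if k + 1 < n:
            fixmap = np.maximum(0.0, cumulative - inhib)
            xs[k + 1], ys[k + 1] = select_next_fixation(
                fixmap, (xs[k], ys[k]), float(yoke.distances_px[k]), rng)

    return GazeRecord(observer_id=observer_id, x=xs, y=ys,
                      duration_ms=yoke.durations_frames * frame_ms)


def _feasible_distance(current, d, config, n_angles=720):
    """Largest radius <= d with some point of the circle on the display."""
    ang = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    r = d
    for _ in range(64):
        x = current[0] + r * np.cos(ang)
        y = current[1] + r * np.sin(ang)
        ok = (x >= 0) & (x < config.width_px) & (y >= 0) & (y < config.height_px)
        if ok.any():
            return r
        r *= 0.9
    return 0.0


def simulate_random_observer(yoke: YokeSpec, config: DisplayConfig | None = None,
                             seed: int = 0, frame_ms: float = _FRAME_MS,
                             observer_id: str = "random") -> GazeRecord:
    """Simulate the random-gaze observer under the same yoke.

    Each next fixation is drawn uniformly on the circle of the yoked
    radius around the current point; draws landing off the display are
    rejected and resampled.  If the entire circle lies off the display
    the distance is clipped to the largest feasible radius (with a
    warning).
    """
    cfg = config if config is not None else DisplayConfig()
    rng = np.random.default_rng(seed)
    n = yoke.n_fixations
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = yoke.first_xy
    for k in range(n - 1):
        d = float(yoke.distances_px[k])
        for attempt in range(10_000):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            x = xs[k] + d * np.cos(theta)
            y = ys[k] + d * np.sin(theta)
            if 0 <= x < cfg.width_px and 0 <= y < cfg.height_px:
                break
        else:
            clipped = _feasible_distance((xs[k], ys[k]), d, cfg)
            warnings.warn(f"gaze-shift distance {d:.1f} infeasible; clipped to "
                          f"{clipped:.1f}", stacklevel=2)
            d = clipped
            while True:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                x = xs[k] + d * np.cos(theta)
                y = ys[k] + d * np.sin(theta)
                if 0 <= x < cfg.width_px and 0 <= y < cfg.height_px:
                    break
        xs[k + 1], ys[k + 1] = x, y
    return GazeRecord(observer_id=observer_id, x=xs, y=ys,
                      duration_ms=yoke.durations_frames * frame_ms)
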