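"""Training/testing regime over runs, cloned networks and observer groups.

One *run* initializes a single SRN and clones it across references, so
performance differences within a run are attributable to the training
sequences alone.  Each epoch sweeps every reference's observer-group
sequences in a per-epoch random order with weight carry-over; every
``test_every`` epochs learning is frozen and each sequence is evaluated
under full recurrence and under 1-, 2- and 5-sample context resets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cog import COGSequence, extract_cog_sequence
from .observers import make_yoke, simulate_random_observer
from .srn import init_weights, run_sequence
from .stimulus import DisplayConfig, FrameStack, render_occluded_rod
from .synthetic_gaze import Anchor, GazeStyleParams, generate_gaze

__all__ = [
    "RegimeConfig",
    "TrainingResult",
    "run_regime",
    "desk_display_config",
    "build_structured_vs_random",
]

CANONICAL = "canonical"


@dataclass(frozen=True)
class RegimeConfig:
    """Scale and hyper-parameters of a training regime.

    The ``full`` preset keeps the original constants (10 runs, 300
    epochs, 400 hidden units); the ``desk`` preset is a scaled-down
    variant (1 run, 100 epochs, 200 hidden units) sized for a single
    CPU.
    """

    n_runs: int = 10
    n_epochs: int = 300
    test_every: int = 10
    reset_conditions: tuple[int, ...] = (1, 2, 5)
    learning_rate: float = 0.1
    n_hidden: int = 400
    seed: int = 0
    test_epoch0: bool = False

    def __post_init__(self) -> None:
        if self.n_epochs < 0 or self.test_every < 1 or self.n_runs < 1:
            raise ValueError("invalid regime dimensions")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def full(cls, seed: int = 0, **kw) -> "RegimeConfig":
        return cls(seed=seed, **kw)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "RegimeConfig":
        kw.setdefault("n_runs", 1)
        kw.setdefault("n_epochs", 100)
        kw.setdefault("n_hidden", 200)
        return cls(seed=seed, **kw)


@dataclass(frozen=True)
class TrainingResult:
    """Tidy test-phase RMSE: (run, network, observer, epoch, condition)."""

    df: pd.DataFrame

    COLUMNS = ("run", "network", "observer", "epoch", "condition", "rmse")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"result frame missing columns {sorted(missing)}")
        if len(self.df) and not np.all(np.isfinite(self.df["rmse"])):
            raise ValueError("non-finite RMSE values")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainingResult":
        return cls(pd.read_csv(path))

    @property
    def observers(self) -> list[str]:
        return sorted(self.df["observer"].unique())


def _test_epochs(cfg: RegimeConfig) -> list[int]:
    epochs = list(range(cfg.test_every, cfg.n_epochs + 1, cfg.test_every))
    if cfg.test_epoch0:
        epochs = [0] + epochs
    return epochs


def run_regime(cfg: RegimeConfig,
               sequences: list[dict[str, COGSequence]]) -> TrainingResult:
    """Execute the full regime; deterministic given ``cfg.seed``.

    ``sequences`` holds, per reference, the yoked COG sequences of each
    observer group (all groups of a reference must have equal length).
    """
    if not sequences:
        raise ValueError("no reference sequences supplied")
    groups = sorted(sequences[0].keys())
    sizes: set[int] = set()
    for ref in sequences:
        if sorted(ref.keys()) != groups:
            raise ValueError("every reference needs the same observer groups")
        if len({len(s) for s in ref.values()}) != 1:
            raise ValueError("observer sequences within a reference are not yoked")
        sizes.update(s.patch_size ** 2 for s in ref.values())
    if len(sizes) != 1:
        raise ValueError("inconsistent patch sizes across sequences")
    n_pixels = sizes.pop()

    root = np.random.SeedSequence(cfg.seed)
    run_seeds = root.spawn(cfg.n_runs)
    rows: list[tuple] = []

    def record_tests(run, net, weights, epoch, ref):
        for g in groups:
            for cond in (None, *cfg.reset_conditions):
                rmse, _ = run_sequence(weights, ref[g], mode="test",
                                       reset_interval=cond, lr=cfg.learning_rate)
                label = CANONICAL if cond is None else f"reset{cond}"
                rows.append((run, net, g, epoch, label, rmse))

    for run, run_ss in enumerate(run_seeds):
        init_ss, *net_ss = run_ss.spawn(len(sequences) + 1)
        base = init_weights(init_ss.generate_state(1)[0] % (2**31),
                            n_pixels=n_pixels, n_hidden=cfg.n_hidden)
        for net, (ref, ss) in enumerate(zip(sequences, net_ss)):
            weights = base.copy()  # clone: identical start across references
            rng = np.random.default_rng(ss)
            if cfg.test_epoch0:
                record_tests(run, net, weights, 0, ref)
            for epoch in range(1, cfg.n_epochs + 1):
                for g_idx in rng.permutation(len(groups)):
                    _, weights = run_sequence(weights, ref[groups[g_idx]],
                                              mode="train",
                                              lr=cfg.learning_rate)
                if epoch % cfg.test_every == 0:
                    record_tests(run, net, weights, epoch, ref)

    df = pd.DataFrame(rows, columns=list(TrainingResult.COLUMNS))
    return TrainingResult(df=df)


def desk_display_config() -> DisplayConfig:
    """Reduced-amplitude display used by the desk preset.

    The rod sweeps a 120-px band so that fixed anchor regions on its
    path see the rod pass frequently, which concentrates the display's
    temporal structure inside small COG patches.
    """
    return DisplayConfig(motion_amplitude_px=60.0)


def _structured_params(seed: int, n_fixations: int) -> GazeStyleParams:
    anchors = (Anchor(215.0, 95.0), Anchor(265.0, 95.0), Anchor(240.0, 60.0))
    cycle = [[0, 1, 0], [0, 0, 1], [1, 0, 0]]  # deterministic 3-anchor loop
    return GazeStyleParams.scripted(anchors, cycle, seed=seed,
                                    n_fixations=n_fixations, jitter_sd_px=4.0)


def build_structured_vs_random(seed: int, n_references: int = 4,
                               n_fixations: int = 40,
                               frames: FrameStack | None = None,
                               patch_size: int = 21
                               ) -> list[dict[str, COGSequence]]:
    """Desk-scale inputs: scripted-structured references plus yoked
    random-gaze controls, as COG sequences.

    Structured references alternate deterministically among three anchor
    regions on the rod's (reduced-amplitude) path, so successive patches
    carry the rod's motion phase; the random control is yoked to each
    reference's timing and shift distances.
    """
    if frames is None:
        frames = render_occluded_rod(desk_display_config())
    cfg = frames.config
    ss = np.random.SeedSequence(seed).spawn(n_references)
    out = []
    for i, ref_ss in enumerate(ss):
        s1, s2 = [int(s.generate_state(1)[0] % (2**31)) for s in ref_ss.spawn(2)]
        structured = generate_gaze(_structured_params(s1, n_fixations), cfg,
                                   observer_id=f"structured-{i}")
        yoke = make_yoke(structured, cfg.frame_ms)
        random_rec = simulate_random_observer(yoke, cfg, seed=s2,
                                              observer_id=f"random-{i}")
        out.append({
            "structured": extract_cog_sequence(frames, structured, patch_size),
            "random": extract_cog_sequence(frames, random_rec, patch_size),
        })
    return out
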