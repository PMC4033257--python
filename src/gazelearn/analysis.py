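"""Scanpath summary statistics and training-result analyses.

Summary statistics per observer: mean fixation duration, saliency
captured (mean saliency under the fixations, as a proportion of
maximal), revisit rate (peak of a per-fixation 41x41 frequency window),
fixation dispersion (mean distance from the fixation centroid) and mean
gaze-shift distance.

Training results are summarized two ways: RMSE rank curves (groups
ranked 1..k per network and epoch by ascending canonical RMSE, then
averaged) and percent-change curves (RMSE increase of each context-reset
condition relative to the canonical condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import CANONICAL, TrainingResult
from .saliency import SaliencyMapSeq
from .synthetic_gaze import GazeRecord

__all__ = [
    "SummaryStats",
    "summary_stats",
    "group_summary",
    "rank_curves",
    "percent_change_curves",
    "plot_rmse_curves",
    "plot_rank_curves",
    "plot_percent_change",
]

_FRAME_MS = 100.0 / 3.0


@dataclass(frozen=True)
class SummaryStats:
    observer_id: str
    mean_fixation_duration_ms: float
    mean_gaze_shift_px: float
    dispersion_px: float
    revisit_rate: float
    saliency_captured: float | None = None


def _revisit_rate(gaze: GazeRecord, display_size: tuple[int, int],
                  window: int = 41) -> float:
    w, h = display_size
    half = window // 2
    freq = np.zeros((h, w))
    for x, y in gaze.positions:
        cx, cy = int(round(x)), int(round(y))
        r0, r1 = max(0, cy - half), min(h, cy + half + 1)
        c0, c1 = max(0, cx - half), min(w, cx + half + 1)
        freq[r0:r1, c0:c1] += 1.0
    return float(freq.max() / gaze.n_fixations)


def summary_stats(gaze: GazeRecord, smaps: SaliencyMapSeq | None = None,
                  display_size: tuple[int, int] = (480, 360),
                  frame_ms: float = _FRAME_MS, window: int = 41) -> SummaryStats:
    """Compute the five scanpath statistics for one gaze record.

    Saliency captured projects each fixation onto the saliency map of
    its onset frame and averages the cell values clipped at 1, yielding
    a proportion of maximal saliency; it is omitted when no saliency
    maps are given.
    """
    if gaze.n_fixations < 2:
        raise ValueError("need at least 2 fixations")
    centroid = gaze.positions.mean(axis=0)
    dispersion = float(np.hypot(*(gaze.positions - centroid).T).mean())

    captured = None
    if smaps is not None:
        onsets = gaze.onset_frames(frame_ms)
        vals = [min(1.0, smaps.at(t, x, y))
                for t, (x, y) in zip(onsets, gaze.positions)]
        captured = float(np.mean(vals))

    return SummaryStats(
        observer_id=gaze.observer_id,
        mean_fixation_duration_ms=float(gaze.duration_ms.mean()),
        mean_gaze_shift_px=float(gaze.shift_distances().mean()),
        dispersion_px=dispersion,
        revisit_rate=_revisit_rate(gaze, display_size, window),
        saliency_captured=captured,
    )


def group_summary(records_by_group: dict[str, list[GazeRecord]],
                  smaps: SaliencyMapSeq | None = None,
                  display_size: tuple[int, int] = (480, 360),
                  frame_ms: float = _FRAME_MS) -> pd.DataFrame:
    """Group means (and SDs) of the five statistics, one row per group."""
    rows = []
    for group, records in records_by_group.items():
        stats = [summary_stats(r, smaps, display_size, frame_ms) for r in records]
        row: dict[str, float | str] = {"group": group}
        for name in ("mean_fixation_duration_ms", "mean_gaze_shift_px",
                     "dispersion_px", "revisit_rate", "saliency_captured"):
            vals = [getattr(s, name) for s in stats]
            if any(v is None for v in vals):
                continue
            row[name] = float(np.mean(vals))
            row[name + "_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def rank_curves(res: TrainingResult) -> pd.DataFrame:
    """Mean canonical-RMSE rank per observer group and test epoch.

    Within each (run, network, epoch) the groups' canonical RMSEs are
    ranked ascending (1 = lowest error; ties share the average rank),
    then averaged over runs and networks.  Returned as a frame indexed
    by epoch with one column per group; ranks at each epoch sum to
    k(k+1)/2 per network by construction.
    """
    df = res.df[res.df["condition"] == CANONICAL].copy()
    df["rank"] = df.groupby(["run", "network", "epoch"])["rmse"].rank(method="average")
    return df.pivot_table(index="epoch", columns="observer", values="rank",
                          aggfunc="mean")


def percent_change_curves(res: TrainingResult) -> pd.DataFrame:
    """Percent RMSE increase of each reset condition over canonical.

    100 * (RMSE_reset - RMSE_canonical) / RMSE_canonical per (run,
    network, observer, epoch, condition), averaged over runs and
    networks.  Cells with zero canonical RMSE are excluded.  Returned
    tidy: observer, epoch, condition, percent_change.
    """
    keys = ["run", "network", "observer", "epoch"]
    wide = res.df.pivot_table(index=keys, columns="condition", values="rmse")
    canon = wide[CANONICAL]
    out = []
    for cond in wide.columns:
        if cond == CANONICAL:
            continue
        pc = 100.0 * (wide[cond] - canon) / canon
        pc = pc[canon > 0]
        tidy = pc.reset_index(name="percent_change")
        tidy["condition"] = cond
        out.append(tidy)
    tidy = pd.concat(out, ignore_index=True)
    return (tidy.groupby(["observer", "epoch", "condition"], as_index=False)
            ["percent_change"].mean())


def _mean_rmse(res: TrainingResult) -> pd.DataFrame:
    df = res.df[res.df["condition"] == CANONICAL]
    return df.pivot_table(index="epoch", columns="observer", values="rmse",
                          aggfunc="mean")


def plot_rmse_curves(res: TrainingResult, ax=None):
    """Mean canonical test RMSE over epochs, one line per observer group."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    curves = _mean_rmse(res)
    for obs in curves.columns:
        ax.plot(curves.index, curves[obs], label=obs)
    ax.set_xlabel("training epoch")
    ax.set_ylabel("mean RMSE per pixel")
    ax.legend()
    return ax


def plot_rank_curves(res: TrainingResult, ax=None):
    """Mean rank over epochs (lower rank = lower prediction error)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ranks = rank_curves(res)
    for obs in ranks.columns:
        ax.plot(ranks.index, ranks[obs], label=obs)
    ax.set_xlabel("training epoch")
    ax.set_ylabel("mean rank")
    ax.legend()
    return ax


def plot_percent_change(res: TrainingResult, ax=None):
    """Percent RMSE change per reset condition (one panel, styled lines)."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    pc = percent_change_curves(res)
    for (obs, cond), sub in pc.groupby(["observer", "condition"]):
        ax.plot(sub["epoch"], sub["percent_change"], label=f"{obs} / {cond}")
    ax.set_xlabel("training epoch")
    ax.set_ylabel("% change in RMSE vs canonical")
    ax.legend(fontsize="small")
    return ax
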