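"""Plain-text and image serialization helpers.

Gaze records travel as CSV (one row per fixation), display configs as
YAML, frames as numbered PNGs, saliency maps as per-frame CSV grids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .saliency import SaliencyMapSeq
from .stimulus import DisplayConfig, FrameStack
from .synthetic_gaze import GazeRecord

__all__ = [
    "write_gaze_csv",
    "read_gaze_csv",
    "write_config_yaml",
    "read_config_yaml",
    "write_frames_png",
    "write_saliency_csv",
    "read_saliency_csv",
]


def write_gaze_csv(records: GazeRecord | list[GazeRecord], path) -> None:
    if isinstance(records, GazeRecord):
        records = [records]
    frames = []
    for rec in records:
        frames.append(pd.DataFrame({
            "observer_id": rec.observer_id,
            "fixation_index": np.arange(rec.n_fixations),
            "x_px": rec.x,
            "y_px": rec.y,
            "duration_ms": rec.duration_ms,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gaze_csv(path) -> list[GazeRecord]:
    df = pd.read_csv(path)
    out = []
    for obs, sub in df.groupby("observer_id", sort=False):
        sub = sub.sort_values("fixation_index")
        out.append(GazeRecord(observer_id=str(obs), x=sub["x_px"].to_numpy(),
                              y=sub["y_px"].to_numpy(),
                              duration_ms=sub["duration_ms"].to_numpy()))
    return out


def write_config_yaml(config: DisplayConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)


def read_config_yaml(path) -> DisplayConfig:
    with open(path) as fh:
        return DisplayConfig.from_dict(yaml.safe_load(fh))


def write_frames_png(frames: FrameStack, out_dir) -> None:
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in range(len(frames)):
        img = (np.clip(frames.frame(t), 0, 1) * 255).astype(np.uint8)
        iio.imwrite(out / f"frame_{t:04d}.png", img)


def write_saliency_csv(smaps: SaliencyMapSeq, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in range(smaps.n_frames):
        np.savetxt(out / f"saliency_{t:04d}.csv", smaps.grid(t), delimiter=",")


def read_saliency_csv(in_dir) -> SaliencyMapSeq:
    paths = sorted(Path(in_dir).glob("saliency_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no saliency_*.csv files in {in_dir}")
    return SaliencyMapSeq(maps=np.stack(
        [np.loadtxt(p, delimiter=",") for p in paths]))
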