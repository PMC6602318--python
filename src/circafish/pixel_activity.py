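"""Frame-differencing activity backend.

Locomotion is quantified per tank as the number of ROI pixels whose
intensity changes by more than a threshold between adjacent frames. This
is deliberately simple and fast, but sensitive to background artifacts
(flicker, rolling dark lines); an optional 3x3 median prefilter suppresses
single-pixel-wide artifacts before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ConfigError, DimensionError, EmptyInputError
from .video_io import FrameSequence, TankLayout, TankROI

__all__ = [
    "ActivitySeries",
    "frame_change_count",
    "activity_series",
    "interval_activity",
    "write_activity_csv",
    "read_activity_csv",
]

DEFAULT_THRESHOLD = 20


@dataclass
class ActivitySeries:
    """Changed-pixel counts for one tank, one entry per adjacent frame pair."""

    tank_id: int
    counts: np.ndarray
    threshold_used: float
    fps: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("changed-pixel counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


def frame_change_count(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    roi: TankROI | None = None,
) -> int:
    """Count ROI pixels whose absolute intensity change exceeds ``threshold``."""
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise DimensionError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if roi is not None:
        rows, cols = roi.slices()
        frame_a = frame_a[rows, cols]
        frame_b = frame_b[rows, cols]
    diff = np.abs(frame_a.astype(np.int16) - frame_b.astype(np.int16))
    return int(np.count_nonzero(diff > threshold))


def activity_series(
    seq: FrameSequence,
    layout: TankLayout,
    threshold: float = DEFAULT_THRESHOLD,
    denoise: bool = False,
) -> list[ActivitySeries]:
    """Per-tank changed-pixel counts for every adjacent frame pair.

    With ``denoise`` each frame is passed through a 3x3 median filter
    before differencing.
    """
    if not layout.tanks:
        raise ConfigError("layout has no tanks")
    if seq.n_frames < 2:
        raise EmptyInputError("need at least 2 frames to measure activity")
    layout.validate_bounds(seq.width, seq.height)

    counts = {t.tank_id: np.empty(seq.n_frames - 1, dtype=np.int64) for t in layout.tanks}
    prev = seq.frames[0]
    if denoise:
        prev = median_filter(prev, size=3)
    for i in range(1, seq.n_frames):
        cur = seq.frames[i]
        if denoise:
            cur = median_filter(cur, size=3)
        diff = np.abs(prev.astype(np.int16) - cur.astype(np.int16)) > threshold
        for t in layout.tanks:
            rows, cols = t.slices()
            counts[t.tank_id][i - 1] = int(np.count_nonzero(diff[rows, cols]))
        prev = cur
    return [
        ActivitySeries(tank_id=t.tank_id, counts=counts[t.tank_id],
                       threshold_used=threshold, fps=seq.fps)
        for t in layout.tanks
    ]


def interval_activity(series: ActivitySeries) -> float:
    """Mean changed pixels per frame pair over one recording interval."""
    if len(series) == 0:
        raise EmptyInputError("activity series is empty")
    return float(np.mean(series.counts))


def write_activity_csv(series_list: list[ActivitySeries], path: str | Path) -> None:
    rows = [
        {"tank_id": s.tank_id, "frame_index": i, "changed_pixels": int(c)}
        for s in series_list
        for i, c in enumerate(s.counts)
    ]
    pd.DataFrame(rows, columns=["tank_id", "frame_index", "changed_pixels"]).to_csv(
        path, index=False
    )


def read_activity_csv(path: str | Path, fps: float, threshold: float = float("nan")) -> list[ActivitySeries]:
    df = pd.read_csv(path)
    out = []
    for tank_id, grp in df.groupby("tank_id", sort=True):
        grp = grp.sort_values("frame_index")
        out.append(
            ActivitySeries(
                tank_id=int(tank_id),
                counts=grp["changed_pixels"].to_numpy(),
                threshold_used=threshold,
                fps=fps,
            )
        )
    return out
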