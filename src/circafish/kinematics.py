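"""Per-fish locomotion endpoints computed from a calibrated trajectory.

All angular statistics use absolute turn magnitudes (fish turn both ways;
signed means cancel). Meandering is total |turn| per unit distance
(deg/cm), a scale-aware tortuosity. Steps shorter than
``displacement_epsilon`` contribute zero speed and undefined heading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .tracker import Trajectory

__all__ = [
    "KinematicsConfig",
    "KinematicsSummary",
    "step_speeds",
    "turning_angles",
    "detect_sleep_bouts",
    "summarize",
    "summarize_many",
    "write_kinematics_csv",
]


@dataclass(frozen=True)
class KinematicsConfig:
    """Speed cutoffs and the sleep-bout rule.

    ``v_freeze``/``v_rapid`` partition step speeds into freezing, swimming
    and rapid regimes. A sleep bout is a maximal quiescent run strictly
    longer than ``sleep_min_duration`` seconds.
    """

    v_freeze: float = 1.0
    v_rapid: float = 10.0
    sleep_min_duration: float = 5.0
    displacement_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 <= self.v_freeze < self.v_rapid:
            raise ValueError("require 0 <= v_freeze < v_rapid")
        if self.sleep_min_duration <= 0:
            raise ValueError("sleep_min_duration must be positive")


@dataclass
class KinematicsSummary:
    fish_id: int
    interval_id: int
    total_distance: float
    average_speed: float
    average_angular_velocity: float
    meandering: float
    freezing_ratio: float
    swimming_ratio: float
    rapid_ratio: float
    sleep_bout_count: int
    sleep_time_fraction: float
    degenerate: bool = False
    n_interpolated: int = 0


def _positions(traj: Trajectory | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(traj, Trajectory):
        return traj.positions, traj.fps
    raise TypeError("expected a Trajectory")


def step_speeds(traj: Trajectory) -> np.ndarray:
    """Per-step speeds v_i = ||p_{i+1} - p_i|| * fps (cm/s, length n-1)."""
    pos, fps = _positions(traj)
    if len(pos) < 2:
        raise EmptyInputError("need at least 2 positions for speeds")
    steps = np.diff(pos, axis=0)
    return np.hypot(steps[:, 0], steps[:, 1]) * fps


def turning_angles(traj: Trajectory, eps: float = 1e-6) -> np.ndarray:
    """Signed heading changes in degrees, length n-2, NaN where undefined.

    The angle at p_{i+1} is the signed rotation from segment
    p_i -> p_{i+1} to segment p_{i+1} -> p_{i+2}, in (-180, 180],
    counterclockwise positive in the mathematical (y-up) convention.
    Angles adjacent to a segment shorter than ``eps`` are undefined.
    """
    pos, _ = _positions(traj)
    if len(pos) < 3:
        raise EmptyInputError("need at least 3 positions for turning angles")
    seg = np.diff(pos, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    u, v = seg[:-1], seg[1:]
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    ang = np.degrees(np.arctan2(cross, dot))
    ang[ang <= -180.0] = 180.0
    undefined = (lengths[:-1] < eps) | (lengths[1:] < eps)
    ang[undefined] = np.nan
    return ang


def detect_sleep_bouts(
    speeds: np.ndarray,
    fps: float,
    cfg: KinematicsConfig = KinematicsConfig(),
) -> tuple[list[tuple[int, int]], float]:
    """Find sleep bouts in a step-speed series.

    A bout is a maximal run of consecutive steps with v < v_freeze whose
    duration strictly exceeds ``sleep_min_duration``. Bouts are returned
    as half-open step-index ranges ``(start, end)``; the fraction is total
    bout time over interval time.
    """
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise EmptyInputError("empty speed series")
    quiet = speeds < cfg.v_freeze
    padded = np.concatenate([[False], quiet, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    bouts = [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if (e - s) / fps > cfg.sleep_min_duration
    ]
    total_bout_steps = sum(e - s for s, e in bouts)
    return bouts, total_bout_steps / speeds.size


def summarize(
    traj: Trajectory,
    cfg: KinematicsConfig = KinematicsConfig(),
    interval_id: int = 0,
) -> KinematicsSummary:
    """All locomotion endpoints for one fish over one recording interval."""
    pos, fps = _positions(traj)
    if len(pos) < 3:
        raise EmptyInputError("need at least 3 positions to summarize")

    speeds = step_speeds(traj)
    # sub-epsilon steps are treated as stationary
    step_len = speeds / fps
    speeds = np.where(step_len < cfg.displacement_epsilon, 0.0, speeds)
    total_distance = float(np.sum(speeds) / fps)
    duration = len(speeds) / fps
    average_speed = total_distance / duration

    angles = turning_angles(traj, eps=cfg.displacement_epsilon)
    abs_angles = np.abs(angles[~np.isnan(angles)])
    total_turn = float(abs_angles.sum())
    avg_ang_vel = float(abs_angles.mean() * fps) if abs_angles.size else 0.0

    degenerate = total_distance < cfg.displacement_epsilon
    meandering = 0.0 if degenerate else total_turn / total_distance

    n = speeds.size
    freezing = float(np.count_nonzero(speeds < cfg.v_freeze)) / n
    rapid = float(np.count_nonzero(speeds > cfg.v_rapid)) / n
    swimming = 1.0 - freezing - rapid

    bouts, sleep_fraction = detect_sleep_bouts(speeds, fps, cfg)

    return KinematicsSummary(
        fish_id=traj.fish_id,
        interval_id=interval_id,
        total_distance=total_distance,
        average_speed=average_speed,
        average_angular_velocity=avg_ang_vel,
        meandering=meandering,
        freezing_ratio=freezing,
        swimming_ratio=swimming,
        rapid_ratio=rapid,
        sleep_bout_count=len(bouts),
        sleep_time_fraction=sleep_fraction,
        degenerate=degenerate,
        n_interpolated=traj.n_interpolated,
    )


def summarize_many(
    trajectories: list[Trajectory],
    cfg: KinematicsConfig = KinematicsConfig(),
    interval_id: int = 0,
) -> pd.DataFrame:
    """Tidy table of endpoints, one row per fish."""
    rows = []
    for t in trajectories:
        s = summarize(t, cfg, interval_id)
        rows.append(
            {
                "tank_id": t.tank_id,
                "fish_id": s.fish_id,
                "interval_id": s.interval_id,
                "total_distance_cm": s.total_distance,
                "average_speed_cms": s.average_speed,
                "average_angular_velocity_degs": s.average_angular_velocity,
                "meandering_degcm": s.meandering,
                "freezing_ratio": s.freezing_ratio,
                "swimming_ratio": s.swimming_ratio,
                "rapid_ratio": s.rapid_ratio,
                "sleep_bout_count": s.sleep_bout_count,
                "sleep_time_fraction": s.sleep_time_fraction,
                "n_interpolated": s.n_interpolated,
                "v_freeze_cms": cfg.v_freeze,
                "v_rapid_cms": cfg.v_rapid,
                "sleep_min_duration_s": cfg.sleep_min_duration,
            }
        )
    return pd.DataFrame(rows)


def write_kinematics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
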