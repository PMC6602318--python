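"""Coordinate-extraction backend: background subtraction, blob detection
and proximity linking.

This stands in for an appearance-based multi-animal tracker: identity is
maintained purely by minimum-distance assignment between consecutive
frames. Within-tank identity swaps between close-passing fish are possible
and documented; tank-level aggregates are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .errors import DimensionError, EmptyInputError
from .video_io import FrameSequence, TankLayout

__all__ = [
    "Detection",
    "Trajectory",
    "estimate_background",
    "segment_frame",
    "link_tracks",
    "calibrate",
    "track_video",
    "write_trajectories_csv",
    "read_trajectories_csv",
]

DEFAULT_SEG_THRESHOLD = 30
DEFAULT_MIN_AREA = 10
DEFAULT_MAX_AREA_FRACTION = 0.10
DEFAULT_MAX_JUMP_CM = 5.0
DEFAULT_MAX_GAP = 5


@dataclass(frozen=True)
class Detection:
    """One segmented blob: intensity-weighted centroid in frame pixels."""

    frame_index: int
    tank_id: int
    x: float
    y: float
    area: int


@dataclass
class Trajectory:
    """Per-fish positions, one entry per source frame.

    ``positions`` is (n_frames, 2) float; units are pixels straight out of
    :func:`link_tracks` and centimetres (relative to the tank's top-left
    corner) after :func:`calibrate`. ``missing`` marks frames with no
    detection; after gap-filling those entries still hold usable values
    (interpolated or held), the mask is kept for QC.
    """

    fish_id: int
    tank_id: int
    positions: np.ndarray
    fps: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_interpolated: int = 0
    units: str = "px"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.missing is None:
            self.missing = np.zeros(len(self.positions), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)


def estimate_background(seq: FrameSequence, n_samples: int = 25) -> np.ndarray:
    """Per-pixel median over ``n_samples`` frames evenly spaced in time."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples > seq.n_frames:
        raise ValueError(
            f"n_samples={n_samples} exceeds frame count {seq.n_frames}"
        )
    idx = np.unique(np.linspace(0, seq.n_frames - 1, n_samples).round().astype(int))
    return np.median(seq.frames[idx], axis=0).astype(np.uint8)


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    layout: TankLayout,
    seg_threshold: float = DEFAULT_SEG_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect fish blobs in one frame.

    Foreground is ``|frame - background| > seg_threshold``; 8-connected
    components inside each ROI with area in ``[min_area, max_area]`` become
    detections with absdiff-intensity-weighted centroids. Tanks yielding
    more components than expected keep the largest.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise DimensionError(
            f"frame {frame.shape} vs background {background.shape}"
        )
    absdiff = np.abs(frame.astype(np.int16) - background.astype(np.int16))
    mask = absdiff > seg_threshold

    eight = np.ones((3, 3), dtype=bool)
    detections: list[Detection] = []
    for tank in layout.tanks:
        rows, cols = tank.slices()
        tank_max_area = max_area
        if tank_max_area is None:
            tank_max_area = int(DEFAULT_MAX_AREA_FRACTION * tank.area)
        labels, n_labels = ndi.label(mask[rows, cols], structure=eight)
        if n_labels == 0:
            continue
        flat = labels.ravel()
        areas = np.bincount(flat, minlength=n_labels + 1)[1:]
        weights = absdiff[rows, cols].astype(np.float64)
        yy, xx = np.indices(labels.shape)
        wsum = np.bincount(flat, weights=weights.ravel(), minlength=n_labels + 1)[1:]
        wx = np.bincount(flat, weights=(weights * xx).ravel(), minlength=n_labels + 1)[1:]
        wy = np.bincount(flat, weights=(weights * yy).ravel(), minlength=n_labels + 1)[1:]
        candidates = [
            Detection(
                frame_index=frame_index,
                tank_id=tank.tank_id,
                x=float(wx[i] / wsum[i]) + tank.x_min,
                y=float(wy[i] / wsum[i]) + tank.y_min,
                area=int(areas[i]),
            )
            for i in np.flatnonzero((areas >= min_area) & (areas <= tank_max_area))
        ]
        candidates.sort(key=lambda d: d.area, reverse=True)
        detections.extend(candidates[: tank.expected_fish])
    return detections


class _Track:
    __slots__ = ("positions", "seen", "last_xy", "last_frame")

    def __init__(self, n_frames: int, frame: int, xy: tuple[float, float]):
        self.positions = np.full((n_frames, 2), np.nan)
        self.seen = np.zeros(n_frames, dtype=bool)
        self.observe(frame, xy)

    def observe(self, frame: int, xy: tuple[float, float]) -> None:
        self.positions[frame] = xy
        self.seen[frame] = True
        self.last_xy = xy
        self.last_frame = frame


def _assign(tracks: list[_Track], dets: list[Detection], frame: int,
            max_jump_px: float) -> tuple[list[tuple[int, int]], list[int]]:
    """Match tracks to detections by minimum total distance.

    Returns (matched (track_idx, det_idx) pairs, unmatched det indices).
    """
    if not tracks or not dets:
        return [], list(range(len(dets)))
    cost = np.empty((len(tracks), len(dets)))
    for i, tr in enumerate(tracks):
        for j, d in enumerate(dets):
            cost[i, j] = np.hypot(d.x - tr.last_xy[0], d.y - tr.last_xy[1])
    rows, cols = linear_sum_assignment(cost)
    matched = []
    used = set()
    for i, j in zip(rows, cols):
        gap = frame - tracks[i].last_frame
        if cost[i, j] <= max_jump_px * gap:
            matched.append((i, j))
            used.add(j)
    unmatched = [j for j in range(len(dets)) if j not in used]
    return matched, unmatched


def _fill_gaps(track: _Track, max_gap: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Interpolate short gaps, hold last position through long ones.

    Returns (positions, missing mask, n_interpolated).
    """
    pos = track.positions.copy()
    seen = track.seen
    n = len(pos)
    missing = ~seen
    n_interp = 0
    idx = np.flatnonzero(seen)
    if len(idx) == 0:
        return pos, missing, 0
    # leading/trailing: hold nearest observed position
    pos[: idx[0]] = pos[idx[0]]
    pos[idx[-1] + 1:] = pos[idx[-1]]
    for a, b in zip(idx[:-1], idx[1:]):
        gap = b - a - 1
        if gap == 0:
            continue
        if gap <= max_gap:
            frac = np.arange(1, gap + 1)[:, None] / (gap + 1)
            pos[a + 1: b] = pos[a] + frac * (pos[b] - pos[a])
            n_interp += gap
        else:
            pos[a + 1: b] = pos[a]
    return pos, missing, n_interp


def link_tracks(
    detections: list[list[Detection]],
    layout: TankLayout,
    max_jump_cm: float = DEFAULT_MAX_JUMP_CM,
    max_gap: int = DEFAULT_MAX_GAP,
    fps: float = 30.0,
) -> list[Trajectory]:
    """Link per-frame detections into full-length pixel trajectories.

    ``detections`` holds one list per frame (as from :func:`segment_frame`).
    Exactly ``expected_fish`` trajectories are returned per tank, each with
    one entry per frame; short detection gaps are linearly interpolated,
    long ones hold the last seen position.
    """
    n_frames = len(detections)
    if n_frames == 0:
        raise EmptyInputError("no frames of detections supplied")
    max_jump_px = max_jump_cm * layout.px_per_cm

    trajectories: list[Trajectory] = []
    for tank in layout.tanks:
        per_frame = [
            [d for d in frame_dets if d.tank_id == tank.tank_id]
            for frame_dets in detections
        ]
        tracks: list[_Track] = []
        for f, dets in enumerate(per_frame):
            matched, unmatched = _assign(tracks, dets, f, max_jump_px)
            for i, j in matched:
                tracks[i].observe(f, (dets[j].x, dets[j].y))
            for j in unmatched:
                if len(tracks) < tank.expected_fish:
                    tracks.append(_Track(n_frames, f, (dets[j].x, dets[j].y)))
        tracks.sort(key=lambda t: int(t.seen.sum()), reverse=True)
        tracks = tracks[: tank.expected_fish]
        if not any(t.seen.any() for t in tracks):
            warnings.warn(
                f"tank {tank.tank_id}: no detections in any frame; "
                "emitting all-missing trajectories",
                stacklevel=2,
            )
        for fish_id in range(tank.expected_fish):
            if fish_id < len(tracks):
                pos, missing, n_interp = _fill_gaps(tracks[fish_id], max_gap)
            else:
                pos = np.full((n_frames, 2), np.nan)
                missing = np.ones(n_frames, dtype=bool)
                n_interp = 0
            trajectories.append(
                Trajectory(
                    fish_id=fish_id,
                    tank_id=tank.tank_id,
                    positions=pos,
                    fps=fps,
                    missing=missing,
                    n_interpolated=n_interp,
                    units="px",
                )
            )
    return trajectories


def calibrate(traj_px: Trajectory, px_per_cm: float,
              layout: TankLayout | None = None) -> Trajectory:
    """Convert a pixel trajectory to centimetres.

    If ``layout`` is given, positions are first re-expressed relative to
    the top-left corner of the trajectory's tank ROI, so calibrated
    coordinates span ``[0, tank_width_cm) x [0, tank_height_cm)``.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    pos = traj_px.positions.copy()
    if layout is not None:
        tank = layout.tank(traj_px.tank_id)
        pos[:, 0] -= tank.x_min
        pos[:, 1] -= tank.y_min
    return Trajectory(
        fish_id=traj_px.fish_id,
        tank_id=traj_px.tank_id,
        positions=pos / px_per_cm,
        fps=traj_px.fps,
        missing=traj_px.missing.copy(),
        n_interpolated=traj_px.n_interpolated,
        units="cm",
    )


def track_video(
    seq: FrameSequence,
    layout: TankLayout,
    seg_threshold: float = DEFAULT_SEG_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
    max_area: int | None = None,
    max_jump_cm: float = DEFAULT_MAX_JUMP_CM,
    max_gap: int = DEFAULT_MAX_GAP,
    n_background_samples: int = 25,
    background: np.ndarray | None = None,
) -> list[Trajectory]:
    """Full pipeline: background, per-frame segmentation, linking, calibration.

    ``background`` overrides the per-video median estimate; supply one
    derived from an interval with moving fish when analyzing recordings
    where fish may stay put for the whole clip (e.g. the rest phase of a
    circadian study), otherwise a motionless fish is absorbed into the
    median background and never detected.
    """
    layout.validate_bounds(seq.width, seq.height)
    if background is None:
        n_bg = min(n_background_samples, seq.n_frames)
        background = estimate_background(seq, n_bg)
    detections = [
        segment_frame(frame, background, layout, seg_threshold,
                      min_area, max_area, frame_index=i)
        for i, frame in enumerate(seq.frames)
    ]
    tracks_px = link_tracks(detections, layout, max_jump_cm, max_gap, fps=seq.fps)
    return [calibrate(t, layout.px_per_cm, layout) for t in tracks_px]


def write_trajectories_csv(trajectories: list[Trajectory], path: str | Path) -> None:
    frames_list = []
    for t in trajectories:
        frames_list.append(
            pd.DataFrame(
                {
                    "frame": np.arange(len(t)),
                    "tank_id": t.tank_id,
                    "fish_id": t.fish_id,
                    "x_cm": t.positions[:, 0],
                    "y_cm": t.positions[:, 1],
                    "interpolated": t.missing.astype(int),
                }
            )
        )
    pd.concat(frames_list, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path, fps: float) -> list[Trajectory]:
    """Read a trajectory table of schema frame,tank_id,fish_id,x_cm,y_cm[,interpolated]."""
    df = pd.read_csv(path)
    out = []
    for (tank_id, fish_id), grp in df.groupby(["tank_id", "fish_id"], sort=True):
        grp = grp.sort_values("frame")
        missing = (
            grp["interpolated"].to_numpy().astype(bool)
            if "interpolated" in grp
            else np.zeros(len(grp), dtype=bool)
        )
        out.append(
            Trajectory(
                fish_id=int(fish_id),
                tank_id=int(tank_id),
                positions=grp[["x_cm", "y_cm"]].to_numpy(),
                fps=fps,
                missing=missing,
                n_interpolated=int(missing.sum()),
                units="cm",
            )
        )
    return out
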