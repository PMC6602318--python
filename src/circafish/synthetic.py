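"""Ground-truthed synthetic behavior: trajectory simulation and video
rendering.

The activity model is a two-state (active/quiescent) Markov switching
process discretized at frame resolution, with phase-dependent mean dwell
times. Active motion is a correlated random walk: per-frame lognormal
speed, wrapped-normal heading increments, reflecting tank walls. This is
the minimal structure that produces both phase-dependent mean activity and
multi-second quiescent (sleep-like) bouts.

Each fish consumes an RNG stream derived from ``(seed..., fish_id)``, so
adding fish never perturbs existing trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circadian import LightSchedule
from .errors import RenderError
from .tracker import Trajectory
from .video_io import FrameSequence, TankLayout, TankROI, write_frames

__all__ = [
    "PhaseBehavior",
    "BehaviorParams",
    "RenderParams",
    "SimulationTruth",
    "diurnal_params",
    "nocturnal_params",
    "grid_layout",
    "simulate_trajectory",
    "render_video",
    "iter_study_intervals",
    "make_study_fixture",
]


@dataclass(frozen=True)
class PhaseBehavior:
    """Behavior parameters for one schedule phase."""

    mean_dwell_active_s: float = 30.0
    mean_dwell_quiescent_s: float = 5.0
    active_speed_mean_cms: float = 6.0
    active_speed_sigma: float = 0.4  # lognormal shape (log-space sd)
    quiescent_speed_cms: float = 0.0
    turn_sigma_deg: float = 25.0

    def __post_init__(self) -> None:
        if self.mean_dwell_active_s <= 0 or self.mean_dwell_quiescent_s <= 0:
            raise ValueError("dwell means must be positive")
        if self.active_speed_mean_cms < 0 or self.quiescent_speed_cms < 0:
            raise ValueError("speeds must be non-negative")


@dataclass(frozen=True)
class BehaviorParams:
    """Full behavioral specification for one simulated tank of fish."""

    light: PhaseBehavior = PhaseBehavior()
    dark: PhaseBehavior = PhaseBehavior()
    tank_w_cm: float = 20.0
    tank_h_cm: float = 10.0
    fps: float = 30.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tank_w_cm <= 0 or self.tank_h_cm <= 0:
            raise ValueError("tank dimensions must be positive")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")

    def phase(self, name: str) -> PhaseBehavior:
        return self.light if name == "light" else self.dark


def diurnal_params(**overrides) -> BehaviorParams:
    """Zebrafish-like: vigorous swimming in light, long quiescent bouts in dark."""
    return BehaviorParams(
        light=PhaseBehavior(
            mean_dwell_active_s=40.0,
            mean_dwell_quiescent_s=4.0,
            active_speed_mean_cms=6.0,
        ),
        dark=PhaseBehavior(
            mean_dwell_active_s=3.0,
            mean_dwell_quiescent_s=30.0,
            active_speed_mean_cms=1.5,
        ),
        **overrides,
    )


def nocturnal_params(**overrides) -> BehaviorParams:
    """Catfish-like: the mirror image of :func:`diurnal_params`."""
    p = diurnal_params(**overrides)
    return replace(p, light=p.dark, dark=p.light)


@dataclass(frozen=True)
class RenderParams:
    """How trajectories become pixels."""

    px_per_cm: float | None = None  # None: use the layout's calibration
    fish_radius_px: float = 3.0
    fish_intensity: float = 30.0
    background_intensity: float = 150.0
    noise_sigma: float = 5.0
    artifact_mode: str = "none"  # 'none' | 'dark_lines'
    artifact_intensity: float = 60.0
    artifact_period: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fish_intensity <= 255 and 0 <= self.background_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.fish_intensity == self.background_intensity:
            raise ValueError("fish must contrast with the background")
        if self.artifact_mode not in ("none", "dark_lines"):
            raise ValueError(f"unknown artifact mode {self.artifact_mode!r}")


@dataclass
class SimulationTruth:
    """Everything the generator knows, for use as a test oracle."""

    positions_cm: np.ndarray  # (n_fish, n_frames, 2)
    active: np.ndarray  # (n_fish, n_frames) bool
    speeds_cms: np.ndarray  # (n_fish, n_frames) realized per-frame speed
    phases: np.ndarray  # (n_frames,) 'light'/'dark'
    seed: int

    def mean_active_speed(self, phase: str | None = None) -> float:
        sel = self.active.copy()
        if phase is not None:
            sel &= self.phases == phase
        if not sel.any():
            return float("nan")
        return float(self.speeds_cms[sel].mean())

    def quiescent_fraction(self, phase: str | None = None) -> float:
        mask = np.ones_like(self.active) if phase is None else np.broadcast_to(
            self.phases == phase, self.active.shape
        )
        return float((~self.active)[mask].mean())


def _simulate_fish(
    params: BehaviorParams,
    phases: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(phases)
    dt = 1.0 / params.fps
    w, h = params.tank_w_cm, params.tank_h_cm

    is_light = phases == "light"
    ph = (params.light, params.dark)

    # pre-draw all randomness so the stream is frame-indexed and stable
    u_switch = rng.random(n)
    z_speed = rng.standard_normal(n)
    z_turn = rng.standard_normal(n)
    x0, y0 = rng.random(2)
    heading = rng.random() * 2 * math.pi
    start_active = rng.random() < 0.5

    # per-phase switching probabilities and lognormal parameters
    p_leave_active = np.empty(2)
    p_leave_quiet = np.empty(2)
    mu = np.empty(2)
    sigma = np.empty(2)
    qspeed = np.empty(2)
    turn_sd = np.empty(2)
    for k, b in enumerate(ph):
        p_leave_active[k] = 1.0 - math.exp(-dt / b.mean_dwell_active_s)
        p_leave_quiet[k] = 1.0 - math.exp(-dt / b.mean_dwell_quiescent_s)
        sigma[k] = b.active_speed_sigma
        mu[k] = (
            math.log(b.active_speed_mean_cms) - 0.5 * sigma[k] ** 2
            if b.active_speed_mean_cms > 0
            else -math.inf
        )
        qspeed[k] = b.quiescent_speed_cms
        turn_sd[k] = math.radians(b.turn_sigma_deg)

    pos = np.empty((n, 2))
    active = np.empty(n, dtype=bool)
    speeds = np.empty(n)

    x, y = x0 * w, y0 * h
    state = start_active
    for i in range(n):
        k = 0 if is_light[i] else 1
        if state:
            if u_switch[i] < p_leave_active[k]:
                state = False
        else:
            if u_switch[i] < p_leave_quiet[k]:
                state = True
        active[i] = state
        if state:
            v = math.exp(mu[k] + sigma[k] * z_speed[i]) if mu[k] > -math.inf else 0.0
            heading += turn_sd[k] * z_turn[i]
        else:
            v = qspeed[k]
        speeds[i] = v
        step = v * dt
        x += step * math.cos(heading)
        y += step * math.sin(heading)
        if x < 0:
            x = -x
            heading = math.pi - heading
        elif x > w:
            x = 2 * w - x
            heading = math.pi - heading
        if y < 0:
            y = -y
            heading = -heading
        elif y > h:
            y = 2 * h - y
            heading = -heading
        pos[i] = (x, y)
    return pos, active, speeds


def simulate_trajectory(
    params: BehaviorParams,
    schedule: LightSchedule,
    n_fish: int = 1,
    start_hour: float = 12.0,
    tank_id: int = 0,
    seed_path: tuple[int, ...] | None = None,
) -> tuple[list[Trajectory], SimulationTruth]:
    """Simulate ``n_fish`` trajectories in one tank.

    ``start_hour`` is the clock time of the first frame; the schedule
    determines each frame's phase. Fully reproducible: fish ``i`` draws
    from the stream keyed by ``(*seed_path or (params.seed,), i)``.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    n = int(round(params.duration_s * params.fps))
    if n < 1:
        raise ValueError("duration too short for one frame")
    hours = start_hour + np.arange(n) / (3600.0 * params.fps)
    phases = np.array([schedule.phase_of(t) for t in hours])

    base = seed_path if seed_path is not None else (params.seed,)
    all_pos = np.empty((n_fish, n, 2))
    all_active = np.empty((n_fish, n), dtype=bool)
    all_speeds = np.empty((n_fish, n))
    trajs = []
    for fish in range(n_fish):
        rng = np.random.default_rng((*base, fish))
        pos, active, speeds = _simulate_fish(params, phases, rng)
        all_pos[fish] = pos
        all_active[fish] = active
        all_speeds[fish] = speeds
        trajs.append(
            Trajectory(
                fish_id=fish,
                tank_id=tank_id,
                positions=pos.copy(),
                fps=params.fps,
                units="cm",
            )
        )
    truth = SimulationTruth(
        positions_cm=all_pos,
        active=all_active,
        speeds_cms=all_speeds,
        phases=phases,
        seed=params.seed,
    )
    return trajs, truth


def grid_layout(
    n_tanks: int = 6,
    fish_per_tank: int = 3,
    tank_w_cm: float = 20.0,
    tank_h_cm: float = 10.0,
    px_per_cm: float = 3.0,
    margin_px: int = 5,
    n_cols: int = 2,
) -> tuple[TankLayout, int, int]:
    """Arrange tanks in a grid; returns (layout, frame_width, frame_height)."""
    tw = int(round(tank_w_cm * px_per_cm))
    th = int(round(tank_h_cm * px_per_cm))
    n_rows = -(-n_tanks // n_cols)
    tanks = []
    for i in range(n_tanks):
        r, c = divmod(i, n_cols)
        x0 = margin_px + c * (tw + margin_px)
        y0 = margin_px + r * (th + margin_px)
        tanks.append(
            TankROI(tank_id=i, x_min=x0, y_min=y0, x_max=x0 + tw, y_max=y0 + th,
                    expected_fish=fish_per_tank)
        )
    width = margin_px + n_cols * (tw + margin_px)
    height = margin_px + n_rows * (th + margin_px)
    return TankLayout(tanks=tanks, px_per_cm=px_per_cm), width, height


def _draw_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    """Anti-aliased disk composited onto ``img`` in place."""
    h, w = img.shape
    x0, x1 = int(math.floor(cx - r - 1)), int(math.ceil(cx + r + 2))
    y0, y1 = int(math.floor(cy - r - 1)), int(math.ceil(cy + r + 2))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cover = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += cover * (value - patch)


def render_video(
    trajs: list[Trajectory],
    layout: TankLayout,
    rp: RenderParams = RenderParams(),
    frame_width: int | None = None,
    frame_height: int | None = None,
) -> FrameSequence:
    """Render cm trajectories into an 8-bit grayscale frame sequence."""
    if not trajs:
        raise ValueError("no trajectories to render")
    n = len(trajs[0])
    if any(len(t) != n for t in trajs):
        raise ValueError("all trajectories must have the same length")
    ppc = rp.px_per_cm if rp.px_per_cm is not None else layout.px_per_cm
    margin = min(min(t.x_min for t in layout.tanks),
                 min(t.y_min for t in layout.tanks))
    width = frame_width or max(t.x_max for t in layout.tanks) + margin
    height = frame_height or max(t.y_max for t in layout.tanks) + margin

    px = np.empty((len(trajs), n, 2))
    for j, t in enumerate(trajs):
        tank = layout.tank(t.tank_id)
        px[j, :, 0] = tank.x_min + t.positions[:, 0] * ppc
        px[j, :, 1] = tank.y_min + t.positions[:, 1] * ppc
    if np.any(px[:, :, 0] < -0.5) or np.any(px[:, :, 0] > width - 0.5) or \
       np.any(px[:, :, 1] < -0.5) or np.any(px[:, :, 1] > height - 0.5):
        raise RenderError("trajectory leaves the frame; check layout/calibration")

    rng = np.random.default_rng(rp.seed)
    fps = trajs[0].fps
    frames = np.empty((n, height, width), dtype=np.uint8)
    for i in range(n):
        img = np.full((height, width), rp.background_intensity, dtype=np.float64)
        for j in range(len(trajs)):
            _draw_disk(img, px[j, i, 0], px[j, i, 1], rp.fish_radius_px,
                       rp.fish_intensity)
        if rp.artifact_mode == "dark_lines":
            rows = np.arange(height)
            img[(rows + i) % rp.artifact_period == 0, :] -= rp.artifact_intensity
        if rp.noise_sigma > 0:
            img += rng.normal(0.0, rp.noise_sigma, img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=fps)


def iter_study_intervals(
    profile: str,
    schedule: LightSchedule,
    n_tanks: int = 6,
    fish_per_tank: int = 3,
    hours: int = 24,
    seed: int = 0,
    fps: float = 30.0,
    duration_s: float = 60.0,
    px_per_cm: float = 3.0,
    rp: RenderParams | None = None,
    start_hour: float = 8.0,
    render: bool = True,
):
    """Yield one (hour_index, clock_hour, phase, seq, trajs, truths) per interval.

    ``trajs`` holds every tank's trajectories for that interval; ``truths``
    maps tank_id -> SimulationTruth. With ``render=False`` the sequence is
    None (trajectory-only studies are much faster).
    """
    if profile == "diurnal":
        base_params = diurnal_params(fps=fps, duration_s=duration_s)
    elif profile == "nocturnal":
        base_params = nocturnal_params(fps=fps, duration_s=duration_s)
    else:
        raise ValueError("profile must be 'diurnal' or 'nocturnal'")
    layout, width, height = grid_layout(
        n_tanks, fish_per_tank,
        tank_w_cm=base_params.tank_w_cm, tank_h_cm=base_params.tank_h_cm,
        px_per_cm=px_per_cm,
    )
    rp = rp or RenderParams(seed=seed)
    for hour in range(hours):
        clock = (start_hour + hour) % 24.0
        phase = schedule.phase_of(clock)
        all_trajs: list[Trajectory] = []
        truths: dict[int, SimulationTruth] = {}
        for tank in layout.tanks:
            trajs, truth = simulate_trajectory(
                base_params,
                schedule,
                n_fish=fish_per_tank,
                start_hour=clock,
                tank_id=tank.tank_id,
                seed_path=(seed, hour, tank.tank_id),
            )
            all_trajs.extend(trajs)
            truths[tank.tank_id] = truth
        seq = None
        if render:
            seq = render_video(
                all_trajs, layout,
                replace(rp, seed=rp.seed + hour * 7919),
                frame_width=width, frame_height=height,
            )
        yield hour, clock, phase, seq, all_trajs, truths


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def make_study_fixture(
    profile: str,
    out_dir: str | Path,
    n_tanks: int = 6,
    fish_per_tank: int = 3,
    hours: int = 24,
    seed: int = 0,
    fps: float = 30.0,
    duration_s: float = 60.0,
    px_per_cm: float = 3.0,
    schedule: LightSchedule | None = None,
    video_format: str = "tif",
) -> Path:
    """Write a full study fixture: one video per hour plus truth tables.

    Layout: ``hour_HH.tif`` (or ``.avi``), ``truth_traj.csv``,
    ``truth_states.csv`` and ``fixture_config.toml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = schedule or LightSchedule()
    layout, _, _ = grid_layout(n_tanks, fish_per_tank, px_per_cm=px_per_cm)

    traj_rows = []
    state_rows = []
    for hour, clock, phase, seq, trajs, truths in iter_study_intervals(
        profile, schedule, n_tanks, fish_per_tank, hours, seed,
        fps, duration_s, px_per_cm,
    ):
        write_frames(seq, out_dir / f"hour_{hour:02d}.{video_format}")
        for t in trajs:
            truth = truths[t.tank_id]
            nf = len(t)
            traj_rows.append(
                pd.DataFrame(
                    {
                        "hour": hour,
                        "frame": np.arange(nf),
                        "tank_id": t.tank_id,
                        "fish_id": t.fish_id,
                        "x_cm": t.positions[:, 0],
                        "y_cm": t.positions[:, 1],
                    }
                )
            )
            state_rows.append(
                pd.DataFrame(
                    {
                        "hour": hour,
                        "frame": np.arange(nf),
                        "tank_id": t.tank_id,
                        "fish_id": t.fish_id,
                        "active": truth.active[t.fish_id].astype(int),
                        "phase": phase,
                    }
                )
            )
    pd.concat(traj_rows, ignore_index=True).to_csv(out_dir / "truth_traj.csv", index=False)
    pd.concat(state_rows, ignore_index=True).to_csv(out_dir / "truth_states.csv", index=False)

    lines = ["[study]"]
    for k, v in dict(
        profile=profile, n_tanks=n_tanks, fish_per_tank=fish_per_tank,
        hours=hours, seed=seed, fps=fps, duration_s=duration_s,
    ).items():
        lines.append(f"{k} = {_toml_value(v)}")
    lines += ["", "[layout]", f"px_per_cm = {_toml_value(px_per_cm)}"]
    for t in layout.tanks:
        lines += [
            "", "[[layout.tanks]]",
            f"tank_id = {t.tank_id}",
            f"x_min = {t.x_min}", f"y_min = {t.y_min}",
            f"x_max = {t.x_max}", f"y_max = {t.y_max}",
            f"expected_fish = {t.expected_fish}",
        ]
    lines += [
        "", "[schedule]",
        f"lights_on_hour = {_toml_value(schedule.lights_on_hour)}",
        f"lights_off_hour = {_toml_value(schedule.lights_off_hour)}",
        f"recording_interval_min = {_toml_value(schedule.recording_interval_min)}",
        f"recording_duration_s = {_toml_value(schedule.recording_duration_s)}",
    ]
    (out_dir / "fixture_config.toml").write_text("\n".join(lines) + "\n")
    return out_dir
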