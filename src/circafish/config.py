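"""TOML configuration: tank layout, light schedule and analysis knobs."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .circadian import LightSchedule
from .errors import ConfigError
from .kinematics import KinematicsConfig
from .video_io import TankLayout, TankROI


@dataclass
class AnalysisConfig:
    layout: TankLayout
    schedule: LightSchedule = field(default_factory=LightSchedule)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    pixel_activity: dict = field(default_factory=dict)
    tracker: dict = field(default_factory=dict)


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse an analysis TOML config.

    Expected sections: ``[layout]`` with ``px_per_cm`` and a
    ``[[layout.tanks]]`` array, optional ``[schedule]``, ``[kinematics]``,
    ``[pixel_activity]`` and ``[tracker]`` tables.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    layout_tbl = raw.get("layout")
    if not layout_tbl or "tanks" not in layout_tbl:
        raise ConfigError(f"{path}: missing [layout] with [[layout.tanks]]")
    if "px_per_cm" not in layout_tbl:
        raise ConfigError(f"{path}: layout.px_per_cm is required (no default)")
    tanks = [
        TankROI(
            tank_id=int(t["tank_id"]),
            x_min=int(t["x_min"]),
            y_min=int(t["y_min"]),
            x_max=int(t["x_max"]),
            y_max=int(t["y_max"]),
            expected_fish=int(t.get("expected_fish", 1)),
        )
        for t in layout_tbl["tanks"]
    ]
    layout = TankLayout(tanks=tanks, px_per_cm=float(layout_tbl["px_per_cm"]))

    sched_tbl = raw.get("schedule", {})
    schedule = LightSchedule(
        lights_on_hour=float(sched_tbl.get("lights_on_hour", 8.0)),
        lights_off_hour=float(sched_tbl.get("lights_off_hour", 20.0)),
        recording_interval_min=float(sched_tbl.get("recording_interval_min", 60.0)),
        recording_duration_s=float(sched_tbl.get("recording_duration_s", 60.0)),
    )

    kin_tbl = raw.get("kinematics", {})
    kin = KinematicsConfig(
        v_freeze=float(kin_tbl.get("v_freeze", 1.0)),
        v_rapid=float(kin_tbl.get("v_rapid", 10.0)),
        sleep_min_duration=float(kin_tbl.get("sleep_min_duration", 5.0)),
        displacement_epsilon=float(kin_tbl.get("displacement_epsilon", 1e-6)),
    )

    return AnalysisConfig(
        layout=layout,
        schedule=schedule,
        kinematics=kin,
        pixel_activity=dict(raw.get("pixel_activity", {})),
        tracker=dict(raw.get("tracker", {})),
    )
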