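"""Light/dark profile assembly and the statistical toolkit.

Covers min-max normalization to percent, Spearman rank correlation (exact
permutation p for small n), Welch's unpaired t-test, and many-to-one
(Dunnett-style) comparisons with a seeded Monte-Carlo family-wise
adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateNormalizationError,
    EmptyInputError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

__all__ = [
    "LightSchedule",
    "CircadianProfile",
    "TestResult",
    "assemble_profile",
    "phase_means",
    "minmax_normalize",
    "spearman",
    "welch_t",
    "dunnett",
]

EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class LightSchedule:
    """Lights-on/off clock hours plus the recording cadence."""

    lights_on_hour: float = 8.0
    lights_off_hour: float = 20.0
    recording_interval_min: float = 60.0
    recording_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.lights_on_hour < 24 and 0 <= self.lights_off_hour < 24):
            raise ValueError("lights_on/off must lie in [0, 24)")
        if self.lights_on_hour == self.lights_off_hour:
            raise ValueError("lights_on and lights_off must differ")
        if self.recording_interval_min <= 0 or self.recording_duration_s <= 0:
            raise ValueError("recording cadence must be positive")

    @property
    def light_hours(self) -> float:
        return (self.lights_off_hour - self.lights_on_hour) % 24

    def phase_of(self, clock_hour: float) -> str:
        """'light' iff clock time falls in [lights_on, lights_off) mod 24."""
        t = clock_hour % 24
        if self.lights_on_hour < self.lights_off_hour:
            in_light = self.lights_on_hour <= t < self.lights_off_hour
        else:
            in_light = t >= self.lights_on_hour or t < self.lights_off_hour
        return "light" if in_light else "dark"


@dataclass
class CircadianProfile:
    """One metric series over the recording, labeled light/dark."""

    subject_id: str
    metric_name: str
    times_h: np.ndarray
    values: np.ndarray
    phases: np.ndarray  # array of 'light'/'dark'

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.phases = np.asarray(self.phases)
        if not (len(self.times_h) == len(self.values) == len(self.phases)):
            raise ValueError("times, values and phases must align")
        if len(self.times_h) > 1 and not np.all(np.diff(self.times_h) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "metric": self.metric_name,
                "time_h": self.times_h,
                "phase": self.phases,
                "value": self.values,
            }
        )


@dataclass
class TestResult:
    test_name: str
    statistic: float
    degrees_of_freedom: float
    p_value: float
    comparison: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def assemble_profile(
    interval_metrics,
    schedule: LightSchedule,
    start_clock_time: float = 0.0,
    subject_id: str = "subject",
    metric_name: str = "activity",
) -> CircadianProfile:
    """Attach timestamps and light/dark labels to an ordered metric series.

    Sample k is stamped ``start_clock_time + k * recording_interval`` and
    labeled by the schedule's half-open convention.
    """
    values = np.asarray(list(interval_metrics), dtype=float)
    step_h = schedule.recording_interval_min / 60.0
    times = start_clock_time + step_h * np.arange(len(values))
    phases = np.array([schedule.phase_of(t) for t in times])
    return CircadianProfile(subject_id, metric_name, times, values, phases)


def phase_means(profile: CircadianProfile) -> tuple[float, float, str]:
    """(light mean, dark mean, diurnal/nocturnal/ambiguous classification)."""
    light = profile.values[profile.phases == "light"]
    dark = profile.values[profile.phases == "dark"]
    if light.size == 0 or dark.size == 0:
        raise InsufficientDataError(
            "profile must contain at least one sample in each phase"
        )
    lm, dm = float(light.mean()), float(dark.mean())
    if lm > dm:
        cls = "diurnal"
    elif dm > lm:
        cls = "nocturnal"
    else:
        cls = "ambiguous"
    return lm, dm, cls


def minmax_normalize(values) -> np.ndarray:
    """Rescale so the series minimum maps to 0% and the maximum to 100%."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise EmptyInputError("need at least 2 values to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateNormalizationError(
            "min-max normalization of a constant series is undefined"
        )
    return (x - lo) / (hi - lo) * 100.0


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    return float(rx @ ry / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is exact (full enumeration of rank permutations)
    for n <= 8 and uses the t-distribution approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation of a constant series is undefined")

    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)

    if n <= EXACT_SPEARMAN_MAX_N:
        target = abs(rho) - 1e-12
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho_of_ranks(rx, np.array(perm))) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, min(p, 1.0)


def welch_t(x, y, comparison: str = "") -> TestResult:
    """Unpaired t-test with Welch's correction (Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult("welch_t", 0.0, float(x.size + y.size - 2), 1.0, comparison)
        raise ValueError("both samples are constant with different means")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return TestResult("welch_t", float(t), float(df), float(min(p, 1.0)), comparison)


def _many_to_one_t(groups: list[np.ndarray], control: int) -> tuple[np.ndarray, float, float]:
    """Per-group t against the control, with variance pooled over all groups."""
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df = int(sizes.sum()) - k
    s2 = ss / df
    ts = np.array(
        [
            (means[i] - means[control])
            / math.sqrt(s2 * (1 / sizes[i] + 1 / sizes[control]))
            for i in range(k)
            if i != control
        ]
    )
    return ts, s2, df


def dunnett(
    groups,
    control_index: int = 0,
    alpha: float = 0.05,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> list[TestResult]:
    """Many-to-one comparisons against a control group.

    Family-wise adjusted p-values come from the seeded Monte-Carlo null
    distribution of the maximum |t| across comparisons, resampling all
    groups from one normal population (equal means, pooled variance).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not 0 <= control_index < len(groups):
        raise ValueError(f"control index {control_index} out of range")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")

    ts, _, df = _many_to_one_t(groups, control_index)

    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    n_total = offsets[-1]
    k = len(groups)
    rng = np.random.default_rng(seed)

    # vectorized null: standard-normal draws suffice (t is scale-free)
    max_abs_t = np.empty(mc_reps)
    chunk = max(1, min(mc_reps, 20_000_000 // max(n_total, 1)))
    done = 0
    while done < mc_reps:
        m = min(chunk, mc_reps - done)
        x = rng.standard_normal((m, n_total))
        gmeans = np.empty((m, k))
        ss = np.zeros(m)
        for i in range(k):
            block = x[:, offsets[i]:offsets[i + 1]]
            gmeans[:, i] = block.mean(axis=1)
            ss += ((block - gmeans[:, i][:, None]) ** 2).sum(axis=1)
        s2 = ss / df
        cols = [i for i in range(k) if i != control_index]
        tmat = np.abs(
            (gmeans[:, cols] - gmeans[:, [control_index]])
            / np.sqrt(
                s2[:, None]
                * np.array([1 / sizes[i] + 1 / sizes[control_index] for i in cols])
            )
        )
        max_abs_t[done:done + m] = tmat.max(axis=1)
        done += m

    results = []
    comp_indices = [i for i in range(k) if i != control_index]
    for t, gi in zip(ts, comp_indices):
        p_adj = (1 + int(np.count_nonzero(max_abs_t >= abs(t)))) / (mc_reps + 1)
        results.append(
            TestResult(
                test_name="dunnett_mc",
                statistic=float(t),
                degrees_of_freedom=float(df),
                p_value=float(min(p_adj, 1.0)),
                comparison=f"group{gi} vs control(group{control_index})",
            )
        )
    return results


def plot_profile(profile: CircadianProfile, path=None):
    """Simple light/dark-shaded line plot of one circadian profile."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.times_h, profile.values, "-o", ms=3, color="black")
    dark = profile.phases == "dark"
    step = np.median(np.diff(profile.times_h)) if len(profile) > 1 else 1.0
    for t, d in zip(profile.times_h, dark):
        if d:
            ax.axvspan(t - step / 2, t + step / 2, color="0.85", zorder=0)
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel(profile.metric_name)
    ax.set_title(profile.subject_id)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
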