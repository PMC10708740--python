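"""Joint-angle traces, stage segmentation and the synthetic trial generator.

A seat-assembly trial is a repeated cycle of three stages: lift the seat
at the pick-up point, carry it 3 m to the vehicle body, then hold a bent
posture for ~10 s of static assembly work.  An inertial motion-capture
suit reports body-segment angles at 60 Hz; this module models those
traces, splits them into stages, and -- because real capture hardware is
out of scope -- provides a seeded generator that emulates one trial of
the 2 (body height) x 3 (seat weight) protocol so the scoring engines
can be exercised end to end.

Segmentation is rule based and deliberately simple: frames with the
walking flag set are carrying; within the remaining runs, sustained
trunk-flexion motion marks lifting and sustained stillness marks the
static hold.  All thresholds are configuration, not physiology: the
capture platform that produced the original per-stage times never
published its splitting rules, so this rule set is an explicit,
overridable stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANGLE_CHANNELS",
    "JointAngleFrame",
    "JointAngleTrace",
    "StageSegment",
    "StageDurations",
    "SynthTrialSpec",
    "SegmenterConfig",
    "generate_trial",
    "segment_stages",
    "stage_durations",
    "generate_oxi_pair",
    "read_trace_csv",
    "write_trace_csv",
]

#: angle channels required by the OWAS and RULA scoring engines (degrees;
#: flexion positive forward)
ANGLE_CHANNELS = (
    "trunk_flexion",
    "trunk_twist",
    "trunk_side_bend",
    "upper_arm_elevation_left",
    "upper_arm_elevation_right",
    "lower_arm_flexion_left",
    "lower_arm_flexion_right",
    "wrist_flexion_left",
    "wrist_flexion_right",
    "wrist_twist_left",
    "wrist_twist_right",
    "neck_flexion",
    "knee_flexion_left",
    "knee_flexion_right",
)

SUPPORT_FLAGS = ("both_feet_on_ground", "walking")

STAGES = ("lifting", "carrying", "static")


@dataclass
class JointAngleFrame:
    """One time-stamped posture: named segment angles plus support flags."""

    time: float
    angles: dict[str, float]
    both_feet_on_ground: bool = True
    walking: bool = False

    def require(self, channel: str) -> float:
        if channel not in self.angles:
            raise KeyError(f"frame is missing required angle channel {channel!r}")
        return self.angles[channel]


class JointAngleTrace:
    """A time-ordered sequence of posture frames, stored column-wise.

    Backed by numpy arrays for vectorised segmentation; iterating yields
    :class:`JointAngleFrame` views for per-frame scoring.
    """

    def __init__(
        self,
        times: np.ndarray,
        angles: dict[str, np.ndarray],
        both_feet_on_ground: np.ndarray,
        walking: np.ndarray,
    ):
        self.times = np.asarray(times, dtype=float)
        if self.times.size == 0:
            raise ValueError("trace must contain at least one frame")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be non-negative and strictly increasing")
        self.angles = {k: np.asarray(v, dtype=float) for k, v in angles.items()}
        for name, col in self.angles.items():
            if col.shape != self.times.shape:
                raise ValueError(f"angle channel {name!r} length mismatch")
            if not np.all(np.isfinite(col)):
                raise ValueError(f"angle channel {name!r} contains non-finite values")
        self.both_feet_on_ground = np.asarray(both_feet_on_ground, dtype=bool)
        self.walking = np.asarray(walking, dtype=bool)

    def __len__(self) -> int:
        return self.times.size

    def __iter__(self) -> Iterator[JointAngleFrame]:
        for i in range(len(self)):
            yield self.frame(i)

    def frame(self, i: int) -> JointAngleFrame:
        return JointAngleFrame(
            time=float(self.times[i]),
            angles={k: float(v[i]) for k, v in self.angles.items()},
            both_feet_on_ground=bool(self.both_feet_on_ground[i]),
            walking=bool(self.walking[i]),
        )

    @property
    def duration(self) -> float:
        """Covered time, counting one sample interval for the last frame."""
        if len(self) == 1:
            return 0.0
        dt = float(np.median(np.diff(self.times)))
        return float(self.times[-1] - self.times[0] + dt)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for k, v in self.angles.items():
            df[k] = v
        df["both_feet_on_ground"] = self.both_feet_on_ground.astype(int)
        df["walking"] = self.walking.astype(int)
        return df


@dataclass(frozen=True)
class StageSegment:
    """A contiguous run of one stage within a trace."""

    stage: str  # lifting | carrying | static
    start: float  # s
    end: float  # s

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.end > self.start:
            raise ValueError("segment end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class StageDurations:
    """Total seconds per stage; the t_i of the time-weighted fusion."""

    lifting: float = 0.0
    carrying: float = 0.0
    static: float = 0.0

    def __post_init__(self):
        if min(self.lifting, self.carrying, self.static) < 0:
            raise ValueError("durations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lifting, self.carrying, self.static])

    @property
    def total(self) -> float:
        return self.lifting + self.carrying + self.static


@dataclass(frozen=True)
class SynthTrialSpec:
    """Parameters of one synthetic assembly trial.

    Defaults mirror the laboratory protocol: 3 m carry, 10 s static
    hold, 60 Hz capture.  ``cycle_count`` controls trace length; a full
    30-min session at the default timing is ~106 cycles.
    """

    seed: int
    seat_weight: float = 14.0  # kg
    body_height: float = 45.0  # cm, vehicle-body height off the ground
    cycle_count: int = 3
    sample_rate: float = 60.0  # Hz
    carry_distance: float = 3.0  # m
    static_hold: float = 10.0  # s
    lift_duration: float = 4.0  # s, floor grab to upright with load
    walk_speed: float = 1.0  # m/s

    def __post_init__(self):
        if self.cycle_count < 1:
            raise ValueError("cycle_count must be at least 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.lift_duration <= 0 or self.walk_speed <= 0 or self.static_hold <= 0:
            raise ValueError("stage timing parameters must be positive")

    @property
    def carry_duration(self) -> float:
        return self.carry_distance / self.walk_speed

    @property
    def cycle_duration(self) -> float:
        return self.lift_duration + self.carry_duration + self.static_hold


def _lift_profile(phase: np.ndarray, peak: float, base: float) -> np.ndarray:
    # half-sine bend-and-rise: max flexion rate at the segment boundaries,
    # which keeps motion-based boundary detection sharp
    return base + (peak - base) * np.sin(np.pi * phase)


def generate_trial(spec: SynthTrialSpec) -> tuple[JointAngleTrace, list[StageSegment]]:
    """Emulate one trial; returns the trace and ground-truth segments.

    Deterministic for a given spec.  A lower vehicle body forces a deeper
    bend: both the lifting peak and the static-hold trunk flexion
    increase as ``body_height`` decreases.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    n_per_cycle = int(round(spec.cycle_duration * spec.sample_rate))
    n = n_per_cycle * spec.cycle_count
    times = np.arange(n) * dt

    lift_peak = 90.0 - 0.3 * spec.body_height  # deg
    static_flexion = 60.0 - 0.6 * spec.body_height  # deg
    load_strain = spec.seat_weight / 20.0  # 0..1 over the protocol range

    flexion = np.empty(n)
    walking = np.zeros(n, dtype=bool)
    segments: list[StageSegment] = []

    t_lift, t_carry = spec.lift_duration, spec.carry_duration
    for c in range(spec.cycle_count):
        t0 = c * spec.cycle_duration
        i0 = c * n_per_cycle
        tloc = times[i0 : i0 + n_per_cycle] - t0
        in_lift = tloc < t_lift
        in_carry = (tloc >= t_lift) & (tloc < t_lift + t_carry)
        in_static = tloc >= t_lift + t_carry
        flexion[i0 : i0 + n_per_cycle][in_lift] = _lift_profile(
            tloc[in_lift] / t_lift, lift_peak, 8.0
        )
        flexion[i0 : i0 + n_per_cycle][in_carry] = 8.0 + 2.0 * load_strain
        flexion[i0 : i0 + n_per_cycle][in_static] = static_flexion
        walking[i0 : i0 + n_per_cycle][in_carry] = True
        segments += [
            StageSegment("lifting", t0, t0 + t_lift),
            StageSegment("carrying", t0 + t_lift, t0 + t_lift + t_carry),
            StageSegment("static", t0 + t_lift + t_carry, t0 + spec.cycle_duration),
        ]

    def noise(scale: float) -> np.ndarray:
        # bounded per-frame jitter (clipped at 3 sigma)
        return np.clip(rng.normal(0.0, scale, n), -3 * scale, 3 * scale)

    gait = 8.0 * np.sin(2 * np.pi * 1.8 * times) * walking  # knee swing while walking

    angles = {
        "trunk_flexion": flexion + noise(0.6),
        "trunk_twist": noise(2.0),
        "trunk_side_bend": noise(2.0),
        "upper_arm_elevation_left": 12.0 + 0.35 * flexion + 5.0 * load_strain + noise(2.0),
        "upper_arm_elevation_right": 12.0 + 0.35 * flexion + 5.0 * load_strain + noise(2.0),
        "lower_arm_flexion_left": 70.0 + 10.0 * load_strain + noise(3.0),
        "lower_arm_flexion_right": 70.0 + 10.0 * load_strain + noise(3.0),
        "wrist_flexion_left": 8.0 + noise(3.0),
        "wrist_flexion_right": 8.0 + noise(3.0),
        "wrist_twist_left": noise(4.0),
        "wrist_twist_right": noise(4.0),
        "neck_flexion": 5.0 + 0.25 * flexion + noise(1.5),
        "knee_flexion_left": 10.0 + 0.25 * flexion + gait + noise(1.5),
        "knee_flexion_right": 10.0 + 0.25 * flexion - gait + noise(1.5),
    }
    for k in angles:
        angles[k] = np.clip(angles[k], -90.0, 180.0)

    trace = JointAngleTrace(
        times=times,
        angles=angles,
        both_feet_on_ground=~walking,
        walking=walking,
    )
    return trace, segments


@dataclass(frozen=True)
class SegmenterConfig:
    """Thresholds of the rule-based stage splitter (all overridable)."""

    flexion_channel: str = "trunk_flexion"
    smooth_window_s: float = 0.25  # moving-average window before differentiating
    motion_rate_threshold: float = 15.0  # deg/s of smoothed trunk flexion
    min_static_s: float = 2.0  # shorter still runs merge into lifting
    min_lift_s: float = 1.5  # shorter motion runs are posture transitions, not lifts


def segment_stages(
    trace: JointAngleTrace | Sequence[JointAngleFrame],
    config: SegmenterConfig = SegmenterConfig(),
) -> list[StageSegment]:
    """Partition a trace into lifting / carrying / static segments.

    Walking frames are carrying.  Non-walking runs are split by smoothed
    trunk-flexion rate: sustained motion is lifting, sustained stillness
    is the static hold.  A trace with no walking and no motion collapses
    to a single static segment.  The result is a partition: contiguous,
    non-overlapping, covering the whole trace.
    """
    trace = _as_trace(trace)
    n = len(trace)
    dt = 1.0 / _sample_rate(trace)

    flex = trace.angles.get(config.flexion_channel)
    if flex is None:
        raise KeyError(f"trace is missing channel {config.flexion_channel!r}")

    win = max(1, int(round(config.smooth_window_s / dt)))
    kernel = np.ones(win) / win
    smooth = np.convolve(flex, kernel, mode="same")
    rate = np.abs(np.gradient(smooth, dt))

    labels = np.full(n, "static", dtype=object)
    labels[trace.walking] = "carrying"
    moving = (rate > config.motion_rate_threshold) & ~trace.walking
    labels[moving] = "lifting"

    # merge short still runs inside non-walking blocks into lifting: the
    # instant of zero flexion rate at the top of a lift is not a hold
    min_run = max(1, int(round(config.min_static_s / dt)))
    for i0, i1 in _runs(labels == "static"):
        if i1 - i0 < min_run:
            left_lift = i0 > 0 and labels[i0 - 1] == "lifting"
            right_lift = i1 < n and labels[i1] == "lifting"
            if left_lift or right_lift:
                labels[i0:i1] = "lifting"

    # motion runs too short to be a lift are transitions into/out of the
    # hold (e.g. settling into the bent posture after a carry)
    for i0, i1 in _runs(labels == "lifting"):
        if (i1 - i0) * dt < config.min_lift_s:
            labels[i0:i1] = "static"

    segments = []
    for i0, i1 in _runs_by_value(labels):
        start = trace.times[i0]
        end = trace.times[i1 - 1] + dt if i1 == n else trace.times[i1]
        segments.append(StageSegment(str(labels[i0]), float(start), float(end)))
    return segments


def stage_durations(segments: Sequence[StageSegment]) -> StageDurations:
    """Sum segment lengths per stage."""
    totals = {s: 0.0 for s in STAGES}
    for seg in segments:
        totals[seg.stage] += seg.duration
    return StageDurations(
        lifting=totals["lifting"], carrying=totals["carrying"], static=totals["static"]
    )


def generate_oxi_pair(
    seed: int,
    fatigue_level: float,
    slope: float = -15.0,
    baseline: float = 70.0,
    duration_s: float = 600.0,
    sample_rate: float = 1.0,
):
    """Seeded pre/post rSO2 trace pair for one simulated trial.

    The pre trace fluctuates within the +-0.5 % resting band around
    ``baseline``; the post trace plateaus at ``baseline + slope *
    fatigue_level`` with the same bounded noise, modelling exertion-driven
    desaturation proportional to fatigue.  ``slope`` is % rSO2 per unit
    fatigue and should be <= 0 for desaturation.
    """
    from .oximetry import OxiTrace  # local import avoids a cycle

    if not 0.0 < baseline < 100.0:
        raise ValueError("baseline must lie strictly between 0 and 100 %")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)

    def resting_noise() -> np.ndarray:
        # slow drift + sensor jitter, clipped inside the resting band
        drift = 0.2 * np.sin(2 * np.pi * t / duration_s * rng.uniform(1.0, 3.0)
                             + rng.uniform(0, 2 * np.pi))
        jitter = rng.normal(0.0, 0.08, t.size)
        return np.clip(drift + jitter, -0.45, 0.45)

    pre = OxiTrace(times=t, rso2=baseline + resting_noise())
    post_level = baseline + slope * fatigue_level
    post = OxiTrace(times=t, rso2=post_level + resting_noise())
    return pre, post


# ---------------------------------------------------------------- trace I/O

def read_trace_csv(path: str | Path) -> JointAngleTrace:
    """Read a joint-angle trace CSV (wide or long format).

    Wide: ``time_s`` + one column per angle + flag columns.
    Long: ``time_s, channel, value`` (flags as 0/1 channels).
    """
    df = pd.read_csv(path)
    if {"time_s", "channel", "value"}.issubset(df.columns):
        df = df.pivot_table(index="time_s", columns="channel", values="value").reset_index()
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    flag_cols = {f: df[f].astype(bool).to_numpy() if f in df else None for f in SUPPORT_FLAGS}
    angle_cols = [c for c in df.columns if c not in ("time_s", *SUPPORT_FLAGS)]
    n = len(df)
    return JointAngleTrace(
        times=df["time_s"].to_numpy(),
        angles={c: df[c].to_numpy() for c in angle_cols},
        both_feet_on_ground=(
            flag_cols["both_feet_on_ground"]
            if flag_cols["both_feet_on_ground"] is not None
            else np.ones(n, dtype=bool)
        ),
        walking=(
            flag_cols["walking"] if flag_cols["walking"] is not None else np.zeros(n, bool)
        ),
    )


def write_trace_csv(trace: JointAngleTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------- helpers

def _as_trace(obj) -> JointAngleTrace:
    if isinstance(obj, JointAngleTrace):
        return obj
    frames = list(obj)
    if not frames:
        raise ValueError("cannot segment an empty trace")
    channels = frames[0].angles.keys()
    return JointAngleTrace(
        times=np.array([f.time for f in frames]),
        angles={k: np.array([f.angles[k] for f in frames]) for k in channels},
        both_feet_on_ground=np.array([f.both_feet_on_ground for f in frames]),
        walking=np.array([f.walking for f in frames]),
    )


def _sample_rate(trace: JointAngleTrace) -> float:
    if len(trace) < 2:
        return 1.0
    return 1.0 / float(np.median(np.diff(trace.times)))


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    for i in range(0, idx.size, 2):
        yield int(idx[i]), int(idx[i + 1])


def _runs_by_value(labels: np.ndarray):
    """Yield (start, stop) pairs of equal-label runs, in order."""
    n = labels.size
    i0 = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[i0]:
            yield i0, i
            i0 = i
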