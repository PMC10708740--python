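"""Posture-coefficient metabolic energy expenditure (MEE) model.

The comparator method for the fatigue score: energy cost of a work
bout as a sum of posture terms, E_pos = K_pos * T_pos * W, where K_pos
is the metabolic coefficient of the posture in kcal/(min*kg), T_pos the
minutes spent in it and W the operator's body mass in kg.  Total task
energy adds the action terms and the postural baseline terms
(standing/sitting/bending) covering the rest of the bout.

The default coefficient table (a CSV resource, freely editable) carries
typical published metabolic-cost values for standing, walking, load
carriage and bent postures; commercial simulation tools use proprietary
coefficients, so absolute totals are comparable only in ordering, not
magnitude.  An optional load factor (1 + load/W) scales terms in which
the operator carries external weight; it is off by default because the
basic model prices posture and duration only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .fixtures import TrialRecord

__all__ = [
    "OperatorProfile",
    "PostureEnergyTerm",
    "MeeTask",
    "posture_energy",
    "total_energy",
    "build_task_from_trial",
    "default_coefficients",
]


@dataclass(frozen=True)
class OperatorProfile:
    """The worker the task is priced for."""

    body_mass: float  # kg
    height: float = 176.3  # cm, model setup only

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")


@dataclass(frozen=True)
class PostureEnergyTerm:
    """One posture bout: coefficient, duration and any carried load."""

    posture: str
    k_pos: float  # kcal / (min * kg)
    t_pos: float  # min
    load: float = 0.0  # kg of external load, used only when the load factor is on

    def __post_init__(self):
        if self.k_pos < 0 or self.t_pos < 0 or self.load < 0:
            raise ValueError("coefficient, duration and load must be non-negative")


@dataclass
class MeeTask:
    """An ordered sequence of action terms plus postural baseline terms."""

    terms: list[PostureEnergyTerm] = field(default_factory=list)
    baseline_terms: list[PostureEnergyTerm] = field(default_factory=list)

    @property
    def all_terms(self) -> list[PostureEnergyTerm]:
        return [*self.terms, *self.baseline_terms]

    @property
    def duration_min(self) -> float:
        return sum(t.t_pos for t in self.all_terms)

    def concat(self, other: "MeeTask") -> "MeeTask":
        return MeeTask(
            terms=[*self.terms, *other.terms],
            baseline_terms=[*self.baseline_terms, *other.baseline_terms],
        )


@lru_cache(maxsize=None)
def default_coefficients() -> dict[str, float]:
    """Posture -> kcal/(min*kg) from the packaged coefficient table."""
    with resources.as_file(
        resources.files("ergofatigue.data") / "mee_coefficients.csv"
    ) as p:
        tab = pd.read_csv(p)
    return dict(zip(tab["posture"], tab["k_kcal_per_min_kg"].astype(float)))


def posture_energy(
    term: PostureEnergyTerm,
    operator: OperatorProfile,
    load_factor: bool = False,
) -> float:
    """Energy of one posture bout in kcal: K_pos * T_pos * W.

    With ``load_factor`` on, a term carrying external load is scaled by
    (1 + load / W).
    """
    e = term.k_pos * term.t_pos * operator.body_mass
    if load_factor and term.load > 0:
        e *= 1.0 + term.load / operator.body_mass
    return e


def total_energy(
    task: MeeTask,
    operator: OperatorProfile,
    load_factor: bool = False,
) -> float:
    """Total task energy: action terms plus baseline posture terms, kcal."""
    return sum(posture_energy(t, operator, load_factor) for t in task.all_terms)


#: stage -> MEE posture type used when pricing an assembly trial;
#: a vehicle body at or below ``deep_bend_height_cm`` forces the deeper
#: (more expensive) static bend
_STAGE_POSTURES = {"lifting": "lifting", "carrying": "walking_with_load"}
DEEP_BEND_HEIGHT_CM = 30.0


def build_task_from_trial(
    trial: TrialRecord,
    cycle_count: int,
    operator: OperatorProfile,
    coefficients: dict[str, float] | None = None,
    trial_duration_min: float = 30.0,
) -> MeeTask:
    """Price one assembly trial as an MEE task.

    Stage durations are per cycle (seconds); the trial repeats the
    lift -> carry -> static-hold cycle for ``trial_duration_min``
    minutes, so stage proportions are preserved and the per-posture
    minutes sum to the trial duration.  The lifting and carrying terms
    carry the seat weight; the static stage maps to a bent-standing
    posture, deep when the vehicle body sits low.
    """
    if cycle_count < 1:
        raise ValueError("cycle_count must be at least 1")
    if trial.stage_durations_s is None:
        raise ValueError("trial has no stage durations")
    k = coefficients or default_coefficients()

    t1, t2, t3 = trial.stage_durations_s
    cycle_s = t1 + t2 + t3
    if cycle_s <= 0:
        raise ValueError("stage durations sum to zero")
    # scale per-cycle stage times to the full trial
    scale = trial_duration_min / (cycle_s / 60.0 * cycle_count)

    static_posture = (
        "deep_bend_standing"
        if trial.design.body_height <= DEEP_BEND_HEIGHT_CM
        else "bent_standing"
    )
    load = float(trial.design.seat_weight)
    terms = [
        PostureEnergyTerm("lifting", k["lifting"],
                          cycle_count * t1 / 60.0 * scale, load=load),
        PostureEnergyTerm("walking_with_load", k["walking_with_load"],
                          cycle_count * t2 / 60.0 * scale, load=load),
    ]
    baseline = [
        PostureEnergyTerm(static_posture, k[static_posture],
                          cycle_count * t3 / 60.0 * scale),
    ]
    return MeeTask(terms=terms, baseline_terms=baseline)
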