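"""Stage-level ergonomic scoring: NIOSH lifting index, OWAS, RULA.

Three classical observational methods, one per assembly stage:

* **NIOSH revised lifting equation (1991)** for the lifting stage.  The
  recommended weight limit is RWL = LC * HM * VM * DM * AM * FM * CM
  with load constant LC = 23 kg and six multiplicative penalties for
  horizontal reach, vertical origin, travel distance, asymmetry,
  frequency and coupling quality; the lifting index LI = load / RWL.
* **OWAS** for the carrying stage, extended with a fourth digit for the
  handled load (1: < 10 kg, 2: 10-20 kg, 3: > 20 kg) on top of the
  classic back/arms/legs posture digits; the code maps to an action
  category 1-4 through the published classification matrix.
* **RULA** for the static stage: posture scores for the arm/wrist group
  (Table A) and neck/trunk/legs group (Table B), muscle-use and force
  additions, and a grand score 1-7 from Table C.

The FM/CM/OWAS/RULA lookup tables ship as CSV resources and are loaded
once on first use.  Angle-to-score bracketing for frame-based scoring
follows each method's published angle bands; the exact OWAS bend/twist
thresholds are configurable because observational methods define them
by inspection, not degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .kinematics import JointAngleFrame

__all__ = [
    "LiftTaskParams",
    "NioshResult",
    "OwasCode",
    "OwasAngleConfig",
    "RulaInputs",
    "RulaResult",
    "niosh_li",
    "owas_classify",
    "owas_load_digit",
    "rula_score",
    "rula_from_frame",
    "aggregate",
]

LOAD_CONSTANT_KG = 23.0

DURATION_CLASSES = ("<=1h", "<=2h", "<=8h")
COUPLINGS = ("good", "fair", "poor")


@lru_cache(maxsize=None)
def _table(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("ergofatigue.data") / name) as p:
        return pd.read_csv(p)


# --------------------------------------------------------------- NIOSH 1991

@dataclass(frozen=True)
class LiftTaskParams:
    """Geometry and organisation of a lifting task (cm, degrees, lifts/min)."""

    load: float  # kg
    horizontal: float  # cm, hand distance from mid-ankles at lift origin
    vertical: float  # cm, hand height at lift origin
    travel: float  # cm, vertical travel of the lift
    asymmetry: float = 0.0  # deg of trunk rotation
    frequency: float = 0.2  # lifts/min
    work_duration_class: str = "<=1h"
    coupling: str = "good"

    def __post_init__(self):
        if self.load < 0:
            raise ValueError("load must be non-negative")
        if self.horizontal <= 0:
            raise ValueError("horizontal distance must be positive")
        if self.travel < 0:
            raise ValueError("travel distance must be non-negative")
        if not 0 <= self.asymmetry <= 135:
            raise ValueError("asymmetry angle must lie in [0, 135] degrees")
        if self.work_duration_class not in DURATION_CLASSES:
            raise ValueError(f"work_duration_class must be one of {DURATION_CLASSES}")
        if self.coupling not in COUPLINGS:
            raise ValueError(f"coupling must be one of {COUPLINGS}")


@dataclass
class NioshResult:
    """RWL, LI and the six multipliers behind them.

    When the task geometry exceeds the equation's applicability limits
    some multiplier is zero, RWL is zero and LI is reported as ``inf``
    with an explanatory ``note``.
    """

    rwl: float  # kg
    li: float
    multipliers: dict[str, float]  # HM, VM, DM, AM, FM, CM
    note: str | None = None


def _fm(frequency: float, duration_class: str, vertical: float) -> float:
    tab = _table("niosh_frequency_multiplier.csv")
    col = {"<=1h": "d1", "<=2h": "d2", "<=8h": "d8"}[duration_class]
    col += "_vlow" if vertical < 75.0 else "_vhigh"
    f = np.asarray(tab["lifts_per_min"], dtype=float)
    m = np.asarray(tab[col], dtype=float)
    if frequency <= f[0]:
        return float(m[0])
    if frequency > f[-1]:
        return 0.0
    # linear interpolation between tabulated frequencies, but an exact hit
    # on a zero row (beyond the duration class limit) stays zero
    fm = float(np.interp(frequency, f, m))
    return fm


def _cm(coupling: str, vertical: float) -> float:
    if coupling == "good":
        return 1.0
    if coupling == "fair":
        return 0.95 if vertical < 75.0 else 1.0
    return 0.90


def niosh_li(params: LiftTaskParams) -> NioshResult:
    """Revised-lifting-equation RWL and LI for one task."""
    h, v, d, a = params.horizontal, params.vertical, params.travel, params.asymmetry

    hm = 1.0 if h <= 25.0 else (25.0 / h if h <= 63.0 else 0.0)
    vm = max(0.0, 1.0 - 0.003 * abs(v - 75.0)) if v <= 175.0 else 0.0
    dm = 1.0 if d <= 25.0 else (0.82 + 4.5 / d if d <= 175.0 else 0.0)
    am = 1.0 - 0.0032 * a
    fm = _fm(params.frequency, params.work_duration_class, v)
    cm = _cm(params.coupling, v)
    mult = {"HM": hm, "VM": vm, "DM": dm, "AM": am, "FM": fm, "CM": cm}

    rwl = LOAD_CONSTANT_KG * hm * vm * dm * am * fm * cm
    if rwl == 0.0:
        dead = ", ".join(k for k, x in mult.items() if x == 0.0)
        return NioshResult(
            rwl=0.0,
            li=float("inf"),
            multipliers=mult,
            note=f"task outside equation limits ({dead} = 0); treat as maximal risk",
        )
    return NioshResult(rwl=rwl, li=params.load / rwl, multipliers=mult)


# -------------------------------------------------------------------- OWAS

@dataclass(frozen=True)
class OwasAngleConfig:
    """Angle thresholds for reading OWAS posture digits off a frame."""

    back_bend_deg: float = 20.0
    back_twist_deg: float = 20.0
    arm_raised_deg: float = 90.0  # upper-arm elevation above shoulder level
    knee_bent_deg: float = 30.0


@dataclass(frozen=True)
class OwasCode:
    """Four-digit OWAS code (back, arms, legs, load) plus action category."""

    back: int  # 1-4
    arms: int  # 1-3
    legs: int  # 1-7
    load_digit: int  # 1-3
    action_category: int  # 1-4

    def __post_init__(self):
        if not (1 <= self.back <= 4 and 1 <= self.arms <= 3 and 1 <= self.legs <= 7
                and 1 <= self.load_digit <= 3):
            raise ValueError("OWAS digits out of range")
        if not 1 <= self.action_category <= 4:
            raise ValueError("action category out of range")


def owas_load_digit(load: float) -> int:
    """Standard OWAS load bands: < 10 kg, 10-20 kg, > 20 kg."""
    if load < 10.0:
        return 1
    if load <= 20.0:
        return 2
    return 3


@lru_cache(maxsize=None)
def _owas_categories() -> dict[tuple[int, int, int, int], int]:
    tab = _table("owas_action_categories.csv")
    return {
        (r.back, r.arms, r.legs, r.load_class): int(r.action_category)
        for r in tab.itertuples()
    }


def owas_action_category(back: int, arms: int, legs: int, load_digit: int) -> int:
    """Action category 1-4 from the published OWAS classification matrix."""
    try:
        return _owas_categories()[(back, arms, legs, load_digit)]
    except KeyError:
        raise ValueError(
            f"OWAS code ({back},{arms},{legs},{load_digit}) outside the matrix domain"
        ) from None


def owas_classify(
    frame: JointAngleFrame,
    load: float,
    config: OwasAngleConfig = OwasAngleConfig(),
) -> OwasCode:
    """Read the four-digit OWAS code off one posture frame."""
    trunk = frame.require("trunk_flexion")
    twist = abs(frame.require("trunk_twist"))
    side = abs(frame.require("trunk_side_bend"))
    bent = trunk > config.back_bend_deg
    twisted = max(twist, side) > config.back_twist_deg
    back = 4 if (bent and twisted) else 2 if bent else 3 if twisted else 1

    raised = sum(
        frame.require(f"upper_arm_elevation_{s}") > config.arm_raised_deg
        for s in ("left", "right")
    )
    arms = 1 + raised  # 0, 1, 2 arms above shoulder level -> 1, 2, 3

    knee_l = frame.require("knee_flexion_left")
    knee_r = frame.require("knee_flexion_right")
    n_bent = (knee_l > config.knee_bent_deg) + (knee_r > config.knee_bent_deg)
    if frame.walking:
        legs = 7
    elif not frame.both_feet_on_ground:
        legs = 3 if n_bent == 0 else 5  # one-leg stance, straight or bent
    elif n_bent == 0:
        legs = 2  # standing, both legs straight
    elif n_bent == 2:
        legs = 4  # standing/squatting, both knees bent
    else:
        legs = 5  # weight on one bent leg

    ld = owas_load_digit(load)
    return OwasCode(back, arms, legs, ld, owas_action_category(back, arms, legs, ld))


# -------------------------------------------------------------------- RULA

_RULA_RANGES = {
    "upper_arm": (1, 6),
    "lower_arm": (1, 3),
    "wrist": (1, 4),
    "wrist_twist": (1, 2),
    "neck": (1, 6),
    "trunk": (1, 6),
    "legs": (1, 2),
}


@dataclass(frozen=True)
class RulaInputs:
    """Posture scores per the RULA worksheet plus muscle-use/force additions."""

    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int
    muscle_use_a: int = 0  # 0/1: static posture or high repetition, arm/wrist
    muscle_use_b: int = 0  # 0/1: same for neck/trunk/legs
    force_load_a: int = 0  # 0-3
    force_load_b: int = 0  # 0-3

    def __post_init__(self):
        for name, (lo, hi) in _RULA_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"RULA {name} score {v} outside [{lo}, {hi}]")
        for name in ("muscle_use_a", "muscle_use_b"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")
        for name in ("force_load_a", "force_load_b"):
            if not 0 <= getattr(self, name) <= 3:
                raise ValueError(f"{name} must lie in 0..3")


@dataclass
class RulaResult:
    """Intermediate group scores and the grand score 1-7."""

    score_a: int  # arm/wrist posture score (Table A), before additions
    score_b: int  # neck/trunk/legs posture score (Table B), before additions
    wrist_arm_score: int  # score_a + muscle + force
    neck_trunk_leg_score: int  # score_b + muscle + force
    grand: int  # 1-7 (Table C)


@lru_cache(maxsize=None)
def _rula_a() -> dict[tuple[int, int, int, int], int]:
    tab = _table("rula_table_a.csv")
    return {(r.upper_arm, r.lower_arm, r.wrist, r.wrist_twist): int(r.score)
            for r in tab.itertuples()}


@lru_cache(maxsize=None)
def _rula_b() -> dict[tuple[int, int, int], int]:
    tab = _table("rula_table_b.csv")
    return {(r.neck, r.trunk, r.legs): int(r.score) for r in tab.itertuples()}


@lru_cache(maxsize=None)
def _rula_c() -> dict[tuple[int, int], int]:
    tab = _table("rula_table_c.csv")
    return {(r.score_a, r.score_b): int(r.grand) for r in tab.itertuples()}


def rula_score(inputs: RulaInputs) -> RulaResult:
    """Grand RULA score via Tables A, B and C with the published caps."""
    a = _rula_a()[(inputs.upper_arm, inputs.lower_arm, inputs.wrist, inputs.wrist_twist)]
    b = _rula_b()[(inputs.neck, inputs.trunk, inputs.legs)]
    wrist_arm = a + inputs.muscle_use_a + inputs.force_load_a
    neck_trunk = b + inputs.muscle_use_b + inputs.force_load_b
    grand = _rula_c()[(min(wrist_arm, 8), min(neck_trunk, 7))]
    return RulaResult(
        score_a=a,
        score_b=b,
        wrist_arm_score=wrist_arm,
        neck_trunk_leg_score=neck_trunk,
        grand=grand,
    )


def _bracket_upper_arm(elev: float) -> int:
    if -20.0 <= elev <= 20.0:
        return 1
    if elev < -20.0 or elev <= 45.0:
        return 2
    if elev <= 90.0:
        return 3
    return 4


def _bracket_lower_arm(flex: float) -> int:
    return 1 if 60.0 <= flex <= 100.0 else 2


def _bracket_wrist(flex: float) -> int:
    a = abs(flex)
    if a < 1.0:
        return 1
    if a <= 15.0:
        return 2
    return 3


def _bracket_neck(flex: float) -> int:
    if flex < 0.0:
        return 4  # extension
    if flex <= 10.0:
        return 1
    if flex <= 20.0:
        return 2
    return 3


def _bracket_trunk(flex: float) -> int:
    if flex <= 2.0:
        return 1  # upright / supported
    if flex <= 20.0:
        return 2
    if flex <= 60.0:
        return 3
    return 4


def _force_score(load: float) -> int:
    # intermittent loading assumed for frame scoring
    if load < 2.0:
        return 0
    if load <= 10.0:
        return 2
    return 3


def rula_from_frame(
    frame: JointAngleFrame,
    load: float = 0.0,
    static_posture: bool = True,
) -> RulaResult:
    """Bracket a posture frame into RULA scores and look up the grand score.

    The worse (higher-scoring) arm side is assessed, as the worksheet
    prescribes.  ``static_posture`` sets the muscle-use addition for a
    posture held longer than a minute, which is the default for the
    static assembly stage.
    """
    sides = []
    for s in ("left", "right"):
        ua = _bracket_upper_arm(frame.require(f"upper_arm_elevation_{s}"))
        la = _bracket_lower_arm(frame.require(f"lower_arm_flexion_{s}"))
        wr = _bracket_wrist(frame.require(f"wrist_flexion_{s}"))
        tw = 1 if abs(frame.require(f"wrist_twist_{s}")) <= 45.0 else 2
        sides.append((ua, la, wr, tw))
    ua, la, wr, tw = max(sides, key=lambda x: _rula_a()[x])

    inputs = RulaInputs(
        upper_arm=ua,
        lower_arm=la,
        wrist=wr,
        wrist_twist=tw,
        neck=_bracket_neck(frame.require("neck_flexion")),
        trunk=_bracket_trunk(frame.require("trunk_flexion")),
        legs=1 if frame.both_feet_on_ground and not frame.walking else 2,
        muscle_use_a=1 if static_posture else 0,
        muscle_use_b=1 if static_posture else 0,
        force_load_a=_force_score(load),
        force_load_b=_force_score(load),
    )
    return rula_score(inputs)


# ------------------------------------------------------------- aggregation

def aggregate(values, how: str = "max") -> float:
    """Collapse per-cycle (or per-frame) scores into one trial value.

    The recording platform logged one score per trial without stating
    whether it was the worst, the typical or the average cycle; all
    three are offered.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    if how == "max":
        return float(v.max())
    if how == "mean":
        return float(v.mean())
    if how == "mode":
        vals, counts = np.unique(v, return_counts=True)
        return float(vals[np.argmax(counts)])
    raise ValueError(f"unknown aggregator {how!r}; use max, mean or mode")
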