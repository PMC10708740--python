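"""Embedded reference tables from the seat-assembly fatigue experiment.

The experiment is a balanced 2 (vehicle-body height: 15, 45 cm) x
3 (seat weight: 8, 14, 20 kg) x 3 (replicate) factorial, 18 trials in
total.  Four measured tables are shipped as package resources:

``table1_rso2_diff``
    pre/post difference of regional cerebral oxygen saturation (rSO2), %.
``table2_scores``
    raw per-trial NIOSH lifting index, OWAS action category and RULA
    grand score (the 18 x 3 score matrix of the fusion pipeline).
``table4_fatigue``
    time-weighted composite fatigue score per trial (dimensionless).
``table6_mee``
    simulated metabolic energy expenditure per trial, kcal.

All tables share one canonical flat row order -- the 15 cm height block
before the 45 cm block, weights ascending within a block, replicates in
recorded order -- so that position-wise pairing of any two tables is
well defined.  That pairing is what the downstream Pearson validation
relies on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "TrialDesign",
    "TrialRecord",
    "FixtureTable",
    "TABLE_NAMES",
    "load_table",
    "trial_design",
    "export_fixtures",
    "fixture_checksums",
]

TABLE_NAMES = (
    "table1_rso2_diff",
    "table2_scores",
    "table4_fatigue",
    "table6_mee",
)

#: value column(s) and unit annotation per table
_TABLE_META = {
    "table1_rso2_diff": (["rso2_diff_pct"], "%"),
    "table2_scores": (["niosh_li", "owas_category", "rula_grand"], "dimensionless"),
    "table4_fatigue": (["fatigue_score"], "dimensionless"),
    "table6_mee": (["mee_kcal"], "kcal"),
}

#: resting rSO2 fluctuation band observed over 40 min in a calm state;
#: stored as a precision annotation, never folded into the values
RSO2_PRECISION_PCT = 0.5

SEAT_WEIGHTS_KG = (8, 14, 20)
BODY_HEIGHTS_CM = (15, 45)
N_REPLICATES = 3
N_TRIALS = len(SEAT_WEIGHTS_KG) * len(BODY_HEIGHTS_CM) * N_REPLICATES


@dataclass(frozen=True, order=True)
class TrialDesign:
    """Factor levels of one trial in the balanced 2x3x3 layout."""

    body_height: int  # cm, height of the vehicle body off the ground
    seat_weight: int  # kg
    replicate: int  # 1..3


@dataclass
class TrialRecord:
    """One experimental trial: factors plus whatever was measured on it.

    ``stage_scores`` is (NIOSH LI, OWAS category, RULA grand);
    ``stage_durations_s`` is (lifting, carrying, static) seconds.
    Either may be absent depending on the pipeline step.
    """

    design: TrialDesign
    stage_scores: tuple[float, float, float] | None = None
    stage_durations_s: tuple[float, float, float] | None = None


@dataclass
class FixtureTable:
    """A printed reference table in canonical flat row order."""

    name: str
    data: pd.DataFrame  # design columns + value column(s)
    value_columns: list[str]
    units: str
    precision: float | None = None  # measurement precision annotation

    @property
    def values(self):
        """Numeric payload as an ndarray, one row per trial."""
        return self.data[self.value_columns].to_numpy(dtype=float)

    def cell(self, body_height: int, seat_weight: int, replicate: int):
        """Value(s) for one (height, weight, replicate) trial."""
        m = (
            (self.data["height_cm"] == body_height)
            & (self.data["weight_kg"] == seat_weight)
            & (self.data["replicate"] == replicate)
        )
        sub = self.data.loc[m, self.value_columns]
        if sub.empty:
            raise KeyError(
                f"no trial with height={body_height} cm, weight={seat_weight} kg, "
                f"replicate={replicate}"
            )
        row = sub.iloc[0]
        return float(row.iloc[0]) if len(self.value_columns) == 1 else tuple(row)


def trial_design() -> list[TrialDesign]:
    """The 18 trials in canonical flat order.

    15 cm block first, weights ascending within a block, replicates 1-3.
    """
    return [
        TrialDesign(body_height=h, seat_weight=w, replicate=r)
        for h in BODY_HEIGHTS_CM
        for w in SEAT_WEIGHTS_KG
        for r in range(1, N_REPLICATES + 1)
    ]


def _resource_text(filename: str) -> str:
    return (resources.files("ergofatigue.data") / filename).read_text(encoding="utf-8")


def _read_resource_csv(filename: str) -> pd.DataFrame:
    with resources.as_file(resources.files("ergofatigue.data") / filename) as p:
        return pd.read_csv(p)


def load_table(name: str) -> FixtureTable:
    """Load one of the four embedded reference tables by identifier."""
    if name not in TABLE_NAMES:
        raise KeyError(
            f"unknown table {name!r}; valid identifiers are: {', '.join(TABLE_NAMES)}"
        )
    value_cols, units = _TABLE_META[name]
    df = _read_resource_csv(f"{name}.csv")
    if len(df) != N_TRIALS:
        raise RuntimeError(f"fixture {name} is corrupt: expected {N_TRIALS} rows")
    precision = RSO2_PRECISION_PCT if name == "table1_rso2_diff" else None
    return FixtureTable(
        name=name, data=df, value_columns=value_cols, units=units, precision=precision
    )


def export_fixtures(dest: str | Path) -> list[Path]:
    """Write the four fixture CSVs to a user directory; returns the paths."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    written = []
    for name in TABLE_NAMES:
        out = dest / f"{name}.csv"
        out.write_text(_resource_text(f"{name}.csv"), encoding="utf-8")
        written.append(out)
    return written


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of each fixture resource, to guard against accidental edits."""
    return {
        name: hashlib.sha256(_resource_text(f"{name}.csv").encode()).hexdigest()
        for name in TABLE_NAMES
    }
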