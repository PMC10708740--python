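"""Regional cerebral oxygen saturation (rSO2) processing.

rSO2 is the percentage of haemoglobin carrying oxygen at the sensor
site, rSO2 = C_HbO2 / (C_HbO2 + C_HbR) * 100, where C_HbO2 and C_HbR
are the oxy- and deoxy-haemoglobin concentrations reported by a NIRS
monitor.  Physical exertion desaturates cerebral tissue, so the change
in baseline rSO2 from a calm pre-trial recording to a calm post-trial
recording (post minus pre; negative = desaturation) serves as the
objective fatigue reference against which score-based methods are
validated.

Baselines are taken from the longest stable stretch of a recording.
"Stable" here means a window of at least 60 s whose peak-to-peak spread
stays within 1 % (the resting fluctuation of rSO2 over 40 min is about
+-0.5 %); the window statistic defaults to the mean.  Both the window
rule and the statistic are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OxiTrace", "rso2", "baseline_rso2", "rso2_difference", "read_oxi_csv"]


def rso2(c_hbo2, c_hbr):
    """Oxygen saturation percentage from haemoglobin concentrations.

    Accepts scalars or arrays; concentrations share any common unit
    (the ratio is unit-free).
    """
    a = np.asarray(c_hbo2, dtype=float)
    b = np.asarray(c_hbr, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("haemoglobin concentrations must be non-negative")
    total = a + b
    if np.any(total == 0):
        raise ValueError("total haemoglobin concentration is zero; rSO2 undefined")
    out = np.clip(100.0 * a / total, 0.0, 100.0)  # guard float round-off at 100
    return float(out) if out.ndim == 0 else out


@dataclass
class OxiTrace:
    """Time-ordered rSO2 series with an optional preselected baseline window."""

    times: np.ndarray  # s
    rso2: np.ndarray  # %
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rso2 = np.asarray(self.rso2, dtype=float)
        if self.times.shape != self.rso2.shape or self.times.ndim != 1:
            raise ValueError("times and rso2 must be matching one-dimensional arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any((self.rso2 < 0) | (self.rso2 > 100)):
            raise ValueError("rSO2 values must lie within [0, 100] %")
        if self.baseline_window is not None:
            lo, hi = self.baseline_window
            if not (self.times[0] <= lo < hi <= self.times[-1]):
                raise ValueError("baseline window must lie within the trace span")

    @classmethod
    def from_concentrations(cls, times, c_hbo2, c_hbr, **kw) -> "OxiTrace":
        return cls(times=np.asarray(times, float), rso2=rso2(c_hbo2, c_hbr), **kw)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def baseline_rso2(
    trace: OxiTrace,
    min_window_s: float = 60.0,
    max_spread_pct: float = 1.0,
    stat: str = "mean",
) -> tuple[float, tuple[float, float]]:
    """Baseline value and the stable window it came from.

    Picks the longest window of length >= ``min_window_s`` whose
    peak-to-peak rSO2 spread is <= ``max_spread_pct``; ties go to the
    latest such window (late in a calm recording the subject is most
    settled).  If the trace carries a preselected ``baseline_window``
    that window is used as-is.
    """
    if trace.baseline_window is not None:
        lo, hi = trace.baseline_window
        mask = (trace.times >= lo) & (trace.times <= hi)
        return _window_stat(trace.rso2[mask], stat), (lo, hi)

    if trace.duration < 2 * min_window_s:
        raise ValueError(
            f"trace too short for baseline selection (need >= {2 * min_window_s:g} s)"
        )

    t, y = trace.times, trace.rso2
    n = t.size
    best: tuple[float, int, int] | None = None  # (length, i0, i1)
    # two-pointer sweep with running min/max deques: O(n)
    lo_dq: list[int] = []
    hi_dq: list[int] = []
    i0 = 0
    for i1 in range(n):
        while hi_dq and y[hi_dq[-1]] <= y[i1]:
            hi_dq.pop()
        hi_dq.append(i1)
        while lo_dq and y[lo_dq[-1]] >= y[i1]:
            lo_dq.pop()
        lo_dq.append(i1)
        while y[hi_dq[0]] - y[lo_dq[0]] > max_spread_pct:
            i0 += 1
            if hi_dq[0] < i0:
                hi_dq.pop(0)
            if lo_dq[0] < i0:
                lo_dq.pop(0)
        length = t[i1] - t[i0]
        if length >= min_window_s and (best is None or length >= best[0]):
            best = (length, i0, i1)
    if best is None:
        raise ValueError(
            "no stable baseline window found (spread exceeds "
            f"{max_spread_pct:g} % everywhere); select a window manually via "
            "OxiTrace.baseline_window"
        )
    _, i0, i1 = best
    window = (float(t[i0]), float(t[i1]))
    return _window_stat(y[i0 : i1 + 1], stat), window


def rso2_difference(pre: OxiTrace, post: OxiTrace, **baseline_kw) -> float:
    """Signed baseline change, post minus pre (negative = desaturation)."""
    pre_val, _ = baseline_rso2(pre, **baseline_kw)
    post_val, _ = baseline_rso2(post, **baseline_kw)
    return post_val - pre_val


def read_oxi_csv(path: str | Path) -> OxiTrace:
    """Read ``time_s, rso2_pct`` or ``time_s, c_hbo2, c_hbr`` CSVs."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_s' column")
    if "rso2_pct" in df.columns:
        return OxiTrace(times=df["time_s"].to_numpy(), rso2=df["rso2_pct"].to_numpy())
    if {"c_hbo2", "c_hbr"}.issubset(df.columns):
        return OxiTrace.from_concentrations(
            df["time_s"].to_numpy(), df["c_hbo2"].to_numpy(), df["c_hbr"].to_numpy()
        )
    raise ValueError(f"{path}: expected 'rso2_pct' or 'c_hbo2'/'c_hbr' columns")


def _window_stat(values: np.ndarray, stat: str) -> float:
    if values.size == 0:
        raise ValueError("baseline window contains no samples")
    if stat == "mean":
        return float(np.mean(values))
    if stat == "median":
        return float(np.median(values))
    if stat == "last":
        return float(values[-1])
    raise ValueError(f"unknown baseline statistic {stat!r}")
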