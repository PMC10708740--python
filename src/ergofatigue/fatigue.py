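"""Entropy-weighted, time-weighted fusion of stage-level ergonomic scores.

One manual-assembly trial yields three raw indices -- the NIOSH lifting
index for the lifting stage, the OWAS action category for the carrying
stage and the RULA grand score for the static assembly stage.  This
module fuses an n-trial x 3-index score matrix into a single
dimensionless fatigue value per trial:

1. each index column is min-max normalised to [0, 1],
       r_ij = (r'_ij - min_j r'_ij) / (max_j r'_ij - min_j r'_ij);
2. objective index weights come from the entropy-weight method: column
   share probabilities p_ij = r_ij / sum_j r_ij (with 0 * ln 0 = 0),
   Shannon entropy e_i = -(1/ln n) * sum_j p_ij ln p_ij, utility
   d_i = 1 - e_i, and weights w_i = d_i / sum d_i.  An index whose
   normalised values vary a lot across trials carries low entropy and
   hence high weight;
3. the per-trial fatigue value weights each stage by its actual
   duration t_i (fatigue accumulates over time spent in a stage):
       e_j = sum_i r_ij * w_i * t_i / sum_i t_i.

With all r_ij in [0, 1] and weights summing to one, e_j is bounded by
max_i w_i.  Scaling all durations by a common factor leaves e_j
unchanged; only the stage-time proportions matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ScoreMatrix",
    "EntropyWeights",
    "min_max_normalize",
    "entropy_weights",
    "fatigue_score",
    "evaluate_trials",
]

INDEX_NAMES = ("NIOSH", "OWAS", "RULA")


@dataclass
class ScoreMatrix:
    """Raw n x 3 score matrix (columns: NIOSH LI, OWAS category, RULA grand)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("score matrix must be two-dimensional")
        if v.shape[0] < 2:
            raise ValueError("at least two trials are required")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("scores must be finite and non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class EntropyWeights:
    """Per-index information entropy e, utility d = 1 - e and weight w."""

    entropy: np.ndarray
    utility: np.ndarray
    weights: np.ndarray  # sums to 1

    @property
    def weights_pct(self) -> np.ndarray:
        return 100.0 * self.weights


def min_max_normalize(matrix: ScoreMatrix | np.ndarray) -> np.ndarray:
    """Column-wise (x - min) / (max - min); a constant column maps to zeros."""
    v = matrix.values if isinstance(matrix, ScoreMatrix) else np.asarray(matrix, float)
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    out = np.zeros_like(v)
    nz = span > 0
    out[:, nz] = (v[:, nz] - lo[nz]) / span[nz]
    return out


def entropy_weights(matrix: ScoreMatrix | np.ndarray) -> EntropyWeights:
    """Entropy-weight method on a score matrix.

    Normalises first, then forms column-share probabilities over trials.
    A constant column is maximally uninformative: it gets e = 1, d = 0
    and weight 0.  All columns constant leaves every weight undefined
    and raises.
    """
    if not isinstance(matrix, ScoreMatrix):
        matrix = ScoreMatrix(np.asarray(matrix, dtype=float))
    r = min_max_normalize(matrix)
    n = matrix.n
    colsum = r.sum(axis=0)
    if np.all(colsum == 0):
        raise ValueError("all columns are constant; entropy weights are undefined")
    e = np.ones(r.shape[1])  # constant column -> entropy 1 by convention
    nz = colsum > 0
    p = r[:, nz] / colsum[nz]
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e[nz] = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e
    w = d / d.sum()
    return EntropyWeights(entropy=e, utility=d, weights=w)


def fatigue_score(
    normalized_row: Sequence[float],
    weights: EntropyWeights | Sequence[float],
    durations: Sequence[float],
) -> float:
    """Time-weighted fatigue value e_j = sum r_ij w_i t_i / sum t_i.

    ``durations`` is (lifting, carrying, static) seconds, paired with the
    (NIOSH, OWAS, RULA) columns in that order.
    """
    r = np.asarray(normalized_row, dtype=float)
    w = weights.weights if isinstance(weights, EntropyWeights) else np.asarray(weights, float)
    t = np.asarray(getattr(durations, "as_array", lambda: durations)(), dtype=float)
    if r.shape != w.shape or r.shape != t.shape:
        raise ValueError("row, weights and durations must have matching length")
    if np.any(t < 0):
        raise ValueError("durations must be non-negative")
    total = t.sum()
    if total == 0:
        raise ValueError("total stage duration is zero; fatigue value undefined")
    return float(np.sum(r * w * t) / total)


def evaluate_trials(
    matrix: ScoreMatrix | np.ndarray,
    durations,
) -> np.ndarray:
    """Full pipeline over a trial set: normalise, weight, time-fuse.

    ``durations`` is either one (t1, t2, t3) triple applied to every
    trial or a per-trial sequence of triples.  Weights are derived from
    the supplied matrix itself.  Values are returned at full precision.
    """
    if not isinstance(matrix, ScoreMatrix):
        matrix = ScoreMatrix(np.asarray(matrix, dtype=float))
    r = min_max_normalize(matrix)
    w = entropy_weights(matrix)
    if hasattr(durations, "as_array"):
        durations = durations.as_array()
    t = np.asarray(
        [getattr(d, "as_array", lambda d=d: d)() for d in durations]
        if _is_per_trial(durations, matrix.n)
        else [durations] * matrix.n,
        dtype=float,
    )
    return np.array([fatigue_score(r[j], w, t[j]) for j in range(matrix.n)])


def _is_per_trial(durations, n: int) -> bool:
    try:
        first = durations[0]
    except (TypeError, KeyError):
        return False
    return hasattr(first, "__len__") or hasattr(first, "as_array")
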