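"""Quantitative comparison of gaze patterns.

* the H-A scale — a bounded score placing a child between the holistic
  and analytic representative models,
* Monte-Carlo Kullback–Leibler divergence between two HMMs with a
  paired t-test on the per-sequence log-likelihood differences,
* the paired log-likelihood t-test itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .vbhmm import GazeHMM, log_likelihood, sample_sequence

__all__ = [
    "HAScaleRecord",
    "KLResult",
    "ha_scale",
    "ha_record",
    "kl_divergence_mc",
    "paired_t_loglik",
    "ha_table",
]


@dataclass
class HAScaleRecord:
    """Per-child, per-face log-likelihoods under both representatives and
    the resulting H-A value (positive = holistic-leaning)."""

    child_id: str
    face_type: str
    holistic_loglik: float
    analytic_loglik: float
    value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError("H-A value outside [-1, 1]")


@dataclass
class KLResult:
    """Monte-Carlo KL estimate with its paired-t significance test."""

    d: float
    t_statistic: float
    p_value: float
    df: int
    n_samples: int
    se: float
    per_fixation: bool = False


def ha_scale(holistic_loglik: float, analytic_loglik: float) -> float:
    """(H - A) / (|H| + |A|): positive means the holistic representative
    explains the child's fixations better than the analytic one."""
    h, a = float(holistic_loglik), float(analytic_loglik)
    if not (math.isfinite(h) and math.isfinite(a)):
        raise ValueError("log-likelihoods must be finite")
    denom = abs(h) + abs(a)
    if denom == 0.0:
        raise ValueError("H-A scale undefined when both log-likelihoods are 0")
    return (h - a) / denom


def ha_record(child_id: str, face_type: str, sequence,
              holistic: GazeHMM, analytic: GazeHMM) -> HAScaleRecord:
    """Evaluate one child's sequence under both representatives."""
    h = log_likelihood(holistic, sequence)
    a = log_likelihood(analytic, sequence)
    return HAScaleRecord(child_id, face_type, h, a, ha_scale(h, a))


def paired_t_loglik(ll_under_a, ll_under_b) -> tuple[float, float, int]:
    """Paired t-test on two equal-length lists of log-likelihoods.

    Returns (t, two-sided p, df = n - 1).  Identical nonzero differences
    give an infinite t (flagged as ±inf) with p reported as 0.0.
    """
    a = np.asarray(ll_under_a, dtype=float)
    b = np.asarray(ll_under_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean), 0.0, df
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p), df


def kl_divergence_mc(
    model_p: GazeHMM,
    model_q: GazeHMM,
    n_sequences: int = 2000,
    seq_length: int = 20,
    rng: np.random.Generator | None = None,
    per_fixation: bool = False,
) -> KLResult:
    """Monte-Carlo KL divergence D(P || Q) between two gaze HMMs.

    Draws ``n_sequences`` sequences of ``seq_length`` fixations from
    ``model_p`` and averages log P(x|p) - log P(x|q); with
    ``per_fixation`` the average is per fixation instead of per
    sequence.  The paired t-test across the per-sequence differences
    tests whether the mean difference departs from zero.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    ll_p = np.empty(n_sequences)
    ll_q = np.empty(n_sequences)
    for i in range(n_sequences):
        seq = sample_sequence(model_p, seq_length, rng)
        ll_p[i] = log_likelihood(model_p, seq)
        ll_q[i] = log_likelihood(model_q, seq)
    if per_fixation:
        ll_p = ll_p / seq_length
        ll_q = ll_q / seq_length
    diffs = ll_p - ll_q
    d = float(diffs.mean())
    se = float(diffs.std(ddof=1) / math.sqrt(n_sequences)) if n_sequences > 1 else float("nan")
    if n_sequences > 1:
        t, p, df = paired_t_loglik(ll_p, ll_q)
    else:
        t, p, df = float("nan"), float("nan"), 0
    return KLResult(d, t, p, df, n_sequences, se, per_fixation)


def ha_table(records: list[HAScaleRecord],
             assignments: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-child H-A table: child_id, face_type, both log-likelihoods,
    the H-A value and (optionally) the assigned pattern label."""
    rows = []
    for r in records:
        pattern = assignments.get(r.child_id, "") if assignments else ""
        rows.append((r.child_id, r.face_type, r.holistic_loglik,
                     r.analytic_loglik, r.value, pattern))
    return pd.DataFrame(rows, columns=[
        "child_id", "face_type", "holistic_ll", "analytic_ll",
        "ha_scale", "assigned_pattern",
    ])


def mean_face_ha(table: pd.DataFrame) -> pd.Series:
    """Unweighted mean of the per-face H-A values for each child."""
    return table.groupby("child_id")["ha_scale"].mean()
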