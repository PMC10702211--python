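"""Inferential statistics used in the cohort analysis.

Chi-square tests on pattern counts, one-way and two-way (Type-II)
ANOVAs on the H-A scale, Spearman rank correlations against cognitive
scores, and the a-priori noncentral-F sample-size computation.  No
continuity corrections are applied anywhere; Spearman p-values use the
t approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ContingencyTable",
    "PowerSpec",
    "chisq_gof",
    "chisq_independence",
    "one_way_anova",
    "two_way_anova",
    "spearman",
    "anova_sample_size",
    "inflate_sample_size",
    "anova_power",
]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("table must have a positive entry")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels inconsistent with counts shape")


@dataclass
class PowerSpec:
    """A-priori power computation request for a one-way fixed-effects ANOVA."""

    effect_size_f: float
    n_groups: int
    alpha: float = 0.05
    target_power: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be > 0")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")


def chisq_gof(counts, expected_proportions=None) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square (no continuity correction).

    Defaults to a uniform expectation.  Returns (chi2, df, p).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    k = counts.size
    if expected_proportions is None:
        expected_proportions = np.full(k, 1.0 / k)
    props = np.asarray(expected_proportions, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    expected = counts.sum() * props
    if np.any(expected == 0):
        raise ValueError("expected cell count of 0")
    chi2, p = sps.chisquare(counts, f_exp=expected)
    return float(chi2), k - 1, float(p)


def chisq_independence(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row or column marginal")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


def one_way_anova(values_by_group) -> tuple[float, int, int, float]:
    """Classical fixed-effects one-way ANOVA: (F, df1, df2, p)."""
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 groups, each non-empty")
    n = sum(g.size for g in groups)
    df1, df2 = len(groups) - 1, n - len(groups)
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("F undefined: zero within-group variance everywhere")
    F, p = sps.f_oneway(*groups)
    return float(F), df1, df2, float(p)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Between-subjects factorial ANOVA with Type-II sums of squares.

    Returns a DataFrame indexed by effect (A, B, A:B, Residual) with
    columns sum_sq, df, F, p.  Every cell of the crossed design must be
    observed.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "a": pd.Categorical(factor_a),
        "b": pd.Categorical(factor_b),
    })
    if df["a"].nunique() < 2 or df["b"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["a", "b"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty.index)}")
    fit = smf.ols("value ~ C(a) * C(b)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    tab = tab.rename(index={"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B"})
    return tab.rename(columns={"PR(>F)": "p"})


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; p via the
    t approximation.  Returns (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def anova_power(N: int, f: float, n_groups: int, alpha: float) -> float:
    """Achieved power of a one-way fixed-effects ANOVA at total size N,
    using noncentrality lambda = f^2 * N (the G*Power convention)."""
    df1 = n_groups - 1
    df2 = N - n_groups
    if df2 < 1:
        return 0.0
    lam = f * f * N
    crit = sps.f.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - sps.ncf.cdf(crit, df1, df2, lam))


def anova_sample_size(spec: PowerSpec, max_n: int = 1_000_000) -> int:
    """Smallest total N whose achieved noncentral-F power reaches the
    target (lambda = f^2 * N, df1 = groups - 1, df2 = N - groups)."""
    N = spec.n_groups + 1
    while N <= max_n:
        if anova_power(N, spec.effect_size_f, spec.n_groups, spec.alpha) >= spec.target_power:
            return N
        N += 1
    raise ValueError("target power unreachable within the search bound")


def inflate_sample_size(n_min: int, loss_rate: float, inclusion_rate: float) -> int:
    """Inflate a minimum N for attrition and data-inclusion losses:
    ceil(n_min / ((1 - loss_rate) * inclusion_rate))."""
    if not 0 <= loss_rate < 1:
        raise ValueError("loss_rate must be in [0, 1)")
    if not 0 < inclusion_rate <= 1:
        raise ValueError("inclusion_rate must be in (0, 1]")
    return math.ceil(n_min / ((1.0 - loss_rate) * inclusion_rate))
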