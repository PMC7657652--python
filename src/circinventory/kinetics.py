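"""Assay-level computations: X0 RT-qPCR quantification, BrU pulse-chase
decay fitting, BrU-IP synthesis fold changes, and the two-group test
convention used for biochemical replicates.

Decay series follow the pulse-chase design: the first harvested sample
(shortly after label washout) is the time origin and is normalized to 1;
subsequent samples at 3, 6 and 9 h trace first-order loss, so ln(abundance)
is linear in time and the slope gives the decay constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass
class QpcrMeasure:
    """One RT-qPCR measurement: target vs reference quantification cycles."""

    target_cq: float
    reference_cq: float
    efficiency: float = 2.0  # amplification factor per cycle

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")
        if self.target_cq <= 0 or self.reference_cq <= 0:
            raise ValueError("Cq values must be > 0")


def x0_relative(m: QpcrMeasure) -> float:
    """Initial template amount of the target relative to the reference.

    X0 back-computes the starting amount from the quantification cycle,
    X0 = E**(-Cq) up to a shared constant, so the relative level is
    E**(Cq_ref - Cq_target).
    """
    return m.efficiency ** (m.reference_cq - m.target_cq)


@dataclass
class DecaySeries:
    timepoints: Tuple[float, ...]  # hours since chase start
    values: Tuple[float, ...]      # reference-normalized, first point = 1

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.timepoints)
        v = tuple(float(x) for x in self.values)
        if len(t) != len(v):
            raise ValueError("timepoints and values differ in length")
        if len(t) < 3:
            raise ValueError("a decay series needs >= 3 points")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if min(v) <= 0:
            raise ValueError("abundances must be > 0")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "values", v)


@dataclass
class DecayFit:
    rate: float        # per hour; positive for decaying species
    half_life: float   # hours; inf for stable (non-decaying) fits
    r_squared: float
    stable: bool = False


def fit_decay(series: DecaySeries) -> DecayFit:
    """Ordinary least squares of ln(abundance) on time.

    With few timepoints and multiplicative noise, log-linear OLS is the
    standard, stable estimator of a first-order decay constant. A
    non-negative slope is reported as a stable species (infinite half-life)
    rather than a negative rate.
    """
    t = np.asarray(series.timepoints)
    logv = np.log(np.asarray(series.values))
    fit = stats.linregress(t, logv)
    k = -float(fit.slope)
    r2 = float(fit.rvalue) ** 2
    if k <= 0:
        return DecayFit(rate=k, half_life=math.inf, r_squared=r2, stable=True)
    return DecayFit(rate=k, half_life=math.log(2.0) / k, r_squared=r2)


def bru_fold_change(ip_level: float, input_level: float,
                    ref_ip: float, ref_input: float) -> float:
    """Knockdown-vs-control ratio of input-normalized BrU-IP signal."""
    if min(ip_level, input_level, ref_ip, ref_input) <= 0:
        raise ValueError("all levels must be > 0")
    return (ip_level / input_level) / (ref_ip / ref_input)


@dataclass
class TwoGroupResult:
    t: float
    df: float
    p: float
    variance_p: float  # two-sided F-test p for equal variances
    variant: str       # "pooled" | "welch" | "degenerate"


def two_group_test(a: Sequence[float], b: Sequence[float],
                   variance_alpha: float = 0.05) -> TwoGroupResult:
    """Two-tailed two-sample t-test with an F-test variance gate.

    Equality of variances is tested by a two-sided F test; if rejected at
    ``variance_alpha`` the Welch (unequal-variance) variant is used,
    otherwise the pooled Student form. Degenerate zero-variance inputs are
    resolved by convention: identical constant samples give p = 1, constant
    samples with different means give the p -> 0 limit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = len(a) + len(b) - 2
        if a.mean() == b.mean():
            return TwoGroupResult(0.0, df, 1.0, 1.0, "degenerate")
        sign = math.copysign(1.0, a.mean() - b.mean())
        return TwoGroupResult(sign * math.inf, df, 0.0, 1.0, "degenerate")
    f = va / vb if vb > 0 else math.inf
    dfn, dfd = len(a) - 1, len(b) - 1
    if math.isinf(f):
        variance_p = 0.0
    else:
        cdf = stats.f.cdf(f, dfn, dfd)
        variance_p = 2.0 * min(cdf, 1.0 - cdf)
    equal_var = variance_p >= variance_alpha
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return TwoGroupResult(float(res.statistic), df, float(res.pvalue),
                          float(variance_p), "pooled" if equal_var else "welch")
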