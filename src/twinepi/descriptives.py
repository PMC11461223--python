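"""Descriptive statistics and the assumption gates for two-sample testing.

Each genotype comparison is routed to one of three tests by two gates:
Shapiro-Wilk normality per group (violation in either group sends the
comparison to the Mann-Whitney U test) and Levene's mean-centered
homogeneity-of-variances test (violation sends it to Welch's t). Both gates
run at alpha = 0.05 by default and both the tests and the level are
configurable.

Skewness is the adjusted Fisher-Pearson standardized third moment (G1) and
kurtosis the sample-adjusted *excess* kurtosis (G2), so a normal sample has
kurtosis near 0 and platykurtic data go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

GATE_ALPHA = 0.05

STUDENT_T = "student_t"
WELCH_T = "welch_t"
MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class DescriptiveStats:
    """Mean, median, SD (n-1), min, max, skewness (G1), excess kurtosis (G2)."""

    m: float
    mdn: float
    s: float
    min: float
    max: float
    sk: float
    ku: float


@dataclass(frozen=True)
class GateResult:
    p_value: float
    passed: bool


@dataclass(frozen=True)
class GateReport:
    normality_p: tuple[float, float]
    variance_homogeneity_p: float
    decision: str
    gate_alpha: float


def describe(values) -> DescriptiveStats:
    """Summary statistics in published-table shape (M, Mdn, s, Min, Max, Sk, Ku).

    Requires n >= 2 and a non-constant sample; excess kurtosis additionally
    requires n >= 4 and is NaN below that.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError("describe requires a 1-d sample with n >= 2")
    if np.any(np.isnan(x)):
        raise InsufficientDataError("describe requires a complete sample")
    if np.ptp(x) == 0.0:
        raise InsufficientDataError("constant sample: skewness/kurtosis undefined")
    sk = float(stats.skew(x, bias=False))
    ku = float(stats.kurtosis(x, fisher=True, bias=False)) if x.size >= 4 else np.nan
    return DescriptiveStats(
        m=float(np.mean(x)),
        mdn=float(np.median(x)),
        s=float(np.std(x, ddof=1)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        sk=sk,
        ku=ku,
    )


def normality_gate(values, alpha: float = GATE_ALPHA) -> GateResult:
    """Shapiro-Wilk normality check; passes iff p >= alpha."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("normality gate requires n >= 3")
    if np.ptp(x) == 0.0:
        # a constant sample is grossly non-normal for routing purposes
        return GateResult(0.0, False)
    p = float(stats.shapiro(x).pvalue)
    return GateResult(p, p >= alpha)


def variance_gate(x, y, alpha: float = GATE_ALPHA) -> GateResult:
    """Levene's test (mean-centered) for homogeneity; passes iff p >= alpha.

    Degenerate convention: two constant samples with equal values pass.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("variance gate requires n >= 2 per group")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        equal = x[0] == y[0]
        return GateResult(1.0 if equal else 0.0, bool(equal))
    p = float(stats.levene(x, y, center="mean").pvalue)
    return GateResult(p, p >= alpha)


def choose_test(x, y, gate_alpha: float = GATE_ALPHA) -> GateReport:
    """Route a two-sample comparison: normality failure in either group ->
    Mann-Whitney; else variance heterogeneity -> Welch; else Student t."""
    norm_x = normality_gate(x, gate_alpha)
    norm_y = normality_gate(y, gate_alpha)
    var = variance_gate(x, y, gate_alpha)
    if not (norm_x.passed and norm_y.passed):
        decision = MANN_WHITNEY
    elif not var.passed:
        decision = WELCH_T
    else:
        decision = STUDENT_T
    return GateReport(
        normality_p=(norm_x.p_value, norm_y.p_value),
        variance_homogeneity_p=var.p_value,
        decision=decision,
        gate_alpha=gate_alpha,
    )
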