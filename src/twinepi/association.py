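"""Dominant-model rs4680 association battery over the NEO-PI-R scales.

Twins carrying at least one Val allele (Val/Val or Val/Met) form the Val+
group; Met/Met homozygotes form Met+. For each of the 35 scales the
assumption gates route the comparison to Student's t, Welch's t, or the
Mann-Whitney U test; effect sizes are Cohen's d (t variants, with a
noncentral-t confidence interval) or the rank-biserial correlation
r = 2U/(n1 n2) - 1 (U variant, with a normal-approximation CI on U). The
sign convention is positive when the Met+ group tends higher. Bonferroni
adjustment is min(1, m p) with a configurable family size m (default 2,
the convention every printed adjusted p in the source table follows).

Twins are treated as independent observations here; co-twin clustering is
a documented caveat, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .catalog import DEFAULT_CATALOG, ScaleCatalog
from .cohort import Cohort, GenotypeCall
from .descriptives import GATE_ALPHA, MANN_WHITNEY, STUDENT_T, WELCH_T, choose_test
from .errors import InsufficientDataError, ParameterError

DEFAULT_BONFERRONI_M = 2
#: exact Mann-Whitney null distribution up to this per-group size
EXACT_U_MAX_N = 20


@dataclass(frozen=True)
class GenotypeGroups:
    val_plus: frozenset[str]
    met_plus: frozenset[str]

    @property
    def n_val(self) -> int:
        return len(self.val_plus)

    @property
    def n_met(self) -> int:
        return len(self.met_plus)


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    allele_freq_p: float
    report_df: int


@dataclass(frozen=True)
class AssociationResult:
    scale: str
    test_name: str
    statistic: float
    df: Optional[float]
    p: float
    p_bonf: float
    effect: float
    effect_ci_low: float
    effect_ci_high: float
    direction: int  # +1 when Met+ tends higher, -1 lower, 0 no trend


def dominant_grouping(cohort: Cohort) -> GenotypeGroups:
    """Partition genotyped twins into Val+ (any Val allele) and Met+ (Met/Met)."""
    val, met = set(), set()
    for t in cohort.genotyped_twins:
        (val if t.genotype.carries_val else met).add(t.twin_id)
    if not val and not met:
        raise InsufficientDataError("no genotyped twins in cohort")
    return GenotypeGroups(frozenset(val), frozenset(met))


def hwe_chi_square(
    counts: tuple[int, int, int], report_df: int = 1
) -> HweResult:
    """Hardy-Weinberg chi-square from (n_MetMet, n_MetVal, n_ValVal) counts.

    The Met allele frequency is estimated from the data, so the test has
    1 degree of freedom; ``report_df`` only relabels the df in reports and
    never changes the computation. Monomorphic samples give chi2 = 0 by
    convention (expected = observed).
    """
    n_mm, n_mv, n_vv = counts
    if min(counts) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_mm + n_mv + n_vv
    if n == 0:
        raise ParameterError("total genotype count must be positive")
    p_met = (2 * n_mm + n_mv) / (2 * n)
    q = 1.0 - p_met
    if p_met in (0.0, 1.0):
        expected = (float(n_mm), float(n_mv), float(n_vv))
        chi2 = 0.0
    else:
        expected = (n * p_met**2, n * 2 * p_met * q, n * q**2)
        chi2 = float(
            sum((o - e) ** 2 / e for o, e in zip(counts, expected))
        )
    return HweResult(
        chi2=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        observed=counts,
        expected=expected,
        allele_freq_p=p_met,
        report_df=report_df,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U for the first sample, with a two-sided p-value.

    U counts cross-group pairs where an x exceeds a y, plus half-credit for
    ties. The p-value uses the exact null distribution when both groups are
    small (n <= 20) and tie-free, and the tie-corrected normal approximation
    with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = min(x.size, y.size) <= EXACT_U_MAX_N
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def student_t(x, y) -> tuple[float, float, float]:
    """Pooled-variance t-test: (t, df, two-sided p)."""
    return _t_test(x, y, equal_var=True)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's t-test with Satterthwaite df: (t, df, two-sided p)."""
    return _t_test(x, y, equal_var=False)


def _t_test(x, y, equal_var: bool) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("t-tests require n >= 2 per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    n1, n2 = x.size, y.size
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            df = n1 + n2 - 2
            return 0.0, float(df), 1.0
        raise InsufficientDataError("zero variance in both groups, unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        df = float(
            (vx / n1 + vy / n2) ** 2
            / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1))
        )
    return float(res.statistic), df, float(res.pvalue)


def cohens_d_ci(x, y, level: float = 0.95) -> tuple[float, float, float]:
    """Cohen's d (pooled SD) with a noncentral-t confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("Cohen's d requires n >= 2 per group")
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / (
        n1 + n2 - 2
    )
    if sp2 == 0.0:
        raise InsufficientDataError("zero pooled SD: Cohen's d undefined")
    d = float((np.mean(x) - np.mean(y)) / math.sqrt(sp2))
    df = n1 + n2 - 2
    scale = math.sqrt(n1 * n2 / (n1 + n2))
    t_obs = d * scale
    alpha = 1.0 - level

    def _nc_for(prob: float) -> float:
        # noncentrality nc with P(T_{df,nc} <= t_obs) = prob; nct.cdf can
        # underflow to NaN deep in the tails, where the limits are 0/1
        def f(nc: float) -> float:
            val = stats.nct.cdf(t_obs, df, nc)
            if math.isnan(val):
                val = 0.0 if nc > t_obs else 1.0
            return val - prob

        half = 2.0
        while f(t_obs - half) * f(t_obs + half) > 0 and half < 64.0:
            half *= 2.0
        return brentq(f, t_obs - half, t_obs + half, xtol=1e-10)

    nc_low = _nc_for(1.0 - alpha / 2.0)
    nc_high = _nc_for(alpha / 2.0)
    return d, nc_low / scale, nc_high / scale


def rank_biserial(u: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 2U/(n1 n2) - 1, in [-1, 1]."""
    if n1 < 1 or n2 < 1:
        raise ParameterError("group sizes must be >= 1")
    if not 0 <= u <= n1 * n2:
        raise ParameterError(f"U = {u} outside [0, {n1 * n2}]")
    return 2.0 * u / (n1 * n2) - 1.0


def rank_biserial_ci(
    u: float, n1: int, n2: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI on U, mapped through r = 2U/(n1 n2) - 1.

    SE(U) = sqrt(n1 n2 (n1 + n2 + 1) / 12) under the null-variance
    approximation; the interval is clipped to [-1, 1].
    """
    rank_biserial(u, n1, n2)  # domain check
    se_u = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = 2.0 * (u - z * se_u) / (n1 * n2) - 1.0
    hi = 2.0 * (u + z * se_u) / (n1 * n2) - 1.0
    return max(lo, -1.0), min(hi, 1.0)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m p)."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"p-value outside [0, 1]: {p}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ParameterError(f"family size m must be an integer >= 1, got {m}")
    return min(1.0, m * p)


def run_snp_battery(
    cohort: Cohort,
    gate_alpha: float = GATE_ALPHA,
    bonferroni_m: int = DEFAULT_BONFERRONI_M,
    catalog: ScaleCatalog = DEFAULT_CATALOG,
) -> list[AssociationResult]:
    """Gated two-sample battery over all 35 scales, Met+ vs Val+.

    Output rows follow catalog order (each domain, then its six facets).
    """
    groups = dominant_grouping(cohort)
    if groups.n_val == 0 or groups.n_met == 0:
        raise InsufficientDataError(
            f"both genotype groups must be non-empty "
            f"(Val+ = {groups.n_val}, Met+ = {groups.n_met})"
        )
    by_id = {t.twin_id: t for t in cohort.twins}
    results: list[AssociationResult] = []
    for scale in catalog.all_scales:
        met_scores = np.array(
            [by_id[i].traits.score(scale) for i in sorted(groups.met_plus)]
        )
        val_scores = np.array(
            [by_id[i].traits.score(scale) for i in sorted(groups.val_plus)]
        )
        met_scores = met_scores[~np.isnan(met_scores)]
        val_scores = val_scores[~np.isnan(val_scores)]
        try:
            report = choose_test(met_scores, val_scores, gate_alpha)
        except InsufficientDataError:
            # flagged, not dropped: the battery always has 35 rows
            results.append(
                AssociationResult(
                    scale=scale, test_name="insufficient_data",
                    statistic=math.nan, df=None, p=math.nan, p_bonf=math.nan,
                    effect=math.nan, effect_ci_low=math.nan,
                    effect_ci_high=math.nan, direction=0,
                )
            )
            continue
        if report.decision == MANN_WHITNEY:
            u, p = mann_whitney(met_scores, val_scores)
            n1, n2 = met_scores.size, val_scores.size
            effect = rank_biserial(u, n1, n2)
            ci_lo, ci_hi = rank_biserial_ci(u, n1, n2)
            stat, df = u, None
        else:
            if report.decision == STUDENT_T:
                stat, df, p = student_t(met_scores, val_scores)
            else:
                stat, df, p = welch_t(met_scores, val_scores)
            effect, ci_lo, ci_hi = cohens_d_ci(met_scores, val_scores)
        results.append(
            AssociationResult(
                scale=scale,
                test_name=report.decision,
                statistic=stat,
                df=df,
                p=p,
                p_bonf=bonferroni_adjust(p, bonferroni_m),
                effect=effect,
                effect_ci_low=ci_lo,
                effect_ci_high=ci_hi,
                direction=int(np.sign(effect)),
            )
        )
    return results
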