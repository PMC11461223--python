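"""Barnard's unconditional exact test for 2x2 tables, from scratch.

Model: two independent binomials, X1 ~ Bin(n1, pi1) and X2 ~ Bin(n2, pi2),
with only the row sizes fixed. Under H0 both rows share a common success
probability pi — the nuisance parameter. The test orders tables by a pooled
Wald/score statistic

    T = (p1_hat - p2_hat) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)),

with pooled p_hat = (x1 + x2)/(n1 + n2) and the convention T = 0 when the
pooled proportion is degenerate (0 or 1). The p-value is the supremum over
pi in (0, 1) of the null probability of the extreme set

    greater:   { (k1, k2) : T(k1, k2) >= T_obs }
    less:      { (k1, k2) : T(k1, k2) <= T_obs }
    two_sided: { (k1, k2) : |T(k1, k2)| >= |T_obs| }

(ties in T included). Unlike Fisher's conditional test it does not condition
on the column margin, which buys power at small sample sizes — the reason
this test is preferred for the discordant-twin contingency batteries.

The supremum is located on a uniform grid over (eps, 1 - eps) and then
sharpened by bounded scalar maximization around the best grid point; the
null probability is a polynomial in pi restricted to the extreme set, so it
is smooth with few local maxima at these table sizes.

A dense-grid brute-force oracle (`barnard_oracle`) implements the same
definition with no refinement and exhaustive enumeration, for verification
only. `fisher_p` provides the conditional comparator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom, hypergeom

from .errors import ParameterError

ALTERNATIVES = ("greater", "less", "two_sided")
_EPS = 1e-6
#: tolerance for tie detection in the ordering statistic
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class Table2x2:
    """A 2x2 table with fixed row sizes; x counts the "success" column."""

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ParameterError("row sizes must be >= 1")
        if not (0 <= self.x1 <= self.n1 and 0 <= self.x2 <= self.n2):
            raise ParameterError("success counts must satisfy 0 <= x <= n")

    def swapped(self) -> "Table2x2":
        return Table2x2(self.x2, self.n2, self.x1, self.n1)


@dataclass(frozen=True)
class BarnardResult:
    wald_stat: float
    p_value: float
    pi_at_sup: float
    alternative: str
    grid_size: int


def wald_statistic(table: Table2x2) -> float:
    """Pooled-variance Wald statistic; 0 by convention for degenerate tables."""
    x1, n1, x2, n2 = table.x1, table.n1, table.x2, table.n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    return (x1 / n1 - x2 / n2) / se


@lru_cache(maxsize=512)
def _stat_matrix(n1: int, n2: int) -> np.ndarray:
    """T(k1, k2) over the full (n1+1) x (n2+1) sample space."""
    k1 = np.arange(n1 + 1)[:, None]
    k2 = np.arange(n2 + 1)[None, :]
    pooled = (k1 + k2) / (n1 + n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
        t = (k1 / n1 - k2 / n2) / se
    return np.where((pooled <= 0.0) | (pooled >= 1.0), 0.0, t)


def _extreme_mask(n1: int, n2: int, t_obs: float, alternative: str) -> np.ndarray:
    t = _stat_matrix(n1, n2)
    if alternative == "greater":
        return t >= t_obs - _TIE_TOL
    if alternative == "less":
        return t <= t_obs + _TIE_TOL
    if alternative == "two_sided":
        return np.abs(t) >= abs(t_obs) - _TIE_TOL
    raise ParameterError(f"invalid alternative: {alternative!r}")


def _null_prob(pi: float, n1: int, n2: int, mask: np.ndarray) -> float:
    p1 = binom.pmf(np.arange(n1 + 1), n1, pi)
    p2 = binom.pmf(np.arange(n2 + 1), n2, pi)
    return float(p1 @ mask @ p2)


@lru_cache(maxsize=64)
def _pmf_grid(n: int, grid_points: int) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(_EPS, 1.0 - _EPS, grid_points)
    pmf = binom.pmf(np.arange(n + 1)[None, :], n, grid[:, None])
    return grid, pmf


@lru_cache(maxsize=200_000)
def _barnard_p_cached(
    x1: int, n1: int, x2: int, n2: int,
    alternative: str, grid_points: int, refine: bool,
) -> tuple[float, float, float]:
    t_obs = wald_statistic(Table2x2(x1, n1, x2, n2))
    mask = _extreme_mask(n1, n2, t_obs, alternative)
    grid, pmf1 = _pmf_grid(n1, grid_points)
    _, pmf2 = _pmf_grid(n2, grid_points)
    # p(pi) on the grid for every pi at once: (G, n1+1) @ (n1+1, n2+1) -> (G, n2+1)
    probs = np.einsum("gj,gj->g", pmf1 @ mask, pmf2)
    best = int(np.argmax(probs))
    p_sup = float(probs[best])
    pi_sup = float(grid[best])
    if refine:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid_points - 1)]
        res = minimize_scalar(
            lambda pi: -_null_prob(pi, n1, n2, mask),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if -res.fun > p_sup:
            p_sup = float(-res.fun)
            pi_sup = float(res.x)
    return t_obs, min(p_sup, 1.0), pi_sup


def barnard_p(
    table: Table2x2,
    alternative: str = "two_sided",
    grid_points: int = 1001,
    refine: bool = True,
) -> BarnardResult:
    """Barnard unconditional exact p-value (see module docstring)."""
    if alternative not in ALTERNATIVES:
        raise ParameterError(f"invalid alternative: {alternative!r}")
    t_obs, p, pi_sup = _barnard_p_cached(
        table.x1, table.n1, table.x2, table.n2,
        alternative, grid_points, refine,
    )
    return BarnardResult(t_obs, p, pi_sup, alternative, grid_points)


def barnard_oracle(
    table: Table2x2, alternative: str = "two_sided", grid_points: int = 100_001
) -> float:
    """Definitional brute-force p-value: exhaustive enumeration, dense grid.

    Verification oracle only — no refinement, quadratic enumeration, size
    guard at n1 + n2 <= 60.
    """
    if alternative not in ALTERNATIVES:
        raise ParameterError(f"invalid alternative: {alternative!r}")
    n1, n2 = table.n1, table.n2
    if n1 + n2 > 60:
        raise ParameterError("oracle size guard: n1 + n2 must be <= 60")
    t_obs = wald_statistic(table)
    extreme = []
    for k1 in range(n1 + 1):
        for k2 in range(n2 + 1):
            t = wald_statistic(Table2x2(k1, n1, k2, n2))
            if alternative == "greater":
                hit = t >= t_obs - _TIE_TOL
            elif alternative == "less":
                hit = t <= t_obs + _TIE_TOL
            else:
                hit = abs(t) >= abs(t_obs) - _TIE_TOL
            if hit:
                extreme.append((k1, k2))
    grid = np.linspace(_EPS, 1.0 - _EPS, grid_points)
    total = np.zeros_like(grid)
    for k1, k2 in extreme:
        total += binom.pmf(k1, n1, grid) * binom.pmf(k2, n2, grid)
    return float(min(total.max(), 1.0))


def fisher_p(table: Table2x2, alternative: str = "two_sided") -> float:
    """Fisher's conditional exact p-value (hypergeometric, both margins fixed).

    Two-sided by the usual convention of summing the probabilities of all
    tables no more probable than the observed one.
    """
    if alternative not in ALTERNATIVES:
        raise ParameterError(f"invalid alternative: {alternative!r}")
    x1, n1, x2, n2 = table.x1, table.n1, table.x2, table.n2
    m = x1 + x2                       # successes margin
    n = n1 + n2
    support = np.arange(max(0, m - n2), min(n1, m) + 1)
    pmf = hypergeom.pmf(support, n, m, n1)
    if alternative == "greater":
        return float(pmf[support >= x1].sum())
    if alternative == "less":
        return float(pmf[support <= x1].sum())
    obs = hypergeom.pmf(x1, n, m, n1)
    return float(min(pmf[pmf <= obs * (1 + 1e-12)].sum(), 1.0))
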