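"""Discordant-MZ-pair methylation-trait contingency batteries.

Each MZ pair is oriented by within-pair methylation rank at one CpG site:
the co-twin with the higher percent methylation is the H twin, the other L.
For a given trait and one-sided alternative, each twin is then classified by
whether its trait score is lower than its co-twin's, with alternative-
specific tie rules:

* "greater" (H1: p1 > p2, where p1 is the probability a twin has higher
  methylation *and* the lower trait score): ties count as "not higher", so
  tied co-twins both land in the success ("lower or equal") column;
* "less" (H1: p1 < p2): ties count as "not lower", so tied co-twins both
  land in the failure column.

Every non-excluded pair contributes two observations — one to the H row and
one to the L row — giving a 2x2 table with fixed, equal row sizes whose
success column is the "lower trait" side; Barnard's unconditional exact test
(module :mod:`twinepi.exact2x2`) is applied with the same-named alternative.
The mirrored construction makes the two rows statistically dependent; this
is replicated as specified and documented as a caveat, not corrected.

Exclusions are local: a methylation tie or missing value at CpG k removes
the pair from CpG-k cells only; a missing trait score removes the pair from
that (CpG, scale) cell only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .catalog import DEFAULT_CATALOG, ScaleCatalog
from .cohort import Cohort, N_CPG_SITES, Twin, TwinPair
from .errors import InsufficientDataError, ParameterError
from .exact2x2 import Table2x2, barnard_p

logger = logging.getLogger("twinepi")

ALTERNATIVES = ("greater", "less")
PAIR_CONTRIBUTIONS = ("both_twins", "index_twin")


@dataclass(frozen=True)
class PairOrientation:
    high_meth_twin: Optional[Twin]
    low_meth_twin: Optional[Twin]
    excluded: bool
    reason: Optional[str] = None


@dataclass(frozen=True)
class DiscordanceClassification:
    """One twin's (methylation rank, trait status) label for one cell."""

    pair_id: str
    cpg: int
    scale: str
    meth_rank: str      # "H" | "L"
    lower_trait: bool   # success-column membership under the tie rule
    alternative: str


@dataclass(frozen=True)
class BatteryCell:
    cpg: int
    scale: str
    alternative: str
    table: Table2x2
    n_pairs_used: int
    n_pairs_excluded: int
    p_value: float


def orient_pair(pair: TwinPair, cpg: int) -> PairOrientation:
    """Rank co-twins by methylation at a 1-based CpG index.

    Missing values or an exact tie exclude the pair for this CpG only.
    """
    a, b = pair.twins
    va = a.methylation.site(cpg) if a.methylation is not None else math.nan
    vb = b.methylation.site(cpg) if b.methylation is not None else math.nan
    if math.isnan(va) or math.isnan(vb):
        return PairOrientation(None, None, True, "missing")
    if va == vb:
        return PairOrientation(None, None, True, "methylation tie")
    if va > vb:
        return PairOrientation(a, b, False)
    return PairOrientation(b, a, False)


def classify_pair(
    pair: TwinPair, cpg: int, scale: str, alternative: str
) -> Optional[tuple[DiscordanceClassification, DiscordanceClassification]]:
    """Two per-twin records (H row, L row) for one (CpG, scale, alternative).

    Returns None when the pair is excluded (methylation tie/missing, or a
    missing trait score).
    """
    if alternative not in ALTERNATIVES:
        raise ParameterError(f"invalid alternative: {alternative!r}")
    orient = orient_pair(pair, cpg)
    if orient.excluded:
        return None
    hi, lo = orient.high_meth_twin, orient.low_meth_twin
    t_hi, t_lo = hi.traits.score(scale), lo.traits.score(scale)
    if math.isnan(t_hi) or math.isnan(t_lo):
        return None
    if alternative == "greater":
        # ties are "not higher" and belong to the success column
        success_hi = t_hi <= t_lo
        success_lo = t_lo <= t_hi
    else:
        # ties are "not lower" and belong to the failure column
        success_hi = t_hi < t_lo
        success_lo = t_lo < t_hi
    return (
        DiscordanceClassification(
            pair.pair_id, cpg, scale, "H", success_hi, alternative
        ),
        DiscordanceClassification(
            pair.pair_id, cpg, scale, "L", success_lo, alternative
        ),
    )


def build_table(
    pairs: list[TwinPair],
    cpg: int,
    scale: str,
    alternative: str,
    pair_contribution: str = "both_twins",
) -> BatteryCell:
    """Assemble the 2x2 count table for one battery cell (p-value unset).

    Rows are the methylation ranks (H, L); the success column is the "lower
    trait" side under the alternative's tie rule. With the default
    ``both_twins`` contribution each usable pair adds one observation per
    row; with ``index_twin`` only the first co-twin (by within-pair order)
    is classified, rows are its methylation rank, and row sizes are random.
    """
    if pair_contribution not in PAIR_CONTRIBUTIONS:
        raise ParameterError(f"invalid pair_contribution: {pair_contribution!r}")
    x_h = x_l = n_used = 0
    n_h = n_l = 0
    n_excluded = 0
    for pair in pairs:
        recs = classify_pair(pair, cpg, scale, alternative)
        if recs is None:
            n_excluded += 1
            logger.debug(
                "pair %s excluded at cpg%d/%s", pair.pair_id, cpg, scale
            )
            continue
        n_used += 1
        rec_h, rec_l = recs
        if pair_contribution == "both_twins":
            n_h += 1
            n_l += 1
            x_h += int(rec_h.lower_trait)
            x_l += int(rec_l.lower_trait)
        else:
            # index twin: classify the first co-twin only
            first = pair.twins[0]
            orient = orient_pair(pair, cpg)
            if orient.high_meth_twin.twin_id == first.twin_id:
                n_h += 1
                x_h += int(rec_h.lower_trait)
            else:
                n_l += 1
                x_l += int(rec_l.lower_trait)
    if n_used == 0:
        raise InsufficientDataError(
            f"no usable pairs for cpg{cpg}/{scale} ({alternative})"
        )
    if pair_contribution == "index_twin" and (n_h == 0 or n_l == 0):
        raise InsufficientDataError(
            f"index-twin contribution left an empty row for cpg{cpg}/{scale}"
        )
    return BatteryCell(
        cpg=cpg,
        scale=scale,
        alternative=alternative,
        table=Table2x2(x_h, n_h, x_l, n_l),
        n_pairs_used=n_used,
        n_pairs_excluded=n_excluded,
        p_value=math.nan,
    )


def run_epigenetic_battery(
    cohort: Cohort,
    alternatives: tuple[str, ...] = ALTERNATIVES,
    grid_points: int = 1001,
    pair_contribution: str = "both_twins",
    catalog: ScaleCatalog = DEFAULT_CATALOG,
) -> list[BatteryCell]:
    """Barnard battery over 5 CpG sites x 35 scales x the alternatives.

    Cells are ordered (CpG ascending, catalog scale order, alternative
    order); per-cell exclusions follow the locality rules above.
    """
    pairs = cohort.mz_pairs_with_methylation
    if not pairs:
        raise InsufficientDataError("epigenetic view is empty")
    for alt in alternatives:
        if alt not in ALTERNATIVES:
            raise ParameterError(f"invalid alternative: {alt!r}")
    cells: list[BatteryCell] = []
    for cpg in range(1, N_CPG_SITES + 1):
        for scale in catalog.all_scales:
            for alt in alternatives:
                cell = build_table(pairs, cpg, scale, alt, pair_contribution)
                res = barnard_p(cell.table, alt, grid_points=grid_points)
                cells.append(
                    BatteryCell(
                        cpg=cell.cpg,
                        scale=cell.scale,
                        alternative=cell.alternative,
                        table=cell.table,
                        n_pairs_used=cell.n_pairs_used,
                        n_pairs_excluded=cell.n_pairs_excluded,
                        p_value=res.p_value,
                    )
                )
    return cells


def summarize_significant(
    cells: list[BatteryCell], alpha: float = 0.05
) -> dict:
    """Filter cells at p < alpha and emit bubble-chart-ready records.

    Bubble sizes are the four cell counts of each significant table; the
    battery itself applies no multiple-testing adjustment (raw p-values, as
    the discordance analysis reports them) — downstream consumers may add
    their own.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("alpha must lie in [0, 1]")
    significant = [c for c in cells if c.p_value <= alpha and alpha > 0.0]
    bubbles = []
    for c in significant:
        t = c.table
        bubbles.append(
            {
                "cpg": c.cpg,
                "scale": c.scale,
                "alternative": c.alternative,
                "counts": {
                    "H_lower": t.x1,
                    "H_not_lower": t.n1 - t.x1,
                    "L_lower": t.x2,
                    "L_not_lower": t.n2 - t.x2,
                },
                "n_pairs_excluded": c.n_pairs_excluded,
                "p": c.p_value,
            }
        )
    return {
        "alpha": alpha,
        "n_cells": len(cells),
        "n_significant": len(significant),
        "cells": significant,
        "bubbles": bubbles,
    }
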