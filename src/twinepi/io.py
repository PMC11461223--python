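"""CSV/JSON readers and writers for cohorts and result tables.

One input dialect: comma-separated UTF-8 wide format, one row per twin, '.'
decimal separator, empty cell = missing. Result tables are written with
fixed precision (p-values to 4 decimals, effect sizes to 3) so that
round-tripping is exact up to the declared precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from .catalog import DEFAULT_CATALOG, ScaleCatalog
from .cohort import (
    Cohort,
    GenotypeCall,
    MethylationProfile,
    N_CPG_SITES,
    TraitProfile,
    Twin,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger("twinepi")

MANDATORY_COLUMNS = ("pair_id", "twin_id", "zygosity", "sex", "age", "genotype")
CPG_COLUMNS = tuple(f"cpg{i}" for i in range(1, N_CPG_SITES + 1))

#: columns rounded on export: p-like to 4 decimals, effect-like to 3
_PRECISION = {
    "p": 4, "p_bonf": 4, "p_value": 4, "gate_normality_p_met": 4,
    "gate_normality_p_val": 4, "gate_variance_p": 4,
    "effect": 3, "effect_ci_low": 3, "effect_ci_high": 3,
}


def neo_column(scale: str, catalog: ScaleCatalog = DEFAULT_CATALOG) -> str:
    return f"neo_{catalog.canonicalize(scale)}"


def cohort_columns(catalog: ScaleCatalog = DEFAULT_CATALOG) -> list[str]:
    return (
        list(MANDATORY_COLUMNS)
        + list(CPG_COLUMNS)
        + [neo_column(s, catalog) for s in catalog.all_scales]
    )


def _row_to_twin(row: pd.Series, catalog: ScaleCatalog) -> Twin:
    cpg = tuple(
        float(row[c]) if not pd.isna(row[c]) else math.nan for c in CPG_COLUMNS
    )
    meth = MethylationProfile(cpg) if any(not math.isnan(v) for v in cpg) else None
    scores = {
        s: (float(row[neo_column(s, catalog)])
            if not pd.isna(row[neo_column(s, catalog)]) else math.nan)
        for s in catalog.all_scales
    }
    genotype = (
        GenotypeCall.MISSING
        if pd.isna(row["genotype"])
        else GenotypeCall.parse(str(row["genotype"]))
    )
    return Twin(
        twin_id=str(row["twin_id"]),
        pair_id=str(row["pair_id"]),
        zygosity=str(row["zygosity"]).strip().upper(),
        sex=str(row["sex"]).strip().upper(),
        age=float(row["age"]),
        genotype=genotype,
        traits=TraitProfile(scores, catalog),
        methylation=meth,
    )


def read_cohort_csv(
    path: str | Path,
    strict: bool = False,
    catalog: ScaleCatalog = DEFAULT_CATALOG,
) -> Cohort:
    """Read and validate a wide-format cohort CSV.

    With ``strict=False`` rows failing validation are dropped with a logged
    warning and pairs left incomplete are dropped too; with ``strict=True``
    any violation raises.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in cohort_columns(catalog) if c not in frame.columns]
    if missing:
        raise FormatError(f"cohort CSV lacks mandatory columns: {missing}")

    twins: list[Twin] = []
    for _, row in frame.iterrows():
        try:
            twins.append(_row_to_twin(row, catalog))
        except ValidationError as exc:
            if strict:
                raise
            logger.warning("dropping twin %r: %s", row.get("twin_id"), exc)

    seen: set[str] = set()
    deduped: list[Twin] = []
    for t in twins:
        if t.twin_id in seen:
            raise ValidationError(f"duplicated twin_id: {t.twin_id}")
        seen.add(t.twin_id)
        deduped.append(t)

    by_pair: dict[str, list[Twin]] = {}
    for t in deduped:
        by_pair.setdefault(t.pair_id, []).append(t)
    kept: list[Twin] = []
    for pid, members in by_pair.items():
        if len(members) != 2:
            if strict:
                raise ValidationError(
                    f"pair {pid} has {len(members)} members (expected 2)"
                )
            logger.warning(
                "dropping pair %s with %d member(s)", pid, len(members)
            )
            continue
        kept.extend(members)
    return Cohort(kept)


def write_cohort_csv(
    cohort: Cohort, path: str | Path, catalog: ScaleCatalog = DEFAULT_CATALOG
) -> Path:
    rows = []
    for t in cohort.twins:
        row: dict[str, Any] = {
            "pair_id": t.pair_id, "twin_id": t.twin_id,
            "zygosity": t.zygosity, "sex": t.sex, "age": t.age,
            "genotype": "" if t.genotype is GenotypeCall.MISSING
            else t.genotype.value,
        }
        for i, c in enumerate(CPG_COLUMNS):
            v = t.methylation.cpg[i] if t.methylation is not None else math.nan
            row[c] = "" if math.isnan(v) else v
        for s in catalog.all_scales:
            v = t.traits.score(s)
            row[neo_column(s, catalog)] = "" if math.isnan(v) else v
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cohort_columns(catalog))
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def _as_record(item: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(item) and not isinstance(item, type):
        return dataclasses.asdict(item)
    if isinstance(item, dict):
        return dict(item)
    raise FormatError(f"cannot serialize record of type {type(item).__name__}")


def _format_value(key: str, value: Any) -> Any:
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        digits = _PRECISION.get(key)
        if digits is not None:
            return format(value, f".{digits}f")
    return value


def write_results_csv(rows: Iterable[Any], path: str | Path) -> Path:
    """Write homogeneous result records with deterministic column order.

    p-values are serialized to 4 decimals and effect sizes to 3 (banker's
    rounding via float formatting), matching the precision of a published
    association table.
    """
    records = [_as_record(r) for r in rows]
    if records:
        columns = list(records[0])
        for r in records:
            if list(r) != columns:
                raise FormatError("heterogeneous record schema in results rows")
    else:
        columns = []
    formatted = [
        {k: _format_value(k, v) for k, v in r.items()} for r in records
    ]
    frame = pd.DataFrame(formatted, columns=columns or None)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def write_contingency_json(cells: Sequence[Any], path: str | Path) -> Path:
    """Export battery cells as JSON records for bubble-chart front-ends."""
    payload = []
    for cell in cells:
        t = cell.table
        payload.append(
            {
                "cpg": cell.cpg,
                "scale": cell.scale,
                "alternative": cell.alternative,
                "a": t.x1, "b": t.n1 - t.x1,
                "c": t.x2, "d": t.n2 - t.x2,
                "n_pairs_excluded": cell.n_pairs_excluded,
                "p": cell.p_value,
            }
        )
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path
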