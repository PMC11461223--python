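"""Cohort data model: twins, pairs, genotype, methylation and trait profiles.

A cohort is a flat list of twins; derived views group them into pairs and
select the monozygotic subset with complete methylation data (the
"epigenetic view" used by the discordant-pair analysis). Two nested samples
are modeled: the full genotyped sample feeds the SNP association battery,
while only MZ pairs where both co-twins carry complete 5-site methylation
and trait data enter the epigenetic arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .catalog import DEFAULT_CATALOG, ScaleCatalog
from .errors import ValidationError

N_CPG_SITES = 5
MIN_AGE = 18


class GenotypeCall(Enum):
    """rs4680 genotype call; Met/Met is the low-activity homozygote."""

    MET_MET = "Met/Met"
    MET_VAL = "Met/Val"
    VAL_VAL = "Val/Val"
    MISSING = "missing"

    @classmethod
    def parse(cls, text: str) -> "GenotypeCall":
        key = text.strip().lower().replace("/", "").replace("_", "")
        table = {
            "metmet": cls.MET_MET,
            "metval": cls.MET_VAL,
            "valmet": cls.MET_VAL,
            "valval": cls.VAL_VAL,
            "": cls.MISSING,
            "missing": cls.MISSING,
            "na": cls.MISSING,
        }
        try:
            return table[key]
        except KeyError:
            raise ValidationError(f"unrecognized genotype call: {text!r}") from None

    @property
    def carries_val(self) -> bool:
        return self in (GenotypeCall.MET_VAL, GenotypeCall.VAL_VAL)


@dataclass(frozen=True)
class MethylationProfile:
    """Percent methylation at the 5 assayed CpG sites; NaN marks a missing site."""

    cpg: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cpg) != N_CPG_SITES:
            raise ValidationError(
                f"methylation profile must have {N_CPG_SITES} sites, got {len(self.cpg)}"
            )
        for v in self.cpg:
            if not math.isnan(v) and not (0.0 <= v <= 100.0):
                raise ValidationError(f"percent methylation out of [0, 100]: {v}")

    def site(self, cpg_index: int) -> float:
        """Value at 1-based CpG index (CpG1..CpG5, assay order)."""
        if not 1 <= cpg_index <= N_CPG_SITES:
            raise ValidationError(f"CpG index out of range: {cpg_index}")
        return self.cpg[cpg_index - 1]

    @property
    def complete(self) -> bool:
        return not any(math.isnan(v) for v in self.cpg)


@dataclass(frozen=True)
class TraitProfile:
    """NEO-PI-R scale scores keyed by canonical scale name (35 scales)."""

    scores: dict[str, float]
    catalog: ScaleCatalog = field(default=DEFAULT_CATALOG, compare=False)

    def __post_init__(self) -> None:
        canon: dict[str, float] = {}
        for name, value in self.scores.items():
            key = self.catalog.canonicalize(name)
            if not math.isnan(value):
                lo, hi = self.catalog.score_range(key)
                if not lo <= value <= hi:
                    raise ValidationError(
                        f"score {value} for {key!r} outside [{lo}, {hi}]"
                    )
            canon[key] = value
        object.__setattr__(self, "scores", canon)

    def score(self, scale: str) -> float:
        key = self.catalog.canonicalize(scale)
        return self.scores.get(key, math.nan)

    @property
    def complete(self) -> bool:
        return all(
            not math.isnan(self.scores.get(s, math.nan))
            for s in self.catalog.all_scales
        )


@dataclass(frozen=True)
class Twin:
    twin_id: str
    pair_id: str
    zygosity: str  # "MZ" | "DZ"
    sex: str       # "F" | "M"
    age: float
    genotype: GenotypeCall
    traits: TraitProfile
    methylation: Optional[MethylationProfile] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise ValidationError(f"zygosity must be MZ or DZ, got {self.zygosity!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if self.age < MIN_AGE:
            raise ValidationError(
                f"twin {self.twin_id}: age {self.age} below minimum {MIN_AGE}"
            )


@dataclass(frozen=True)
class TwinPair:
    """Two co-twins sharing a pair id and zygosity."""

    first: Twin
    second: Twin

    def __post_init__(self) -> None:
        if self.first.pair_id != self.second.pair_id:
            raise ValidationError("pair members have different pair_id")
        if self.first.zygosity != self.second.zygosity:
            raise ValidationError(
                f"pair {self.first.pair_id}: members disagree on zygosity"
            )

    @property
    def pair_id(self) -> str:
        return self.first.pair_id

    @property
    def zygosity(self) -> str:
        return self.first.zygosity

    @property
    def twins(self) -> tuple[Twin, Twin]:
        return (self.first, self.second)


@dataclass
class Cohort:
    """A validated twin cohort with pair and epigenetic-subset views."""

    twins: list[Twin]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.twins:
            if t.twin_id in seen:
                raise ValidationError(f"duplicated twin_id: {t.twin_id}")
            seen.add(t.twin_id)
        by_pair: dict[str, list[Twin]] = {}
        for t in self.twins:
            by_pair.setdefault(t.pair_id, []).append(t)
        for pid, members in by_pair.items():
            if len(members) != 2:
                raise ValidationError(
                    f"pair {pid} has {len(members)} members (expected 2)"
                )
        self._pairs = {pid: TwinPair(*members) for pid, members in by_pair.items()}

    @property
    def pairs(self) -> list[TwinPair]:
        return list(self._pairs.values())

    @property
    def n_pairs(self) -> int:
        return len(self._pairs)

    @property
    def genotyped_twins(self) -> list[Twin]:
        return [t for t in self.twins if t.genotype is not GenotypeCall.MISSING]

    @property
    def mz_pairs_with_methylation(self) -> list[TwinPair]:
        """MZ pairs where both co-twins have complete methylation and trait data."""
        out = []
        for p in self.pairs:
            if p.zygosity != "MZ":
                continue
            ok = all(
                t.methylation is not None
                and t.methylation.complete
                and t.traits.complete
                for t in p.twins
            )
            if ok:
                out.append(p)
        return out
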