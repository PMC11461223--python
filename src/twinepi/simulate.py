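"""Synthetic twin-cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without access to the original registry data:

* rs4680 genotypes drawn under Hardy-Weinberg equilibrium at the sample Met
  allele frequency (482/860 by default), one draw per MZ pair (co-twins are
  genetically identical) and independent draws per DZ twin;
* NEO-PI-R scale scores as rounded, range-clipped bivariate normals with a
  configurable within-pair correlation (ICC) per scale;
* percent methylation as a zero-inflated, pair-correlated lognormal clipped
  to [0, 100] — the simplest right-skewed family matching the published
  per-site moments (means ~4-8%, skewness ~2, zero minima);
* an optional planted within-pair discordance effect linking one CpG site to
  one trait, used by parameter-recovery tests, and an optional crude
  genotype-group mean shift for power checks of the SNP arm.

Randomness is split into named substreams keyed off the single global seed,
so adding a scale or site never perturbs the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .catalog import DEFAULT_CATALOG, ScaleCatalog
from .cohort import (
    Cohort,
    GenotypeCall,
    MethylationProfile,
    N_CPG_SITES,
    TraitProfile,
    Twin,
)
from .errors import ParameterError

# substream tags (second word of the rng key after the seed)
_S_STRUCTURE, _S_GENOTYPE, _S_TRAIT, _S_METH, _S_PLANT = 1, 2, 3, 4, 5

#: domain-scale moments the generator targets by default (0-192 scale)
DOMAIN_MOMENTS: dict[str, tuple[float, float]] = {
    "neuroticism": (87.31, 20.21),
    "extraversion": (118.04, 17.67),
    "openness": (114.60, 14.96),
    "agreeableness": (115.04, 14.34),
    "conscientiousness": (122.26, 20.13),
}

#: per-site percent-methylation means the lognormal defaults target
CPG_MEANS = (7.75, 4.55, 6.18, 6.16, 4.40)
DEFAULT_METH_LOG_SD = 0.8
DEFAULT_METH_ZERO_MASS = 0.02
#: within-pair methylation correlation; no published estimate exists, this
#: default is an arbitrary moderate value and is flagged as such
DEFAULT_METH_PAIR_CORR = 0.4
DEFAULT_TRAIT_ICC = 0.5

AGE_MEAN, AGE_SD, AGE_RANGE = 24.66, 7.72, (18, 60)
FRACTION_FEMALE = 0.744


@dataclass(frozen=True)
class PlantedEffect:
    """A planted methylation-trait discordance at one (CpG, scale) cell.

    ``direction`` names the one-sided battery alternative the planted
    association favors: "greater" orients the higher-methylation twin toward
    the *lower* trait score (H1: p1 > p2), "less" toward the higher score.
    ``delta`` shifts the orientation probability to 0.5 + delta.
    """

    cpg: int
    scale: str
    delta: float
    direction: str

    def __post_init__(self) -> None:
        if not 1 <= self.cpg <= N_CPG_SITES:
            raise ParameterError(f"CpG index out of range: {self.cpg}")
        if not 0.0 <= self.delta <= 0.5:
            raise ParameterError(f"delta must lie in [0, 0.5]: {self.delta}")
        if self.direction not in ("greater", "less"):
            raise ParameterError(f"invalid direction: {self.direction!r}")


@dataclass(frozen=True)
class GroupShift:
    """Crude genotype-group mean shift (Met+ group), in SD units of the scale."""

    scale: str
    delta_in_sd: float


@dataclass
class SimulationConfig:
    n_pairs_total: int = 215
    fraction_mz: float = 0.758
    n_epi_pairs: int = 35
    p_met: float = 482.0 / 860.0
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)
    icc_mz: dict[str, float] = field(default_factory=dict)
    meth_log_mean: tuple[float, ...] = ()
    meth_log_sd: tuple[float, ...] = ()
    meth_zero_mass: tuple[float, ...] = ()
    meth_pair_corr: float = DEFAULT_METH_PAIR_CORR
    planted_effect: Optional[PlantedEffect] = None
    group_shift: Optional[GroupShift] = None
    seed: int = 0
    catalog: ScaleCatalog = field(default=DEFAULT_CATALOG, repr=False)

    def __post_init__(self) -> None:
        cat = self.catalog
        means, sds, iccs = {}, {}, {}
        for domain, facets in cat.facets.items():
            dm, dsd = DOMAIN_MOMENTS[domain]
            means[domain], sds[domain] = dm, dsd
            for f in facets:
                # facet heuristic: items are 1/6 of the domain's
                means[f] = dm / 6.0
                sds[f] = dsd / math.sqrt(6.0)
        means.update({cat.canonicalize(k): v for k, v in self.trait_means.items()})
        sds.update({cat.canonicalize(k): v for k, v in self.trait_sds.items()})
        for s in cat.all_scales:
            iccs[s] = DEFAULT_TRAIT_ICC
        iccs.update({cat.canonicalize(k): v for k, v in self.icc_mz.items()})
        self.trait_means, self.trait_sds, self.icc_mz = means, sds, iccs
        if not self.meth_log_sd:
            self.meth_log_sd = (DEFAULT_METH_LOG_SD,) * N_CPG_SITES
        if not self.meth_log_mean:
            self.meth_log_mean = tuple(
                math.log(m) - sd**2 / 2.0
                for m, sd in zip(CPG_MEANS, self.meth_log_sd)
            )
        if not self.meth_zero_mass:
            self.meth_zero_mass = (DEFAULT_METH_ZERO_MASS,) * N_CPG_SITES
        self._validate()

    def _validate(self) -> None:
        if self.n_pairs_total < 1:
            raise ParameterError("n_pairs_total must be >= 1")
        if not 0.0 <= self.fraction_mz <= 1.0:
            raise ParameterError("fraction_mz must lie in [0, 1]")
        if not 0.0 < self.p_met < 1.0:
            raise ParameterError("p_met must lie in (0, 1)")
        if self.n_epi_pairs > self.n_mz_pairs:
            raise ParameterError(
                f"n_epi_pairs ({self.n_epi_pairs}) exceeds MZ pair count "
                f"({self.n_mz_pairs})"
            )
        for z in self.meth_zero_mass:
            if not 0.0 <= z < 1.0:
                raise ParameterError("meth_zero_mass must lie in [0, 1)")
        for sd in self.meth_log_sd:
            if sd <= 0.0:
                raise ParameterError("meth_log_sd must be positive")
        if not -1.0 < self.meth_pair_corr < 1.0:
            raise ParameterError("meth_pair_corr must lie in (-1, 1)")

    @property
    def n_mz_pairs(self) -> int:
        return round(self.n_pairs_total * self.fraction_mz)

    @property
    def n_dz_pairs(self) -> int:
        return self.n_pairs_total - self.n_mz_pairs


@dataclass
class GeneratedCohort:
    cohort: Cohort
    truth: dict


def _rng(seed, *tags: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng([int(seed)] + list(tags))


def gen_genotypes_hwe(n_individuals: int, p_met: float, seed) -> list[GenotypeCall]:
    """I.i.d. genotype draws with HWE probabilities (p^2, 2pq, q^2)."""
    if not 0.0 < p_met < 1.0:
        raise ParameterError("p_met must lie in (0, 1)")
    rng = _rng(seed, _S_GENOTYPE)
    q = 1.0 - p_met
    draws = rng.choice(
        3, size=n_individuals, p=[p_met**2, 2 * p_met * q, q**2]
    )
    lut = (GenotypeCall.MET_MET, GenotypeCall.MET_VAL, GenotypeCall.VAL_VAL)
    return [lut[i] for i in draws]


def gen_trait_pairs(
    n_pairs: int,
    mean: float,
    sd: float,
    icc: float,
    scale_range: tuple[float, float],
    seed,
) -> np.ndarray:
    """(n_pairs, 2) integer scores from a bivariate normal with correlation icc,
    rounded and clipped to scale_range."""
    if sd <= 0.0:
        raise ParameterError("sd must be positive")
    if not -1.0 < icc < 1.0 and icc != 1.0:
        raise ParameterError("icc must lie in (-1, 1]")
    lo, hi = scale_range
    if lo >= hi:
        raise ParameterError(f"invalid scale range: {scale_range}")
    rng = _rng(seed, _S_TRAIT)
    shared = rng.standard_normal(n_pairs)
    if icc >= 0.0:
        a, b = math.sqrt(icc), math.sqrt(1.0 - icc)
        unique = rng.standard_normal((n_pairs, 2))
        z = a * shared[:, None] + b * unique
    else:  # negative correlation via antithetic mixing
        rho = icc
        u1 = rng.standard_normal(n_pairs)
        u2 = rho * u1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n_pairs)
        z = np.stack([u1, u2], axis=1)
    scores = np.clip(np.rint(mean + sd * z), lo, hi)
    return scores


def gen_methylation_pairs(
    n_pairs: int,
    log_mean: float,
    log_sd: float,
    zero_mass: float,
    pair_corr: float,
    seed,
) -> np.ndarray:
    """(n_pairs, 2) percent-methylation values.

    A shared and a unique standard-normal component combine on the log scale
    to give within-pair correlation ~ pair_corr; values are exponentiated,
    zeroed with probability zero_mass, and clipped to [0, 100].
    """
    if not 0.0 <= zero_mass < 1.0:
        raise ParameterError("zero_mass must lie in [0, 1)")
    if log_sd <= 0.0:
        raise ParameterError("log_sd must be positive")
    if not -1.0 < pair_corr < 1.0:
        raise ParameterError("pair_corr must lie in (-1, 1)")
    rng = _rng(seed, _S_METH)
    rho = max(pair_corr, 0.0)
    shared = rng.standard_normal(n_pairs)
    unique = rng.standard_normal((n_pairs, 2))
    z = math.sqrt(rho) * shared[:, None] + math.sqrt(1.0 - rho) * unique
    values = np.exp(log_mean + log_sd * z)
    zeros = rng.random((n_pairs, 2)) < zero_mass
    values[zeros] = 0.0
    return np.clip(values, 0.0, 100.0)


def plant_discordance_effect(
    trait_pairs: np.ndarray,
    cpg_values: np.ndarray,
    delta: float,
    direction: str,
    seed,
) -> np.ndarray:
    """Orient trait values within pairs relative to the methylation rank.

    With probability 0.5 + delta the pair is oriented so that the
    higher-methylation twin carries the trait value favored by
    ``direction`` ("greater": the lower score; "less": the higher score) —
    see :class:`PlantedEffect`. Orientation only swaps the two values of a
    pair, so every pair's multiset of trait scores (and hence the marginal
    trait distribution) is unchanged. Pairs tied on methylation or trait
    are left untouched.
    """
    if not 0.0 <= delta <= 0.5:
        raise ParameterError("delta must lie in [0, 0.5]")
    if direction not in ("greater", "less"):
        raise ParameterError(f"invalid direction: {direction!r}")
    traits = np.array(trait_pairs, dtype=float)
    cpg = np.asarray(cpg_values, dtype=float)
    rng = _rng(seed, _S_PLANT)
    concordant = rng.random(len(traits)) < 0.5 + delta
    for i in range(len(traits)):
        if cpg[i, 0] == cpg[i, 1] or traits[i, 0] == traits[i, 1]:
            continue
        hi_meth = int(cpg[i, 1] > cpg[i, 0])
        hi_trait = int(traits[i, 1] > traits[i, 0])
        # favored orientation: under "greater" the higher-meth twin holds
        # the lower trait value
        favored = (hi_trait != hi_meth) if direction == "greater" else (
            hi_trait == hi_meth
        )
        if favored != bool(concordant[i]):
            traits[i] = traits[i, ::-1]
    return traits


def gen_cohort(config: SimulationConfig) -> GeneratedCohort:
    """Assemble a full synthetic cohort from a :class:`SimulationConfig`."""
    cat = config.catalog
    n_mz, n_dz = config.n_mz_pairs, config.n_dz_pairs
    n_pairs = config.n_pairs_total
    rng_struct = _rng(config.seed, _S_STRUCTURE)

    ages = np.clip(
        np.rint(rng_struct.normal(AGE_MEAN, AGE_SD, n_pairs)), *AGE_RANGE
    )
    pair_sex = rng_struct.random(n_pairs) < FRACTION_FEMALE
    dz_second_sex = rng_struct.random(n_pairs) < 0.5  # DZ co-twin flips coin

    # one genotype draw per MZ pair, one per DZ twin
    draws = gen_genotypes_hwe(n_mz + 2 * n_dz, config.p_met, config.seed)
    genotypes: list[tuple[GenotypeCall, GenotypeCall]] = []
    for i in range(n_mz):
        genotypes.append((draws[i], draws[i]))
    for j in range(n_dz):
        genotypes.append((draws[n_mz + 2 * j], draws[n_mz + 2 * j + 1]))

    scales = cat.all_scales
    trait_arrays: dict[str, np.ndarray] = {}
    for k, scale in enumerate(scales):
        trait_arrays[scale] = gen_trait_pairs(
            n_pairs,
            config.trait_means[scale],
            config.trait_sds[scale],
            config.icc_mz[scale],
            cat.score_range(scale),
            _rng(config.seed, _S_TRAIT, k),
        )

    meth_arrays: list[np.ndarray] = []
    for c in range(N_CPG_SITES):
        meth_arrays.append(
            gen_methylation_pairs(
                config.n_epi_pairs,
                config.meth_log_mean[c],
                config.meth_log_sd[c],
                config.meth_zero_mass[c],
                config.meth_pair_corr,
                _rng(config.seed, _S_METH, c),
            )
        )

    if config.planted_effect is not None:
        pe = config.planted_effect
        scale = cat.canonicalize(pe.scale)
        planted = plant_discordance_effect(
            trait_arrays[scale][: config.n_epi_pairs],
            meth_arrays[pe.cpg - 1],
            pe.delta,
            pe.direction,
            _rng(config.seed, _S_PLANT),
        )
        trait_arrays[scale] = np.vstack(
            [planted, trait_arrays[scale][config.n_epi_pairs:]]
        )

    if config.group_shift is not None:
        gs = config.group_shift
        scale = cat.canonicalize(gs.scale)
        lo, hi = cat.score_range(scale)
        shift = gs.delta_in_sd * config.trait_sds[scale]
        arr = trait_arrays[scale].copy()
        for i in range(n_pairs):
            for j in range(2):
                if genotypes[i][j] is GenotypeCall.MET_MET:
                    arr[i, j] = min(max(round(arr[i, j] + shift), lo), hi)
        trait_arrays[scale] = arr

    twins: list[Twin] = []
    for i in range(n_pairs):
        mz = i < n_mz
        pid = f"p{i + 1:04d}"
        sex_first = "F" if pair_sex[i] else "M"
        for j in range(2):
            if mz:
                sex = sex_first
            else:
                sex = sex_first if j == 0 or not dz_second_sex[i] else (
                    "M" if sex_first == "F" else "F"
                )
            meth = None
            if mz and i < config.n_epi_pairs:
                meth = MethylationProfile(
                    tuple(float(meth_arrays[c][i, j]) for c in range(N_CPG_SITES))
                )
            scores = {s: float(trait_arrays[s][i, j]) for s in scales}
            twins.append(
                Twin(
                    twin_id=f"{pid}_{'ab'[j]}",
                    pair_id=pid,
                    zygosity="MZ" if mz else "DZ",
                    sex=sex,
                    age=float(ages[i]),
                    genotype=genotypes[i][j],
                    traits=TraitProfile(scores, cat),
                    methylation=meth,
                )
            )

    truth = {
        "seed": config.seed,
        "n_pairs_total": n_pairs,
        "n_mz_pairs": n_mz,
        "n_epi_pairs": config.n_epi_pairs,
        "p_met": config.p_met,
        "meth_pair_corr": config.meth_pair_corr,
        "planted_effect": asdict(config.planted_effect)
        if config.planted_effect else None,
        "group_shift": asdict(config.group_shift) if config.group_shift else None,
    }
    return GeneratedCohort(Cohort(twins), truth)
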