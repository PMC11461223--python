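import math

import numpy as np
import pytest

from twinepi.cohort import Cohort, TwinPair
from twinepi.discordance import (
    build_table,
    classify_pair,
    orient_pair,
    run_epigenetic_battery,
    summarize_significant,
)
from twinepi.errors import InsufficientDataError, ParameterError
from twinepi.exact2x2 import Table2x2, barnard_p
from twinepi.simulate import PlantedEffect, SimulationConfig, gen_cohort

from conftest import make_twin


def pair_with(cpg_a, cpg_b, trait_a=None, trait_b=None, pid="p0", scale="warmth"):
    traits_a = traits_b = None
    if trait_a is not None:
        traits_a, traits_b = {scale: float(trait_a)}, {scale: float(trait_b)}
    a = make_twin(f"{pid}a", pid, cpg=cpg_a, traits=traits_a)
    b = make_twin(f"{pid}b", pid, cpg=cpg_b, traits=traits_b)
    return TwinPair(a, b)


class TestOrientPair:
    def test_higher_methylation_is_h(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1))
        o = orient_pair(p, 1)
        assert not o.excluded
        assert o.high_meth_twin.twin_id == "p0a"

    def test_exact_tie_excluded_locally(self):
        p = pair_with((0, 1, 1, 1, 1), (0, 2, 1, 1, 1))
        assert orient_pair(p, 1).reason == "methylation tie"
        assert not orient_pair(p, 2).excluded

    def test_missing_methylation_excluded(self):
        p = pair_with((5, 1, 1, 1, 1), (math.nan, 1, 1, 1, 1))
        assert orient_pair(p, 1).reason == "missing"


class TestClassifyPair:
    def test_discordant_pair_under_greater(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, 15)
        rec_h, rec_l = classify_pair(p, 1, "warmth", "greater")
        assert (rec_h.meth_rank, rec_h.lower_trait) == ("H", False)
        assert (rec_l.meth_rank, rec_l.lower_trait) == ("L", True)

    def test_trait_tie_is_not_higher_for_both(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, 20)
        rec_h, rec_l = classify_pair(p, 1, "warmth", "greater")
        assert rec_h.lower_trait and rec_l.lower_trait

    def test_trait_tie_is_not_lower_for_both_under_less(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, 20)
        rec_h, rec_l = classify_pair(p, 1, "warmth", "less")
        assert not rec_h.lower_trait and not rec_l.lower_trait

    def test_missing_trait_excludes_cell(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, math.nan)
        assert classify_pair(p, 1, "warmth", "greater") is None

    def test_invalid_alternative(self):
        p = pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, 15)
        with pytest.raises(ParameterError):
            classify_pair(p, 1, "warmth", "two_sided")


class TestBuildTable:
    def test_three_pair_fixture(self):
        pairs = [
            pair_with((10, 1, 1, 1, 1), (5, 1, 1, 1, 1), 20, 15, pid="p0"),
            pair_with((3, 1, 1, 1, 1), (8, 1, 1, 1, 1), 30, 12, pid="p1"),
            pair_with((4, 1, 1, 1, 1), (4, 1, 1, 1, 1), 10, 11, pid="p2"),
        ]
        cell = build_table(pairs, 1, "warmth", "less")
        assert cell.n_pairs_used == 2
        assert cell.n_pairs_excluded == 1
        # pair p0: H twin higher trait; pair p1: H twin (second) lower trait
        assert cell.table == Table2x2(1, 2, 1, 2)

    def test_fully_concordant_orientation(self):
        pairs = [
            pair_with((9, 1, 1, 1, 1), (2, 1, 1, 1, 1), 10, 20, pid=f"q{i}")
            for i in range(4)
        ]
        cell = build_table(pairs, 1, "warmth", "greater")
        assert cell.table == Table2x2(4, 4, 0, 4)

    def test_single_pair_is_uninformative(self):
        pairs = [pair_with((9, 1, 1, 1, 1), (2, 1, 1, 1, 1), 10, 20)]
        cell = build_table(pairs, 1, "warmth", "greater")
        p = barnard_p(cell.table, "greater").p_value
        assert p >= 0.2

    def test_no_usable_pairs_is_error(self):
        pairs = [pair_with((4, 1, 1, 1, 1), (4, 1, 1, 1, 1), 1, 2)]
        with pytest.raises(InsufficientDataError):
            build_table(pairs, 1, "warmth", "greater")

    def test_mirror_symmetry_without_ties(self):
        rng = np.random.default_rng(0)
        pairs = []
        for i in range(12):
            m = rng.uniform(1, 20, 2)
            t = rng.choice(np.arange(10, 30), size=2, replace=False)
            pairs.append(
                pair_with(
                    (m[0], 1, 1, 1, 1), (m[1], 1, 1, 1, 1),
                    int(t[0]), int(t[1]), pid=f"m{i}",
                )
            )
        cell = build_table(pairs, 1, "warmth", "less")
        # count(H, lower) == count(L, higher): mirrored contributions
        assert cell.table.x1 == cell.table.n2 - cell.table.x2


@pytest.fixture(scope="module")
def small_epi_cohort():
    cfg = SimulationConfig(
        n_pairs_total=20, fraction_mz=1.0, n_epi_pairs=12, seed=23
    )
    return gen_cohort(cfg).cohort


@pytest.fixture(scope="module")
def summary_cells():
    cfg = SimulationConfig(
        n_pairs_total=15, fraction_mz=1.0, n_epi_pairs=10, seed=2
    )
    return run_epigenetic_battery(gen_cohort(cfg).cohort)


class TestBattery:

    def test_cell_count_and_order(self, small_epi_cohort):
        cells = run_epigenetic_battery(small_epi_cohort)
        assert len(cells) == 350
        assert [c.cpg for c in cells[:70]] == [1] * 70
        assert cells[0].alternative == "greater"
        assert cells[1].alternative == "less"

    def test_pair_accounting(self, small_epi_cohort):
        for c in run_epigenetic_battery(small_epi_cohort):
            assert c.n_pairs_used + c.n_pairs_excluded == 12
            assert c.table.n1 == c.table.n2 == c.n_pairs_used

    def test_exclusion_locality(self):
        cfg = SimulationConfig(
            n_pairs_total=10, fraction_mz=1.0, n_epi_pairs=8, seed=5,
        )
        cohort = gen_cohort(cfg).cohort
        # force a methylation tie at CpG2 for the first epi pair
        pair = cohort.mz_pairs_with_methylation[0]
        twins = []
        for t in cohort.twins:
            if t.pair_id == pair.pair_id:
                cpg = list(t.methylation.cpg)
                cpg[1] = 0.0
                twins.append(make_twin(
                    t.twin_id, t.pair_id, zygosity=t.zygosity, sex=t.sex,
                    age=t.age, genotype=t.genotype, cpg=cpg,
                    traits=dict(t.traits.scores),
                ))
            else:
                twins.append(t)
        cells = run_epigenetic_battery(Cohort(twins))
        by_cpg = {c.cpg: c.n_pairs_excluded for c in cells}
        assert by_cpg[2] >= 1
        assert all(by_cpg[c] == 0 for c in (1, 3, 4, 5))

    def test_alternative_duality_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        pairs = []
        for i in range(10):
            m = rng.uniform(1, 30, 2)
            t = rng.choice(np.arange(5, 30), size=2, replace=False)
            pairs.append(
                pair_with(
                    (m[0], 1, 1, 1, 1), (m[1], 1, 1, 1, 1),
                    int(t[0]), int(t[1]), pid=f"d{i}",
                )
            )
        cell_g = build_table(pairs, 1, "warmth", "greater")
        cell_l = build_table(pairs, 1, "warmth", "less")
        assert cell_g.table == cell_l.table  # tie-free: same counts
        pg = barnard_p(cell_g.table, "greater").p_value
        pl = barnard_p(cell_l.table.swapped(), "less").p_value
        assert pg == pytest.approx(pl, abs=1e-9)

    def test_planted_effect_surfaces_in_its_cell(self):
        cfg = SimulationConfig(
            seed=31,
            planted_effect=PlantedEffect(3, "trust", 0.45, "greater"),
        )
        cells = run_epigenetic_battery(gen_cohort(cfg).cohort)
        target = next(
            c for c in cells
            if (c.cpg, c.scale, c.alternative) == (3, "trust", "greater")
        )
        others = [c.p_value for c in cells if c is not target]
        assert target.p_value < 0.05
        assert target.p_value <= min(others)


class TestSummarize:
    def test_alpha_bounds(self, summary_cells):
        assert summarize_significant(summary_cells, 0.0)["n_significant"] == 0
        assert summarize_significant(summary_cells, 1.0)["n_significant"] == 350

    def test_bubble_records_carry_counts(self, summary_cells):
        report = summarize_significant(summary_cells, 1.0)
        rec = report["bubbles"][0]
        counts = rec["counts"]
        assert set(counts) == {"H_lower", "H_not_lower", "L_lower", "L_not_lower"}
        assert counts["H_lower"] + counts["H_not_lower"] == counts["L_lower"] + counts["L_not_lower"]
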