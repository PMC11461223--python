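import math

import pytest

from twinepi.catalog import DEFAULT_CATALOG
from twinepi.cohort import (
    Cohort,
    GenotypeCall,
    MethylationProfile,
    TraitProfile,
    Twin,
)
from twinepi.io import cohort_columns, neo_column
from twinepi.simulate import SimulationConfig, gen_cohort


def make_twin(
    twin_id,
    pair_id,
    zygosity="MZ",
    sex="F",
    age=25,
    genotype=GenotypeCall.MET_VAL,
    cpg=None,
    traits=None,
):
    """Hand-built twin with sensible defaults for fixture cohorts."""
    meth = MethylationProfile(tuple(float(v) for v in cpg)) if cpg else None
    scores = traits if traits is not None else {
        s: (96.0 if DEFAULT_CATALOG.is_domain(s) else 16.0)
        for s in DEFAULT_CATALOG.all_scales
    }
    return Twin(
        twin_id=twin_id, pair_id=pair_id, zygosity=zygosity, sex=sex,
        age=age, genotype=genotype,
        traits=TraitProfile(scores), methylation=meth,
    )


def cohort_with_genotype_counts(n_met_met, n_met_val, n_val_val):
    """DZ-pair cohort carrying exactly the requested genotype counts."""
    calls = (
        [GenotypeCall.MET_MET] * n_met_met
        + [GenotypeCall.MET_VAL] * n_met_val
        + [GenotypeCall.VAL_VAL] * n_val_val
    )
    assert len(calls) % 2 == 0
    twins = []
    for i, call in enumerate(calls):
        pid = f"p{i // 2:04d}"
        twins.append(
            make_twin(f"t{i:04d}", pid, zygosity="DZ", genotype=call)
        )
    return Cohort(twins)


def csv_row(twin, cpg=("", "", "", "", ""), overrides=None):
    row = {
        "pair_id": twin.pair_id, "twin_id": twin.twin_id,
        "zygosity": twin.zygosity, "sex": twin.sex, "age": twin.age,
        "genotype": twin.genotype.value,
    }
    for i in range(5):
        row[f"cpg{i + 1}"] = cpg[i]
    for s in DEFAULT_CATALOG.all_scales:
        row[neo_column(s)] = twin.traits.score(s)
    if overrides:
        row.update(overrides)
    return row


def write_csv(path, rows, drop_columns=()):
    columns = [c for c in cohort_columns() if c not in drop_columns]
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(str(row.get(c, "")) for c in columns))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_pair_csv(tmp_path):
    """Two complete MZ pairs with methylation, as a wide CSV file."""
    rows = []
    for p in range(2):
        for j, suffix in enumerate("ab"):
            t = make_twin(f"t{p}{suffix}", f"p{p}", cpg=None)
            rows.append(
                csv_row(t, cpg=tuple(str(5.0 + p + j + i) for i in range(5)))
            )
    return write_csv(tmp_path / "cohort.csv", rows)


@pytest.fixture(scope="session")
def null_cohort():
    """Default synthetic cohort with no planted effect (seed fixed)."""
    return gen_cohort(SimulationConfig(seed=11)).cohort
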