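import numpy as np
import pandas as pd
import pytest

from gxegwas import env_classes
from gxegwas.datatypes import Pedigree
from gxegwas.relatedness import a_matrix
from gxegwas.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_temperatures,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_founders=60,
        n_generations=2,
        offspring_per_pair=2,
        n_snps=40,
        n_years=9,
        v_a=10.8,
        v_pe=3.0,
        v_res=14.5,
        age_effect=-2.0,
        mean_records=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ped = simulate_pedigree(small_config)
    geno, info = simulate_genotypes(ped, small_config)
    temps = simulate_temperatures(small_config)
    pheno = simulate_phenotypes(ped, geno, temps, small_config)
    return ped, geno, info, temps, pheno


@pytest.fixture(scope="session")
def classification(small_dataset):
    _, _, _, temps, _ = small_dataset
    years = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
    means = {int(y): env_classes.window_mean(temps, int(y)) for y in years}
    return env_classes.classify_years(means)


@pytest.fixture(scope="session")
def centered_pheno(small_dataset, classification):
    *_, pheno = small_dataset
    return env_classes.center_phenotypes(pheno, classification)


@pytest.fixture(scope="session")
def small_amatrix(small_dataset):
    ped, *_ = small_dataset
    return a_matrix(ped)


def manual_pedigree(rows) -> Pedigree:
    """rows: (id, sire, dam, sex, generation) tuples."""
    return Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])
    )


@pytest.fixture
def trio_pedigree():
    return manual_pedigree(
        [
            ("s", None, None, "M", 0),
            ("d", None, None, "F", 0),
            ("o1", "s", "d", "F", 1),
            ("o2", "s", "d", "M", 1),
        ]
    )


def kinship_oracle(ped: Pedigree) -> np.ndarray:
    """Independent memoized-recursion relatedness oracle (2x kinship)."""
    table = ped.table
    parents = {
        r["id"]: (r["sire"], r["dam"]) for _, r in table.iterrows()
    }
    order = {v: i for i, v in enumerate(table["id"])}
    memo = {}

    def kin(a, b):
        if order[a] > order[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + (kin(s, d) if s and d else 0.0))
        else:
            # b is not an ancestor of a because order[b] >= order[a]
            s, d = parents[b]
            val = 0.0
            if s:
                val += 0.5 * kin(a, s)
            if d:
                val += 0.5 * kin(a, d)
        memo[key] = val
        return val

    ids = table["id"].tolist()
    n = len(ids)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = 2.0 * kin(ids[i], ids[j])
    return K
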