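import dataclasses

import numpy as np
import pandas as pd
import pytest

from gxegwas import env_classes
from gxegwas.datatypes import MISSING
from gxegwas.relatedness import a_matrix
from gxegwas.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_temperatures,
)

from conftest import kinship_oracle


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_founders": 1},
            {"n_generations": 0},
            {"offspring_per_pair": 0},
            {"n_snps": 0},
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"n_years": 2},
            {"v_a": -1.0},
            {"v_res": {"cold": -2.0}},
            {"missing_rate": 1.0},
            {"mean_records": 0.5},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestPedigree:
    def test_two_founders_one_pair(self):
        cfg = SimulationConfig(n_founders=2, n_generations=1, offspring_per_pair=2)
        ped = simulate_pedigree(cfg)
        assert ped.n == 4
        kids = ped.table[ped.table["generation"] == 1]
        assert kids["sire"].nunique() == 1 and kids["dam"].nunique() == 1

    def test_deterministic(self):
        cfg = SimulationConfig(n_founders=30, n_generations=2, seed=5)
        pd.testing.assert_frame_equal(
            simulate_pedigree(cfg).table, simulate_pedigree(cfg).table
        )

    def test_relatedness_matches_path_oracle(self):
        cfg = SimulationConfig(n_founders=100, n_generations=3, seed=17)
        ped = simulate_pedigree(cfg)
        A = a_matrix(ped).values
        K = kinship_oracle(ped)
        last = (ped.table["generation"] == 3).to_numpy()
        np.testing.assert_allclose(A[np.ix_(last, last)], K[np.ix_(last, last)],
                                   atol=1e-12)
        assert abs(A[np.ix_(last, last)].mean() - K[np.ix_(last, last)].mean()) < 1e-12


class TestGenotypes:
    def test_no_ld_limit(self):
        cfg = SimulationConfig(
            n_founders=1000, n_generations=1, n_snps=30, ld_decay_bp=0.0, seed=2
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        founders = ped.table["generation"].to_numpy() == 0
        vals = G.values[founders].astype(float)
        rs = [
            np.corrcoef(vals[:, j], vals[:, j + 1])[0, 1]
            for j in range(G.n_snps - 1)
        ]
        assert np.max(np.abs(rs)) < 0.1

    def test_ld_raises_adjacent_correlation(self):
        cfg = SimulationConfig(
            n_founders=500,
            n_generations=1,
            n_snps=30,
            n_chromosomes=1,
            ld_decay_bp=5000.0,
            seed=2,
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        vals = G.values[ped.table["generation"].to_numpy() == 0].astype(float)
        rs = [
            np.corrcoef(vals[:, j], vals[:, j + 1])[0, 1]
            for j in range(G.n_snps - 1)
        ]
        assert np.mean(rs) > 0.4

    def test_mendelian_transmission(self, small_dataset):
        ped, G, *_ = small_dataset
        pos = {v: i for i, v in enumerate(G.ids)}
        checked = 0
        for _, row in ped.table.iterrows():
            if row["sire"] is None:
                continue
            sire_row = G.values[pos[row["sire"]]]
            child_row = G.values[pos[row["id"]]]
            hom = sire_row == 2
            assert (child_row[hom] >= 1).all()
            checked += int(hom.sum())
        assert checked > 0

    def test_founder_maf_binomial_bound(self):
        cfg = SimulationConfig(
            n_founders=1000, n_generations=1, n_snps=1, maf_range=(0.3, 0.3), seed=9
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        founders = ped.table["generation"].to_numpy() == 0
        maf = G.values[founders, 0].mean() / 2.0
        assert abs(maf - 0.3) < 0.03

    def test_deterministic(self, small_config):
        ped = simulate_pedigree(small_config)
        G1, i1 = simulate_genotypes(ped, small_config)
        G2, i2 = simulate_genotypes(ped, small_config)
        np.testing.assert_array_equal(G1.values, G2.values)
        pd.testing.assert_frame_equal(i1, i2)

    def test_positions_increase_within_chromosome(self, small_dataset):
        _, _, info, *_ = small_dataset
        for _, sub in info.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_missing_rate_applied(self):
        cfg = SimulationConfig(
            n_founders=100, n_generations=1, n_snps=50, missing_rate=0.1, seed=3
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        frac = (G.values == MISSING).mean()
        assert 0.07 < frac < 0.13


class TestTemperatures:
    def test_constant_mean_no_noise(self):
        cfg = SimulationConfig(
            n_years=3, year_temp_range=(6.2, 6.2), day_sd=0.0, seed=1
        )
        temps = simulate_temperatures(cfg)
        for year in (2000, 2001, 2002):
            assert env_classes.window_mean(temps, year) == pytest.approx(6.2)

    def test_17_years_classify_665(self):
        cfg = SimulationConfig(n_years=17, seed=4)
        temps = simulate_temperatures(cfg)
        means = {
            y: env_classes.window_mean(temps, y)
            for y in range(2000, 2017)
        }
        sizes = env_classes.classify_years(means).sizes()
        assert sizes == {"cold": 6, "intermediate": 6, "warm": 5}

    def test_deterministic(self, small_config):
        pd.testing.assert_frame_equal(
            simulate_temperatures(small_config), simulate_temperatures(small_config)
        )


class TestPhenotypes:
    def test_degenerate_all_mu(self):
        cfg = SimulationConfig(
            n_founders=20,
            n_generations=1,
            n_snps=5,
            v_a=0.0,
            v_pe=0.0,
            v_res=0.0,
            age_effect=0.0,
            mu=100.0,
            seed=6,
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, G, temps, cfg)
        assert (pheno["laying_date"] == 100.0).all()

    def test_unknown_causal_snp_rejected(self, small_dataset, small_config):
        ped, G, _, temps, _ = small_dataset
        cfg = dataclasses.replace(
            small_config, causal_snps={"nope": {"cold": (0, 0, 1)}}
        )
        with pytest.raises(ConfigurationError, match="nope"):
            simulate_phenotypes(ped, G, temps, cfg)

    def test_deterministic(self, small_dataset, small_config):
        ped, G, _, temps, pheno = small_dataset
        again = simulate_phenotypes(ped, G, temps, small_config)
        pd.testing.assert_frame_equal(pheno, again)

    def test_all_phenotyped_are_females(self, small_dataset):
        ped, *_, pheno = small_dataset
        females = set(ped.females())
        assert set(pheno["id"]) <= females

    def test_one_record_per_individual_year(self, small_dataset):
        *_, pheno = small_dataset
        assert not pheno.duplicated(subset=["id", "year"]).any()

    @pytest.mark.parametrize(
        "component,expected_var",
        [("v_a", 10.8), ("v_pe", 3.0), ("v_res", 14.5)],
    )
    def test_variance_decomposition(self, component, expected_var):
        # activate one component at a time; with one record per female the
        # record variance estimates that component's target
        kwargs = {"v_a": 0.0, "v_pe": 0.0, "v_res": 0.0, component: expected_var}
        cfg = SimulationConfig(
            n_founders=1000,
            n_generations=2,
            offspring_per_pair=2,
            n_snps=2,
            age_effect=0.0,
            mean_records=1.0,
            seed=12,
            **kwargs,
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, G, temps, cfg)
        assert len(pheno) >= 1500
        var = pheno["laying_date"].var(ddof=1)
        assert abs(var - expected_var) / expected_var < 0.15

    def test_breeding_value_covariance_matches_a(self):
        # 6-individual pedigree, many replicates: cov(a_i, a_j) / V_A -> A
        rows = [
            ("s", None, None, "M", 0),
            ("d", None, None, "F", 0),
            ("o1", "s", "d", "F", 1),
            ("o2", "s", "d", "F", 1),
            ("m", None, None, "M", 0),
            ("x", "m", "o1", "F", 2),
        ]
        ped_table = pd.DataFrame(
            rows, columns=["id", "sire", "dam", "sex", "generation"]
        ).sort_values("generation", ignore_index=True)
        from gxegwas.datatypes import Pedigree

        ped = Pedigree(ped_table)
        cfg = SimulationConfig(
            n_founders=2,
            n_generations=1,
            n_snps=1,
            n_years=3,
            v_a=1.0,
            v_pe=0.0,
            v_res=0.0,
            age_effect=0.0,
            mu=0.0,
            mean_records=1.0,
            seed=0,
        )
        G, _ = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        females = ped.females()
        draws = []
        for rep in range(2000):
            c = dataclasses.replace(cfg, seed=rep)
            pheno = simulate_phenotypes(ped, G, temps, c)
            draws.append(pheno.set_index("id")["laying_date"].loc[females].to_numpy())
        draws = np.array(draws)
        emp = np.cov(draws.T)
        A = a_matrix(ped).to_frame().loc[females, females].to_numpy()
        np.testing.assert_allclose(emp, A, atol=0.08)

    def test_class_record_weights_shift_shares(self):
        cfg = SimulationConfig(
            n_founders=300,
            n_generations=2,
            n_snps=2,
            mean_records=1.5,
            class_record_weights={"cold": 0.5, "intermediate": 1.0, "warm": 2.0},
            seed=13,
        )
        ped = simulate_pedigree(cfg)
        G, _ = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, G, temps, cfg)
        years = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
        cls = env_classes.classify_years(
            {int(y): env_classes.window_mean(temps, int(y)) for y in years}
        )
        out = env_classes.center_phenotypes(pheno, cls)
        shares = out["tclass"].value_counts(normalize=True)
        assert shares["warm"] > shares["intermediate"] > shares["cold"]
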