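"""Simulation studies that validate the pipeline's statistical behavior.

These are the stochastic experiments behind the acceptance checks:
heritability recovery from data generated under known variance components,
the residual-heteroscedasticity inflation demonstration, and the
interaction-vs-main model comparison under true class-specific SNP
effects.  Each function is deterministic given its seed and scales with
its size arguments so callers can trade precision for runtime.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import env_classes, gwas
from .mixed_model import ModelSpec, heritability, reml_fit
from .relatedness import a_matrix
from .simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_temperatures,
)

# optimizer settings for bulk fits: point estimates at these tolerances
# agree with the tight default to ~1e-4, at a fraction of the cost
_FAST = {"n_restarts": 0, "fatol": 1e-7, "xatol": 1e-4, "polish": False}


def _classification(temps: pd.DataFrame) -> env_classes.YearClassification:
    years = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
    means = {int(y): env_classes.window_mean(temps, int(y)) for y in years}
    return env_classes.classify_years(means)


def h2_recovery(
    seed: int,
    n_seeds: int = 20,
    v_a: float = 10.8,
    v_pe: float = 3.0,
    v_res: float = 14.5,
    n_founders: int = 750,
    n_generations: int = 3,
    mean_records: float = 1.3,
) -> dict:
    """Simulate under known components and REML-estimate h² repeatedly.

    The default pedigree yields ~1500 phenotyped females per replicate.
    Returns per-seed estimates, their mean, and the generative truth.
    """
    truth = v_a / (v_a + v_pe + v_res)
    estimates = []
    n_records = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_founders=n_founders,
            n_generations=n_generations,
            offspring_per_pair=2,
            n_snps=2,
            n_years=9,
            v_a=v_a,
            v_pe=v_pe,
            v_res=v_res,
            age_effect=-2.0,
            mean_records=mean_records,
            seed=seed + k,
        )
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, geno, temps, cfg)
        A = a_matrix(ped)
        fit = reml_fit(
            pheno,
            "laying_date",
            A,
            ModelSpec(fixed_factors=("age_class",)),
            compute_se=False,
            **_FAST,
        )
        h2, _ = heritability(fit.vc)
        estimates.append(h2)
        n_records = max(n_records, fit.n_records)
    return {
        "estimates": estimates,
        "mean_h2": float(np.mean(estimates)),
        "truth": truth,
        "n_records": n_records,
    }


def _inflation_base(seed: int) -> SimulationConfig:
    # null model with class-dependent residual variances (2:1:1) and the
    # high-variance class under-represented in records, as in observed
    # data where breeding effort varies across springs
    return SimulationConfig(
        n_founders=240,
        n_generations=2,
        offspring_per_pair=2,
        n_snps=25,
        n_years=9,
        v_a=10.8,
        v_pe=3.0,
        v_res={"cold": 29.0, "intermediate": 14.5, "warm": 14.5},
        class_record_weights={"cold": 0.6, "intermediate": 0.9, "warm": 1.5},
        age_effect=-2.0,
        mean_records=1.5,
        seed=seed,
    )


def inflation_study(seed: int, n_reps: int = 80) -> dict:
    """Genomic inflation of the interaction test under residual
    heteroscedasticity.

    One pedigree and SNP panel are fixed; each replicate redraws the
    phenotypes under the null (no SNP effects) with class-dependent
    residual variances, then scans all SNPs under both the homogeneous-
    and heterogeneous-residual models with REML-estimated components.
    Lambda is computed from the pooled interaction p-values.
    """
    base = _inflation_base(seed)
    ped = simulate_pedigree(base)
    geno, info = simulate_genotypes(ped, base)
    temps = simulate_temperatures(base)
    A = a_matrix(ped)
    classification = _classification(temps)
    pooled = {"homogeneous": [], "heterogeneous": []}
    for rep in range(n_reps):
        cfg = dataclasses.replace(base, seed=seed + 7919 * (rep + 1))
        pheno = simulate_phenotypes(ped, geno, temps, cfg)
        records = env_classes.center_phenotypes(pheno, classification)
        for residuals in pooled:
            res = gwas.run_scan(
                records, geno, info, A, residuals=residuals, **_FAST
            )
            pooled[residuals] += res["p_interaction"].tolist()
    return {
        "lambda_homogeneous": gwas.genomic_inflation(pooled["homogeneous"], df=4),
        "lambda_heterogeneous": gwas.genomic_inflation(
            pooled["heterogeneous"], df=4
        ),
        "n_tests": len(pooled["homogeneous"]),
    }


def _reversing_effects(delta: float) -> dict:
    """Class-specific per-genotype effects whose sign flips between cold
    and warm springs; no marginal effect when classes are balanced."""
    return {
        "cold": (-delta, 0.0, delta),
        "intermediate": (0.0, 0.0, 0.0),
        "warm": (delta, 0.0, -delta),
    }


def model_comparison_study(
    seed: int,
    n_seeds: int = 20,
    n_causal: int = 10,
    n_null: int = 10,
    delta: float = 2.0,
) -> dict:
    """Adjusted marginal r² of interaction vs main-effect models when SNP
    effects genuinely differ among temperature classes.

    Each replicate plants class-reversing effects at ``n_causal`` SNPs,
    scans causal and null SNPs with both models, and pools the
    model-comparison summaries over the SNPs significant at 0.05.
    """
    favored = 0
    significant = 0
    for k in range(n_seeds):
        n_snps = n_causal + n_null
        cfg = SimulationConfig(
            n_founders=240,
            n_generations=2,
            offspring_per_pair=2,
            n_snps=n_snps,
            n_years=9,
            v_a=10.8,
            v_pe=3.0,
            v_res=14.5,
            age_effect=-2.0,
            mean_records=1.5,
            seed=seed + 1000 * k,
        )
        causal = {
            f"snp{j:05d}": _reversing_effects(delta) for j in range(n_causal)
        }
        cfg = dataclasses.replace(cfg, causal_snps=causal)
        ped = simulate_pedigree(cfg)
        geno, info = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, geno, temps, cfg)
        A = a_matrix(ped)
        records = env_classes.center_phenotypes(pheno, _classification(temps))
        results = gwas.run_scan(records, geno, info, A, **_FAST)
        sig, summary = gwas.compare_models(results, alpha=0.05)
        significant += summary["n_significant"]
        if summary["n_significant"]:
            favored += int(sig["interaction_better"].sum())
    return {
        "n_significant": significant,
        "fraction_interaction_better": favored / significant
        if significant
        else float("nan"),
    }


def interaction_power_study(
    seed: int,
    n_seeds: int = 20,
    n_null: int = 200,
    delta: float = 2.5,
) -> dict:
    """Power of the interaction test at one planted class-reversing SNP.

    Counts the replicates in which (a) the planted SNP has the smallest
    interaction p-value genome-wide and (b) its interaction p beats its
    main-effect p.
    """
    smallest = 0
    beats_main = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_founders=240,
            n_generations=2,
            offspring_per_pair=2,
            n_snps=n_null + 1,
            n_years=9,
            v_a=10.8,
            v_pe=3.0,
            v_res=14.5,
            age_effect=-2.0,
            mean_records=1.5,
            causal_snps={"snp00000": _reversing_effects(delta)},
            seed=seed + 1000 * k,
        )
        ped = simulate_pedigree(cfg)
        geno, info = simulate_genotypes(ped, cfg)
        temps = simulate_temperatures(cfg)
        pheno = simulate_phenotypes(ped, geno, temps, cfg)
        A = a_matrix(ped)
        records = env_classes.center_phenotypes(pheno, _classification(temps))
        results = gwas.run_scan(records, geno, info, A, **_FAST).set_index("snp")
        if results["p_interaction"].idxmin() == "snp00000":
            smallest += 1
        row = results.loc["snp00000"]
        if row["p_interaction"] < row["p_main"]:
            beats_main += 1
    return {
        "n_seeds": n_seeds,
        "planted_snp_smallest_p": smallest,
        "interaction_beats_main": beats_main,
    }
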