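"""End-to-end pipeline: simulate -> qc -> classify/center -> relatedness ->
gwas -> h2 -> compare, with a manifest written next to the artifacts.

Every stage reads its inputs from, and writes its outputs to, plain-text
files under the configured output directory, so a run can be resumed from
any stage's artifacts.  Identical configuration (including the root seed)
produces byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, env_classes, gwas, io_formats, mixed_model, qc, relatedness
from .datatypes import ValidationError
from .simulate import SimulationConfig, simulate_dataset

STAGES = ("simulate", "qc", "classify", "relatedness", "gwas", "h2", "compare")


@dataclasses.dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    simulate: SimulationConfig = None
    thresholds: qc.QcThresholds = None
    residuals: str = "heterogeneous"
    vc_mode: str = "null-fixed"
    alpha: float = 0.05
    keff_window: int = 20

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)
        if self.thresholds is None:
            self.thresholds = qc.QcThresholds()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        seed = int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("simulate", {}))
        sim_kwargs.setdefault("seed", seed)
        for key in ("maf_range", "year_temp_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        analysis = raw.get("analysis", {})
        return cls(
            outdir=Path(raw.get("outdir", "pipeline_out")),
            seed=seed,
            simulate=SimulationConfig(**sim_kwargs),
            thresholds=qc.QcThresholds(**raw.get("qc", {})),
            residuals=analysis.get("residuals", "heterogeneous"),
            vc_mode=analysis.get("vc_mode", "null-fixed"),
            alpha=float(analysis.get("alpha", 0.05)),
            keff_window=int(analysis.get("keff_window", 20)),
        )

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "simulate": self.simulate.to_dict(),
            "qc": dataclasses.asdict(self.thresholds),
            "analysis": {
                "residuals": self.residuals,
                "vc_mode": self.vc_mode,
                "alpha": self.alpha,
                "keff_window": self.keff_window,
            },
        }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dictionary.

    On stage failure the manifest (with the failing stage recorded) is
    still written and the exception re-raised; earlier artifacts remain on
    disk.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "failed_stage": None,
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest["failed_stage"] = manifest.get("_current")
        manifest["error"] = str(exc)
        raise
    finally:
        manifest.pop("_current", None)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: dict) -> None:
    log = manifest["stages"]

    manifest["_current"] = "simulate"
    ped, G, info, temps, pheno = simulate_dataset(config.simulate)
    sexes = dict(zip(ped.table["id"], ped.table["sex"]))
    io_formats.write_plink_text(G, info, out / "sim.ped", out / "sim.map", sexes=sexes)
    io_formats.write_pedigree_csv(ped, out / "pedigree.csv")
    io_formats.write_phenotype_csv(pheno, out / "phenotypes.csv")
    io_formats.write_temperature_csv(temps, out / "temperatures.csv")
    log["simulate"] = {
        "n_individuals": G.n_individuals,
        "n_snps": G.n_snps,
        "n_records": len(pheno),
    }

    manifest["_current"] = "classify"
    years = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
    means = {int(y): env_classes.window_mean(temps, int(y)) for y in years}
    classification = env_classes.classify_years(means)
    classification.table.to_csv(out / "year_classes.csv", index=False)
    pheno_c = env_classes.center_phenotypes(pheno, classification)
    pheno_c.to_csv(out / "phenotypes_centered.csv", index=False)
    log["classify"] = classification.sizes()

    manifest["_current"] = "qc"
    thr = config.thresholds
    G1, info1, snp_report = qc.snp_filters(G, info, thr)
    surviving_ids, ind_report = qc.individual_filters(G1, thr)
    G2 = G1.subset(ids=surviving_ids)
    record_classes = pheno_c.loc[
        pheno_c["id"].isin(set(surviving_ids)), ["id", "tclass"]
    ]
    class_ok = qc.genotype_class_support(G2, record_classes, thr)
    G3 = G2.subset(snps=class_ok)
    info3 = info1[info1["snp"].isin(set(class_ok))].reset_index(drop=True)
    report = qc.QcReport(stages=snp_report.stages + ind_report.stages)
    report.add(
        "class_support",
        sorted(set(G2.snps) - set(class_ok)),
        f">= {thr.min_class_count} per genotype x class cell",
    )
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    io_formats.write_plink_text(
        G3, info3, out / "qc.ped", out / "qc.map", sexes=sexes
    )
    log["qc"] = {
        "snps_in": G.n_snps,
        "snps_out": G3.n_snps,
        "individuals_in": G.n_individuals,
        "individuals_out": len(surviving_ids),
    }
    if G3.n_snps == 0:
        raise ValidationError("QC removed every SNP; nothing to scan")

    manifest["_current"] = "relatedness"
    amat = relatedness.a_matrix(ped)
    io_formats.write_matrix_tsv(amat.values, amat.ids, out / "a_matrix.tsv")
    log["relatedness"] = {"n": len(amat.ids)}

    manifest["_current"] = "gwas"
    pheno_scan = pheno_c[pheno_c["id"].isin(set(G3.ids))].reset_index(drop=True)
    results = gwas.run_scan(
        pheno_scan,
        G3,
        info3,
        amat,
        residuals=config.residuals,
        vc_mode=config.vc_mode,
    )
    io_formats.write_gwas_tsv(results, out / "gwas_results.tsv")
    mt = gwas.multiple_testing(
        G3, info3, alpha=config.alpha, window=config.keff_window
    )
    with open(out / "multiple_testing.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(mt) | {"reduction": mt.reduction}, fh, indent=2)
    gwas.qq_table(results["p_interaction"]).to_csv(
        out / "qq_interaction.tsv", sep="\t", index=False
    )
    gwas.manhattan_table(results).to_csv(
        out / "manhattan_interaction.tsv", sep="\t", index=False
    )
    log["gwas"] = {"n_snps": len(results), "keff": mt.keff}

    manifest["_current"] = "h2"
    table1 = mixed_model.h2_by_class(pheno_c, amat)
    table1.to_csv(out / "h2_by_class.tsv", sep="\t", index=False)
    log["h2"] = {"classes": len(table1)}

    manifest["_current"] = "compare"
    sig, summary = gwas.compare_models(results, alpha=config.alpha)
    sig.to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    log["compare"] = summary
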