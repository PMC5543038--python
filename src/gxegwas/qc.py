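"""SNP- and individual-level quality control cascade.

Filter order is fixed: duplicated/missing genomic coordinates, monomorphic
SNPs, SNP call rate, MAF; then individual call rate, heterozygosity
outliers (normal approximation + Benjamini-Hochberg FDR), near-duplicate
pairs by IBS; finally the genotype x temperature-class support rule.
Hardy-Weinberg deviation is deliberately NOT a removal criterion: trait
loci under directional selection may deviate from HWE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix, ValidationError
from .relatedness import ibs_matrix


@dataclass
class QcThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.10
    het_fdr: float = 0.01
    max_ibs: float = 0.95
    min_class_count: int = 20
    mds_dims: int = 2
    mds_sd_multiplier: float = 6.0

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "het_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValidationError(
                f"min_maf must be in [0, 0.5] (MAF cannot exceed 0.5), "
                f"got {self.min_maf}"
            )
        if self.min_class_count < 0:
            raise ValidationError("min_class_count must be >= 0")


@dataclass
class QcReport:
    """Ordered log of (filter name, removed ids, threshold applied)."""

    stages: list = field(default_factory=list)

    def add(self, name: str, removed, threshold) -> None:
        self.stages.append(
            {"filter": name, "removed": sorted(map(str, removed)), "threshold": threshold}
        )

    def removed(self, name: str) -> list:
        for stage in self.stages:
            if stage["filter"] == name:
                return stage["removed"]
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s["filter"], str(s["threshold"]), len(s["removed"]), ";".join(s["removed"]))
            for s in self.stages
        ]
        return pd.DataFrame(rows, columns=["filter", "threshold", "n_removed", "removed"])


def snp_filters(
    G: GenotypeMatrix, info: pd.DataFrame, thr: QcThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """SNP cascade: bad coordinates, monomorphic, call rate, MAF."""
    if G.n_snps == 0 or G.n_individuals == 0:
        raise ValidationError("empty genotype matrix")
    if list(info["snp"]) != list(G.snps):
        raise ValidationError("SNP info must match genotype columns in order")
    report = QcReport()
    keep = pd.Series(True, index=info["snp"].to_numpy())

    pos_bad = info["pos"].isna() | (info["pos"] <= 0)
    coord_dup = info.duplicated(subset=["chrom", "pos"], keep=False) & ~pos_bad
    bad = info.loc[pos_bad.to_numpy() | coord_dup.to_numpy(), "snp"]
    report.add("coordinates", bad, "missing or duplicated (chrom, pos)")
    keep[bad] = False

    sub = G.subset(snps=keep.index[keep])
    called = sub.called()
    mono = np.zeros(sub.n_snps, dtype=bool)
    for j in range(sub.n_snps):
        vals = sub.values[called[:, j], j]
        mono[j] = len(np.unique(vals)) <= 1
    bad = sub.snps[mono]
    report.add("monomorphic", bad, "single observed genotype")
    keep[bad] = False

    sub = G.subset(snps=keep.index[keep])
    low_cr = sub.snp_call_rate() < thr.min_call_rate
    bad = sub.snps[low_cr]
    report.add("snp_call_rate", bad, f"< {thr.min_call_rate}")
    keep[bad] = False

    sub = G.subset(snps=keep.index[keep])
    low_maf = sub.maf() < thr.min_maf
    bad = sub.snps[low_maf]
    report.add("maf", bad, f"< {thr.min_maf}")
    keep[bad] = False

    surviving = keep.index[keep]
    out_info = info[info["snp"].isin(set(surviving))].reset_index(drop=True)
    return G.subset(snps=surviving), out_info, report


def individual_filters(
    G: GenotypeMatrix, thr: QcThresholds
) -> tuple[list, QcReport]:
    """Individual cascade: call rate, heterozygosity FDR, IBS duplicates."""
    if G.n_individuals < 2:
        raise ValidationError("need >= 2 individuals")
    report = QcReport()
    ids = list(G.ids)

    call_rate = dict(zip(ids, G.individual_call_rate()))
    removed_cr = [i for i in ids if call_rate[i] < thr.min_call_rate]
    report.add("individual_call_rate", removed_cr, f"< {thr.min_call_rate}")
    ids = [i for i in ids if i not in set(removed_cr)]

    # heterozygosity outliers: z-score against the sample, two-sided normal
    # p-values, Benjamini-Hochberg at the configured FDR level.  This is an
    # approximate reconstruction; the exact test behind the published
    # "FDR < 1%" rule is tool-internal and unspecified.
    sub = G.subset(ids=ids)
    called = sub.called()
    het = np.where(called, sub.values == 1, False).sum(axis=1) / np.maximum(
        called.sum(axis=1), 1
    )
    sd = het.std(ddof=1) if len(het) > 1 else 0.0
    if sd > 0:
        z = (het - het.mean()) / sd
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        padj = stats.false_discovery_control(pvals, method="bh")
        removed_het = [i for i, p in zip(ids, padj) if p < thr.het_fdr]
    else:
        removed_het = []
    report.add("heterozygosity", removed_het, f"BH FDR < {thr.het_fdr}")
    ids = [i for i in ids if i not in set(removed_het)]

    # near-duplicates: among pairs at or above the IBS threshold, drop the
    # member with the lower call rate (tie -> lexicographically larger id).
    sub = G.subset(ids=ids)
    ibs = ibs_matrix(sub)
    iu, ju = np.triu_indices(len(ids), k=1)
    high = ibs.values[iu, ju] >= thr.max_ibs
    order = np.argsort(-ibs.values[iu, ju][high])
    removed_ibs: list = []
    alive = set(ids)
    for k in order:
        a, b = ids[iu[high][k]], ids[ju[high][k]]
        if a not in alive or b not in alive:
            continue
        if call_rate[a] < call_rate[b]:
            drop = a
        elif call_rate[b] < call_rate[a]:
            drop = b
        else:
            drop = max(a, b)
        removed_ibs.append(drop)
        alive.discard(drop)
    report.add("ibs_duplicates", removed_ibs, f">= {thr.max_ibs}")
    ids = [i for i in ids if i in alive]
    return ids, report


def genotype_class_support(
    G: GenotypeMatrix,
    record_classes: pd.DataFrame,
    thr: QcThresholds,
) -> list:
    """Retain SNPs whose 9 genotype x temperature-class cells are all
    supported.

    ``record_classes`` needs columns ``id`` and ``tclass`` (one row per
    phenotype record); an individual is counted once per class it bred in.
    A SNP survives iff all three genotypes occur overall and every
    genotype x class cell holds at least ``min_class_count`` distinct
    phenotyped individuals (inclusive threshold).
    """
    if not {"id", "tclass"} <= set(record_classes.columns):
        raise ValidationError("record_classes needs columns id, tclass")
    if record_classes["tclass"].isna().any():
        raise ValidationError("missing temperature class labels")
    pos = {v: i for i, v in enumerate(G.ids)}
    members = {
        c: np.array(
            sorted({pos[i] for i in grp["id"] if i in pos}), dtype=int
        )
        for c, grp in record_classes.groupby("tclass")
    }
    surviving = []
    for j, snp in enumerate(G.snps):
        col = G.values[:, j]
        overall = {g for g in col[col != MISSING]}
        if overall != {0, 1, 2}:
            continue
        ok = True
        for idx in members.values():
            sub = col[idx]
            for g in (0, 1, 2):
                if (sub == g).sum() < thr.min_class_count:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            surviving.append(snp)
    return surviving
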