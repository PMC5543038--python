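"""Shared domain containers used across the pipeline.

Conventions
-----------
* Individual ids, SNP ids, chromosome names and area names are strings.
* Genotypes count alternate alleles: 0, 1, 2; missing is stored as -1.
* Laying dates are 1-based day-of-year; temperatures are daily means in
  degrees Celsius.
* Temperature classes are the strings ``"cold"``, ``"intermediate"`` and
  ``"warm"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

CLASS_LABELS = ("cold", "intermediate", "warm")

AGE_LEVELS = ("first", "older")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass(frozen=True)
class Pedigree:
    """Pedigree table with columns id, sire, dam, sex, generation.

    ``sire``/``dam`` are ``None`` for unknown parents (founders).  Rows are
    ordered so that parents precede offspring (ascending generation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"id", "sire", "dam", "sex", "generation"}
        missing_cols = required - set(t.columns)
        if missing_cols:
            raise ValidationError(f"pedigree missing columns: {sorted(missing_cols)}")
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate pedigree ids: {dups[:5]}")
        if not t["sex"].isin(["F", "M"]).all():
            raise ValidationError("pedigree sex must be 'F' or 'M'")
        gen = dict(zip(t["id"], t["generation"]))
        sex = dict(zip(t["id"], t["sex"]))
        for _, row in t.iterrows():
            for parent, want in ((row["sire"], "M"), (row["dam"], "F")):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent not in gen:
                    raise ValidationError(
                        f"unknown parent id {parent!r} of {row['id']!r}"
                    )
                if gen[parent] >= row["generation"]:
                    raise ValidationError(
                        f"parent {parent!r} does not precede offspring {row['id']!r}"
                    )
                if sex[parent] != want:
                    raise ValidationError(
                        f"parent {parent!r} of {row['id']!r} has sex "
                        f"{sex[parent]!r}, expected {want!r}"
                    )

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def females(self) -> list[str]:
        t = self.table
        return t.loc[t["sex"] == "F", "id"].tolist()


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele counts; -1 marks a missing call."""

    values: np.ndarray
    ids: np.ndarray
    snps: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.ids = np.asarray(self.ids, dtype=object)
        self.snps = np.asarray(self.snps, dtype=object)
        if self.values.shape != (len(self.ids), len(self.snps)):
            raise ValidationError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snps)} snps"
            )
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("genotype entries must be 0, 1, 2 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.values != MISSING

    def snp_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return self.called().mean(axis=1)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP over non-missing calls."""
        called = self.called()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.values, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2.0 * n_called)
        freq = np.where(n_called == 0, np.nan, freq)
        return np.minimum(freq, 1.0 - freq)

    def column(self, snp: str) -> np.ndarray:
        (j,) = np.where(self.snps == snp)
        if len(j) == 0:
            raise KeyError(f"SNP {snp!r} not in genotype matrix")
        return self.values[:, j[0]]

    def subset(self, ids=None, snps=None) -> "GenotypeMatrix":
        vals, out_ids, out_snps = self.values, self.ids, self.snps
        if ids is not None:
            idx = _index_of(self.ids, ids, "individual")
            vals, out_ids = vals[idx], self.ids[idx]
        if snps is not None:
            jdx = _index_of(self.snps, snps, "SNP")
            vals, out_snps = vals[:, jdx], self.snps[jdx]
        return GenotypeMatrix(vals.copy(), out_ids.copy(), out_snps.copy())


def _index_of(universe: np.ndarray, wanted, kind: str) -> np.ndarray:
    pos = {v: i for i, v in enumerate(universe)}
    try:
        return np.array([pos[w] for w in wanted], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown {kind} id {exc.args[0]!r}") from None


def validate_snp_info(info: pd.DataFrame) -> pd.DataFrame:
    required = {"snp", "chrom", "pos", "ref", "alt"}
    missing = required - set(info.columns)
    if missing:
        raise ValidationError(f"SNP info missing columns: {sorted(missing)}")
    if info["snp"].duplicated().any():
        raise ValidationError("duplicate SNP ids in SNP info")
    return info


def validate_temperature_series(temps: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "temp_c"}
    missing = required - set(temps.columns)
    if missing:
        raise ValidationError(f"temperature series missing columns: {sorted(missing)}")
    if temps["date"].duplicated().any():
        dup = temps.loc[temps["date"].duplicated(), "date"].iloc[0]
        raise ValidationError(f"duplicate temperature date {dup}")
    return temps


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "year", "area", "laying_date", "age_class"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
    bad_age = ~pheno["age_class"].isin(AGE_LEVELS)
    if bad_age.any():
        labels = sorted(pheno.loc[bad_age, "age_class"].unique())
        raise ValidationError(
            f"unknown age labels {labels}; expected one of {list(AGE_LEVELS)}"
        )
    dup = pheno.duplicated(subset=["id", "year"], keep=False)
    if dup.any():
        lines = (pheno.index[dup] + 2).tolist()  # 1-based + header line
        raise ValidationError(
            f"duplicate (id, year) phenotype rows at lines {lines[:10]}"
        )
    return pheno


@dataclass
class Dataset:
    """All pipeline inputs cross-indexed by individual id."""

    genotypes: GenotypeMatrix | None = None
    snp_info: pd.DataFrame | None = None
    pedigree: Pedigree | None = None
    phenotypes: pd.DataFrame | None = None
    temperatures: pd.DataFrame | None = None
    ungenotyped: set = field(default_factory=set)

    def validate_links(self) -> None:
        if self.phenotypes is not None and self.genotypes is not None:
            geno_ids = set(self.genotypes.ids)
            pheno_ids = set(self.phenotypes["id"])
            orphans = pheno_ids - geno_ids - set(self.ungenotyped)
            if orphans:
                raise ValidationError(
                    f"phenotyped ids without genotypes and not flagged "
                    f"ungenotyped: {sorted(orphans)[:5]}"
                )
        if self.genotypes is not None and self.pedigree is not None:
            ped_ids = set(self.pedigree.ids)
            missing = set(self.genotypes.ids) - ped_ids
            if missing:
                raise ValidationError(
                    f"genotyped ids absent from pedigree: {sorted(missing)[:5]}"
                )
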