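"""Readers and writers for PLINK text genotypes and the project CSV/TSV
tables.

PLINK .ped rows are ``FID IID PAT MAT SEX PHENO`` followed by two
space-separated alleles per SNP; ``0 0`` is a missing call.  On read the
alternate allele is recoded as the minor allele (ties broken toward the
lexicographically larger base, so round trips are stable for simulated
data with MAF < 0.5).  All CSVs are comma-separated, UTF-8, with a header
row; parsers reject malformed rows instead of coercing them.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    Pedigree,
    ValidationError,
    validate_phenotypes,
    validate_snp_info,
    validate_temperature_series,
)


def read_plink_text(
    ped_path, map_path
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read text .ped/.map into alt-allele counts plus SNP info."""
    map_rows = []
    with open(map_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 .map columns")
            chrom, snp, _cm, pos = parts
            map_rows.append((snp, chrom, int(pos)))
    n_snps = len(map_rows)

    ids: list[str] = []
    sexes: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2 x {n_snps} SNPs), got {len(parts)}"
                )
            ids.append(parts[1])
            sexes.append(parts[4])
            pairs = list(zip(parts[6::2], parts[7::2]))
            allele_pairs.append(pairs)

    # determine per-SNP alleles and recode with the minor allele as alt
    geno = np.full((len(ids), n_snps), MISSING, dtype=np.int8)
    alleles_out = []
    for j in range(n_snps):
        counts: dict[str, int] = {}
        for i in range(len(ids)):
            for a in allele_pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise FormatError(
                f"SNP {map_rows[j][0]!r} is not biallelic: "
                f"alleles {sorted(counts)}"
            )
        if len(counts) == 0:
            alleles_out.append(("N", "N"))
            continue
        # alt = minor allele; ties -> lexicographically larger allele
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ordered) == 1:
            ref, alt = ordered[0][0], "N"
        else:
            alt, ref = ordered[0][0], ordered[1][0]
        alleles_out.append((ref, alt))
        for i in range(len(ids)):
            a, b = allele_pairs[i][j]
            if a == "0" or b == "0":
                if a != b:
                    raise FormatError(
                        f"{ped_path}: half-missing call at individual "
                        f"{ids[i]!r}, SNP {map_rows[j][0]!r}"
                    )
                continue
            geno[i, j] = (a == alt) + (b == alt)

    info = pd.DataFrame(
        [
            (snp, chrom, pos, ref, alt)
            for (snp, chrom, pos), (ref, alt) in zip(map_rows, alleles_out)
        ],
        columns=["snp", "chrom", "pos", "ref", "alt"],
    )
    gm = GenotypeMatrix(
        geno, np.array(ids, dtype=object), info["snp"].to_numpy()
    )
    return gm, validate_snp_info(info)


def write_plink_text(
    G: GenotypeMatrix,
    info: pd.DataFrame,
    ped_path,
    map_path,
    sexes: dict | None = None,
) -> None:
    """Inverse of :func:`read_plink_text` up to allele-label convention."""
    validate_snp_info(info)
    if list(info["snp"]) != list(G.snps):
        raise ValidationError("SNP info rows must match genotype columns in order")
    sex_code = {"M": "1", "F": "2"}
    ref = info["ref"].to_numpy()
    alt = info["alt"].to_numpy()
    with open(map_path, "w", encoding="utf-8") as fh:
        for _, row in info.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t0\t{row['pos']}\n")
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i, iid in enumerate(G.ids):
            sex = sex_code.get((sexes or {}).get(iid, ""), "0")
            fields = [str(iid), str(iid), "0", "0", sex, "-9"]
            g = G.values[i]
            for j in range(G.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [ref[j], ref[j]]
                elif g[j] == 1:
                    # canonical order keeps heterozygotes byte-stable under
                    # the reader's minor-allele relabelling
                    fields += sorted((ref[j], alt[j]))
                else:
                    fields += [alt[j], alt[j]]
            fh.write(" ".join(fields) + "\n")


def _parse_laying_date(value, year: int, line: int) -> float:
    """Accept a day-of-year number or an ISO calendar date."""
    s = str(value).strip()
    try:
        return float(s)
    except ValueError:
        pass
    try:
        d = dt.date.fromisoformat(s)
    except ValueError:
        raise FormatError(
            f"phenotype line {line}: cannot parse laying date {value!r}"
        ) from None
    return float(d.timetuple().tm_yday)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    required = {"id", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing pedigree columns {sorted(missing)}")
    df["sire"] = df["sire"].where(df["sire"].notna(), None)
    df["dam"] = df["dam"].where(df["dam"].notna(), None)
    if "generation" not in df.columns:
        gen: dict[str, int] = {}
        for _, row in df.iterrows():
            parents = [p for p in (row["sire"], row["dam"]) if p is not None]
            gen[row["id"]] = 1 + max((gen.get(p, 0) for p in parents), default=-1)
        df["generation"] = df["id"].map(gen)
        df = df.sort_values("generation", kind="stable", ignore_index=True)
    return Pedigree(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    out = ped.table[["id", "sire", "dam", "sex", "generation"]].copy()
    out.to_csv(path, index=False)


def read_phenotype_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "area": str, "age_class": str})
    required = {"id", "year", "area", "laying_date", "age_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing phenotype columns {sorted(missing)}")
    df["year"] = df["year"].astype(int)
    df["laying_date"] = [
        _parse_laying_date(v, y, i + 2)
        for i, (v, y) in enumerate(zip(df["laying_date"], df["year"]))
    ]
    return validate_phenotypes(df)


def write_phenotype_csv(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno)
    pheno.to_csv(path, index=False)


def read_temperature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"date", "temp_c"} <= set(df.columns):
        raise FormatError(f"{path}: temperature CSV needs columns date,temp_c")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise FormatError(f"{path}: unparseable date ({exc})") from None
    df["temp_c"] = df["temp_c"].astype(float)
    return validate_temperature_series(df)


def write_temperature_csv(temps: pd.DataFrame, path) -> None:
    validate_temperature_series(temps)
    temps.to_csv(path, index=False)


GWAS_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "maf",
    "df_main",
    "stat_main",
    "p_main",
    "df_interaction",
    "stat_interaction",
    "p_interaction",
    "r2adj_main",
    "r2adj_interaction",
    "converged",
]


def write_gwas_tsv(results: pd.DataFrame, path) -> None:
    missing = set(GWAS_COLUMNS) - set(results.columns)
    if missing:
        raise ValidationError(f"GWAS results missing columns {sorted(missing)}")
    results[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})


def write_matrix_tsv(values: np.ndarray, ids, path) -> None:
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: matrix row/column ids differ")
    return df.to_numpy(dtype=float), df.index.to_numpy(dtype=object)
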