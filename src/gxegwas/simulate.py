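"""Simulation of pedigrees, genotypes, spring temperatures and phenotypes.

The generator emulates the structure assumed by the analysis: a
multi-generation pedigree of phenotyped females, biallelic SNPs with local
LD produced by a first-order Markov haplotype model plus Mendelian gene
dropping, annual spring temperature series, and repeated laying-date
records built from the repeated-measures animal model with class-specific
residual variances and optionally class-specific SNP effects.

All randomness flows from a single root seed.  The root ``SeedSequence``
is split into four named child streams (pedigree, genotypes, temperatures,
phenotypes) so that, e.g., regenerating phenotypes with a different causal
specification leaves the pedigree and genotypes untouched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CLASS_LABELS,
    MISSING,
    GenotypeMatrix,
    Pedigree,
    ValidationError,
)

_BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Declarative description of one synthetic dataset.

    ``v_res`` may be a single float (homogeneous residuals) or a mapping
    from temperature class to residual variance in days².  ``causal_snps``
    maps a SNP id to per-class genotype effects:
    ``{"snp0001": {"cold": (0.0, 0.5, 1.0), ...}}`` where the tuple gives
    the effect in days added for genotypes 0, 1 and 2.
    """

    # pedigree
    n_founders: int = 100
    n_generations: int = 3
    offspring_per_pair: int = 2
    # genotypes
    n_snps: int = 200
    n_chromosomes: int = 2
    snp_spacing_bp: int = 1000
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_decay_bp: float = 0.0  # 0 disables LD
    missing_rate: float = 0.0
    # temperatures
    n_years: int = 9
    start_year: int = 2000
    year_temp_range: tuple[float, float] = (5.5, 10.0)
    day_sd: float = 1.5
    # phenotypes
    mu: float = 100.0
    v_a: float = 10.8
    v_pe: float = 3.0
    v_res: float | dict = 14.5
    age_effect: float = -2.0
    year_effect_sd: float = 0.0
    areas: dict = field(default_factory=lambda: {"A": 0.0})
    mean_records: float = 1.3
    class_record_weights: dict = field(default_factory=dict)
    causal_snps: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if self.offspring_per_pair < 1:
            raise ConfigurationError("offspring_per_pair must be >= 1")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_years < 3:
            raise ConfigurationError("n_years must be >= 3 (terciles undefined)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.v_a < 0 or self.v_pe < 0:
            raise ConfigurationError("variance components must be >= 0")
        for v in self.residual_variances().values():
            if v < 0:
                raise ConfigurationError("residual variances must be >= 0")
        if self.mean_records < 1.0:
            raise ConfigurationError("mean_records must be >= 1")

    def residual_variances(self) -> dict:
        if isinstance(self.v_res, dict):
            unknown = set(self.v_res) - set(CLASS_LABELS)
            if unknown:
                raise ConfigurationError(f"unknown residual classes {unknown}")
            return {c: float(self.v_res.get(c, 0.0)) for c in CLASS_LABELS}
        return {c: float(self.v_res) for c in CLASS_LABELS}

    def streams(self) -> dict:
        root = np.random.SeedSequence(self.seed)
        names = ("pedigree", "genotypes", "temperatures", "phenotypes")
        return dict(zip(names, root.spawn(len(names))))

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(self.streams()[stream])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Grow a pedigree by monogamous random pairing within each generation.

    Founders have unknown parents; sexes alternate F, M so pair counts are
    stable.  Each pair contributes ``offspring_per_pair`` offspring whose
    sexes also alternate within the family.
    """
    rng = config.rng("pedigree")
    rows: list[tuple] = []
    current: list[tuple[str, str]] = []  # (id, sex) in current generation
    for i in range(config.n_founders):
        sex = "F" if i % 2 == 0 else "M"
        iid = f"G0_{i:05d}"
        rows.append((iid, None, None, sex, 0))
        current.append((iid, sex))
    for g in range(1, config.n_generations + 1):
        females = [i for i, s in current if s == "F"]
        males = [i for i, s in current if s == "M"]
        rng.shuffle(females)
        rng.shuffle(males)
        pairs = list(zip(females, males))
        nxt: list[tuple[str, str]] = []
        k = 0
        for dam, sire in pairs:
            for j in range(config.offspring_per_pair):
                sex = "F" if j % 2 == 0 else "M"
                iid = f"G{g}_{k:05d}"
                rows.append((iid, sire, dam, sex, g))
                nxt.append((iid, sex))
                k += 1
        if not nxt:
            raise ConfigurationError(
                f"generation {g} produced no offspring (no complete pairs)"
            )
        current = nxt
    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "generation"])
    return Pedigree(table)


def _founder_haplotypes(
    n_hap: int, freqs: np.ndarray, adj_corr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov haplotypes with given per-SNP allele frequencies.

    ``adj_corr[j]`` is the target correlation between SNP ``j-1`` and
    SNP ``j`` (``adj_corr[0]`` ignored).  Transition probabilities are the
    unique ones matching both marginals and the target covariance, clipped
    into [0, 1] where the correlation is infeasible for the marginals.
    """
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    for j in range(1, m):
        p_prev, p_cur, r = freqs[j - 1], freqs[j], adj_corr[j]
        cov = r * np.sqrt(p_prev * (1 - p_prev) * p_cur * (1 - p_cur))
        p_given1 = np.clip(p_cur + cov / p_prev, 0.0, 1.0)
        p_given0 = np.clip(p_cur - cov / (1 - p_prev), 0.0, 1.0)
        prob = np.where(hap[:, j - 1] == 1, p_given1, p_given0)
        hap[:, j] = rng.random(n_hap) < prob
    return hap


def _meiosis(
    hap_pair: np.ndarray, chrom_slices: list[slice], rng: np.random.Generator
) -> np.ndarray:
    """One gamete: per chromosome, one uniform crossover between the
    parental haplotypes, starting from a random haplotype."""
    gamete = np.empty(hap_pair.shape[1], dtype=np.int8)
    for sl in chrom_slices:
        m = sl.stop - sl.start
        start = rng.integers(2)
        if m == 1:
            gamete[sl] = hap_pair[start, sl]
            continue
        cut = rng.integers(1, m)
        seg = np.concatenate(
            [hap_pair[start, sl][:cut], hap_pair[1 - start, sl][cut:]]
        )
        gamete[sl] = seg
    return gamete


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Founder Markov haplotypes + Mendelian gene dropping with one uniform
    crossover per chromosome per meiosis."""
    rng = config.rng("genotypes")
    m = config.n_snps
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    per_chrom = per_chrom[per_chrom > 0]
    chrom_slices: list[slice] = []
    start = 0
    for c in per_chrom:
        chrom_slices.append(slice(start, start + int(c)))
        start += int(c)

    freqs = rng.uniform(*config.maf_range, size=m)
    if config.ld_decay_bp > 0:
        r = float(np.exp(-config.snp_spacing_bp / config.ld_decay_bp))
    else:
        r = 0.0
    adj_corr = np.full(m, r)
    for sl in chrom_slices:
        adj_corr[sl.start] = 0.0  # chains restart at chromosome boundaries

    info_rows = []
    for ci, sl in enumerate(chrom_slices):
        for k in range(sl.stop - sl.start):
            j = sl.start + k
            ref, alt = rng.choice(4, size=2, replace=False)
            info_rows.append(
                (
                    f"snp{j:05d}",
                    f"chr{ci + 1}",
                    (k + 1) * config.snp_spacing_bp,
                    _BASES[ref],
                    _BASES[alt],
                )
            )
    snp_info = pd.DataFrame(info_rows, columns=["snp", "chrom", "pos", "ref", "alt"])

    table = pedigree.table
    founder_mask = table["generation"] == 0
    founder_ids = table.loc[founder_mask, "id"].tolist()
    founder_haps = _founder_haplotypes(2 * len(founder_ids), freqs, adj_corr, rng)

    haps: dict[str, np.ndarray] = {}
    for i, iid in enumerate(founder_ids):
        haps[iid] = founder_haps[2 * i : 2 * i + 2]
    for _, row in table.loc[~founder_mask].iterrows():
        sire, dam = row["sire"], row["dam"]
        if sire not in haps or dam not in haps:
            raise ValidationError(
                f"pedigree not in parents-first order at {row['id']!r}"
            )
        paternal = _meiosis(haps[sire], chrom_slices, rng)
        maternal = _meiosis(haps[dam], chrom_slices, rng)
        haps[row["id"]] = np.stack([paternal, maternal])

    ids = table["id"].to_numpy()
    values = np.stack([haps[i].sum(axis=0) for i in ids]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = MISSING
    return GenotypeMatrix(values, ids, snp_info["snp"].to_numpy()), snp_info


def simulate_temperatures(config: SimulationConfig) -> pd.DataFrame:
    """Daily mean temperatures, March 1 – April 30 of each simulated year.

    Annual means are spread evenly across ``year_temp_range`` and shuffled
    over calendar years, so tercile classification is never degenerate;
    daily values add N(0, day_sd²) noise.
    """
    rng = config.rng("temperatures")
    years = np.arange(config.start_year, config.start_year + config.n_years)
    means = np.linspace(*config.year_temp_range, num=config.n_years)
    rng.shuffle(means)
    frames = []
    for year, mean in zip(years, means):
        dates = pd.date_range(f"{year}-03-01", f"{year}-04-30", freq="D")
        temps = mean + rng.normal(0.0, config.day_sd, size=len(dates))
        frames.append(pd.DataFrame({"date": dates.date, "temp_c": temps}))
    return pd.concat(frames, ignore_index=True)


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    temps: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Repeated laying-date records from the generative animal model.

    Breeding values are gene-dropped down the pedigree: founders draw
    N(0, V_A), offspring draw midparent plus Mendelian sampling
    N(0, V_A/2 · (1 − mean parental inbreeding)).  Each female receives
    records in ``1 + Poisson(mean_records − 1)`` distinct years; the first
    year is her "first" breeding; later records are "older".
    """
    from .env_classes import classify_years, window_mean
    from .relatedness import a_matrix

    rng = config.rng("phenotypes")
    for snp_id in config.causal_snps:
        if snp_id not in set(genotypes.snps):
            raise ConfigurationError(
                f"causal SNP {snp_id!r} absent from genotype matrix"
            )

    table = pedigree.table
    ids = table["id"].tolist()
    amat = a_matrix(pedigree)
    inbreeding = dict(zip(amat.ids, np.diag(amat.values) - 1.0))

    # generative breeding values (not drawn from the joint MVN; the pedigree
    # recursion yields the same covariance V_A * A)
    a: dict[str, float] = {}
    sd_f = np.sqrt(config.v_a) if config.v_a > 0 else 0.0
    for _, row in table.iterrows():
        sire, dam = row["sire"], row["dam"]
        if sire is None and dam is None:
            a[row["id"]] = rng.normal(0.0, sd_f)
        else:
            f_bar = 0.5 * (inbreeding[sire] + inbreeding[dam])
            ms_var = 0.5 * config.v_a * (1.0 - f_bar)
            a[row["id"]] = 0.5 * (a[sire] + a[dam]) + rng.normal(
                0.0, np.sqrt(max(ms_var, 0.0))
            )

    years = sorted(pd.to_datetime(temps["date"]).dt.year.unique())
    means = {int(y): window_mean(temps, int(y)) for y in years}
    classification = classify_years(means)
    year_class = dict(zip(classification.table["year"], classification.table["tclass"]))
    v_res = config.residual_variances()

    if config.year_effect_sd > 0:
        year_eff = dict(zip(years, rng.normal(0, config.year_effect_sd, len(years))))
    else:
        year_eff = {y: 0.0 for y in years}
    area_names = list(config.areas)

    females = pedigree.females()
    geno_idx = {v: i for i, v in enumerate(genotypes.ids)}
    causal_cols = {
        s: genotypes.values[:, list(genotypes.snps).index(s)]
        for s in config.causal_snps
    }

    # optional per-class sampling weights for record years: lets record
    # counts differ among temperature classes (observed data are rarely
    # balanced across environments)
    if config.class_record_weights:
        unknown = set(config.class_record_weights) - set(CLASS_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown classes in record weights: {unknown}")
        w = np.array(
            [config.class_record_weights.get(year_class[y], 1.0) for y in years]
        )
        if (w <= 0).any():
            raise ConfigurationError("class record weights must be positive")
        year_probs = w / w.sum()
    else:
        year_probs = None

    sd_pe = np.sqrt(config.v_pe) if config.v_pe > 0 else 0.0
    rows = []
    for iid in females:
        pe = rng.normal(0.0, sd_pe)
        area = area_names[rng.integers(len(area_names))]
        n_rec = 1 + rng.poisson(max(config.mean_records - 1.0, 0.0))
        n_rec = min(n_rec, len(years))
        rec_years = sorted(
            rng.choice(years, size=n_rec, replace=False, p=year_probs)
        )
        for k, year in enumerate(rec_years):
            tclass = year_class[year]
            causal = 0.0
            for snp_id, effects in config.causal_snps.items():
                g = causal_cols[snp_id][geno_idx[iid]]
                if g != MISSING and tclass in effects:
                    causal += effects[tclass][int(g)]
            resid = rng.normal(0.0, np.sqrt(v_res[tclass]))
            value = (
                config.mu
                + year_eff[year]
                + config.areas[area]
                + (config.age_effect if k > 0 else 0.0)
                + causal
                + a[iid]
                + pe
                + resid
            )
            rows.append((iid, int(year), area, value, "first" if k == 0 else "older"))
    return pd.DataFrame(
        rows, columns=["id", "year", "area", "laying_date", "age_class"]
    )


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper running all four stages in order."""
    ped = simulate_pedigree(config)
    geno, info = simulate_genotypes(ped, config)
    temps = simulate_temperatures(config)
    pheno = simulate_phenotypes(ped, geno, temps, config)
    return ped, geno, info, temps, pheno
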