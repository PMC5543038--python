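"""Per-SNP association scans, multiple-testing correction and diagnostics.

The default scan estimates variance components once under the no-SNP null
model and holds them fixed for every SNP (two-stage, GRAMMAR-style); the
``per_snp`` mode refits REML at each SNP.  Both the main-effect model
(3-level genotype factor, 2 df) and the interaction model (genotype x
temperature class, 4 df with 3 classes) are scanned, and each model's
adjusted marginal r² is recorded for model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import MISSING, GenotypeMatrix, ValidationError
from .mixed_model import (
    ModelSpec,
    Workspace,
    build_design,
    reml_fit,
    wald_test,
)
from .relatedness import RelationshipMatrix


@dataclass
class MultipleTesting:
    n_tests: int
    alpha: float
    bonferroni_threshold: float
    keff: float
    keff_threshold: float
    window: int

    @property
    def reduction(self) -> float:
        """(M - Keff) / M, the fraction of tests absorbed by LD."""
        return (self.n_tests - self.keff) / self.n_tests


def bonferroni(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValidationError("need at least one test")
    return alpha / n_tests


def keff(
    G: GenotypeMatrix,
    info: pd.DataFrame,
    window: int = 20,
    alpha: float | None = None,
) -> float:
    """Effective number of independent tests under local LD.

    Per chromosome (SNPs sorted by position), the first SNP contributes 1
    and SNP j contributes sqrt(1 - r²max) where r²max is the largest
    squared Pearson genotype correlation with the preceding
    ``window - 1`` SNPs.  Passing ``alpha`` switches on the
    alpha-dependent exponent refinement (off by default): the contribution
    becomes sqrt(1 - |r|max ** (-1.31 * log10(alpha))).
    """
    if list(info["snp"]) != list(G.snps):
        raise ValidationError("SNP info must match genotype columns in order")
    vals = np.where(G.values == MISSING, np.nan, G.values).astype(float)
    total = 0.0
    for _, chrom_info in info.groupby("chrom", sort=False):
        order = chrom_info.sort_values("pos").index.to_numpy()
        cols = vals[:, order]
        m = len(order)
        contributions = np.ones(m)
        for j in range(1, m):
            lo = max(0, j - (window - 1))
            r2max = 0.0
            for k in range(lo, j):
                pair = ~np.isnan(cols[:, j]) & ~np.isnan(cols[:, k])
                a, b = cols[pair, j], cols[pair, k]
                if a.std() == 0 or b.std() == 0:
                    raise ValidationError(
                        f"zero-variance SNP in Keff window "
                        f"({chrom_info['snp'].iloc[k]!r}); run QC first"
                    )
                r = np.corrcoef(a, b)[0, 1]
                r2max = max(r2max, r * r)
            if alpha is None:
                contributions[j] = np.sqrt(max(0.0, 1.0 - r2max))
            else:
                expo = -1.31 * np.log10(alpha)
                contributions[j] = np.sqrt(
                    max(0.0, 1.0 - np.sqrt(r2max) ** expo)
                )
        total += contributions.sum()
    return float(total)


def multiple_testing(
    G: GenotypeMatrix,
    info: pd.DataFrame,
    alpha: float = 0.05,
    window: int = 20,
) -> MultipleTesting:
    m = G.n_snps
    k = keff(G, info, window=window)
    return MultipleTesting(
        n_tests=m,
        alpha=alpha,
        bonferroni_threshold=bonferroni(m, alpha),
        keff=k,
        keff_threshold=alpha / k,
        window=window,
    )


def genomic_inflation(p_values, df: int) -> float:
    """Median-based inflation factor for chi-square(df) test statistics."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValidationError("no valid p-values")
    if len(p) < 20:
        raise ValidationError("need >= 20 valid p-values for lambda")
    observed = stats.chi2.isf(p, df)
    return float(np.median(observed) / stats.chi2.ppf(0.5, df))


# ---------------------------------------------------------------------------
# scanning


class _FixedVCScanner:
    """GLS engine with variance components frozen at the null-model REML
    estimates; handles per-SNP complete-case subsets by Gram downdating."""

    def __init__(self, ws: Workspace, vc) -> None:
        self.ws = ws
        self.v_a = vc.v_a
        self.v_pe = vc.v_pe
        self.v_res = np.array([vc.v_res[g] for g in ws.group_labels])
        self.full_cache = ws.cache(self.v_a, self.v_pe, self.v_res)

    def gls(self, X: np.ndarray, mask: np.ndarray | None):
        ws = self.ws
        if mask is None or mask.all():
            y = ws.y
            VinvX = ws.vinv(self.full_cache, X)
            Vinvy = ws.vinv(self.full_cache, y)
        else:
            y = ws.y[mask]
            rinv = self.full_cache["rinv"][mask]
            if ws.has_random:
                g = self.full_cache["g"]
                C = np.diag(1.0 / g)
                for k in range(len(ws.group_labels)):
                    rows = (ws.rg == k) & mask
                    Wk = ws.W[rows]
                    C += (Wk.T @ Wk) / self.v_res[k]
                cho = linalg.cho_factor(C, lower=True, check_finite=False)
                W = ws.W[mask]

                def vinv(M):
                    one_d = M.ndim == 1
                    B = rinv[:, None] * (M[:, None] if one_d else M)
                    T = W.T @ B
                    S = linalg.cho_solve(cho, T, check_finite=False)
                    B = B - rinv[:, None] * (W @ S)
                    return B[:, 0] if one_d else B

            else:

                def vinv(M):
                    return rinv[:, None] * M if M.ndim > 1 else rinv * M

            VinvX = vinv(X)
            Vinvy = vinv(y)
        XtViX = X.T @ VinvX
        XtViy = X.T @ Vinvy
        cov = np.linalg.inv(XtViX)
        beta = cov @ XtViy
        return beta, cov


def _wald_block(beta, cov, idx) -> tuple[float, int, float]:
    b = beta[idx]
    S = cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(S, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def _adjusted_r2(var_fixed, vc_total, n, p) -> float:
    r2 = var_fixed / (var_fixed + vc_total)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def run_scan(
    pheno: pd.DataFrame,
    G: GenotypeMatrix,
    info: pd.DataFrame,
    A: RelationshipMatrix,
    residuals: str = "heterogeneous",
    vc_mode: str = "null-fixed",
    response: str = "centered",
    fixed_factors: tuple[str, ...] = ("age_class", "year:area"),
    n_restarts: int = 1,
    fatol: float = 1e-10,
    xatol: float = 1e-7,
    polish: bool = True,
) -> pd.DataFrame:
    """Scan every SNP with the main-effect and interaction models.

    ``pheno`` must carry ``centered`` and ``tclass`` columns (see
    env_classes).  Records of individuals with a missing call at a SNP are
    dropped for that SNP only.  Returns one row per SNP, sorted by
    chromosome and position.

    Although centering already removes the year x area cell means, the
    cell dummies stay in the design: on centered data their coefficients
    vanish, but carrying them makes the test covariance account for the
    degrees of freedom the centering consumed (equivalent to analysing
    raw dates with year, area and year x area fixed effects).  Dropping
    them deflates the interaction test noticeably at desk scale.
    """
    if vc_mode not in ("null-fixed", "per-snp"):
        raise ValidationError(f"unknown vc_mode {vc_mode!r}")
    pheno = pheno[pheno["id"].isin(set(G.ids))].reset_index(drop=True)
    null_spec = ModelSpec(fixed_factors=fixed_factors, residuals=residuals)
    main_spec = ModelSpec(
        fixed_factors=fixed_factors, residuals=residuals, snp_term=True
    )
    ixn_spec = ModelSpec(
        fixed_factors=fixed_factors,
        residuals=residuals,
        snp_term=True,
        interaction=True,
    )

    null_fit = reml_fit(
        pheno, response, A, null_spec, n_restarts=n_restarts, compute_se=False,
        fatol=fatol, xatol=xatol, polish=polish,
    )
    ws = Workspace(pheno, response, A, null_spec)
    scanner = _FixedVCScanner(ws, null_fit.vc)
    vc_total = (
        null_fit.vc.v_a
        + null_fit.vc.v_pe
        + float(np.mean([null_fit.vc.v_res[g] for g in ws.group_labels]))
    )

    geno_pos = {v: i for i, v in enumerate(G.ids)}
    rec_ind = np.array([geno_pos[i] for i in ws.records["id"]], dtype=int)
    info_by_snp = info.set_index("snp")
    maf = G.maf()

    rows = []
    for j, snp_id in enumerate(G.snps):
        snp_rec = G.values[rec_ind, j].astype(int)
        mask = snp_rec != MISSING
        sub = ws.records if mask.all() else ws.records[mask]
        snp_vals = snp_rec if mask.all() else snp_rec[mask]
        row = {
            "snp": snp_id,
            "chrom": info_by_snp.loc[snp_id, "chrom"],
            "pos": int(info_by_snp.loc[snp_id, "pos"]),
            "maf": float(maf[j]),
            "converged": True,
        }
        for label, spec, term in (
            ("main", main_spec, "snp"),
            ("interaction", ixn_spec, "interaction"),
        ):
            try:
                if vc_mode == "per-snp":
                    fit = reml_fit(
                        sub,
                        response,
                        A,
                        spec,
                        snp=snp_vals,
                        n_restarts=n_restarts,
                        compute_se=False,
                        fatol=fatol,
                        xatol=xatol,
                        polish=polish,
                    )
                    stat, df, p = wald_test(fit, term)
                    var_fixed = float(np.var(fit.fitted_fixed))
                    tot = (
                        fit.vc.v_a
                        + fit.vc.v_pe
                        + float(np.mean(list(fit.vc.v_res.values())))
                    )
                    n_eff, p_fixed = fit.n_records, len(fit.beta) - 1
                    row["converged"] = row["converged"] and fit.vc.converged
                else:
                    X, names, blocks, _ = build_design(sub, spec, snp=snp_vals)
                    beta, cov = scanner.gls(X, None if mask.all() else mask)
                    idx = [names.index(c) for c in blocks[term]]
                    if not idx:
                        raise ValidationError(f"{term} block aliased at {snp_id}")
                    stat, df, p = _wald_block(beta, cov, np.array(idx))
                    var_fixed = float(np.var(X @ beta))
                    tot = vc_total
                    n_eff, p_fixed = X.shape[0], X.shape[1] - 1
                row[f"stat_{label}"] = stat
                row[f"df_{label}"] = df
                row[f"p_{label}"] = p
                row[f"r2adj_{label}"] = _adjusted_r2(var_fixed, tot, n_eff, p_fixed)
            except (np.linalg.LinAlgError, ValidationError):
                row["converged"] = False
                row[f"stat_{label}"] = np.nan
                row[f"df_{label}"] = 2 if label == "main" else 4
                row[f"p_{label}"] = np.nan
                row[f"r2adj_{label}"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    chrom_rank = {c: i for i, c in enumerate(pd.unique(info["chrom"]))}
    out = out.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(chrom_rank) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return out


def compare_models(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Adjusted marginal r² comparison over the significant SNP subset.

    Keeps SNPs where either the main-effect or the interaction test has
    p < alpha and reports the fraction for which the interaction model
    explains more (adjusted) fixed-effect variance.
    """
    needed = {"p_main", "p_interaction", "r2adj_main", "r2adj_interaction"}
    if not needed <= set(results.columns):
        raise ValidationError("results table lacks both scans; run both models")
    sig = results[
        (results["p_main"] < alpha) | (results["p_interaction"] < alpha)
    ].copy()
    if sig.empty:
        return sig, {
            "n_significant": 0,
            "fraction_interaction_better": np.nan,
            "note": f"no SNP significant at {alpha}",
        }
    sig["interaction_better"] = sig["r2adj_interaction"] > sig["r2adj_main"]
    summary = {
        "n_significant": int(len(sig)),
        "fraction_interaction_better": float(sig["interaction_better"].mean()),
    }
    return sig, summary


def qq_table(p_values, df: int | None = None) -> pd.DataFrame:
    """Expected vs observed -log10 p quantiles for a QQ plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_minus_log10_p": -np.log10(expected),
            "observed_minus_log10_p": -np.log10(np.clip(p, 1e-300, 1.0)),
        }
    )


def manhattan_table(results: pd.DataFrame, which: str = "interaction") -> pd.DataFrame:
    col = f"p_{which}"
    out = results[["snp", "chrom", "pos", col]].copy()
    out["minus_log10_p"] = -np.log10(np.clip(out[col], 1e-300, 1.0))
    return out.drop(columns=[col])
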