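import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxegwas.datatypes import ValidationError
from gxegwas.mixed_model import (
    AliasingError,
    ModelFit,
    ModelSpec,
    NotNestedError,
    VarianceComponents,
    Workspace,
    build_design,
    h2_by_class,
    heritability,
    lrt_component,
    lrt_pvalue,
    marginal_r2,
    reml_fit,
    wald_test,
)
from gxegwas.simulate import SimulationConfig, simulate_pedigree
from gxegwas.relatedness import a_matrix


def _fit_stub(beta, cov, blocks, vc=None, n=100, fitted=None):
    names = list(beta.keys())
    return ModelFit(
        spec=ModelSpec(),
        vc=vc
        or VarianceComponents(1.0, 1.0, {"all": 1.0}, loglik=0.0, converged=True),
        beta=pd.Series(beta),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        blocks=blocks,
        dropped=[],
        n_records=n,
        n_individuals=n,
        fitted_fixed=np.zeros(n) if fitted is None else fitted,
    )


class TestRemlOracles:
    def test_balanced_one_way_equals_anova(self):
        rng = np.random.default_rng(42)
        k, n_per = 30, 6
        sigma_u2, sigma_e2 = 4.0, 2.0
        u = rng.normal(0, np.sqrt(sigma_u2), k)
        y = np.repeat(u, n_per) + rng.normal(0, np.sqrt(sigma_e2), k * n_per)
        records = pd.DataFrame({"id": np.repeat([f"g{i}" for i in range(k)], n_per),
                                "y": y})
        spec = ModelSpec(fixed_factors=(), include_genetic=False, include_pe=True)
        fit = reml_fit(records, "y", None, spec, compute_se=False,
                       n_restarts=2, fatol=1e-14, xatol=1e-10)
        grand = y.mean()
        means = records.groupby("id")["y"].mean().to_numpy()
        ssb = n_per * ((means - grand) ** 2).sum()
        ssw = (
            records.assign(m=records.groupby("id")["y"].transform("mean"))
            .eval("(y - m) ** 2")
            .sum()
        )
        msb = ssb / (k - 1)
        msw = ssw / (k * (n_per - 1))
        anova_u = (msb - msw) / n_per
        assert fit.vc.v_res["all"] == pytest.approx(msw, abs=1e-8)
        assert fit.vc.v_pe == pytest.approx(anova_u, abs=1e-8)

    def test_two_group_gls_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        n = 30
        tclass = np.array(["cold"] * 15 + ["warm"] * 15)
        truth = {"cold": 2.0, "warm": 0.7}
        y = 5.0 + rng.normal(0, np.sqrt([truth[c] for c in tclass]))
        records = pd.DataFrame({"id": [f"i{j}" for j in range(n)],
                                "y": y, "tclass": tclass})
        spec = ModelSpec(fixed_factors=(), include_genetic=False,
                         include_pe=False, residuals="heterogeneous")
        fit = reml_fit(records, "y", None, spec, compute_se=False,
                       n_restarts=2, fatol=1e-14, xatol=1e-10)

        # independent oracle: direct restricted likelihood on a (v1, v2)
        # grid refined to 1e-3 resolution
        X = np.ones((n, 1))
        cold = tclass == "cold"

        def ll(v1, v2):
            v = np.where(cold, v1, v2)
            xvx = (1.0 / v).sum()
            beta = (y / v).sum() / xvx
            return -0.5 * (np.log(v).sum() + np.log(xvx)
                           + ((y - beta) ** 2 / v).sum())

        best, best_ll = None, -np.inf
        grid = np.arange(0.05, 6.0, 0.05)
        for v1 in grid:
            for v2 in grid:
                cur = ll(v1, v2)
                if cur > best_ll:
                    best, best_ll = (v1, v2), cur
        fine1 = np.arange(best[0] - 0.06, best[0] + 0.06, 0.001)
        fine2 = np.arange(best[1] - 0.06, best[1] + 0.06, 0.001)
        for v1 in fine1:
            for v2 in fine2:
                cur = ll(v1, v2)
                if cur > best_ll:
                    best, best_ll = (v1, v2), cur
        assert fit.vc.v_res["cold"] == pytest.approx(best[0], abs=2e-3)
        assert fit.vc.v_res["warm"] == pytest.approx(best[1], abs=2e-3)

    def test_recovers_simulated_components(self):
        from gxegwas.studies import h2_recovery

        out = h2_recovery(seed=50, n_seeds=5, n_founders=240, n_generations=2,
                          mean_records=1.5)
        assert out["truth"] == pytest.approx(0.38163, abs=1e-4)
        assert abs(out["mean_h2"] - out["truth"]) < 0.08


@pytest.fixture(scope="module")
def coding_fits(centered_pheno, small_amatrix):
    out = {}
    for coding in ("treatment", "sum"):
        spec = ModelSpec(fixed_factors=("age_class",), coding=coding)
        out[coding] = reml_fit(centered_pheno, "centered", small_amatrix,
                               spec, compute_se=False, n_restarts=1)
    return out


class TestRemlInvariances:
    def test_coding_invariant_loglik(self, coding_fits):
        assert coding_fits["treatment"].loglik == pytest.approx(
            coding_fits["sum"].loglik, abs=1e-6
        )

    def test_het_at_equal_components_equals_hom(self, centered_pheno, small_amatrix):
        hom = ModelSpec(fixed_factors=("age_class",), residuals="homogeneous")
        fit = reml_fit(centered_pheno, "centered", small_amatrix, hom,
                       compute_se=False, n_restarts=1)
        het = ModelSpec(fixed_factors=("age_class",), residuals="heterogeneous")
        ws = Workspace(centered_pheno, "centered", small_amatrix, het)
        X, *_ = build_design(ws.records, het)
        v = fit.vc.v_res["all"]
        ll_het = ws.reml_loglik(X, fit.vc.v_a, fit.vc.v_pe, [v, v, v])
        assert ll_het == pytest.approx(fit.loglik, abs=1e-6)

    def test_boundary_component_flagged(self):
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(n_founders=80, n_generations=2, n_snps=1, seed=33)
        ped = simulate_pedigree(cfg)
        females = ped.females()
        records = pd.DataFrame({
            "id": np.repeat(females, 2),
            "y": rng.normal(0, 3, 2 * len(females)),  # no genetic signal
        })
        spec = ModelSpec(fixed_factors=())
        fit = reml_fit(records, "y", a_matrix(ped), spec, n_restarts=1)
        assert "v_a" in fit.vc.boundary
        assert fit.vc.se["v_a"] is None


class TestWald:
    def test_zero_coefficients(self):
        fit = _fit_stub(
            {"intercept": 1.0, "snp[1]": 0.0, "snp[2]": 0.0},
            np.eye(3) * 0.5,
            {"snp": ["snp[1]", "snp[2]"]},
        )
        stat, df, p = wald_test(fit, "snp")
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_single_coefficient_squared_z(self):
        beta, var = 0.8, 0.04
        fit = _fit_stub(
            {"intercept": 0.0, "snp[1]": beta},
            np.diag([1.0, var]),
            {"snp": ["snp[1]"]},
        )
        stat, df, p = wald_test(fit, "snp")
        assert stat == pytest.approx(beta**2 / var)
        assert df == 1
        z_p = 2 * stats.norm.sf(abs(beta) / np.sqrt(var))
        assert p == pytest.approx(z_p, rel=1e-10)

    def test_missing_term_rejected(self):
        fit = _fit_stub({"intercept": 0.0}, np.eye(1), {})
        with pytest.raises(ValidationError):
            wald_test(fit, "snp")

    def test_aliased_block_raises(self):
        # all records in one temperature class: the interaction block is
        # aliased away entirely
        rng = np.random.default_rng(1)
        n = 60
        records = pd.DataFrame({
            "id": [f"i{j}" for j in range(n)],
            "y": rng.normal(size=n),
            "age_class": "first",
            "tclass": "cold",
        })
        snp = rng.choice([0, 1, 2], n)
        spec = ModelSpec(fixed_factors=(), snp_term=True, interaction=True,
                         include_genetic=False, include_pe=False)
        fit = reml_fit(records, "y", None, spec, snp=snp, compute_se=False)
        with pytest.raises(AliasingError):
            wald_test(fit, "interaction")

    def test_null_p_values_uniform(self):
        # correct model, known covariance structure, fresh response per
        # replicate: Wald p-values for the interaction block are uniform
        rng = np.random.default_rng(5)
        n = 240
        records = pd.DataFrame({
            "id": [f"i{j}" for j in range(n)],
            "age_class": rng.choice(["first", "older"], n),
            "tclass": rng.choice(["cold", "intermediate", "warm"], n),
            "y": np.zeros(n),
        })
        v_res = {"cold": 2.0, "intermediate": 1.0, "warm": 1.0}
        sd = np.sqrt(records["tclass"].map(v_res).to_numpy())
        spec = ModelSpec(fixed_factors=("age_class",), snp_term=True,
                         interaction=True, include_genetic=False,
                         include_pe=False, residuals="heterogeneous")
        ws = Workspace(records, "y", None, spec)
        cache = ws.cache(0.0, 0.0, [v_res[g] for g in ws.group_labels])
        pvals = []
        for _ in range(2000):
            snp = rng.choice([0, 1, 2], n, p=[0.36, 0.48, 0.16])
            y = rng.normal(0, sd)
            X, names, blocks, _ = build_design(records, spec, snp=snp)
            VinvX = ws.vinv(cache, X)
            XtViX = X.T @ VinvX
            cov = np.linalg.inv(XtViX)
            beta = cov @ (X.T @ ws.vinv(cache, y))
            fit = _fit_stub(dict(zip(names, beta)), cov, blocks)
            _, _, p = wald_test(fit, "interaction")
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        reject = np.mean(np.array(pvals) < 0.05)
        assert 0.04 <= reject <= 0.06


class TestLrt:
    def test_identical_fits(self):
        fit = _fit_stub({"intercept": 0.0}, np.eye(1), {})
        red = _fit_stub({"intercept": 0.0}, np.eye(1), {})
        red.spec = ModelSpec(include_genetic=False)
        chi2, df, p = lrt_component(fit, red)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_printed_tail_values(self):
        assert lrt_pvalue(9.39) == pytest.approx(0.002, abs=5e-4)
        assert lrt_pvalue(41.9) < 0.001
        assert lrt_pvalue(57.5) < 0.001

    def test_mixture_halves_tail(self):
        assert lrt_pvalue(3.0, mixture=True) == pytest.approx(
            0.5 * stats.chi2.sf(3.0, 1)
        )
        assert lrt_pvalue(0.0, mixture=True) == 1.0

    def test_non_nested_rejected(self):
        fit = _fit_stub({"intercept": 0.0}, np.eye(1), {})
        other = _fit_stub({"intercept": 0.0, "x": 1.0}, np.eye(2), {})
        with pytest.raises(NotNestedError):
            lrt_component(fit, other)


class TestHeritability:
    @pytest.mark.parametrize(
        "v_a,v_pe,v_res,expected",
        [
            (3.75, 8.24, 15.4, 0.14),  # cold
            (10.8, 3.00, 14.5, 0.38),  # medium
            (9.69, 2.27, 11.9, 0.41),  # warm
        ],
    )
    def test_published_columns(self, v_a, v_pe, v_res, expected):
        vc = VarianceComponents(v_a, v_pe, {"all": v_res}, 0.0, True)
        h2, _ = heritability(vc)
        assert round(h2, 2) == expected

    def test_limit_case(self):
        vc = VarianceComponents(5.0, 0.0, {"all": 0.0}, 0.0, True)
        assert heritability(vc)[0] == 1.0

    def test_zero_total_undefined(self):
        vc = VarianceComponents(0.0, 0.0, {"all": 0.0}, 0.0, True)
        with pytest.raises(ValidationError):
            heritability(vc)

    def test_delta_method_se(self):
        cov = pd.DataFrame(
            np.diag([1.0, 0.5, 0.3]),
            index=["v_a", "v_pe", "v_res[all]"],
            columns=["v_a", "v_pe", "v_res[all]"],
        )
        vc = VarianceComponents(10.0, 5.0, {"all": 5.0}, 0.0, True, cov=cov)
        h2, se = heritability(vc)
        total = 20.0
        grad = np.array([(total - 10) / total**2, -10 / total**2, -10 / total**2])
        assert se == pytest.approx(float(np.sqrt(grad @ cov.to_numpy() @ grad)))


class TestMarginalR2:
    def test_intercept_only_zero(self):
        fit = _fit_stub({"intercept": 2.0, "age_class[older]": 0.0},
                        np.eye(2), {}, n=50, fitted=np.full(50, 2.0))
        assert marginal_r2(fit, adjusted=False) == 0.0
        assert marginal_r2(fit, adjusted=True) <= 0.0

    def test_noiseless_limit(self):
        vc = VarianceComponents(1e-9, 1e-9, {"all": 1e-9}, 0.0, True)
        fitted = np.tile([0.0, 4.0], 25)
        fit = _fit_stub({"intercept": 0.0, "age_class[older]": 4.0},
                        np.eye(2), {}, vc=vc, n=50, fitted=fitted)
        assert marginal_r2(fit, adjusted=False) == pytest.approx(1.0, abs=1e-6)

    def test_known_variance_share_recovered(self):
        rng = np.random.default_rng(8)
        n = 2000
        age = rng.choice(["first", "older"], n)
        effect = 2.0  # var(fixed) = 1.0 with balanced classes
        noise_var = 3.0  # fixed share = 1 / (1 + 3) = 0.25
        y = (age == "older") * effect + rng.normal(0, np.sqrt(noise_var), n)
        records = pd.DataFrame({"id": [f"i{j}" for j in range(n)],
                                "age_class": age, "y": y})
        spec = ModelSpec(fixed_factors=("age_class",), include_genetic=False,
                         include_pe=False)
        fit = reml_fit(records, "y", None, spec, compute_se=False)
        assert marginal_r2(fit) == pytest.approx(0.25, abs=0.05)

    def test_undefined_when_overparameterized(self):
        fit = _fit_stub({"intercept": 0.0, "b": 1.0}, np.eye(2), {}, n=2)
        with pytest.raises(ValidationError):
            marginal_r2(fit)


class TestH2ByClass:
    def test_shape_and_ranges(self, centered_pheno, small_amatrix):
        table = h2_by_class(centered_pheno, small_amatrix, n_restarts=0)
        assert set(table["tclass"]) == {"cold", "intermediate", "warm"}
        assert ((table["h2"] >= 0) & (table["h2"] <= 1)).all()
        assert ((table["lrt_p"] > 0) & (table["lrt_p"] <= 1)).all()
        assert (table["v_res"] > 0).all()
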