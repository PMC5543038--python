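"""REML estimation and inference for the repeated-measures animal model.

Model per phenotype record j of individual i::

    y_ij = mu + age_i + SNP_i + class:SNP_i + pe_i + a_i + e_ij

with cov(a) = V_A * A (pedigree numerator matrix), cov(pe) = V_PE * I over
individuals, and residual variance either shared or stratified by
temperature class.

Implementation notes.  With Z the record->individual incidence matrix and
A = U diag(lam) U', the marginal covariance is

    V = W diag(V_A*lam + V_PE) W' + R,     W = Z U,   R = diag(V_res[group])

so Woodbury reduces every likelihood evaluation to one Cholesky of an
(n_individuals x n_individuals) capacitance matrix; the per-group Gram
matrices W_g' W_g are cached, which also makes residual-variance changes
cheap.  The overall scale is profiled out analytically, leaving a simplex
search over 2-4 log variance ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .datatypes import CLASS_LABELS, ValidationError
from .relatedness import RelationshipMatrix

_LOG2PI = np.log(2.0 * np.pi)


class AliasingError(ValueError):
    """Raised when a tested coefficient block is aliased out of the design."""


class NotNestedError(ValueError):
    """Raised when an LRT is requested for non-nested fits."""


# ---------------------------------------------------------------------------
# model specification and fixed-effects design


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model.

    ``fixed_factors`` are categorical record columns added as treatment- or
    sum-coded fixed effects (``"a:b"`` denotes an interaction of two
    columns).  ``snp_term`` adds a 3-level genotype factor; ``interaction``
    adds the genotype x temperature-class interaction (requires
    ``snp_term``).  ``residuals`` is ``"homogeneous"`` or
    ``"heterogeneous"`` (stratified by the ``tclass`` column).
    """

    fixed_factors: tuple[str, ...] = ("age_class",)
    snp_term: bool = False
    interaction: bool = False
    include_genetic: bool = True
    include_pe: bool = True
    residuals: str = "homogeneous"
    coding: str = "treatment"

    def __post_init__(self) -> None:
        if self.interaction and not self.snp_term:
            raise ValidationError("interaction requires the SNP term")
        if self.residuals not in ("homogeneous", "heterogeneous"):
            raise ValidationError(f"unknown residual structure {self.residuals!r}")
        if self.coding not in ("treatment", "sum"):
            raise ValidationError(f"unknown coding {self.coding!r}")


def _levels(series: pd.Series, column: str) -> list:
    vals = series.unique().tolist()
    if column == "age_class":
        return [v for v in ("first", "older") if v in vals]
    if column == "tclass":
        return [v for v in CLASS_LABELS if v in vals]
    return sorted(vals)


def _factor_columns(series, levels, prefix, coding):
    cols, names = [], []
    for lev in levels[1:]:
        if coding == "treatment":
            col = (series == lev).astype(float)
        else:  # sum coding: baseline level coded -1
            col = np.where(series == lev, 1.0, np.where(series == levels[0], -1.0, 0.0))
        cols.append(np.asarray(col, dtype=float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    snp: np.ndarray | None = None,
) -> tuple[np.ndarray, list, dict, list]:
    """Build the fixed-effects matrix.

    Returns (X, column names, term blocks as name lists, dropped aliased
    column names).  The genotype factor is coded against genotype 0 and the
    interaction against the coldest class present.
    """
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    blocks: dict[str, list] = {}
    for term in spec.fixed_factors:
        if ":" in term:
            a, b = term.split(":")
            fa = records[a].astype(str) + "|" + records[b].astype(str)
            levels = sorted(fa.unique())
            c, nm = _factor_columns(fa, levels, term, spec.coding)
        else:
            levels = _levels(records[term], term)
            c, nm = _factor_columns(records[term], levels, term, spec.coding)
        cols += c
        names += nm
        blocks[term] = nm
    if spec.snp_term:
        if snp is None:
            raise ValidationError("spec has a SNP term but no genotypes supplied")
        snp = np.asarray(snp)
        block = []
        for g in (1, 2):
            cols.append((snp == g).astype(float))
            names.append(f"snp[{g}]")
            block.append(f"snp[{g}]")
        blocks["snp"] = block
        if spec.interaction:
            classes = _levels(records["tclass"], "tclass")
            block = []
            for g in (1, 2):
                for c in classes[1:]:
                    cols.append(((snp == g) & (records["tclass"] == c)).astype(float))
                    names.append(f"snp[{g}]:tclass[{c}]")
                    block.append(f"snp[{g}]:tclass[{c}]")
            blocks["interaction"] = block
    X = np.column_stack(cols)

    # drop aliased columns by pivoted QR
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep)]
    X = X[:, keep]
    names = [names[j] for j in keep]
    blocks = {t: [c for c in b if c in set(names)] for t, b in blocks.items()}
    return X, names, blocks, dropped


# ---------------------------------------------------------------------------
# variance components and fit containers


@dataclass
class VarianceComponents:
    v_a: float
    v_pe: float
    v_res: dict  # residual-group label -> variance
    loglik: float
    converged: bool
    boundary: list = field(default_factory=list)
    se: dict | None = None  # component name -> SE (None at boundary)
    cov: pd.DataFrame | None = None  # component covariance (delta method input)

    def component_names(self) -> list:
        return ["v_a", "v_pe"] + [f"v_res[{g}]" for g in self.v_res]


@dataclass
class ModelFit:
    spec: ModelSpec
    vc: VarianceComponents
    beta: pd.Series
    cov_beta: pd.DataFrame
    blocks: dict
    dropped: list
    n_records: int
    n_individuals: int
    fitted_fixed: np.ndarray
    blups: pd.DataFrame | None = None

    @property
    def loglik(self) -> float:
        return self.vc.loglik


# ---------------------------------------------------------------------------
# marginal-covariance workspace


class Workspace:
    """Caches the covariance structure of one record table.

    Independent of the fixed-effects design, so one workspace serves a
    whole GWAS scan.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        response: str,
        A: RelationshipMatrix | None,
        spec: ModelSpec,
    ) -> None:
        self.records = records.reset_index(drop=True)
        self.response = response
        self.spec = spec
        self.y = self.records[response].to_numpy(dtype=float)
        self.n = len(self.records)

        codes, uniques = pd.factorize(self.records["id"])
        self.ind_codes = codes
        self.ind_ids = np.asarray(uniques, dtype=object)
        self.n_ind = len(uniques)

        if spec.residuals == "heterogeneous":
            if "tclass" not in self.records.columns:
                raise ValidationError(
                    "heterogeneous residuals require a tclass column"
                )
            labels = _levels(self.records["tclass"], "tclass")
            self.group_labels = list(labels)
            self.rg = (
                self.records["tclass"].map({c: i for i, c in enumerate(labels)})
                .to_numpy()
            )
        else:
            self.group_labels = ["all"]
            self.rg = np.zeros(self.n, dtype=int)
        counts = np.bincount(self.rg, minlength=len(self.group_labels))
        if (counts < 2).any():
            raise ValidationError(
                f"residual group with < 2 records: "
                f"{[g for g, c in zip(self.group_labels, counts) if c < 2]}"
            )

        self.has_random = spec.include_genetic or spec.include_pe
        if self.has_random:
            if spec.include_genetic and A is not None:
                sub = A.subset(list(self.ind_ids))
                lam, U = np.linalg.eigh(sub.values)
                self.lam = np.clip(lam, 1e-10, None)
                self.W = np.ascontiguousarray(U[self.ind_codes, :])
                self.U = U
            else:
                # A = I (or pe only): rotation is the identity
                self.lam = np.ones(self.n_ind)
                self.W = np.eye(self.n_ind)[self.ind_codes, :]
                self.U = np.eye(self.n_ind)
            self.grams = [
                self.W[self.rg == g].T @ self.W[self.rg == g]
                for g in range(len(self.group_labels))
            ]

    # -- covariance cache ---------------------------------------------------

    def cache(self, v_a: float, v_pe: float, v_res: np.ndarray) -> dict:
        v_res = np.clip(np.asarray(v_res, dtype=float), 1e-12, None)
        rinv = 1.0 / v_res[self.rg]
        out = {"v_res": v_res, "rinv": rinv}
        out["logdet"] = float(np.log(v_res[self.rg]).sum())
        if self.has_random:
            g = np.zeros(self.n_ind)
            if self.spec.include_genetic:
                g = g + v_a * self.lam
            if self.spec.include_pe:
                g = g + v_pe
            g = np.clip(g, 1e-12, None)
            C = np.diag(1.0 / g)
            for k, gram in enumerate(self.grams):
                C += gram / v_res[k]
            cho = linalg.cho_factor(C, lower=True, check_finite=False)
            out["g"] = g
            out["cho"] = cho
            out["logdet"] += float(np.log(g).sum()) + 2.0 * float(
                np.log(np.diag(cho[0])).sum()
            )
        return out

    def vinv(self, cache: dict, M: np.ndarray) -> np.ndarray:
        """V^{-1} M for a vector or matrix of columns."""
        one_d = M.ndim == 1
        if one_d:
            M = M[:, None]
        B = cache["rinv"][:, None] * M
        if self.has_random:
            T = self.W.T @ B
            S = linalg.cho_solve(cache["cho"], T, check_finite=False)
            B = B - cache["rinv"][:, None] * (self.W @ S)
        return B[:, 0] if one_d else B

    # -- restricted likelihood ---------------------------------------------

    def reml_loglik(self, X: np.ndarray, v_a, v_pe, v_res) -> float:
        """Full restricted log-likelihood (with constants) at given
        components."""
        cache = self.cache(v_a, v_pe, np.asarray(v_res, dtype=float))
        n, p = X.shape
        M = np.column_stack([X, self.y])
        VinvM = self.vinv(cache, M)
        XtViX = X.T @ VinvM[:, :p]
        XtViy = X.T @ VinvM[:, p]
        ytViy = float(self.y @ VinvM[:, p])
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        beta = np.linalg.solve(XtViX, XtViy)
        ypy = ytViy - float(XtViy @ beta)
        return -0.5 * (
            cache["logdet"] + logdet_xvx - logdet_xx + ypy + (n - p) * _LOG2PI
        )

    def reml_gradient(self, X: np.ndarray, theta: np.ndarray, names: list):
        """Analytic gradient of the restricted log-likelihood.

        ``theta``/``names`` list the active components in the order
        (v_a?, v_pe?, v_res per group).  Uses
        dll/dθ_k = -0.5 [tr(P dV_k) - y'P dV_k P y].
        """
        d = dict(zip(names, theta))
        v_res = np.array([d[f"res{g}"] for g in range(len(self.group_labels))])
        cache = self.cache(d.get("a", 0.0), d.get("pe", 0.0), v_res)
        n, p = X.shape
        Q = self.vinv(cache, X)
        u = self.vinv(cache, self.y)
        C_x = X.T @ Q
        beta = np.linalg.solve(C_x, X.T @ u)
        w = u - Q @ beta  # P y

        grad = np.zeros(len(names))
        if self.has_random:
            rinv = cache["rinv"]
            # d_i = (W C^{-1} W')_ii and M2 = W' V^{-1} W
            S = linalg.cho_solve(cache["cho"], self.W.T, check_finite=False)
            d_diag = np.einsum("ij,ji->i", self.W, S)
            T1 = sum(
                gram / v_res[g] for g, gram in enumerate(self.grams)
            )
            M2 = T1 - T1 @ linalg.cho_solve(cache["cho"], T1, check_finite=False)
            Qw = self.W.T @ Q
            Ww = self.W.T @ w
        for k, name in enumerate(names):
            if name == "a":
                tr_vinv = float(self.lam @ np.diag(M2))
                quad = float(self.lam @ (Ww**2))
                small = Qw.T * self.lam @ Qw
            elif name == "pe":
                tr_vinv = float(np.trace(M2))
                quad = float(Ww @ Ww)
                small = Qw.T @ Qw
            else:
                g = int(name[3:])
                rows = self.rg == g
                quad = float(w[rows] @ w[rows])
                if self.has_random:
                    tr_vinv = float(
                        rinv[rows].sum() - (rinv[rows] ** 2 * d_diag[rows]).sum()
                    )
                else:
                    tr_vinv = float(cache["rinv"][rows].sum())
                Qg = Q[rows]
                small = Qg.T @ Qg
            tr_p = tr_vinv - float(np.trace(np.linalg.solve(C_x, small)))
            grad[k] = -0.5 * (tr_p - quad)
        return grad

    def _profiled(self, X: np.ndarray, ratios: dict) -> tuple[float, float]:
        """Profiled REML: returns (loglik, sigma2hat) at unit-scale ratios."""
        v_res0 = np.array([ratios["res"][g] for g in range(len(self.group_labels))])
        cache = self.cache(ratios.get("a", 0.0), ratios.get("pe", 0.0), v_res0)
        n, p = X.shape
        M = np.column_stack([X, self.y])
        VinvM = self.vinv(cache, M)
        XtViX = X.T @ VinvM[:, :p]
        XtViy = X.T @ VinvM[:, p]
        ytViy = float(self.y @ VinvM[:, p])
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, np.nan
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        beta = np.linalg.solve(XtViX, XtViy)
        ypy = ytViy - float(XtViy @ beta)
        if ypy <= 0:
            return -np.inf, np.nan
        sigma2 = ypy / (n - p)
        ll = -0.5 * (
            cache["logdet"]
            + logdet_xvx
            - logdet_xx
            + (n - p) * (np.log(sigma2) + 1.0 + _LOG2PI)
        )
        return ll, sigma2


# ---------------------------------------------------------------------------
# REML fitting


def _free_param_names(spec: ModelSpec, n_groups: int) -> list:
    names = []
    if spec.include_genetic:
        names.append("a")
    if spec.include_pe:
        names.append("pe")
    names += [f"res{g}" for g in range(1, n_groups)]
    return names


def _ratios_from_x(x: np.ndarray, names: list, n_groups: int) -> dict:
    x = np.clip(x, -30.0, 30.0)
    vals = dict(zip(names, np.exp(x)))
    res = {0: 1.0}
    for g in range(1, n_groups):
        res[g] = vals.pop(f"res{g}")
    vals["res"] = res
    return vals


def reml_fit(
    records: pd.DataFrame,
    response: str,
    A: RelationshipMatrix | None,
    spec: ModelSpec,
    snp: np.ndarray | None = None,
    n_restarts: int = 2,
    compute_se: bool = True,
    compute_blups: bool = False,
    max_iter: int = 4000,
    fatol: float = 1e-10,
    xatol: float = 1e-7,
    polish: bool = True,
) -> ModelFit:
    """Restricted maximum likelihood for the animal model.

    The overall variance scale is profiled out; a Nelder-Mead simplex over
    the remaining log variance ratios is run from a default start and
    ``n_restarts`` deterministic perturbations of the best point.
    """
    ws = Workspace(records, response, A, spec)
    X, names, blocks, dropped = build_design(ws.records, spec, snp=snp)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"{n} records cannot identify {p} fixed effects")

    free = _free_param_names(spec, len(ws.group_labels))
    converged = True
    if free:
        def objective(x):
            ll, _ = ws._profiled(X, _ratios_from_x(x, free, len(ws.group_labels)))
            return -ll

        x0 = np.array([np.log(0.5) if nm in ("a", "pe") else 0.0 for nm in free])
        best = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"fatol": fatol, "xatol": xatol, "maxiter": max_iter},
        )
        rng = np.random.default_rng(2024)
        for _ in range(n_restarts):
            trial = optimize.minimize(
                objective,
                best.x + rng.normal(0.0, 0.4, size=len(free)),
                method="Nelder-Mead",
                options={"fatol": fatol, "xatol": xatol, "maxiter": max_iter},
            )
            if trial.fun < best.fun - 1e-12:
                best = trial
        if polish:
            # derivative-free pass: Powell line searches tighten the
            # optimum beyond the simplex's resolution
            refined = optimize.minimize(
                objective,
                best.x,
                method="Powell",
                options={"xtol": 1e-12, "ftol": 1e-15, "maxiter": max_iter},
            )
            if refined.fun <= best.fun:
                best = refined
        converged = bool(best.success or best.fun < np.inf)
        ratios = _ratios_from_x(best.x, free, len(ws.group_labels))
    else:
        ratios = {"res": {0: 1.0}}
    ll, sigma2 = ws._profiled(X, ratios)

    v_a = sigma2 * ratios.get("a", 0.0) if spec.include_genetic else 0.0
    v_pe = sigma2 * ratios.get("pe", 0.0) if spec.include_pe else 0.0
    v_res_arr = np.array(
        [sigma2 * ratios["res"][g] for g in range(len(ws.group_labels))]
    )
    if polish and free:
        v_a, v_pe, v_res_arr, ll = _newton_polish(
            ws, X, spec, v_a, v_pe, v_res_arr, ll
        )
    v_res = dict(zip(ws.group_labels, v_res_arr))

    total = v_a + v_pe + float(v_res_arr.mean())
    boundary = []
    if spec.include_genetic and v_a < 1e-6 * total:
        boundary.append("v_a")
    if spec.include_pe and v_pe < 1e-6 * total:
        boundary.append("v_pe")
    vc = VarianceComponents(
        v_a=float(v_a),
        v_pe=float(v_pe),
        v_res=v_res,
        loglik=float(ll),
        converged=converged,
        boundary=boundary,
    )

    cache = ws.cache(v_a, v_pe, v_res_arr)
    VinvX = ws.vinv(cache, X)
    XtViX = X.T @ VinvX
    XtViy = X.T @ ws.vinv(cache, ws.y)
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ XtViy

    if compute_se:
        _attach_component_se(ws, X, vc)

    blups = None
    if compute_blups and ws.has_random:
        resid = ws.y - X @ beta
        t = ws.W.T @ ws.vinv(cache, resid)
        a_hat = ws.U @ (v_a * ws.lam * t) if spec.include_genetic else np.zeros(ws.n_ind)
        pe_hat = ws.U @ (v_pe * t) if spec.include_pe else np.zeros(ws.n_ind)
        blups = pd.DataFrame({"id": ws.ind_ids, "a_hat": a_hat, "pe_hat": pe_hat})

    return ModelFit(
        spec=spec,
        vc=vc,
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov_beta, index=names, columns=names),
        blocks=blocks,
        dropped=dropped,
        n_records=n,
        n_individuals=ws.n_ind,
        fitted_fixed=X @ beta,
        blups=blups,
    )


def _newton_polish(ws, X, spec, v_a, v_pe, v_res_arr, ll):
    """Refine interior REML optima to machine precision.

    Newton iterations in log-component space using the analytic gradient
    (Hessian by central differences of the gradient).  Skipped when any
    component sits near the zero boundary, where the stationarity
    condition does not hold.
    """
    names = []
    theta = []
    if spec.include_genetic:
        names.append("a")
        theta.append(v_a)
    if spec.include_pe:
        names.append("pe")
        theta.append(v_pe)
    for g in range(len(ws.group_labels)):
        names.append(f"res{g}")
        theta.append(v_res_arr[g])
    theta = np.array(theta)
    total = v_a + v_pe + float(v_res_arr.mean())
    if (theta < 1e-7 * total).any() or total <= 0:
        return v_a, v_pe, v_res_arr, ll

    def unpack(t):
        d = dict(zip(names, t))
        return (
            d.get("a", 0.0),
            d.get("pe", 0.0),
            np.array([d[f"res{g}"] for g in range(len(ws.group_labels))]),
        )

    x = np.log(theta)
    cur_ll = ll
    for _ in range(6):
        t = np.exp(x)
        grad = ws.reml_gradient(X, t, names) * t  # chain rule to log scale
        if np.max(np.abs(grad)) < 1e-9:
            break
        h = 1e-5
        H = np.zeros((len(x), len(x)))
        for k in range(len(x)):
            e = np.zeros(len(x))
            e[k] = h
            gp = ws.reml_gradient(X, np.exp(x + e), names) * np.exp(x + e)
            gm = ws.reml_gradient(X, np.exp(x - e), names) * np.exp(x - e)
            H[:, k] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(-step, -1.0, 1.0)
        # backtracking on the restricted likelihood; near the optimum the
        # likelihood change sits below fp noise, so ties are accepted and
        # progress is judged by the gradient norm at the next iteration
        improved = False
        for scale in (1.0, 0.5, 0.25):
            cand = x + scale * step
            cand_ll = ws.reml_loglik(X, *unpack(np.exp(cand)))
            if cand_ll >= cur_ll - 1e-10:
                x, cur_ll = cand, max(cand_ll, cur_ll)
                improved = True
                break
        if not improved:
            break
    v_a2, v_pe2, v_res2 = unpack(np.exp(x))
    return v_a2, v_pe2, v_res2, float(ws.reml_loglik(X, v_a2, v_pe2, v_res2))


def _attach_component_se(ws: Workspace, X: np.ndarray, vc: VarianceComponents) -> None:
    """Numerical observed-information SEs for the variance components."""
    names = []
    theta = []
    if ws.spec.include_genetic:
        names.append("v_a")
        theta.append(vc.v_a)
    if ws.spec.include_pe:
        names.append("v_pe")
        theta.append(vc.v_pe)
    for g in vc.v_res:
        names.append(f"v_res[{g}]")
        theta.append(vc.v_res[g])
    theta = np.array(theta)

    def ll_at(t):
        d = dict(zip(names, t))
        v_res = np.array([d[f"v_res[{g}]"] for g in ws.group_labels])
        return ws.reml_loglik(X, d.get("v_a", 0.0), d.get("v_pe", 0.0), v_res)

    k = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1e-2)
    H = np.zeros((k, k))
    f0 = ll_at(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = ll_at(theta + ei)
                fmm = ll_at(theta - ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
            else:
                fpp = ll_at(theta + ei + ej)
                fpm = ll_at(theta + ei - ej)
                fmp = ll_at(theta - ei + ej)
                fmm = ll_at(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vc.se = {nm: None for nm in names}
        return
    se = {}
    for i, nm in enumerate(names):
        at_boundary = nm in vc.boundary
        var = cov[i, i]
        se[nm] = None if (at_boundary or var <= 0) else float(np.sqrt(var))
    vc.se = se
    vc.cov = pd.DataFrame(cov, index=names, columns=names)


# ---------------------------------------------------------------------------
# inference


def wald_test(fit: ModelFit, term: str) -> tuple[float, int, float]:
    """Wald chi-square for a whole coefficient block (``"snp"`` or
    ``"interaction"``)."""
    if term not in fit.blocks:
        raise ValidationError(f"term {term!r} not in the fitted model")
    cols = fit.blocks[term]
    aliased = [c for c in fit.dropped if c.startswith(("snp[", "tclass[")) or c in cols]
    missing = [c for c in cols if c not in fit.beta.index]
    if missing:
        raise AliasingError(f"aliased levels in {term!r} block: {missing + aliased}")
    if not cols:
        raise AliasingError(f"entire {term!r} block aliased: {aliased}")
    b = fit.beta[cols].to_numpy()
    S = fit.cov_beta.loc[cols, cols].to_numpy()
    stat = float(b @ np.linalg.solve(S, b))
    df = len(cols)
    return stat, df, float(stats.chi2.sf(stat, df))


def lrt_component(
    fit_full: ModelFit, fit_reduced: ModelFit, mixture: bool = False
) -> tuple[float, int, float]:
    """Likelihood-ratio test for one variance component (1 df).

    By default the plain chi-square(1) tail is reported; ``mixture=True``
    uses the 50:50 boundary mixture instead.
    """
    if list(fit_full.beta.index) != list(fit_reduced.beta.index):
        raise NotNestedError("fits have different fixed-effects designs")
    n_full = 2 * int(fit_full.spec.include_genetic) + 2 * int(fit_full.spec.include_pe)
    n_red = 2 * int(fit_reduced.spec.include_genetic) + 2 * int(
        fit_reduced.spec.include_pe
    )
    if n_red >= n_full:
        raise NotNestedError("reduced model must drop one variance component")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = lrt_pvalue(chi2, mixture=mixture)
    return chi2, 1, p


def lrt_pvalue(chi2: float, mixture: bool = False) -> float:
    """Upper-tail p for a 1-df variance-component LRT statistic."""
    if chi2 < 0:
        raise ValidationError("chi-square statistic must be >= 0")
    plain = float(stats.chi2.sf(chi2, 1))
    if not mixture:
        return plain
    return 1.0 if chi2 == 0 else 0.5 * plain


def heritability(
    vc: VarianceComponents, group: str = "all"
) -> tuple[float, float | None]:
    """h² = V_A / (V_A + V_PE + V_res[group]) with a delta-method SE."""
    if group not in vc.v_res:
        raise ValidationError(f"unknown residual group {group!r}")
    total = vc.v_a + vc.v_pe + vc.v_res[group]
    if total <= 0:
        raise ValidationError("total variance is zero; h2 undefined")
    h2 = vc.v_a / total
    se = None
    if vc.cov is not None:
        comps = ["v_a", "v_pe", f"v_res[{group}]"]
        if all(c in vc.cov.index for c in comps):
            grad = np.array(
                [(total - vc.v_a) / total**2, -vc.v_a / total**2, -vc.v_a / total**2]
            )
            cov = vc.cov.loc[comps, comps].to_numpy()
            var = float(grad @ cov @ grad)
            se = float(np.sqrt(var)) if var > 0 else None
    return float(h2), se


def marginal_r2(fit: ModelFit, adjusted: bool = True) -> float:
    """Variance explained by the fixed effects alone.

    r2_m = var(X beta) / (var(X beta) + V_A + V_PE + mean V_res); the
    adjusted version applies the classical Wherry correction with p = the
    number of non-intercept fixed-effect columns.
    """
    var_fixed = float(np.var(fit.fitted_fixed))
    mean_res = float(np.mean(list(fit.vc.v_res.values())))
    r2 = var_fixed / (var_fixed + fit.vc.v_a + fit.vc.v_pe + mean_res)
    if not adjusted:
        return r2
    n = fit.n_records
    p = len(fit.beta) - 1
    if n <= p + 1:
        raise ValidationError("adjusted r2 undefined: n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# per-class quantitative-genetic table


def h2_by_class(
    pheno: pd.DataFrame,
    A: RelationshipMatrix,
    fixed_factors: tuple[str, ...] = ("age_class", "year", "area", "year:area"),
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Per-temperature-class animal models on raw laying dates.

    Fits each class subset separately with age, year, area and year x area
    fixed effects, and reports variance components, h² and the 1-df LRT
    for the additive genetic variance.
    """
    rows = []
    for tclass in CLASS_LABELS:
        sub = pheno[pheno["tclass"] == tclass]
        if sub.empty:
            continue
        factors = tuple(
            f
            for f in fixed_factors
            if all(sub[c.strip()].nunique() > 1 for c in f.split(":"))
        )
        spec = ModelSpec(fixed_factors=factors, residuals="homogeneous")
        fit = reml_fit(
            sub, "laying_date", A, spec, n_restarts=n_restarts, compute_se=True
        )
        spec_red = ModelSpec(
            fixed_factors=factors, residuals="homogeneous", include_genetic=False
        )
        fit_red = reml_fit(
            sub, "laying_date", A, spec_red, n_restarts=n_restarts, compute_se=False
        )
        chi2, _, p = lrt_component(fit, fit_red)
        h2, h2_se = heritability(fit.vc)
        se = fit.vc.se or {}
        rows.append(
            {
                "tclass": tclass,
                "v_a": fit.vc.v_a,
                "v_a_se": se.get("v_a"),
                "v_pe": fit.vc.v_pe,
                "v_pe_se": se.get("v_pe"),
                "v_res": fit.vc.v_res["all"],
                "v_res_se": se.get("v_res[all]"),
                "h2": h2,
                "h2_se": h2_se,
                "lrt_chi2": chi2,
                "lrt_p": p,
                "n_obs": fit.n_records,
                "n_ind": fit.n_individuals,
            }
        )
    return pd.DataFrame(rows)
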