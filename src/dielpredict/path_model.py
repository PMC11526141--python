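"""Recursive path analysis with normal-theory ML and CFI/RMSEA fit indices.

A path model here is a recursive (acyclic) system of linear regressions
among observed, standardized species-level variables — environmental
fluctuation amplitudes, predictability indices, thermal safety margins and
ΔLT50 — plus free covariances among designated (typically exogenous)
variables. The model-implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T

with B the path-coefficient matrix and Psi the (co)variance matrix of
exogenous variables and residuals. Parameters minimize the normal-theory
discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p against the sample
covariance S; chi2 = (n - 1) F at the optimum. For recursive models the
point estimates coincide with per-equation least squares on standardized
data, which also supplies the optimizer's starting point.

Model specifications use a small lavaan-style grammar, one statement per
line: ``y ~ x1 + x2`` (regression) and ``a ~~ b`` (free covariance).

A d-separation test (Fisher's C over the model's basis set of implied
conditional independencies) is available as a secondary ranking criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools import numdiff


@dataclass
class PathModelSpec:
    """Regressions (response <- predictors) and free covariance pairs."""

    variables: list
    regressions: list       # (response, [predictors])
    covariances: list       # (a, b) unordered pairs

    @classmethod
    def from_string(cls, text: str) -> "PathModelSpec":
        regressions, covariances, variables = [], [], []

        def seen(v):
            if v not in variables:
                variables.append(v)

        for raw in text.splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "~~" in line:
                lhs, rhs = (s.strip() for s in line.split("~~"))
                seen(lhs), seen(rhs)
                covariances.append((lhs, rhs))
            elif "~" in line:
                lhs, rhs = (s.strip() for s in line.split("~", 1))
                preds = [p.strip() for p in rhs.split("+") if p.strip()]
                seen(lhs)
                for p in preds:
                    seen(p)
                regressions.append((lhs, preds))
            else:
                raise ValueError(f"cannot parse model line: {raw!r}")
        spec = cls(variables=variables, regressions=regressions, covariances=covariances)
        spec.validate()
        return spec

    def validate(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("the regression graph must be acyclic (recursive model)")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for resp, preds in self.regressions:
            for p in preds:
                g.add_edge(p, resp)
        return g

    @property
    def endogenous(self) -> list:
        return [resp for resp, _ in self.regressions]

    @property
    def exogenous(self) -> list:
        return [v for v in self.variables if v not in self.endogenous]

    @classmethod
    def saturated(cls, variables: list) -> "PathModelSpec":
        """All paths in a fixed order plus all exogenous covariances: dof = 0."""
        regs = [(v, list(variables[:i])) for i, v in enumerate(variables) if i > 0]
        return cls(variables=list(variables), regressions=regs, covariances=[])


@dataclass
class PathFit:
    spec: PathModelSpec
    coefficients: dict       # (response, predictor) -> (estimate, se, p)
    covariances: dict        # (a, b) -> estimate
    variances: dict          # variable -> residual (endogenous) or total (exogenous)
    chi2: float
    dof: int
    chi2_null: float
    dof_null: int
    n: int
    loglik: float
    converged: bool
    cfi: float | None = None
    rmsea: float | None = None
    notes: list = field(default_factory=list)


def standardize_table(records, variables: list) -> pd.DataFrame:
    """Columns centred to mean 0 and scaled to sample sd 1 (n-1 denominator)."""
    if isinstance(records, pd.DataFrame):
        df = records[variables].copy()
    else:
        from .thermal_tolerance import records_frame
        df = records_frame(records)[variables].copy()
    if df.isna().any().any():
        raise ValueError("missing values in the species table")
    if len(df) < len(variables) + 1:
        raise ValueError(f"need at least {len(variables) + 1} records for {len(variables)} variables")
    for c in variables:
        sd = df[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column: {c!r}")
        df[c] = (df[c] - df[c].mean()) / sd
    return df


def _parameter_layout(spec: PathModelSpec):
    """Free parameters: path coefficients, then variances, then covariances."""
    coef_idx = [(resp, p) for resp, preds in spec.regressions for p in preds]
    var_idx = list(spec.variables)
    cov_idx = list(spec.covariances)
    return coef_idx, var_idx, cov_idx


def _implied_cov(theta, spec: PathModelSpec, vindex: dict):
    coef_idx, var_idx, cov_idx = _parameter_layout(spec)
    p = len(spec.variables)
    B = np.zeros((p, p))
    Psi = np.zeros((p, p))
    k = 0
    for resp, pred in coef_idx:
        B[vindex[resp], vindex[pred]] = theta[k]
        k += 1
    for v in var_idx:
        Psi[vindex[v], vindex[v]] = theta[k]
        k += 1
    for a, b in cov_idx:
        Psi[vindex[a], vindex[b]] = Psi[vindex[b], vindex[a]] = theta[k]
        k += 1
    ImB_inv = np.linalg.inv(np.eye(p) - B)
    return ImB_inv @ Psi @ ImB_inv.T


def _fml(theta, spec, vindex, S, logdet_S):
    Sigma = _implied_cov(theta, spec, vindex)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e10
    try:
        SigInv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        return 1e10
    return logdet + float(np.trace(S @ SigInv)) - logdet_S - len(vindex)


def fit_path_model(spec: PathModelSpec, table: pd.DataFrame) -> PathFit:
    """Normal-theory ML fit of the path model to the sample covariance.

    ``table`` rows are observations (species); columns must cover
    ``spec.variables`` and should be standardized for standardized path
    coefficients. Standard errors come from the inverse expected information
    ((n-1)/2 times the Hessian of the discrepancy) at the optimum.
    """
    spec.validate()
    missing = [v for v in spec.variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables missing from the data: {missing}")
    X = table[spec.variables].to_numpy(float)
    n, p = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("singular sample covariance matrix")
    vindex = {v: i for i, v in enumerate(spec.variables)}
    coef_idx, var_idx, cov_idx = _parameter_layout(spec)
    n_free = len(coef_idx) + len(var_idx) + len(cov_idx)
    dof = p * (p + 1) // 2 - n_free
    if dof < 0:
        raise ValueError(f"model has more free parameters ({n_free}) than moments")

    # start from per-equation OLS (the exact ML solution for recursive models
    # with a saturated exogenous block)
    theta0 = []
    resid_var = {}
    for resp, preds in spec.regressions:
        yi = X[:, vindex[resp]]
        yi = yi - yi.mean()
        Xi = X[:, [vindex[q] for q in preds]]
        Xi = Xi - Xi.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        theta0.extend(beta)
        resid = yi - Xi @ beta
        resid_var[resp] = float(resid @ resid) / (n - 1)
    for v in var_idx:
        theta0.append(resid_var.get(v, float(S[vindex[v], vindex[v]])))
    for a, b in cov_idx:
        theta0.append(float(S[vindex[a], vindex[b]]))
    theta0 = np.asarray(theta0, float)

    res = optimize.minimize(_fml, theta0, args=(spec, vindex, S, logdet_S),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 200 * max(1, n_free),
                                     "maxfev": 200 * max(1, n_free)})
    # polish with BFGS from the simplex optimum
    res2 = optimize.minimize(_fml, res.x, args=(spec, vindex, S, logdet_S), method="BFGS",
                             options={"gtol": 1e-10, "maxiter": 500})
    theta = res2.x if res2.fun <= res.fun else res.x
    fmin = min(res.fun, res2.fun)
    converged = bool((res.success or res2.success) and fmin < 1e9)

    chi2_stat = max((n - 1) * fmin, 0.0)
    # independence (null) baseline: diagonal Sigma
    F_null = float(np.sum(np.log(np.diag(S)))) - logdet_S
    chi2_null = max((n - 1) * F_null, 0.0)
    dof_null = p * (p - 1) // 2

    ses = np.full(n_free, np.nan)
    if converged and n_free > 0:
        H = numdiff.approx_hess(theta, _fml, args=(spec, vindex, S, logdet_S))
        info = (n - 1) / 2.0 * H
        try:
            cov_theta = np.linalg.inv(info)
            d = np.diag(cov_theta)
            ses = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    coefficients = {}
    for k, key in enumerate(coef_idx):
        est, se = float(theta[k]), float(ses[k])
        pval = 2 * stats.norm.sf(abs(est / se)) if np.isfinite(se) and se > 0 else np.nan
        coefficients[key] = (est, se, pval)
    variances = {v: float(theta[len(coef_idx) + i]) for i, v in enumerate(var_idx)}
    covariances = {pair: float(theta[len(coef_idx) + len(var_idx) + i])
                   for i, pair in enumerate(cov_idx)}

    # Gaussian log-likelihood at the optimum (additive constant included)
    Sigma = _implied_cov(theta, spec, vindex)
    sign, logdet = np.linalg.slogdet(Sigma)
    ll = -0.5 * n * (p * np.log(2 * np.pi) + logdet
                     + float(np.trace(S @ np.linalg.inv(Sigma))) * (n - 1) / n)

    fit = PathFit(spec=spec, coefficients=coefficients, covariances=covariances,
                  variances=variances, chi2=float(chi2_stat), dof=int(dof),
                  chi2_null=float(chi2_null), dof_null=int(dof_null), n=n,
                  loglik=float(ll), converged=converged)
    return fit_indices(fit, n)


def fit_indices(fit: PathFit, n: int) -> PathFit:
    """Complete a fit with CFI and RMSEA.

    CFI compares the excess chi-square over dof with the independence
    baseline; RMSEA is the per-dof misfit rate sqrt(max(chi2-dof,0)/(dof(n-1))).
    A saturated model (dof = 0) gets RMSEA 0 with a note.
    """
    excess = max(fit.chi2 - fit.dof, 0.0)
    excess_null = max(fit.chi2_null - fit.dof_null, 0.0)
    denom = max(excess_null, excess)
    fit.cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    if fit.dof == 0:
        fit.rmsea = 0.0
        fit.notes.append("dof = 0 (saturated): RMSEA undefined, reported as 0")
    else:
        fit.rmsea = float(np.sqrt(excess / (fit.dof * (n - 1))))
    return fit


def fishers_c(spec: PathModelSpec, table: pd.DataFrame):
    """d-separation test: Fisher's C over the model's basis set.

    For each non-adjacent variable pair (no directed edge, no free
    covariance) the claimed conditional independence given both variables'
    parents is tested by the partial regression coefficient's t-test;
    C = -2 sum(ln p_i) is chi-square with 2k dof under the model.
    Returns (C, dof, p_value, claims) where claims lists
    (response, other, conditioning set, p).
    """
    g = spec.graph()
    order = list(nx.topological_sort(g))
    linked = {frozenset(e) for e in g.edges} | {frozenset(c) for c in spec.covariances}
    claims = []
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if frozenset((u, v)) in linked:
                continue
            cond = sorted((set(g.predecessors(v)) | set(g.predecessors(u))) - {u, v})
            X = sm.add_constant(table[[u] + cond]) if cond else sm.add_constant(table[[u]])
            pval = float(sm.OLS(table[v], X).fit().pvalues[u])
            claims.append((v, u, tuple(cond), pval))
    if not claims:
        return 0.0, 0, 1.0, []
    C = -2.0 * sum(np.log(max(p, 1e-300)) for *_, p in claims)
    dof = 2 * len(claims)
    return float(C), dof, float(stats.chi2.sf(C, dof)), claims


def compare_models(fits: list) -> list:
    """Rank fits by CFI (descending), then RMSEA (ascending); stable on ties."""
    if not fits:
        raise ValueError("no fits to compare")
    return sorted(fits, key=lambda f: (-(f.cfi if f.cfi is not None else -np.inf),
                                       f.rmsea if f.rmsea is not None else np.inf))
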