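"""Variance-component estimation and testing for inbred-line expression data.

The observational unit is a replicate measurement of one line in one
environment.  Three models are fitted per gene:

* single environment:  y = Xb + line + e        -> (sigma2_G, sigma2_e)
* combined:            y = Xb + line + line:env + e
                                                -> (sigma2_G, sigma2_GE, sigma2_e)
* heterogeneity:       per-environment line and residual variances, with a
  likelihood-ratio test of whether one component (G or e) is shared across
  the two environments.

For balanced designs (every line measured the same number of times in
every environment, covariates constant within line) the restricted
likelihood factorizes over orthogonal strata, so REML is available in
closed form (with ordered pooling at the non-negativity boundary) and
thousands of genes are fitted from their sums of squares alone.  An
iterative dense REML path covers unbalanced data.

Boundary tests of a single variance component use the 1/2 chi2_0 + 1/2
chi2_1 mixture null; when the LRT statistic is exactly 0 the reported p
is 1.  The heterogeneity parameter is interior under the null, so that
test uses a plain chi2 with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.multitest import multipletests

_EPS = 1e-12


# ------------------------------------------------------------------ utilities

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def gxe_index(sigma2_G: float, sigma2_GE: float) -> float:
    """Proportion of total genetic variance due to G-by-E interaction.

    Returns NaN when both components are zero (index undefined).
    """
    if sigma2_G < 0 or sigma2_GE < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_G + sigma2_GE
    if tot <= 0:
        return float("nan")
    return sigma2_GE / tot


def _mixture_boundary_p(lrt) -> np.ndarray:
    """p-value under the 1/2 chi2_0 + 1/2 chi2_1 boundary mixture."""
    lrt = np.asarray(lrt, dtype=float)
    p = np.where(lrt <= 0, 1.0, 0.5 * special.chdtrc(1, np.maximum(lrt, 0.0)))
    return p


def _residual_projector(X: np.ndarray) -> np.ndarray:
    """I - X(X'X)^-1 X' for a full-column-rank design."""
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


def _strata_ll(ss, df, lam):
    """Restricted log-likelihood (up to constant) of independent strata."""
    lam = np.maximum(lam, _EPS)
    return -0.5 * np.sum(df * np.log(lam) + ss / lam, axis=-1)


# -------------------------------------------------- balanced design detection

def _line_level_design(meta: pd.DataFrame, covariates: list) -> tuple:
    """Per-line covariate values; raises if a covariate varies within line."""
    lines = meta["line"].unique()
    if covariates:
        tab = meta.groupby("line")[covariates].nunique()
        if (tab > 1).any().any():
            raise ValueError("covariates must be constant within line for the balanced path")
        vals = meta.groupby("line")[covariates].first().loc[lines].to_numpy(dtype=float)
        X_line = np.column_stack([np.ones(len(lines)), vals])
    else:
        X_line = np.ones((len(lines), 1))
    return lines, X_line


# ------------------------------------------------------- single-env fitting

@dataclass
class SingleEnvStrata:
    """Sufficient statistics of the balanced one-way layout, per gene."""

    ss_within: np.ndarray
    df_within: int
    ss_between: np.ndarray
    df_between: int
    n_rep: int
    n_lines: int


def single_env_strata(expr: np.ndarray, meta: pd.DataFrame, covariates=None) -> SingleEnvStrata:
    """Sums of squares of the balanced one-way (line) layout.

    ``expr`` is genes x samples aligned with ``meta`` rows.
    """
    covariates = list(covariates or [])
    counts = meta.groupby("line").size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design; use fit_single_env per gene instead")
    r = int(counts.iloc[0])
    lines, X_line = _line_level_design(meta, covariates)
    L, p = X_line.shape
    if r < 2:
        raise ValueError("sigma2_e inestimable: no within-line replication")
    if L - p < 1:
        raise ValueError("too few lines for the between-line stratum")
    # line means via group indicator
    codes = np.asarray(pd.Categorical(meta["line"], categories=lines).codes, dtype=np.int64)
    A = np.zeros((L, len(meta)))
    A[codes, np.arange(len(meta))] = 1.0 / r
    M = expr @ A.T  # genes x lines
    ss_w = (expr**2).sum(axis=1) - r * (M**2).sum(axis=1)
    P = _residual_projector(X_line)
    R = M @ P
    ss_b = r * (R**2).sum(axis=1)
    return SingleEnvStrata(np.maximum(ss_w, 0.0), L * (r - 1), np.maximum(ss_b, 0.0), L - p, r, L)


def _single_env_estimates(st: SingleEnvStrata) -> tuple:
    """ANOVA/REML point estimates and the boundary-mixture LRT, vectorized.

    Reported estimates follow the classical convention sigma2_e =
    MS_within and sigma2_G = max(0, (MS_between - MS_within)/r); the LRT
    compares restricted likelihoods maximized under non-negativity.
    """
    ms_w = st.ss_within / st.df_within
    ms_b = st.ss_between / st.df_between
    s2e = ms_w
    s2g = np.maximum(0.0, (ms_b - ms_w) / st.n_rep)
    df_tot = st.df_within + st.df_between
    ms_pool = (st.ss_within + st.ss_between) / df_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = np.where(
            ms_b > ms_w,
            df_tot * np.log(ms_pool) - st.df_within * np.log(ms_w) - st.df_between * np.log(ms_b),
            0.0,
        )
    # degenerate strata: zero within-variance with real between-line spread
    lrt = np.where((ms_w <= _EPS) & (ms_b > _EPS), np.inf, lrt)
    lrt = np.where((ms_w <= _EPS) & (ms_b <= _EPS), 0.0, lrt)
    lrt = np.maximum(np.nan_to_num(lrt, nan=0.0, posinf=np.inf), 0.0)
    return s2g, s2e, lrt, _mixture_boundary_p(lrt)


@dataclass
class VarCompSingleEnv:
    gene: str
    environment: str
    sigma2_G: float
    sigma2_e: float
    lrt: float
    pvalue: float


def fit_single_env(values, lines, covariates=None, gene="gene", environment="env") -> VarCompSingleEnv:
    """Fit y = Xb + line + e for one gene in one environment.

    ``values`` are replicate-level measurements, ``lines`` the matching
    line labels; ``covariates`` an optional (n x p) array of line-constant
    fixed effects (an intercept is always included).
    """
    y = np.asarray(values, dtype=float)
    lab = pd.Series(lines).astype(str)
    counts = lab.value_counts()
    if (counts == 1).all():
        raise ValueError("sigma2_e inestimable: every line has a single replicate")
    if counts.nunique() == 1 and counts.iloc[0] >= 2:
        meta = pd.DataFrame({"line": lab.values})
        covs = []
        if covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != len(y):
                C = C.T
            for j in range(C.shape[1]):
                meta[f"cov{j}"] = C[:, j]
                covs.append(f"cov{j}")
        st = single_env_strata(y[None, :], meta, covs)
        s2g, s2e, lrt, p = _single_env_estimates(st)
        return VarCompSingleEnv(gene, environment, float(s2g[0]), float(s2e[0]), float(lrt[0]), float(p[0]))
    # unbalanced: iterative REML on the variance ratio
    X = np.ones((len(y), 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        X = np.column_stack([X, C])
    s2g, s2e, ll1, ll0 = _reml_oneway_unbalanced(y, X, lab.values)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    return VarCompSingleEnv(gene, environment, s2g, s2e, lrt, float(_mixture_boundary_p(lrt)))


def _reml_oneway_unbalanced(y, X, line_labels):
    """Profile REML for y = Xb + line + e with arbitrary line sizes."""
    codes, _ = pd.factorize(line_labels)
    n_i = np.bincount(codes).astype(float)
    n, p = X.shape

    def neg_restricted_ll(gamma):
        # V0 = I + gamma * Z Z'; per-line Woodbury
        w = gamma / (1.0 + gamma * n_i)  # per-line correction weight
        def v0_solve(M):
            M = np.atleast_2d(M.T).T
            line_sums = np.zeros((len(n_i), M.shape[1]))
            np.add.at(line_sums, codes, M)
            return M - w[codes][:, None] * line_sums[codes]
        XtViX = X.T @ v0_solve(X)
        XtViy = X.T @ v0_solve(y[:, None])
        beta = np.linalg.solve(XtViX, XtViy).ravel()
        r = y - X @ beta
        quad = float(r @ v0_solve(r[:, None]).ravel())
        logdet_v0 = float(np.sum(np.log1p(gamma * n_i)))
        sign, logdet_x = np.linalg.slogdet(XtViX)
        s2e = max(quad / (n - p), _EPS)
        ll = -0.5 * ((n - p) * np.log(s2e) + logdet_v0 + logdet_x + (n - p))
        return -ll, s2e

    def obj(t):
        return neg_restricted_ll(np.exp(t))[0]

    res = optimize.minimize_scalar(obj, bounds=(-16.0, 16.0), method="bounded")
    nll0, s2e0 = neg_restricted_ll(0.0)
    if -res.fun > -nll0:
        gamma = float(np.exp(res.x))
        nll1, s2e1 = neg_restricted_ll(gamma)
        return gamma * s2e1, s2e1, -nll1, -nll0
    return 0.0, s2e0, -nll0, -nll0


def test_genetic_variance(fit: VarCompSingleEnv) -> float:
    """Boundary-mixture p-value for sigma2_G > 0 from a single-env fit."""
    return fit.pvalue


# --------------------------------------------------------- combined G + GxE

@dataclass
class CombinedStrata:
    """Sufficient statistics of the balanced line x environment layout."""

    ss: np.ndarray  # genes x 3 (within-cell, line-x-env contrast, between-line)
    df: np.ndarray  # length 3
    n_rep: int
    n_lines: int


def combined_strata(expr: np.ndarray, meta: pd.DataFrame, covariates=None) -> CombinedStrata:
    covariates = list(covariates or [])
    envs = sorted(meta["environment"].unique())
    if len(envs) != 2:
        raise ValueError("combined model requires exactly two environments")
    cell_counts = meta.groupby(["line", "environment"]).size().unstack()
    if cell_counts.isna().any().any():
        raise ValueError("sigma2_GE unidentifiable: some line missing an environment")
    counts = cell_counts.to_numpy()
    if not (counts == counts.flat[0]).all():
        raise ValueError("unbalanced design; use the general fit")
    r = int(counts.flat[0])
    if r < 2:
        raise ValueError("no within-cell replication")
    lines, X_line = _line_level_design(meta, covariates)
    L, p = X_line.shape
    line_codes = np.asarray(pd.Categorical(meta["line"], categories=lines).codes, dtype=np.int64)
    env_codes = np.asarray(pd.Categorical(meta["environment"], categories=envs).codes, dtype=np.int64)
    cell = line_codes * 2 + env_codes
    A = np.zeros((2 * L, len(meta)))
    A[cell, np.arange(len(meta))] = 1.0 / r
    C = expr @ A.T  # genes x cells
    ss_e = (expr**2).sum(axis=1) - r * (C**2).sum(axis=1)
    Ca = C[:, 0::2]
    Cb = C[:, 1::2]
    line_mean = 0.5 * (Ca + Cb)
    contrast = (Ca - Cb) / np.sqrt(2.0)
    P = _residual_projector(X_line)
    ss_g = 2 * r * ((line_mean @ P) ** 2).sum(axis=1)
    ss_ge = r * ((contrast @ P) ** 2).sum(axis=1)
    df = np.array([2 * L * (r - 1), L - p, L - p], dtype=float)
    ss = np.column_stack([np.maximum(ss_e, 0), np.maximum(ss_ge, 0), np.maximum(ss_g, 0)])
    return CombinedStrata(ss, df, r, L)


def _ordered_lambda(ss, df, groups):
    """Per-gene constrained stratum variances under ordered equality groups.

    ``groups`` partitions stratum indices into classes whose variances
    must be non-decreasing (the non-negativity of the variance components
    in the expected mean squares).  The constrained REML optimum is the
    pool-adjacent-violators solution on class mean squares, written out
    explicitly for the k <= 3 classes that occur here.  Vectorized over
    genes; returns genes x n_strata fitted variances.
    """
    ss = np.atleast_2d(ss)
    k = len(groups)
    gdf = np.array([df[list(g)].sum() for g in groups], dtype=float)
    gss = np.column_stack([ss[:, list(g)].sum(axis=1) for g in groups])
    m = gss / gdf
    if k == 1:
        lam_g = m
    elif k == 2:
        pooled = (gss[:, 0] + gss[:, 1]) / (gdf[0] + gdf[1])
        viol = m[:, 1] < m[:, 0]
        lam_g = m.copy()
        lam_g[viol, 0] = pooled[viol]
        lam_g[viol, 1] = pooled[viol]
    elif k == 3:
        a, b, c = m[:, 0], m[:, 1], m[:, 2]
        p12 = (gss[:, 0] + gss[:, 1]) / (gdf[0] + gdf[1])
        p23 = (gss[:, 1] + gss[:, 2]) / (gdf[1] + gdf[2])
        pall = gss.sum(axis=1) / gdf.sum()
        lam_g = m.copy()
        case1 = b < a  # pool first two, maybe all three
        c1_all = case1 & (c < p12)
        c1_two = case1 & ~c1_all
        lam_g[c1_all] = pall[c1_all, None]
        lam_g[c1_two, 0] = p12[c1_two]
        lam_g[c1_two, 1] = p12[c1_two]
        case2 = (~case1) & (c < b)  # pool last two, maybe all three
        c2_all = case2 & (p23 < a)
        c2_two = case2 & ~c2_all
        lam_g[c2_all] = pall[c2_all, None]
        lam_g[c2_two, 1] = p23[c2_two]
        lam_g[c2_two, 2] = p23[c2_two]
    else:  # pragma: no cover - not used
        raise NotImplementedError("ordered pooling implemented for <= 3 classes")
    out = np.empty_like(ss, dtype=float)
    for ci, g in enumerate(groups):
        for s in g:
            out[:, s] = lam_g[:, ci]
    return out


@dataclass
class VarCompCombined:
    gene: str
    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    gxe_index: float
    lrt_GE: float
    p_GE: float
    lrt_G: float
    p_G: float


def combined_estimates(st: CombinedStrata) -> pd.DataFrame:
    """Vectorized REML estimates and boundary LRTs for the combined model."""
    ss, df, r = st.ss, st.df, st.n_rep
    lam_full = _ordered_lambda(ss, df, [(0,), (1,), (2,)])
    ll_full = _strata_ll(ss, df, lam_full)
    s2e = lam_full[:, 0]
    s2ge = np.maximum(0.0, (lam_full[:, 1] - lam_full[:, 0]) / r)
    s2g = np.maximum(0.0, (lam_full[:, 2] - lam_full[:, 1]) / (2 * r))
    lam_noge = _ordered_lambda(ss, df, [(0, 1), (2,)])
    ll_noge = _strata_ll(ss, df, lam_noge)
    lam_nog = _ordered_lambda(ss, df, [(0,), (1, 2)])
    ll_nog = _strata_ll(ss, df, lam_nog)
    lrt_ge = np.maximum(0.0, 2.0 * (ll_full - ll_noge))
    lrt_g = np.maximum(0.0, 2.0 * (ll_full - ll_nog))
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(s2g + s2ge > 0, s2ge / (s2g + s2ge), np.nan)
    return pd.DataFrame(
        {
            "sigma2_G": s2g,
            "sigma2_GE": s2ge,
            "sigma2_e": s2e,
            "gxe_index": idx,
            "lrt_GE": lrt_ge,
            "p_GE": _mixture_boundary_p(lrt_ge),
            "lrt_G": lrt_g,
            "p_G": _mixture_boundary_p(lrt_g),
        }
    )


def fit_combined(values, lines, environments, covariates=None, gene="gene") -> VarCompCombined:
    """Fit y = Xb + line + line:env + e for one gene across two environments."""
    y = np.asarray(values, dtype=float)
    meta = pd.DataFrame({"line": pd.Series(lines).astype(str).values,
                         "environment": pd.Series(environments).astype(str).values})
    if meta["line"].nunique() < 2:
        raise ValueError("sigma2_GE unidentifiable with fewer than two lines")
    covs = []
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        for j in range(C.shape[1]):
            meta[f"cov{j}"] = C[:, j]
            covs.append(f"cov{j}")
    st = combined_strata(y[None, :], meta, covs)
    row = combined_estimates(st).iloc[0]
    return VarCompCombined(gene, row.sigma2_G, row.sigma2_GE, row.sigma2_e,
                           row.gxe_index, row.lrt_GE, row.p_GE, row.lrt_G, row.p_G)


# ------------------------------------------------------ variance heterogeneity

@dataclass
class HeterogeneityResult:
    gene: str
    component: str
    var_env: dict
    fold_change: float
    lrt: float
    pvalue: float


def _het_strata(expr: np.ndarray, meta: pd.DataFrame, covariates=None):
    """Per-environment one-way strata for the heterogeneity models."""
    envs = sorted(meta["environment"].unique())
    if len(envs) != 2:
        raise ValueError("heterogeneity test requires exactly two environments")
    per_env = []
    for env in envs:
        sub = meta["environment"] == env
        st = single_env_strata(expr[:, sub.to_numpy()], meta.loc[sub].reset_index(drop=True), covariates)
        per_env.append(st)
    return envs, per_env


def _het_full_ll(per_env):
    """Unconstrained (per-environment) fit: 2-strata ordered pooling per env."""
    ll = 0.0
    ests = []
    for st in per_env:
        ss = np.column_stack([st.ss_within, st.ss_between])
        df = np.array([st.df_within, st.df_between], dtype=float)
        lam = _ordered_lambda(ss, df, [(0,), (1,)])
        ll = ll + _strata_ll(ss, df, lam)
        ests.append(lam)
    return ll, ests


def heterogeneity_lrt(expr: np.ndarray, meta: pd.DataFrame, component: str, covariates=None) -> pd.DataFrame:
    """LRT of a shared vs environment-specific variance component.

    ``component`` is "G" (between-line variance) or "e" (within-line
    variance); the other component stays environment-specific in both
    models.  Null is chi2 with 1 df (interior parameter).  Fold change is
    larger/smaller of the per-environment moment estimates of the tested
    component (NaN when both are zero).
    """
    if component not in ("G", "e"):
        raise ValueError("component must be 'G' or 'e'")
    envs, per_env = _het_strata(expr, meta, covariates)
    ll_full, _ = _het_full_ll(per_env)
    n_genes = expr.shape[0]
    sw = [st.ss_within for st in per_env]
    sb = [st.ss_between for st in per_env]
    dw = [st.df_within for st in per_env]
    db = [st.df_between for st in per_env]
    rr = [st.n_rep for st in per_env]

    # per-environment moment estimates of the tested component
    ms_w = [sw[j] / dw[j] for j in range(2)]
    ms_b = [sb[j] / db[j] for j in range(2)]
    if component == "e":
        est = np.column_stack(ms_w)
    else:
        est = np.column_stack([np.maximum(0.0, (ms_b[j] - ms_w[j]) / rr[j]) for j in range(2)])

    ll_null = np.empty(n_genes)
    for g in range(n_genes):
        if component == "e":
            ll_null[g] = _shared_e_ll(sw, sb, dw, db, g)
        else:
            ll_null[g] = _shared_g_ll(sw, sb, dw, db, rr, g)
    lrt = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    big = est.max(axis=1)
    small = est.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(small > 0, big / small, np.where(big > 0, np.inf, np.nan))
    p = special.chdtrc(1, lrt)
    p = np.where(np.isnan(fold) & (lrt <= 0), 1.0, p)
    return pd.DataFrame({
        f"var_{envs[0]}": est[:, 0],
        f"var_{envs[1]}": est[:, 1],
        "fold_change": fold,
        "lrt": lrt,
        "pvalue": p,
    })


def _shared_e_ll(sw, sb, dw, db, g):
    """Profiled constrained likelihood with a common residual variance."""
    ss_w = np.array([sw[0][g], sw[1][g]])
    ss_b = np.array([sb[0][g], sb[1][g]])
    df_w = np.array([dw[0], dw[1]], dtype=float)
    df_b = np.array([db[0], db[1]], dtype=float)

    def nll(log_s2e):
        s2e = np.exp(log_s2e)
        lam_b = np.maximum(ss_b / df_b, s2e)  # inner max over lam_b >= s2e
        val = np.sum(df_w * np.log(s2e) + ss_w / s2e + df_b * np.log(np.maximum(lam_b, _EPS)) + ss_b / np.maximum(lam_b, _EPS))
        return 0.5 * val

    tot = (ss_w.sum() + ss_b.sum()) / (df_w.sum() + df_b.sum())
    lo, hi = np.log(max(tot, _EPS)) - 20, np.log(max(tot, _EPS)) + 5
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return -res.fun


def _shared_g_ll(sw, sb, dw, db, rr, g):
    """Constrained likelihood with a common between-line variance."""
    ss_w = np.array([sw[0][g], sw[1][g]])
    ss_b = np.array([sb[0][g], sb[1][g]])
    df_w = np.array([dw[0], dw[1]], dtype=float)
    df_b = np.array([db[0], db[1]], dtype=float)
    r = np.array(rr, dtype=float)

    def inner_nll(s2g):
        # profile each environment's s2e at fixed shared s2g (1-D Brent each)
        tot = 0.0
        for j in range(2):
            def f(log_s2e, j=j):
                s2e = np.exp(log_s2e)
                lam = s2e + r[j] * s2g
                return 0.5 * (df_w[j] * np.log(s2e) + ss_w[j] / s2e
                              + df_b[j] * np.log(max(lam, _EPS)) + ss_b[j] / max(lam, _EPS))
            guess = max(ss_w[j] / df_w[j], _EPS)
            res = optimize.minimize_scalar(f, bounds=(np.log(guess) - 12, np.log(guess) + 8),
                                           method="bounded", options={"xatol": 1e-10})
            tot += res.fun
        return tot

    # outer 1-D search over shared s2g >= 0
    g_hat = [max(0.0, (ss_b[j] / df_b[j] - ss_w[j] / df_w[j]) / r[j]) for j in range(2)]
    guess = max(np.mean(g_hat), _EPS)
    res = optimize.minimize_scalar(lambda t: inner_nll(np.exp(t)),
                                   bounds=(np.log(guess) - 14, np.log(guess) + 6),
                                   method="bounded", options={"xatol": 1e-10})
    best = min(res.fun, inner_nll(0.0))
    return -best


def test_variance_heterogeneity(values, lines, environments, component, covariates=None, gene="gene") -> HeterogeneityResult:
    """Single-gene wrapper around :func:`heterogeneity_lrt`."""
    y = np.asarray(values, dtype=float)
    meta = pd.DataFrame({"line": pd.Series(lines).astype(str).values,
                         "environment": pd.Series(environments).astype(str).values})
    covs = []
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        for j in range(C.shape[1]):
            meta[f"cov{j}"] = C[:, j]
            covs.append(f"cov{j}")
    res = heterogeneity_lrt(y[None, :], meta, component, covs)
    row = res.iloc[0]
    envs = sorted(meta["environment"].unique())
    return HeterogeneityResult(gene, component,
                               {envs[0]: row[f"var_{envs[0]}"], envs[1]: row[f"var_{envs[1]}"]},
                               row.fold_change, row.lrt, row.pvalue)


# ------------------------------------------------------------- classification

def classify_canalization(q_het, fold_change, var_treatment, var_baseline,
                          q_sig_treatment, q_sig_baseline,
                          alpha: float = 0.05, fold: float = 2.0) -> str:
    """Call a gene decanalized/canalized/stable in the treatment environment.

    Decanalized: significant heterogeneity (q <= alpha) of at least
    ``fold``-fold with higher genetic variance in the treatment
    environment and significant genetic variance there; canalized is the
    mirror image; everything else is stable.
    """
    if not (np.isfinite(q_het) and q_het <= alpha):
        return "stable"
    if not (np.isfinite(fold_change) and fold_change >= fold):
        # infinite fold (one zero variance) counts as exceeding the threshold
        if not (np.isinf(fold_change) and var_treatment != var_baseline):
            return "stable"
    if var_treatment > var_baseline and np.isfinite(q_sig_treatment) and q_sig_treatment <= alpha:
        return "decanalized"
    if var_baseline > var_treatment and np.isfinite(q_sig_baseline) and q_sig_baseline <= alpha:
        return "canalized"
    return "stable"


# ------------------------------------------------------------- batch drivers

def varcomp_single_all(study, covariates=None) -> pd.DataFrame:
    """Per-gene, per-environment variance partition over a whole study.

    The study must contain a single sex (the analysis is fully
    sex-stratified); BH q-values are computed within each environment.
    """
    if study.meta["sex"].nunique() > 1:
        raise ValueError("varcomp drivers expect a single-sex study; split by sex first")
    covariates = list(covariates or [])
    frames = []
    for env, sub in study.split_by_environment().items():
        st = single_env_strata(sub.expr.to_numpy(), sub.meta.reset_index(), covariates)
        s2g, s2e, lrt, p = _single_env_estimates(st)
        frames.append(pd.DataFrame({
            "gene": study.genes, "environment": env,
            "sigma2_G": s2g, "sigma2_e": s2e, "lrt": lrt, "pvalue": p,
            "qvalue": bh_adjust(p),
        }))
    return pd.concat(frames, ignore_index=True)


def varcomp_combined_all(study, covariates=None) -> pd.DataFrame:
    """Combined G + GxE partition for every gene; q-values per test family."""
    if study.meta["sex"].nunique() > 1:
        raise ValueError("varcomp drivers expect a single-sex study; split by sex first")
    st = combined_strata(study.expr.to_numpy(), study.meta.reset_index(), list(covariates or []))
    out = combined_estimates(st)
    out.insert(0, "gene", study.genes.to_numpy())
    out["q_GE"] = bh_adjust(out["p_GE"])
    out["q_G"] = bh_adjust(out["p_G"])
    return out


def heterogeneity_all(study, component: str, covariates=None,
                      treatment_env=None, alpha: float = 0.05, fold: float = 2.0,
                      single_env_q: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heterogeneity LRT for every gene plus canalization classes.

    ``single_env_q`` (output of :func:`varcomp_single_all`) supplies the
    per-environment sigma2_G significance gate used for classification of
    the "G" component; without it classes are NaN.
    """
    if study.meta["sex"].nunique() > 1:
        raise ValueError("varcomp drivers expect a single-sex study; split by sex first")
    res = heterogeneity_lrt(study.expr.to_numpy(), study.meta, component, list(covariates or []))
    res.insert(0, "gene", study.genes.to_numpy())
    res["qvalue"] = bh_adjust(res["pvalue"])
    envs = study.environments
    if treatment_env is None:
        treatment_env = envs[0]
    baseline_env = [e for e in envs if e != treatment_env][0]
    if component == "G" and single_env_q is not None:
        qt = single_env_q.query("environment == @treatment_env").set_index("gene")["qvalue"]
        qb = single_env_q.query("environment == @baseline_env").set_index("gene")["qvalue"]
        labels = [
            classify_canalization(row["qvalue"], row["fold_change"],
                                  row[f"var_{treatment_env}"], row[f"var_{baseline_env}"],
                                  qt.get(row["gene"], np.nan), qb.get(row["gene"], np.nan),
                                  alpha=alpha, fold=fold)
            for _, row in res.iterrows()
        ]
        res["label"] = labels
    return res
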