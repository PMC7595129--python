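"""Co-expression structure across environments.

Three analyses:

* gene connectivity — mean absolute pairwise correlation with all other
  genes, computed on line-level expression;
* the correlated-null simulation test of coordinated plasticity — the
  observed variance of pairwise correlation changes (delta r = r_treat -
  r_base) is compared with a null in which each gene's
  treatment-environment expression is resimulated as
  Y = sigma2*(rho*Z1 + sqrt(1-rho^2)*Z2) + mu2 (Z1 = scaled baseline
  expression, Z2 iid standard normal), preserving each gene's mean,
  variance and cross-environment correlation while making the plastic
  responses of different genes independent.  Coordinated plasticity
  shows up as a *smaller* observed variance than the null;
* the connectivity versus stabilizing-selection (V_m/V_g) Spearman
  correlation, optionally stratified by a GxE grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def connectivity(corr: pd.DataFrame) -> pd.Series:
    """Per-gene mean |r| over all other genes (diagonal excluded)."""
    C = np.abs(corr.to_numpy(dtype=float))
    if C.shape[0] < 2 or C.shape[0] != C.shape[1]:
        raise ValueError("need a square correlation matrix over >= 2 genes")
    np.fill_diagonal(C, np.nan)
    return pd.Series(np.nanmean(C, axis=1), index=corr.index, name="connectivity")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations over line-level expression."""
    C = np.corrcoef(expr.to_numpy(dtype=float))
    return pd.DataFrame(C, index=expr.index, columns=expr.index)


def simulate_null_expression(x, mu2: float, sigma2: float, rho: float, rng) -> np.ndarray:
    """One gene's null expression in the treatment environment.

    ``x`` is the baseline-environment expression per line; the output has
    mean mu2, SD sigma2, and expected correlation rho with x, with an
    independent innovation per line.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    x = np.asarray(x, dtype=float)
    s1 = x.std(ddof=1)
    if s1 <= 0:
        raise ValueError("baseline expression has zero variance")
    z1 = (x - x.mean()) / s1
    z2 = rng.standard_normal(len(x))
    return sigma2 * (rho * z1 + np.sqrt(max(1.0 - rho**2, 0.0)) * z2) + mu2


@dataclass
class DeltaRTestResult:
    observed_variance: float
    null_variances: np.ndarray
    pvalue: float
    n_sim: int
    genes: list


def delta_r_test(expr_base: pd.DataFrame, expr_treat: pd.DataFrame,
                 gene_subset=None, n_sim: int = 1000, seed: int = 0) -> DeltaRTestResult:
    """Simulation test for coordinated plasticity of co-expression.

    ``expr_base``/``expr_treat`` are genes x lines matrices on the same
    lines (e.g. line means or BLUPs at the two temperatures).  The
    statistic is the variance of the upper-triangle delta r =
    r_treat - r_base.  Null datasets resimulate every gene's treatment
    values independently with per-gene moments and cross-environment
    correlation estimated from the data; the one-sided empirical p
    (add-one convention) counts null variances <= observed.
    """
    if list(expr_base.columns) != list(expr_treat.columns):
        raise ValueError("both matrices must cover the same lines in the same order")
    genes = list(expr_base.index) if gene_subset is None else [g for g in gene_subset if g in expr_base.index]
    if len(genes) < 3:
        raise ValueError("need at least three genes")
    Xb = expr_base.loc[genes].to_numpy(dtype=float)
    Xt = expr_treat.loc[genes].to_numpy(dtype=float)
    sd_b = Xb.std(axis=1, ddof=1)
    sd_t = Xt.std(axis=1, ddof=1)
    ok = (sd_b > 0) & (sd_t > 0)
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance genes")
        genes = [g for g, keep in zip(genes, ok) if keep]
        Xb, Xt, sd_b, sd_t = Xb[ok], Xt[ok], sd_b[ok], sd_t[ok]
        if len(genes) < 3:
            raise ValueError("fewer than three usable genes")
    n_lines = Xb.shape[1]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(len(genes), k=1)
    r_base = np.corrcoef(Xb)
    r_treat = np.corrcoef(Xt)
    delta = (r_treat - r_base)[iu]
    observed = float(np.var(delta, ddof=1))
    if np.allclose(delta, 0.0):
        warnings.warn("observed delta r identically zero; degenerate input")
    # per-gene moments and cross-environment correlation
    mu2 = Xt.mean(axis=1)
    zb = (Xb - Xb.mean(axis=1, keepdims=True)) / sd_b[:, None]
    zt = (Xt - mu2[:, None]) / sd_t[:, None]
    rho = (zb * zt).sum(axis=1) / (n_lines - 1)
    rho = np.clip(rho, -1.0, 1.0)
    null_vars = np.empty(n_sim)
    root = np.sqrt(np.maximum(1.0 - rho**2, 0.0))
    for b in range(n_sim):
        Z2 = rng.standard_normal(Xb.shape)
        Y = sd_t[:, None] * (rho[:, None] * zb + root[:, None] * Z2) + mu2[:, None]
        r_sim = np.corrcoef(Y)
        null_vars[b] = np.var((r_sim - r_base)[iu], ddof=1)
    p = float((np.sum(null_vars <= observed) + 1) / (n_sim + 1))
    return DeltaRTestResult(observed, null_vars, p, n_sim, genes)


def connectivity_selection_correlation(conn: pd.Series, selection: pd.DataFrame,
                                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Spearman correlation of connectivity with V_m/V_g, overall and by group.

    ``selection`` needs columns V_m and V_g (strength is their ratio);
    ``groups`` is an optional per-gene label (e.g. GxE vs no-GxE) for
    stratified estimates.
    """
    if (selection[["V_m", "V_g"]] <= 0).any().any():
        raise ValueError("V_m and V_g must be positive")
    common = conn.index.intersection(selection.index)
    if len(common) < 3:
        raise ValueError("need at least three genes with both quantities")
    strength = selection.loc[common, "V_m"] / selection.loc[common, "V_g"]
    rows = []
    r, p = spearmanr(conn.loc[common], strength)
    rows.append({"group": "all", "n": len(common), "spearman_r": float(r), "p": float(p)})
    if groups is not None:
        g = groups.reindex(common).dropna()
        for label in sorted(g.unique(), key=str):
            idx = g.index[g == label]
            if len(idx) < 3:
                continue
            r, p = spearmanr(conn.loc[idx], strength.loc[idx])
            rows.append({"group": str(label), "n": len(idx), "spearman_r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def module_crosstab(modules_base: pd.Series, modules_treat: pd.Series) -> pd.DataFrame:
    """Cross-tabulation of module labels between environments (descriptive)."""
    common = modules_base.index.intersection(modules_treat.index)
    return pd.crosstab(modules_base.loc[common], modules_treat.loc[common])
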