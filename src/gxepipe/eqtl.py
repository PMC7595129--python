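"""eQTL mapping on line-level BLUPs with permutation FDR and forward selection.

Workflow per sex and environment:

1. :func:`estimate_line_blups` — per gene, remove fixed effects and shrink
   line-mean deviations toward zero by the mixed-model factor
   lambda_i = sigma2_G * n_i / (sigma2_e + n_i * sigma2_G).
2. :func:`map_eqtl` / :func:`association_stats` — single-variant
   regression of BLUPs on 0/1 allele codes; for a homozygous panel the
   slope t equals the two-sample equal-variance t between allele classes
   (df = n_lines - 2).
3. :func:`empirical_fdr` — permute line labels of the whole BLUP matrix
   jointly (preserving gene-gene correlation), remap, and estimate
   FDR(t) = mean permuted discoveries / observed discoveries at each
   p-value threshold.
4. :func:`forward_select` — stepwise conditional admission of candidates
   at P below an entry threshold (default 1e-5).
5. :func:`classify_sharing` / :func:`cross_env_predict` — compare eQTL
   architecture and predict expression across environments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .datatypes import ExpressionStudy, GenotypeMatrix
from .varcomp import single_env_strata, _single_env_estimates

_EPS = 1e-12


# ----------------------------------------------------------------- line BLUPs

def estimate_line_blups(study: ExpressionStudy, covariates=None) -> dict:
    """Per-environment genes x lines BLUP matrices.

    Fixed effects (intercept + line-constant covariates) are estimated on
    line means; the line BLUP is the shrunken residual line mean,
    shrinkage factor sigma2_G*n_i/(sigma2_e + n_i*sigma2_G) from the
    per-gene single-environment variance fit.  With sigma2_e = 0 BLUPs
    equal centered line means; with sigma2_G = 0 they are identically 0.
    """
    if study.meta["sex"].nunique() > 1:
        raise ValueError("BLUPs are computed within one sex; split the study first")
    covariates = list(covariates or [])
    out = {}
    for env, sub in study.split_by_environment().items():
        meta = sub.meta.reset_index()
        counts = meta.groupby("line").size()
        lines = meta["line"].unique()
        expr = sub.expr.to_numpy()
        st = single_env_strata(expr, meta, covariates)
        s2g, s2e, _, _ = _single_env_estimates(st)
        # line means and fixed-effect adjustment
        codes = pd.Categorical(meta["line"], categories=lines).codes
        r = int(counts.iloc[0])
        A = np.zeros((len(lines), len(meta)))
        A[codes, np.arange(len(meta))] = 1.0 / r
        M = expr @ A.T  # genes x lines
        if covariates:
            X = np.column_stack([np.ones(len(lines)),
                                 meta.groupby("line")[covariates].first().loc[lines].to_numpy(dtype=float)])
        else:
            X = np.ones((len(lines), 1))
        beta, *_ = np.linalg.lstsq(X, M.T, rcond=None)
        dev = M - (X @ beta).T
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(s2g + s2e / r > 0, s2g / (s2g + s2e / r), 0.0)
        out[env] = pd.DataFrame(lam[:, None] * dev, index=sub.expr.index, columns=lines)
    return out


# ---------------------------------------------------------------- association

def association_stats(blups: pd.DataFrame, genos: GenotypeMatrix):
    """Vectorized slope/t/p for every gene x variant pair.

    Returns (beta, t, p) arrays of shape (n_genes, n_variants).  beta is
    the mean difference between allele classes (slope on a 0/1 code); t
    is the equal-variance two-sample t with n_lines - 2 df.
    """
    common = [l for l in blups.columns if l in set(genos.lines)]
    if len(common) < 3:
        raise ValueError("need at least three shared lines")
    B = blups[common].to_numpy(dtype=float)
    G = genos.calls[common].to_numpy(dtype=float)
    n = len(common)
    Bc = B - B.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=1, keepdims=True)
    sb = np.sqrt((Bc**2).sum(axis=1))
    sg = np.sqrt((Gc**2).sum(axis=1))
    if (sg <= 0).any():
        raise ValueError("monomorphic variant among shared lines; filter first")
    rmat = (Bc @ Gc.T) / np.outer(np.maximum(sb, _EPS), sg)
    rmat = np.clip(rmat, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rmat * np.sqrt(df / np.maximum(1.0 - rmat**2, _EPS))
    t = np.where(sb[:, None] <= 0, 0.0, t)
    beta = (Bc @ Gc.T) / (sg**2)[None, :]
    p = special.stdtr(df, -np.abs(t)) * 2.0
    p = np.where(t == 0, 1.0, p)
    return beta, t, p


def map_eqtl(blups: pd.DataFrame, genos: GenotypeMatrix, maf_min: float = 0.05) -> pd.DataFrame:
    """Tidy association table (gene, variant, beta, t, p) after MAF filtering."""
    genos = genos.filter_maf(maf_min)
    beta, t, p = association_stats(blups, genos)
    genes = np.repeat(blups.index.to_numpy(), len(genos.calls.index))
    variants = np.tile(genos.calls.index.to_numpy(), len(blups.index))
    return pd.DataFrame({"gene": genes, "variant": variants,
                         "beta": beta.ravel(), "t": t.ravel(), "p": p.ravel()})


# -------------------------------------------------------------- empirical FDR

@dataclass
class FdrResult:
    threshold: float | None
    curve: pd.DataFrame  # columns: p_threshold, n_observed, mean_permuted, fdr

    def __bool__(self) -> bool:  # truthy iff a threshold was found
        return self.threshold is not None


def permute_blups(blups: pd.DataFrame, rng) -> pd.DataFrame:
    """Shuffle line labels of the whole matrix jointly across genes."""
    perm = rng.permutation(blups.shape[1])
    return pd.DataFrame(blups.to_numpy()[:, perm], index=blups.index, columns=blups.columns)


def empirical_fdr(observed_p: np.ndarray, permuted_p: list, alpha: float = 0.05,
                  n_grid: int = 200) -> FdrResult:
    """Permutation FDR: mean permuted discovery count over observed count.

    ``observed_p`` is the flattened observed p-value collection;
    ``permuted_p`` a list of equally shaped collections from label
    permutations.  FDR(t) is clipped at 1; the reported threshold is the
    largest t in the candidate grid with FDR(t) <= alpha.
    """
    obs = np.sort(np.asarray(observed_p, dtype=float).ravel())
    perms = [np.sort(np.asarray(p, dtype=float).ravel()) for p in permuted_p]
    if obs.size == 0:
        return FdrResult(None, pd.DataFrame(columns=["p_threshold", "n_observed", "mean_permuted", "fdr"]))
    # candidate thresholds: the smallest observed p-values exactly (that is
    # where the discovery region lives) plus a quantile grid for the body
    n_head = min(obs.size, 5000)
    head = obs[:n_head]
    if obs.size > n_grid:
        body = obs[np.linspace(0, obs.size - 1, n_grid).astype(int)]
        qs = np.unique(np.concatenate([head, body]))
    else:
        qs = np.unique(obs)
    n_obs = np.searchsorted(obs, qs, side="right").astype(float)
    mean_perm = np.zeros_like(qs)
    for p in perms:
        mean_perm += np.searchsorted(p, qs, side="right")
    mean_perm /= max(len(perms), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_obs > 0, np.minimum(mean_perm / n_obs, 1.0), np.nan)
    curve = pd.DataFrame({"p_threshold": qs, "n_observed": n_obs,
                          "mean_permuted": mean_perm, "fdr": fdr})
    ok = curve["fdr"] <= alpha
    if not ok.any():
        return FdrResult(None, curve)
    return FdrResult(float(curve.loc[ok, "p_threshold"].max()), curve)


def eqtl_fdr_threshold(blups: pd.DataFrame, genos: GenotypeMatrix,
                       n_perm: int = 100, alpha: float = 0.05,
                       maf_min: float = 0.05, seed: int = 0) -> FdrResult:
    """Run the mapping + permutation machinery end to end for one matrix."""
    genos = genos.filter_maf(maf_min)
    rng = np.random.default_rng(seed)
    _, _, p_obs = association_stats(blups, genos)
    perms = []
    for _ in range(n_perm):
        _, _, pp = association_stats(permute_blups(blups, rng), genos)
        perms.append(pp.ravel())
    return empirical_fdr(p_obs.ravel(), perms, alpha=alpha)


# ----------------------------------------------------------- forward selection

@dataclass
class EqtlModel:
    gene: str
    environment: str
    variants: list = field(default_factory=list)   # ordered variant IDs
    effects: dict = field(default_factory=dict)    # variant -> conditional beta
    tstats: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)    # conditional p at final model

    def __len__(self) -> int:
        return len(self.variants)


def _partial_stats(y: np.ndarray, X: np.ndarray):
    """OLS effects, t statistics and p-values for all columns of X jointly."""
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = n - Xd.shape[1]
    if dof <= 0:
        return None
    s2 = float(resid @ resid) / dof
    XtX = Xd.T @ Xd
    try:
        cov = np.linalg.inv(XtX) * s2
    except np.linalg.LinAlgError:
        return None
    se = np.sqrt(np.maximum(np.diag(cov), _EPS))
    t = beta / se
    p = special.stdtr(dof, -np.abs(t)) * 2.0
    return beta[1:], t[1:], p[1:]


def forward_select(gene: str, candidates: pd.Index, blups_row: pd.Series,
                   genos: GenotypeMatrix, entry_p: float = 1e-5,
                   environment: str = "") -> EqtlModel:
    """Greedy conditional admission of candidate variants.

    At each step every remaining candidate is tested conditional on the
    current model (partial t in the joint regression); the one with the
    smallest conditional p is admitted while that p < ``entry_p``.  Ties
    are broken by (chromosome, position, variant ID); candidates
    perfectly collinear with the model are skipped.  Selection stops when
    the model would exhaust the residual degrees of freedom.
    """
    model = EqtlModel(gene, environment)
    if len(candidates) == 0:
        return model
    lines = list(blups_row.index)
    y = blups_row.to_numpy(dtype=float)
    order = genos.variants.loc[list(candidates)].sort_values(["chrom", "pos"]).index
    G = genos.calls.loc[order, lines].to_numpy(dtype=float)
    remaining = list(range(len(order)))
    chosen: list[int] = []
    n = len(y)
    while remaining:
        if len(chosen) >= n - 2:
            warnings.warn(f"{gene}: model size reached n_lines - 2; stopping")
            break
        best = None
        for j in remaining:
            X = G[chosen + [j]].T
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
                continue  # collinear with current model
            stats = _partial_stats(y, X)
            if stats is None:
                continue
            p_cand = stats[2][-1]
            if best is None or p_cand < best[0] - 0.0:
                best = (p_cand, j)
        if best is None or best[0] >= entry_p:
            break
        chosen.append(best[1])
        remaining.remove(best[1])
    if chosen:
        X = G[chosen].T
        beta, t, p = _partial_stats(y, X)
        for i, j in enumerate(chosen):
            vid = order[j]
            model.variants.append(vid)
            model.effects[vid] = float(beta[i])
            model.tstats[vid] = float(t[i])
            model.pvalues[vid] = float(p[i])
    return model


def best_subset_oracle(gene: str, candidates: pd.Index, blups_row: pd.Series,
                       genos: GenotypeMatrix, entry_p: float = 1e-5,
                       max_candidates: int = 8) -> set:
    """Exhaustive-search reference for forward selection on tiny problems.

    Enumerates every subset (largest first, minimum RSS as tie-break)
    whose members are all conditionally significant at ``entry_p`` and to
    which no remaining candidate can be added at ``entry_p``; returns
    that subset's variant IDs.  Only valid for <= ``max_candidates``.
    """
    if len(candidates) > max_candidates:
        raise ValueError("oracle restricted to small candidate sets")
    lines = list(blups_row.index)
    y = blups_row.to_numpy(dtype=float)
    order = genos.variants.loc[list(candidates)].sort_values(["chrom", "pos"]).index
    G = genos.calls.loc[order, lines].to_numpy(dtype=float)
    n = len(y)
    idx = range(len(order))

    def admissible(subset):
        if not subset:
            return True
        X = G[list(subset)].T
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
            return False
        stats = _partial_stats(y, X)
        return stats is not None and (stats[2] < entry_p).all()

    def saturated(subset):
        for j in idx:
            if j in subset:
                continue
            X = G[list(subset) + [j]].T
            if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
                continue
            stats = _partial_stats(y, X)
            if stats is not None and stats[2][-1] < entry_p:
                return False
        return True

    best = (None, np.inf)
    for k in range(len(order), -1, -1):
        for subset in itertools.combinations(idx, k):
            if admissible(subset) and saturated(subset):
                if subset:
                    X = np.column_stack([np.ones(n), G[list(subset)].T])
                    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                    rss = float(np.sum((y - X @ beta) ** 2))
                else:
                    rss = float(np.sum((y - y.mean()) ** 2))
                if best[0] is None or (len(subset) > len(best[0])) or \
                   (len(subset) == len(best[0]) and rss < best[1] - 1e-12):
                    best = (subset, rss)
        if best[0] is not None and len(best[0]) == k:
            break
    return {order[j] for j in (best[0] or ())}


# --------------------------------------------------------- cross-env analysis

def classify_sharing(models_a: dict, models_b: dict,
                     mapped_a: set, mapped_b: set,
                     env_a: str, env_b: str) -> tuple[pd.DataFrame, dict]:
    """Classify gene x variant pairs retained in at least one environment.

    ``models_*`` map gene -> EqtlModel (post forward selection);
    ``mapped_*`` are sets of (gene, variant) pairs significant before
    selection.  A retained pair is "shared" when it was mapped in both
    environments, otherwise specific to the environment where it was
    mapped.  The summary counts genes with eQTLs per environment and the
    fraction of genes (with eQTLs in both) sharing at least one eQTL
    (NaN when no such gene exists).
    """
    rows = []
    pairs = set()
    for env, models in ((env_a, models_a), (env_b, models_b)):
        for gene, model in models.items():
            for vid in model.variants:
                pairs.add((gene, vid))
    for gene, vid in sorted(pairs):
        in_a = (gene, vid) in mapped_a
        in_b = (gene, vid) in mapped_b
        if in_a and in_b:
            cls = "shared"
        elif in_a:
            cls = f"{env_a}-specific"
        else:
            cls = f"{env_b}-specific"
        rows.append({"gene": gene, "variant": vid, "class": cls})
    table = pd.DataFrame(rows, columns=["gene", "variant", "class"])
    genes_a = {g for g, m in models_a.items() if len(m)}
    genes_b = {g for g, m in models_b.items() if len(m)}
    both = genes_a & genes_b
    sharing = np.nan
    if both:
        n_share = sum(
            any(((g, v) in mapped_a and (g, v) in mapped_b)
                for v in set(models_a[g].variants) | set(models_b[g].variants))
            for g in both
        )
        sharing = n_share / len(both)
    summary = {
        f"genes_with_eqtl_{env_a}": len(genes_a),
        f"genes_with_eqtl_{env_b}": len(genes_b),
        "genes_with_eqtl_both": len(both),
        "fraction_sharing": sharing,
    }
    return table, summary


def effect_pairs(table: pd.DataFrame, assoc_a: pd.DataFrame, assoc_b: pd.DataFrame,
                 env_a: str, env_b: str) -> pd.DataFrame:
    """Per classified pair, the single-variant effect in both environments
    (regardless of significance in the other environment)."""
    ia = assoc_a.set_index(["gene", "variant"])["beta"]
    ib = assoc_b.set_index(["gene", "variant"])["beta"]
    out = table.copy()
    key = pd.MultiIndex.from_frame(table[["gene", "variant"]])
    out[f"beta_{env_a}"] = ia.reindex(key).to_numpy()
    out[f"beta_{env_b}"] = ib.reindex(key).to_numpy()
    return out


def cross_env_predict(models: dict, genos: GenotypeMatrix,
                      observed_blups: pd.DataFrame) -> pd.Series:
    """Predict expression in the other environment from mapped eQTLs.

    Prediction per line is the sum of allele codes times the training
    environment's effects; returns the per-gene Pearson correlation with
    the observed BLUPs.  Genes without a model, or with degenerate
    observed/predicted variance, are skipped.
    """
    out = {}
    lines = list(observed_blups.columns)
    for gene, model in models.items():
        if len(model) == 0 or gene not in observed_blups.index:
            continue
        pred = np.zeros(len(lines))
        for vid in model.variants:
            pred += model.effects[vid] * genos.calls.loc[vid, lines].to_numpy(dtype=float)
        obs = observed_blups.loc[gene].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(obs) == 0:
            continue
        out[gene] = float(np.corrcoef(pred, obs)[0, 1])
    return pd.Series(out, name="pearson_r", dtype=float)
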