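"""Gene-set enrichment over custom per-gene scores.

Two score kinds feed the preranked analysis:

* decanalization score (s2G_treatment - s2G_baseline)/(s2G_treatment +
  s2G_baseline), positive when genetic variance is released in the
  treatment environment;
* GxE score 2*index - 1, where index = s2GE/(s2GE + s2G).

Both live in [-1, 1] and replace the usual correlation scores in the
weighted Kolmogorov-Smirnov running-sum statistic.  Significance comes
from random same-size gene draws, with the normalized enrichment score
(NES) and FDR computed separately for positive and negative scores as in
the original procedure.  A plain hypergeometric test covers fixed gene
lists (e.g. co-expression module members).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .datatypes import GeneSetCollection
from .varcomp import bh_adjust


def decanalization_score(sigma2_G_treatment: float, sigma2_G_baseline: float) -> float:
    """(s2_t - s2_b)/(s2_t + s2_b), in [-1, 1]; positive = decanalized."""
    tot = sigma2_G_treatment + sigma2_G_baseline
    if tot <= 0:
        raise ValueError("denominator must be positive")
    return (sigma2_G_treatment - sigma2_G_baseline) / tot


def gxe_score(gxe_index: float) -> float:
    """Map a GxE index in [0, 1] onto the symmetric score 2*index - 1."""
    if not 0.0 <= gxe_index <= 1.0:
        raise ValueError("gxe index must lie in [0, 1]")
    return 2.0 * gxe_index - 1.0


def running_enrichment_score(ranked_genes, scores, member_set, weight_p: float = 1.0):
    """Running sum and enrichment score for one gene set.

    Genes are assumed ranked by score descending.  Hits increment by
    |score|^p normalized over the set; misses decrement by 1/(N - N_set).
    Returns (running sum array, ES = max deviation from zero).
    """
    ranked_genes = list(ranked_genes)
    s = np.asarray(scores, dtype=float)
    hit = np.fromiter((g in member_set for g in ranked_genes), dtype=bool, count=len(ranked_genes))
    n, nh = len(ranked_genes), int(hit.sum())
    if nh == 0 or nh > n:
        raise ValueError("set has no members in the ranked universe")
    w = np.abs(s) ** weight_p
    denom = w[hit].sum()
    inc = np.where(hit, np.where(denom > 0, w / max(denom, 1e-300), 1.0 / nh), 0.0)
    if n > nh:
        inc = inc - np.where(hit, 0.0, 1.0 / (n - nh))
    run = np.cumsum(inc)
    es = run[np.argmax(np.abs(run))]
    return run, float(es)


def gsea_preranked(scores: pd.Series, sets: GeneSetCollection,
                   weight_p: float = 1.0, n_perm: int = 1000,
                   min_size: int = 20, seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA with a random gene-label null.

    ``scores`` is indexed by gene (unique); ties in score are broken by
    gene ID so the ranking is deterministic.  Sets are filtered to
    ``min_size`` members within the universe.  For each set, ``n_perm``
    random same-size draws give the null ES distribution; p and NES are
    computed on the matching sign side, and FDR q follows the original
    positive/negative NES procedure.
    """
    if scores.index.has_duplicates:
        raise ValueError("gene scores must have unique gene IDs")
    rng = np.random.default_rng(seed)
    order = scores.rename("score").rename_axis("gene").reset_index()
    # ties in score broken by gene ID for a deterministic ranking
    order = order.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    ranked_genes = order["gene"].tolist()
    ranked_scores = order["score"].to_numpy()
    universe = set(ranked_genes)
    sets = sets.filter_min_size(min_size, universe=universe)
    results = []
    null_nes_all = []
    for name, members in sets.sets.items():
        member_set = set(members) & universe
        if len(member_set) == 0 or len(member_set) >= len(ranked_genes):
            warnings.warn(f"set {name!r} empty or spans the whole universe; skipped")
            continue
        _, es = running_enrichment_score(ranked_genes, ranked_scores, member_set, weight_p)
        size = len(member_set)
        null_es = np.empty(n_perm)
        gene_arr = np.array(ranked_genes, dtype=object)
        for b in range(n_perm):
            draw = set(gene_arr[rng.choice(len(gene_arr), size=size, replace=False)])
            _, null_es[b] = running_enrichment_score(ranked_genes, ranked_scores, draw, weight_p)
        pos = null_es[null_es >= 0]
        neg = null_es[null_es < 0]
        if es >= 0:
            p = (np.sum(pos >= es) + 1) / (len(pos) + 1)
            nes = es / pos.mean() if len(pos) and pos.mean() > 0 else np.nan
        else:
            p = (np.sum(neg <= es) + 1) / (len(neg) + 1)
            nes = -es / neg.mean() if len(neg) and neg.mean() < 0 else np.nan
        null_nes = np.concatenate([
            pos / pos.mean() if len(pos) and pos.mean() > 0 else np.empty(0),
            -(neg / neg.mean()) if len(neg) and neg.mean() < 0 else np.empty(0),
        ])
        null_nes_all.append(null_nes)
        results.append({"set": name, "size": size, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(results, columns=["set", "size", "es", "nes", "p"])
    if len(out) == 0:
        out["q"] = []
        return out
    # FDR from the pooled null NES distribution, per sign, as in the
    # original procedure
    pooled = np.concatenate(null_nes_all) if null_nes_all else np.empty(0)
    qs = np.full(len(out), np.nan)
    for i, row in out.iterrows():
        nes = row["nes"]
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            frac_null = np.mean(pooled >= nes) if pooled.size else np.nan
            obs = out["nes"][np.isfinite(out["nes"])]
            frac_obs = np.mean(obs >= nes)
        else:
            frac_null = np.mean(pooled <= nes) if pooled.size else np.nan
            obs = out["nes"][np.isfinite(out["nes"])]
            frac_obs = np.mean(obs <= nes)
        qs[i] = min(1.0, frac_null / frac_obs) if frac_obs > 0 else np.nan
    out["q"] = qs
    return out


def hypergeometric_enrichment(module_genes, annotation_set, background) -> float:
    """Upper-tail hypergeometric p for the overlap of a module with an
    annotation, both intersected with the background universe."""
    bg = set(background)
    module = set(module_genes) & bg
    anno = set(annotation_set) & bg
    if not set(module_genes) <= bg:
        raise ValueError("module genes must be a subset of the background")
    k = len(module & anno)
    return float(hypergeom.sf(k - 1, len(bg), len(anno), len(module)))
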