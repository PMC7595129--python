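"""TF binding-site overlap enrichment among eQTL classes.

Observed eQTLs fall into three classes (specific to either environment,
or common).  For each TF, the observed number of class members inside
binding sites is compared with a null in which sets of the same three
class sizes are drawn simultaneously (a random partition of the eligible
variant pool, without replacement) ``n_draws`` times.  The enrichment
ratio is observed over null mean, and the one-sided empirical p uses the
add-one convention in the direction of the observed deviation, so p is
never zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, TfbsIntervalSet
from .varcomp import bh_adjust


def overlap_mask(variants: pd.DataFrame, sites: TfbsIntervalSet) -> np.ndarray:
    """Boolean mask: variant (1-based pos) inside any interval of the TF.

    A BED interval [s, e) contains 1-based position p iff s < p <= e;
    a variant counts once per TF no matter how many intervals cover it.
    """
    mask = np.zeros(len(variants), dtype=bool)
    for chrom, ivs in sites.intervals.groupby("chrom"):
        sel = variants["chrom"] == chrom
        if not sel.any():
            continue
        pos = variants.loc[sel, "pos"].to_numpy()
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        # merge overlapping intervals so membership is a sorted-interval search
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        idx = np.searchsorted(ms, pos, side="left") - 1  # last interval with s < p
        hit = (idx >= 0) & (pos <= me[np.maximum(idx, 0)])
        mask[np.flatnonzero(sel.to_numpy())[hit]] = True
    return mask


def overlap_count(variants: pd.DataFrame, sites: TfbsIntervalSet) -> int:
    """Number of variants overlapping the TF's binding sites."""
    return int(overlap_mask(variants, sites).sum())


def permutation_enrichment(classes: dict, pool: pd.Index,
                           genos: GenotypeMatrix, sites: list,
                           n_draws: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Class-size-matched resampling test of binding-site overlap.

    ``classes`` maps class label -> iterable of variant IDs (disjoint
    subsets of ``pool``, the post-MAF-filter variant universe).  Each of
    the ``n_draws`` iterations permutes the pool once and slices it into
    the observed class sizes, so all classes are matched simultaneously.
    Returns one row per TF x class with observed count, null mean, ratio,
    direction, one-sided empirical p and BH q across all tests.
    """
    rng = np.random.default_rng(seed)
    pool = pd.Index(pool)
    pool_pos = {v: i for i, v in enumerate(pool)}
    labels, sizes, obs_idx = [], [], []
    for label, vids in classes.items():
        vids = list(vids)
        if len(vids) == 0:
            warnings.warn(f"class {label!r} empty; skipped")
            continue
        missing = [v for v in vids if v not in pool_pos]
        if missing:
            raise ValueError(f"class {label!r} has variants outside the pool: {missing[:3]}")
        labels.append(label)
        sizes.append(len(vids))
        obs_idx.append(np.array([pool_pos[v] for v in vids]))
    if not labels:
        return pd.DataFrame(columns=["tf", "class", "observed", "null_mean",
                                     "ratio", "direction", "p", "q"])
    total = int(np.sum(sizes))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    # one permutation of the pool per draw; slices give the matched partition
    draws = np.empty((n_draws, total), dtype=np.int64)
    n_pool = len(pool)
    for b in range(n_draws):
        draws[b] = rng.permutation(n_pool)[:total]
    var_table = genos.variants.loc[pool]
    rows = []
    for ts in sites:
        hit = overlap_mask(var_table, ts)
        null_counts = hit[draws]  # n_draws x total booleans
        for ci, label in enumerate(labels):
            sl = slice(bounds[ci], bounds[ci + 1])
            null = null_counts[:, sl].sum(axis=1)
            observed = int(hit[obs_idx[ci]].sum())
            mu = float(null.mean())
            ratio = observed / mu if mu > 0 else np.nan
            if observed >= mu:
                direction = "enrichment"
                p = (np.sum(null >= observed) + 1) / (n_draws + 1)
            else:
                direction = "depletion"
                p = (np.sum(null <= observed) + 1) / (n_draws + 1)
            rows.append({"tf": ts.tf, "class": label, "observed": observed,
                         "null_mean": mu, "ratio": ratio, "direction": direction,
                         "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out
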