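"""Expression-matrix hygiene: rank-based normal-quantile transformation
anchored at robust location/scale, and advisory outlier-sample flagging.

The transform maps each gene's values monotonically onto normal scores
with mean equal to the median and standard deviation equal to the median
absolute deviation times 1.4824 (the consistency factor for a normal
distribution), so the robust location and scale of the input are
preserved while the shape becomes Gaussian.  It is applied within sex:
the analysis downstream is fully sex-stratified.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import ExpressionStudy

MAD_FACTOR = 1.4824


def quantile_normal_transform(values) -> np.ndarray:
    """Normal-quantile transform anchored at median and MAD x 1.4824.

    Normal scores are taken at plotting positions (rank - 0.5)/n; tied
    values receive the average score of their rank span.  A constant
    input is returned unchanged with a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least three finite values")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    if mad == 0 and np.all(x[finite] == med):
        warnings.warn("all values identical; transform undefined, input returned")
        return x.copy()
    n = finite.sum()
    order = np.argsort(x[finite], kind="stable")
    scores_by_rank = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    scores = np.empty(n)
    scores[order] = scores_by_rank
    # ties: average the scores over each tied span
    df = pd.DataFrame({"v": x[finite], "s": scores})
    scores = df.groupby("v")["s"].transform("mean").to_numpy()
    out = np.full_like(x, np.nan)
    out[finite] = med + MAD_FACTOR * mad * scores
    return out


def transform_study(study: ExpressionStudy) -> ExpressionStudy:
    """Apply the normal-quantile transform per gene, within each sex."""
    expr = study.expr.copy()
    for _, cols in study.meta.groupby("sex").groups.items():
        block = expr[cols].to_numpy()
        for i in range(block.shape[0]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                block[i] = quantile_normal_transform(block[i])
        expr[cols] = block
    return ExpressionStudy(expr, study.meta)


def detect_outlier_samples(study: ExpressionStudy, k: float = 3.0) -> list:
    """Flag samples that correlate poorly with their stratum.

    Within each sex x environment stratum, each gene is z-scaled across
    samples, the sample-sample Pearson correlation matrix is computed,
    and a sample is flagged when the robust z-score of its mean
    correlation with the other samples (relative to the stratum median
    and MAD x 1.4824) falls below -k.  Deterministic; strata with fewer
    than four samples are skipped with a warning.
    """
    flagged = []
    for (sex, env), idx in study.meta.groupby(["sex", "environment"]).groups.items():
        samples = list(idx)
        if len(samples) < 4:
            warnings.warn(f"stratum sex={sex} env={env} too small; skipped")
            continue
        X = study.expr[samples].to_numpy()
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        C = np.corrcoef(Z.T)
        np.fill_diagonal(C, np.nan)
        mean_corr = np.nanmean(C, axis=1)
        med = np.median(mean_corr)
        mad = np.median(np.abs(mean_corr - med))
        if mad == 0:
            continue
        z = (mean_corr - med) / (MAD_FACTOR * mad)
        flagged.extend([s for s, zi in zip(samples, z) if zi < -k])
    return flagged


def drop_samples(study: ExpressionStudy, sample_ids) -> ExpressionStudy:
    keep = ~study.meta.index.isin(list(sample_ids))
    return study.subset_samples(pd.Series(keep, index=study.meta.index))
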