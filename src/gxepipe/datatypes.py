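"""Core in-memory containers shared across the pipeline.

Everything is pandas-backed: an expression study is a genes x samples
DataFrame plus a sample-metadata DataFrame, and a genotype panel is a
variants x lines 0/1 DataFrame plus a variant table.  Lines are fully
inbred, so a single allele code per line suffices (0 = reference
homozygote, 1 = alternate homozygote).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_META_COLUMNS = ("line", "environment", "sex", "replicate")


@dataclass
class ExpressionStudy:
    """Gene expression matrix with its sample design.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples; row index are gene IDs, columns sample IDs.
    meta : DataFrame
        One row per sample (index = sample ID) with at least columns
        ``line``, ``environment``, ``sex``, ``replicate``; any further
        columns are treated as covariates (e.g. a Wolbachia-infection
        flag).
    """

    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.meta.index.has_duplicates:
            raise ValueError("duplicated sample IDs in metadata")
        if self.expr.columns.has_duplicates:
            raise ValueError("duplicated sample IDs in expression matrix")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if list(self.expr.columns) != list(self.meta.index):
            # allow reordering but not mismatch
            if set(self.expr.columns) != set(self.meta.index):
                raise ValueError("expression columns and metadata samples differ")
            self.meta = self.meta.loc[self.expr.columns]

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def environments(self) -> list:
        return sorted(self.meta["environment"].unique())

    def covariate_columns(self) -> list:
        return [c for c in self.meta.columns if c not in REQUIRED_META_COLUMNS]

    def subset_samples(self, mask: pd.Series) -> "ExpressionStudy":
        keep = self.meta.index[np.asarray(mask, dtype=bool)]
        return ExpressionStudy(self.expr[keep], self.meta.loc[keep])

    def split_by_environment(self) -> dict:
        return {
            env: self.subset_samples(self.meta["environment"] == env)
            for env in self.environments
        }


@dataclass
class GenotypeMatrix:
    """Biallelic homozygous genotypes for an inbred panel.

    ``calls`` is variants x lines with entries in {0, 1}; ``variants``
    carries ``chrom`` and ``pos`` (1-based) indexed by variant ID, with
    positions sorted within chromosome.
    """

    calls: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.variants.index):
            raise ValueError("variant IDs of calls and variant table differ")
        vals = self.calls.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype calls must be 0/1 (inbred panel)")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")

    @property
    def lines(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_lines(self) -> int:
        return self.calls.shape[1]

    def maf(self) -> pd.Series:
        freq = self.calls.mean(axis=1)
        return pd.Series(np.minimum(freq, 1.0 - freq), index=self.calls.index, name="maf")

    def filter_maf(self, maf_min: float) -> "GenotypeMatrix":
        keep = self.maf() > maf_min
        return GenotypeMatrix(self.calls.loc[keep], self.variants.loc[keep])


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def filter_min_size(self, min_size: int, universe=None) -> "GeneSetCollection":
        out = {}
        for name, genes in self.sets.items():
            g = list(genes)
            if universe is not None:
                uni = set(universe)
                g = [x for x in g if x in uni]
            if len(g) >= min_size:
                out[name] = g
        return GeneSetCollection(out, {k: self.descriptions.get(k, "") for k in out})

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TfbsIntervalSet:
    """Binding-site intervals for one TF, BED convention (0-based, half-open)."""

    tf: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("intervals must satisfy start < end")
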