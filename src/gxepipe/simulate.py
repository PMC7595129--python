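"""Synthetic-data generator emulating a two-temperature inbred-panel study.

Ground truth is explicit: per-gene variance components, causal variants
with per-environment effects, a binary line covariate (Wolbachia-style),
TF binding-site intervals, gene sets, and per-gene mutational/standing
variance pairs for the stabilizing-selection analysis.  Every stage of
the pipeline can therefore be tested by parameter recovery without any
external download.

The generative model per gene g, line i, environment j, replicate k is

    y = intercept + env_j + beta_cov * w_i + sum_v x_iv * b_vj
        + a_ij + e_ijk,

where (a_iA, a_iB) are bivariate-normal line effects with per-environment
variances sigma2_G,A / sigma2_G,B and cross-environment covariance
c = (sigma2_G,A + sigma2_G,B)/2 - sigma2_GE, and e is iid
N(0, sigma2_e).  With equal per-environment variances this is exactly the
shared-G plus line-by-environment interaction model (G variance c, GxE
variance sigma2_GE); unequal per-environment variances additionally give
variance heterogeneity.  Line effects are drawn once per line (and
environment) and shared across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSetCollection, GenotypeMatrix, TfbsIntervalSet

_MAF_EPS = 1e-9


@dataclass
class StudyDesign:
    """Shape of the simulated study (single sex; sexes are independent runs)."""

    n_lines: int = 185
    n_reps: int = 2
    environments: tuple = ("18C", "25C")
    covariate_prevalence: float = 0.5
    sex: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least two lines")
        if self.n_reps < 2:
            raise ValueError("need at least two replicates per line x environment")
        if len(self.environments) != 2:
            raise ValueError("exactly two environments")


@dataclass
class SimulationTruth:
    """Known ground truth for a simulated study.

    ``gene_params`` columns: intercept, env_effect, covariate_effect,
    sigma2_G_envA, sigma2_G_envB, sigma2_GE, sigma2_e, module; index =
    gene IDs.  ``causal_variants`` maps gene -> list of
    (variant_id, effect_envA, effect_envB).  ``selection`` (optional)
    holds V_m and V_g per gene.
    """

    gene_params: pd.DataFrame
    causal_variants: dict = field(default_factory=dict)
    selection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        var_cols = ["sigma2_G_envA", "sigma2_G_envB", "sigma2_GE", "sigma2_e"]
        if (self.gene_params[var_cols] < 0).any().any():
            raise ValueError("variance parameters must be non-negative")
        # genetic covariance must be a valid bivariate-normal covariance
        gp = self.gene_params
        c = 0.5 * (gp["sigma2_G_envA"] + gp["sigma2_G_envB"]) - gp["sigma2_GE"]
        bound = np.sqrt(gp["sigma2_G_envA"] * gp["sigma2_G_envB"])
        if (c < -_MAF_EPS).any() or (c > bound + 1e-9).any():
            raise ValueError("sigma2_GE incompatible with per-environment genetic variances")

    @property
    def genes(self) -> pd.Index:
        return self.gene_params.index

    def gxe_index(self) -> pd.Series:
        """sigma2_GE / (sigma2_GE + sigma2_G) with the shared-G parametrization."""
        gp = self.gene_params
        shared = 0.5 * (gp["sigma2_G_envA"] + gp["sigma2_G_envB"]) - gp["sigma2_GE"]
        tot = shared + gp["sigma2_GE"]
        out = gp["sigma2_GE"] / tot
        out[tot <= 0] = np.nan
        return out

    def to_json_dict(self) -> dict:
        return {
            "gene_params": self.gene_params.reset_index().rename(columns={"index": "gene"}).to_dict(orient="list"),
            "causal_variants": {g: [list(v) for v in vs] for g, vs in self.causal_variants.items()},
            "selection": None if self.selection is None
            else self.selection.reset_index().rename(columns={"index": "gene"}).to_dict(orient="list"),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimulationTruth":
        gp = pd.DataFrame(d["gene_params"]).set_index("gene")
        sel = None
        if d.get("selection"):
            sel = pd.DataFrame(d["selection"]).set_index("gene")
        cv = {g: [tuple(v) for v in vs] for g, vs in d.get("causal_variants", {}).items()}
        return cls(gp, cv, sel)


def make_truth(n_genes: int,
               sigma2_G: float = 1.0,
               sigma2_GE: float = 0.5,
               sigma2_e: float = 0.5,
               sigma2_G_envA=None,
               sigma2_G_envB=None,
               covariate_effect: float = 0.0,
               n_modules: int = 1,
               seed: int = 0) -> SimulationTruth:
    """Convenience constructor with homogeneous variance components.

    ``sigma2_G`` is the shared (cross-environment) genetic variance; the
    per-environment genetic variances default to sigma2_G + sigma2_GE.
    Pass ``sigma2_G_envA``/``sigma2_G_envB`` (scalars or arrays) to plant
    variance heterogeneity instead.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    if sigma2_G_envA is None:
        sigma2_G_envA = sigma2_G + sigma2_GE
    if sigma2_G_envB is None:
        sigma2_G_envB = sigma2_G + sigma2_GE
    gp = pd.DataFrame({
        "intercept": np.zeros(n_genes),
        "env_effect": np.zeros(n_genes),
        "covariate_effect": np.full(n_genes, float(covariate_effect)),
        "sigma2_G_envA": np.broadcast_to(np.asarray(sigma2_G_envA, dtype=float), n_genes).copy(),
        "sigma2_G_envB": np.broadcast_to(np.asarray(sigma2_G_envB, dtype=float), n_genes).copy(),
        "sigma2_GE": np.broadcast_to(np.asarray(sigma2_GE, dtype=float), n_genes).copy(),
        "sigma2_e": np.broadcast_to(np.asarray(sigma2_e, dtype=float), n_genes).copy(),
        "module": rng.integers(0, n_modules, size=n_genes),
    }, index=pd.Index(genes, name="gene"))
    return SimulationTruth(gp)


# ------------------------------------------------------------------ genotypes

def generate_genotypes(n_lines: int, n_variants: int,
                       maf_low: float = 0.05, maf_high: float = 0.5,
                       ld_block_size: int = 1, ld_flip_prob: float = 0.05,
                       chrom: str = "2L", seed: int = 0) -> GenotypeMatrix:
    """Biallelic homozygous genotypes with optional blockwise LD.

    The head variant of each block is drawn Bernoulli(f), f ~
    U(maf_low, maf_high), and redrawn until the realized minor-allele
    frequency reaches ``maf_low``; the remaining block members are copies
    of their predecessor with per-line allele flips at ``ld_flip_prob``
    (monomorphic copies are redrawn), giving correlation that decays
    along the block.  Positions are strictly increasing, 1-based.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n_lines < 2:
        raise ValueError("need at least two lines")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    rng = np.random.default_rng(seed)
    calls = np.empty((n_variants, n_lines), dtype=np.int8)
    for v in range(n_variants):
        if v % ld_block_size == 0:
            for _ in range(1000):
                f = rng.uniform(maf_low, maf_high)
                col = (rng.random(n_lines) < f).astype(np.int8)
                maf = min(col.mean(), 1 - col.mean())
                if maf >= maf_low - _MAF_EPS:
                    break
            else:  # pragma: no cover - pathological bounds
                raise RuntimeError("could not realize requested MAF range")
            calls[v] = col
        else:
            for _ in range(1000):
                flips = rng.random(n_lines) < ld_flip_prob
                col = np.where(flips, 1 - calls[v - 1], calls[v - 1]).astype(np.int8)
                if 0 < col.mean() < 1:
                    break
            calls[v] = col
    pos = np.cumsum(rng.integers(50, 500, size=n_variants))
    variants = pd.DataFrame({"chrom": chrom, "pos": pos},
                            index=pd.Index([f"var{v:06d}" for v in range(n_variants)], name="variant"))
    lines = [f"line{i:03d}" for i in range(n_lines)]
    return GenotypeMatrix(pd.DataFrame(calls, index=variants.index, columns=lines), variants)


# ----------------------------------------------------------------- expression

def generate_expression(design: StudyDesign, truth: SimulationTruth,
                        genotypes: GenotypeMatrix | None = None) -> ExpressionStudy:
    """Simulate replicate-level expression under the generative model.

    Line and line-by-environment effects are drawn once per line (and
    environment) and reused across replicates; the binary covariate is
    assigned per line at ``design.covariate_prevalence``.
    """
    rng = np.random.default_rng(design.seed)
    n_genes = len(truth.genes)
    if genotypes is not None:
        lines = list(genotypes.lines[: design.n_lines])
        if len(lines) < design.n_lines:
            raise ValueError("genotype panel has fewer lines than the design")
    else:
        lines = [f"line{i:03d}" for i in range(design.n_lines)]
    L, r = design.n_lines, design.n_reps
    env_a, env_b = design.environments
    covariate = (rng.random(L) < design.covariate_prevalence).astype(int)

    gp = truth.gene_params
    vA = gp["sigma2_G_envA"].to_numpy()
    vB = gp["sigma2_G_envB"].to_numpy()
    c = 0.5 * (vA + vB) - gp["sigma2_GE"].to_numpy()
    # bivariate-normal line effects via explicit Cholesky
    z1 = rng.standard_normal((n_genes, L))
    z2 = rng.standard_normal((n_genes, L))
    sdA = np.sqrt(vA)
    with np.errstate(divide="ignore", invalid="ignore"):
        b21 = np.where(vA > 0, c / np.maximum(sdA, _MAF_EPS), 0.0)
    b22 = np.sqrt(np.maximum(vB - b21**2, 0.0))
    a_envA = sdA[:, None] * z1
    a_envB = b21[:, None] * z1 + b22[:, None] * z2

    # genetic (eQTL) fixed effects per environment
    qtl = {env_a: np.zeros((n_genes, L)), env_b: np.zeros((n_genes, L))}
    if truth.causal_variants:
        if genotypes is None:
            raise ValueError("truth has causal variants but no genotypes were supplied")
        gidx = {g: i for i, g in enumerate(truth.genes)}
        calls = genotypes.calls[lines]
        for gene, variants in truth.causal_variants.items():
            if gene not in gidx:
                raise ValueError(f"causal-variant entry for unknown gene {gene!r}")
            for vid, eff_a, eff_b in variants:
                if vid not in calls.index:
                    raise ValueError(f"causal variant {vid!r} not in the genotype panel")
                x = calls.loc[vid].to_numpy(dtype=float)
                qtl[env_a][gidx[gene]] += eff_a * x
                qtl[env_b][gidx[gene]] += eff_b * x

    cols, metas, blocks = [], [], []
    sd_e = np.sqrt(gp["sigma2_e"].to_numpy())[:, None]
    mu = gp["intercept"].to_numpy()[:, None]
    env_eff = gp["env_effect"].to_numpy()[:, None]
    cov_eff = gp["covariate_effect"].to_numpy()[:, None]
    for env, a_line, env_sign in ((env_a, a_envA, 0.5), (env_b, a_envB, -0.5)):
        for k in range(r):
            e = sd_e * rng.standard_normal((n_genes, L))
            block = mu + env_sign * env_eff + cov_eff * covariate[None, :] + qtl[env] + a_line + e
            blocks.append(block)
            for i, line in enumerate(lines):
                cols.append(f"{line}_{env}_{design.sex}_r{k + 1}")
            metas.extend(
                {"sample_id": f"{line}_{env}_{design.sex}_r{k + 1}", "line": line,
                 "environment": env, "sex": design.sex, "replicate": k + 1,
                 "covariate": int(covariate[i])}
                for i, line in enumerate(lines)
            )
    expr = pd.DataFrame(np.concatenate(blocks, axis=1), index=truth.genes, columns=cols)
    meta = pd.DataFrame(metas).set_index("sample_id")
    return ExpressionStudy(expr, meta)


# ---------------------------------------------------------------- annotations

def generate_annotations(genotypes: GenotypeMatrix, genes,
                         n_tfs: int = 5, site_density_per_kb: float = 0.5,
                         set_sizes=(25, 40, 60), site_length=(5, 20),
                         seed: int = 0) -> tuple[list[TfbsIntervalSet], GeneSetCollection]:
    """Random TF binding-site intervals (BED convention) and gene sets (GMT).

    Interval counts per TF are Poisson(density x chromosome span in kb)
    with uniform starts; gene sets are uniform draws of the requested
    sizes from the gene universe.
    """
    if site_density_per_kb <= 0:
        raise ValueError("site_density_per_kb must be > 0")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sites = []
    for t in range(n_tfs):
        tf = f"TF{t + 1}"
        ivs = []
        for chrom, grp in genotypes.variants.groupby("chrom", sort=False):
            span = int(grp["pos"].max())
            n_sites = rng.poisson(site_density_per_kb * span / 1000.0)
            starts = np.sort(rng.integers(0, max(span - site_length[1], 1), size=n_sites))
            lengths = rng.integers(site_length[0], site_length[1] + 1, size=n_sites)
            for s, ln in zip(starts, lengths):
                ivs.append((chrom, int(s), int(min(s + ln, span))))
        if not ivs:
            ivs.append((genotypes.variants["chrom"].iloc[0], 0, site_length[1]))
        sites.append(TfbsIntervalSet(tf, pd.DataFrame(ivs, columns=["chrom", "start", "end"])))
    sets = {}
    for si, size in enumerate(set_sizes):
        size = min(size, len(genes))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET{si + 1}"] = sorted(members)
    return sites, GeneSetCollection(sets, {k: "synthetic gene set" for k in sets})


# ----------------------------------------------- coordinated plasticity pairs

def simulate_coordinated_plasticity(n_genes: int, n_lines: int, coordination: float,
                                    loading=(0.4, 0.8), rho=(0.3, 0.7),
                                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired line-level expression matrices with tunable response coordination.

    Baseline expression carries a shared co-expression factor (per-gene
    loadings uniform in ``loading``).  Treatment expression keeps each
    gene's cross-environment correlation (uniform in ``rho``) while the
    innovations are a mixture of a factor-structured component (weight
    ``coordination``) and independent noise.  ``coordination = 0``
    reproduces the independent-plasticity null; larger values preserve
    the baseline correlation structure across environments, shrinking
    the variance of pairwise correlation changes.
    """
    if not 0.0 <= coordination <= 1.0:
        raise ValueError("coordination must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    load = rng.uniform(*loading, n_genes)
    u = rng.standard_normal(n_lines)
    Xb = load[:, None] * u[None, :] + np.sqrt(1 - load**2)[:, None] * rng.standard_normal((n_genes, n_lines))
    zb = (Xb - Xb.mean(1, keepdims=True)) / Xb.std(1, ddof=1, keepdims=True)
    r = rng.uniform(*rho, n_genes)
    v = rng.standard_normal(n_lines)
    w_corr = load[:, None] * v[None, :] + np.sqrt(1 - load**2)[:, None] * rng.standard_normal((n_genes, n_lines))
    w_ind = rng.standard_normal((n_genes, n_lines))
    w = np.sqrt(coordination) * w_corr + np.sqrt(1 - coordination) * w_ind
    Xt = r[:, None] * zb + np.sqrt(1 - r**2)[:, None] * w
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    lines = [f"line{j:03d}" for j in range(n_lines)]
    return (pd.DataFrame(Xb, index=genes, columns=lines),
            pd.DataFrame(Xt, index=genes, columns=lines))


# ------------------------------------------------------ stabilizing selection

def generate_selection_params(truth: SimulationTruth, coupling: float,
                              connectivity, seed: int = 0,
                              vm_scale: float = 0.01) -> pd.DataFrame:
    """Per-gene (V_m, V_g) with rank-coupled selection strength.

    The log selection ratio V_m/V_g is generated from a Gaussian copula
    against the supplied per-gene ``connectivity`` vector so that the
    Spearman correlation between connectivity and V_m/V_g converges to
    ``coupling`` as the number of genes grows (Pearson rho of the copula
    is 2 sin(pi * c / 6)).
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    x = np.asarray(connectivity, dtype=float)
    if len(x) != len(genes):
        raise ValueError("connectivity vector must cover all genes")
    n = len(x)
    # normal scores of the connectivity ranks
    ranks = pd.Series(x).rank(method="average").to_numpy()
    from scipy.stats import norm

    zx = norm.ppf((ranks - 0.5) / n)
    rho = 2.0 * np.sin(np.pi * coupling / 6.0)
    z = rho * zx + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n)
    ratio = np.exp(0.5 * z)  # lognormal selection strength, V_m/V_g
    v_g = np.exp(rng.normal(0.0, 0.5, size=n))
    v_m = vm_scale * ratio * v_g
    sel = pd.DataFrame({"V_m": v_m, "V_g": v_g, "strength": v_m / v_g}, index=genes)
    truth.selection = sel
    return sel
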