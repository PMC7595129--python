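# Methods

## Study design and models

The observational unit is one replicate measurement of one inbred line
in one environment; the design crossed by the pipeline is lines ×
2 environments × replicates, analysed separately per sex (sexes are
treated as independent studies throughout — no cross-sex parameter is
ever shared).

**Single-environment partition.** Per gene, y = Xβ + line + e with the
line effect random, N(0, σ²_G), and residual N(0, σ²_e).  X holds an
intercept plus optional line-constant covariates (e.g. a binary
endosymbiont-infection flag).  For balanced data the restricted
likelihood factorizes into two independent strata — within-line
(E[MS] = σ²_e) and between-line (E[MS] = σ²_e + r·σ²_G) — so REML is
closed-form.  Reported estimates follow the classical ANOVA convention:
σ̂²_e = MS_within and σ̂²_G = max(0, (MS_between − MS_within)/r).  The
test of σ²_G > 0 is a likelihood-ratio statistic between the
non-negativity-constrained fit and the null (σ²_G = 0, variances pooled
across strata), referred to the boundary mixture ½χ²₀ + ½χ²₁; an LRT of
exactly 0 reports p = 1.  Unbalanced data go through an iterative
profile-REML on the variance ratio with per-line Woodbury algebra; a
line with a single replicate contributes only to the between-line
stratum.

**Combined G + G×E model.** Pooling both environments,
y = Xβ + line + line:environment + e, with X containing environment,
covariates, and their interaction.  The balanced layout yields three
orthogonal strata with expected mean squares σ²_e, σ²_e + r·σ²_GE, and
σ²_e + r·σ²_GE + 2r·σ²_G.  Constrained REML is the ordered
(pool-adjacent-violators) solution on the three stratum mean squares;
boundary LRTs for σ²_GE and σ²_G use the same mixture null.  The G×E
index is σ²_GE/(σ²_GE + σ²_G), undefined (NaN) when both components
vanish.  The whole fit consumes only per-gene sums of squares, so a
2000-gene panel fits in well under a second.

**Variance heterogeneity.** The heterogeneity model treats the two
environments' line effects as independent with per-environment
variances; the LRT compares a shared parameter for the tested component
(σ²_G or σ²_e) against environment-specific ones, with the *other*
component left environment-specific in both models.  The constrained
optimum is found by profiling: for shared σ²_e the per-environment
between-line variances have a closed inner maximum; for shared σ²_G a
1-D outer search profiles each environment's residual variance by a
nested scalar optimization.  The null parameter value is interior, so p
comes from χ²₁.  Because the model assumes independence of line effects
across environments, its type-I calibration is assessed under data with
independent per-environment line effects; with a strongly shared
genetic effect the test is conservative (the two variance estimates are
positively correlated), never anti-conservative.  Fold change is the
larger over the smaller per-environment moment estimate of the tested
component (infinite if one is zero, NaN if both are).

**Canalization classes.** A gene is *decanalized* in the treatment
environment when the heterogeneity q ≤ α (BH within the test family),
the fold change is at least the threshold (defaults α = 0.05, fold = 2),
σ²_G is larger in the treatment environment, and σ²_G is significant
there; *canalized* is the mirror condition; otherwise *stable*.

## Scores and enrichment

The decanalization score (σ²_G,treat − σ²_G,base)/(σ²_G,treat +
σ²_G,base) and the G×E score 2·G×E − 1 both live in [−1, 1]; callers
are expected to restrict to genes with at least one significant genetic
variance (decanalization) or a significant genetic component (G×E), as
the pipeline driver does.  Preranked GSEA ranks genes by score
descending (ties broken by gene ID for determinism); the running sum
increments by |score|^p normalized over the set at members (weight
p = 1 by default — the exponent is configurable since the classical
unweighted form corresponds to p = 0) and decrements by 1/(N − N_set)
otherwise; ES is the maximum deviation from zero.  Significance uses
random same-size gene draws (default 1000, seeded), with NES, p, and
FDR computed separately on the positive and negative sides as in the
original procedure; a phenotype permutation is not available for a
preranked list, so gene-label draws are the null.  Sets are filtered to
≥ 20 members inside the universe.  Fixed gene lists use an upper-tail
hypergeometric test against a caller-supplied background.

## eQTL mapping

Association operates on line BLUPs: per gene and environment, fixed
effects are estimated on line means and the centred line mean of line i
is shrunk by λ_i = σ̂²_G/(σ̂²_G + σ̂²_e/n_i),
reducing to centred line means when σ̂²_e = 0
and to zero when σ̂²_G = 0.  For homozygous 0/1 allele codes the
regression-slope t equals the equal-variance two-sample t between
allele classes (df = n_lines − 2); variants are filtered at MAF > 0.05.

The empirical FDR permutes the line labels of the whole BLUP matrix
jointly (all genes move together, preserving gene–gene correlation; 100
permutations by default), remaps, and estimates FDR(t) as the mean
permuted discovery count over the observed count, clipped at 1.
Candidate thresholds include the smallest few thousand observed
p-values exactly — the discovery region is in the extreme tail, where a
quantile grid would be too coarse — plus a quantile grid for the body;
the reported threshold is the largest t with FDR(t) ≤ α.

Forward selection admits, per step, the candidate with the smallest
conditional p (partial t in the joint regression on the current model)
while that p < 10⁻⁵; ties break by (chromosome, position, variant ID)
and candidates collinear with the model are skipped.  On small
candidate sets the procedure is verified against an exhaustive search
over all subsets under the same entry rule, including perfect-LD twins
(exactly one of the pair enters, the earlier by position).

Cross-environment comparison: a gene×variant pair retained by model
selection in at least one environment is *shared* if it was mapped
(pre-selection significant) in both environments, otherwise
environment-specific; effects in both environments are reported for all
classified pairs regardless of significance in the other environment.
Prediction into the other environment sums allele codes times the
training-environment effects and scores the per-gene Pearson r against
observed BLUPs.

## TFBS overlap

BED intervals are 0-based half-open; a variant at 1-based position p
overlaps [s, e) iff s < p ≤ e, and counts once per TF regardless of how
many intervals cover it.  The null draws, in each of 10,000 iterations,
one permutation of the eligible pool (all variants tested for
association) sliced into the observed class sizes — all classes matched
simultaneously.  The enrichment ratio is observed over null mean; the
one-sided empirical p uses the (k+1)/(n+1) convention counting
more-extreme-or-equal draws in the observed direction, so p is never 0.
Draws are matched on class size only, not on allele frequency.

## Co-expression robustness

Connectivity is the mean absolute Pearson correlation of a gene with
all other genes, computed on line-level expression (line means by
default; BLUPs are accepted).  The Δr test estimates per-gene (μ, σ, ρ)
by sample moments on line-level values, simulates each gene's
treatment-environment expression as Y = σ₂(ρZ₁ + √(1−ρ²)Z₂) + μ₂ with
independent standard-normal Z₂ per line and gene, and compares the
observed variance of upper-triangle Δr = r_treat − r_base against the
simulated null (default 1000 simulations; empirical p =
(#{null ≤ observed}+1)/(n+1), one-sided toward smaller variance =
coordinated plasticity).  The default gene subset is the significant
G×E genes when available.  Zero-variance genes are excluded with a
warning; an exact-copy input yields a degenerate-statistic warning.
The connectivity–selection analysis reports Spearman correlations of
connectivity with V_m/V_g overall and per G×E stratum.

## Synthetic data

Per gene, line i, environment j, replicate k:
y = intercept + env_j + β_cov·w_i + Σ_v x_iv·b_vj + a_ij + e_ijk.  Line
effects (a_iA, a_iB) are bivariate normal with per-environment
variances σ²_G,A and σ²_G,B and cross-environment covariance
c = (σ²_G,A + σ²_G,B)/2 − σ²_GE; with equal per-environment variances
this is exactly the shared-G (variance c) plus interaction (variance
σ²_GE) model, and unequal ones additionally plant variance
heterogeneity.  Effects are drawn once per line×environment and shared
across replicates.  Genotypes are 0/1 per line (a fully inbred panel;
0/2 coding would only rescale effects), with blockwise copy-with-flip
LD — sufficient to exercise forward selection under collinearity
without a coalescent simulation.  Default study shape mirrors the
target design: 185 lines, 2 replicates per line × environment × sex,
two environments, a binary line covariate at 50 % prevalence.  Default
variance components for recovery studies are σ²_G = 1, σ²_GE = 0.5,
σ²_e = 0.5 (so the mean G×E index is 1/3); eQTL effect sizes are
configurable, with the pipeline demo planting large cis effects (2
expression-SD per allele) for 10 % of genes so that the permutation-FDR
and selection stages operate in their intended regime.  The
coordinated-plasticity generator produces paired line-level matrices in
which treatment innovations mix a factor-structured component (sharing
the baseline co-expression factor; weight = the coordination parameter)
with independent noise; coordination 0 is exactly the Δr null, and 0.3
("moderate") is the power fixture.  Selection parameters couple
log(V_m/V_g) to a supplied connectivity vector through a Gaussian
copula with Pearson ρ = 2·sin(π·c/6), so the Spearman correlation
converges to the requested coupling.

What the generator does *not* emulate: array-probe structure, batch or
surrogate-variable structure, realistic LD decay or demography, sex
sharing of genetic effects, non-normal expression distributions.
Passing recovery and calibration tests therefore validates the
estimators under the stated models, not robustness to those real-data
complications; the transform and covariate machinery are the hooks for
handling them on real inputs.

## Numerical choices and problem sizes

Variance floors of 1e-12 guard logarithms; LRT statistics are clipped
at 0; negative moment estimates truncate to 0 after the constrained
likelihoods are computed.  All empirical p-values use add-one rules.
All stochastic stages take explicit seeds and are bit-reproducible; the
pipeline writes plain TSV/JSON so re-runs are byte-comparable.  The
recovery and calibration studies shipped with the package use 2000
genes at 100–200 lines, 300 replicate datasets for Δr calibration (199
simulations each — the add-one p at α = 0.05 then has exact rejection
mass 0.05 under exchangeability), and 20 replicate datasets for Δr
power; these sizes give Monte-Carlo standard errors comfortably inside
the asserted bands while keeping the default suite fast.

## Known limitations

Only two environments are supported; no dominance/epistatic variance;
no kinship-aware association or LD pruning; module detection (WGCNA)
and preservation statistics are out of scope (module labels can be
supplied for descriptive cross-tabulation); surrogate-variable
adjustment must happen upstream.  The heterogeneity LRT is conservative
when genetic effects are strongly shared across environments (see
above).  PLINK's exact single-variant test is not reproduced verbatim;
the slope-t used here is its equivalent for homozygous biallelic data.
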