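"""End-to-end orchestration: simulate or load inputs, run every stage in
dependency order, write plain-text outputs and a machine-readable report.

Stage order: preprocess -> varcomp -> enrichment; varcomp -> eqtl ->
tfbs; varcomp + eqtl -> network.  Every stochastic stage takes its seed
from the config; re-running an identical config produces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import eqtl as eq
from . import io as gio
from . import network as net
from . import preprocess as pre
from . import simulate as sim
from . import tfbs as tf
from . import varcomp as vc


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run.

    Default thresholds: FDR alpha 0.05, twofold heterogeneity, forward
    selection entry P 1e-5, MAF 0.05, 100 eQTL permutations, 10000 TFBS
    draws, 1000 delta-r simulations.  With no input paths a synthetic
    study is generated first.
    """

    outdir: str = "gxepipe_run"
    seed: int = 1
    # synthetic-study shape (used when no expression input is given)
    n_genes: int = 500
    n_lines: int = 100
    n_reps: int = 2
    n_variants: int = 400
    sigma2_G: float = 1.0
    sigma2_GE: float = 0.5
    sigma2_e: float = 0.5
    frac_eqtl_genes: float = 0.1
    eqtl_effect: float = 2.0  # large cis effect on the BLUP scale
    selection_coupling: float = 0.3
    # optional user inputs
    expr_path: str | None = None
    meta_path: str | None = None
    genotype_path: str | None = None  # TSV dialect or .vcf
    bed_path: str | None = None
    gmt_path: str | None = None
    selection_path: str | None = None
    # thresholds
    alpha: float = 0.05
    fold: float = 2.0
    entry_p: float = 1e-5
    maf: float = 0.05
    n_perm: int = 100
    n_draws: int = 10000
    n_sim: int = 1000
    gsea_n_perm: int = 1000
    gsea_min_size: int = 20
    # stage toggles
    transform: bool = True
    outlier_k: float = 4.0
    drop_outliers: bool = False
    stages: tuple = ("preprocess", "varcomp", "enrichment", "eqtl", "tfbs", "network")

    def to_json(self, path) -> None:
        gio.write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(gio.read_json(path))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    rng_seed = cfg.seed
    genos = sim.generate_genotypes(cfg.n_lines, cfg.n_variants, maf_low=cfg.maf,
                                   seed=rng_seed)
    truth = sim.make_truth(cfg.n_genes, sigma2_G=cfg.sigma2_G, sigma2_GE=cfg.sigma2_GE,
                           sigma2_e=cfg.sigma2_e, n_modules=4, seed=rng_seed + 1)
    rng = np.random.default_rng(rng_seed + 2)
    n_eqtl = int(round(cfg.frac_eqtl_genes * cfg.n_genes))
    eqtl_genes = rng.choice(truth.genes.to_numpy(), size=n_eqtl, replace=False)
    maf = genos.maf()
    eligible = maf.index[maf > cfg.maf].to_numpy()
    for g in eqtl_genes:
        vid = rng.choice(eligible)
        # a shared-effect eQTL with an environment-modulated component
        shift = rng.uniform(-0.5, 0.5)
        truth.causal_variants[str(g)] = [(str(vid), cfg.eqtl_effect + shift, cfg.eqtl_effect - shift)]
    design = sim.StudyDesign(n_lines=cfg.n_lines, n_reps=cfg.n_reps, seed=rng_seed + 3)
    study = sim.generate_expression(design, truth, genos)
    sites, sets = sim.generate_annotations(genos, truth.genes, seed=rng_seed + 4)
    # couple selection strength to connectivity measured on baseline line means
    env_b = design.environments[1]
    sub = study.subset_samples(study.meta["environment"] == env_b)
    line_means = sub.expr.T.groupby(sub.meta["line"]).mean().T
    conn = net.connectivity(net.correlation_matrix(line_means))
    sel = sim.generate_selection_params(truth, cfg.selection_coupling, conn.to_numpy(),
                                        seed=rng_seed + 5)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    gio.write_expression(study, inputs / "expression.tsv", inputs / "metadata.tsv")
    gio.write_genotypes_tsv(genos, inputs / "genotypes.tsv")
    gio.write_vcf(genos, inputs / "genotypes.vcf")
    gio.write_bed(sites, inputs / "tfbs.bed")
    gio.write_gmt(sets, inputs / "gene_sets.gmt")
    sel.rename_axis("gene").reset_index().to_csv(inputs / "selection.tsv", sep="\t", index=False,
                                                 float_format="%.10g")
    gio.write_json(truth.to_json_dict(), inputs / "truth.json")
    return study, genos, sites, sets, sel, truth


def _load_inputs(cfg: PipelineConfig):
    study = gio.read_expression(cfg.expr_path, cfg.meta_path)
    genos = sites = sets = sel = None
    if cfg.genotype_path:
        if str(cfg.genotype_path).endswith(".vcf"):
            genos = gio.read_vcf(cfg.genotype_path)
        else:
            genos = gio.read_genotypes_tsv(cfg.genotype_path)
    if cfg.bed_path:
        sites = gio.read_bed(cfg.bed_path)
    if cfg.gmt_path:
        sets = gio.read_gmt(cfg.gmt_path)
    if cfg.selection_path:
        sel = pd.read_csv(cfg.selection_path, sep="\t", index_col="gene")
    return study, genos, sites, sets, sel, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run report (also written
    to ``<outdir>/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    report: dict = {"seed": config.seed, "stages": {}, "thresholds": {
        "alpha": config.alpha, "fold": config.fold, "entry_p": config.entry_p,
        "maf": config.maf, "n_perm": config.n_perm, "n_draws": config.n_draws,
        "n_sim": config.n_sim}}
    if config.expr_path:
        study, genos, sites, sets, sel, truth = _load_inputs(config)
    else:
        study, genos, sites, sets, sel, truth = _simulate_inputs(config, outdir)
    envs = study.environments
    env_treat, env_base = envs[0], envs[1]  # e.g. 18C treatment, 25C baseline
    covs = study.covariate_columns()

    results: dict = {}
    try:
        if "preprocess" in config.stages:
            flagged = pre.detect_outlier_samples(study, k=config.outlier_k)
            report["stages"]["preprocess"] = {"flagged_samples": flagged,
                                              "dropped": bool(config.drop_outliers and flagged)}
            if config.drop_outliers and flagged:
                study = pre.drop_samples(study, flagged)
            if config.transform:
                study = pre.transform_study(study)

        single = combined = het_g = None
        if "varcomp" in config.stages:
            single = vc.varcomp_single_all(study, covs)
            combined = vc.varcomp_combined_all(study, covs)
            het_g = vc.heterogeneity_all(study, "G", covs, treatment_env=env_treat,
                                         alpha=config.alpha, fold=config.fold,
                                         single_env_q=single)
            het_e = vc.heterogeneity_all(study, "e", covs, treatment_env=env_treat,
                                         alpha=config.alpha, fold=config.fold)
            _write_tsv(single, outdir / "varcomp_single.tsv")
            _write_tsv(combined, outdir / "varcomp_combined.tsv")
            _write_tsv(het_g, outdir / "heterogeneity_G.tsv")
            _write_tsv(het_e, outdir / "heterogeneity_e.tsv")
            label_counts = het_g["label"].value_counts().to_dict() if "label" in het_g else {}
            report["stages"]["varcomp"] = {
                "genes": int(len(combined)),
                "significant_sigma2_G": {
                    env: int(((single["environment"] == env) & (single["qvalue"] <= config.alpha)).sum())
                    for env in envs},
                "significant_GxE": int((combined["q_GE"] <= config.alpha).sum()),
                "canalization_classes": {str(k): int(v) for k, v in label_counts.items()},
            }
            results.update(single=single, combined=combined, het_g=het_g)

        if "enrichment" in config.stages and sets is not None and combined is not None:
            s_wide = single.pivot(index="gene", columns="environment", values="sigma2_G")
            q_wide = single.pivot(index="gene", columns="environment", values="qvalue")
            sig_any = (q_wide <= config.alpha).any(axis=1)
            denom = s_wide.sum(axis=1)
            dec = ((s_wide[env_treat] - s_wide[env_base]) / denom)[sig_any & (denom > 0)]
            comb = combined.set_index("gene")
            sig_gen = (comb["q_G"] <= config.alpha) | (comb["q_GE"] <= config.alpha)
            gxe_scores = (2.0 * comb.loc[sig_gen & comb["gxe_index"].notna(), "gxe_index"] - 1.0)
            gsea_dec = enr.gsea_preranked(dec, sets, n_perm=config.gsea_n_perm,
                                          min_size=config.gsea_min_size, seed=config.seed + 10)
            gsea_gxe = enr.gsea_preranked(gxe_scores, sets, n_perm=config.gsea_n_perm,
                                          min_size=config.gsea_min_size, seed=config.seed + 11)
            _write_tsv(gsea_dec, outdir / "gsea_decanalization.tsv")
            _write_tsv(gsea_gxe, outdir / "gsea_gxe.tsv")
            report["stages"]["enrichment"] = {
                "scored_genes_decanalization": int(len(dec)),
                "scored_genes_gxe": int(len(gxe_scores)),
                "sets_tested": int(len(gsea_dec)),
            }

        models = {}
        blups = None
        assoc = {}
        sharing_table = None
        if "eqtl" in config.stages and genos is not None:
            genos_f = genos.filter_maf(config.maf)
            blups = eq.estimate_line_blups(study, covs)
            fdr_info = {}
            mapped = {}
            for env in envs:
                assoc[env] = eq.map_eqtl(blups[env], genos_f, maf_min=0.0)
                fdr = eq.eqtl_fdr_threshold(blups[env], genos_f, n_perm=config.n_perm,
                                            alpha=config.alpha, maf_min=0.0,
                                            seed=config.seed + 20)
                thr = fdr.threshold if fdr else 0.0
                fdr_info[env] = {"p_threshold": thr, "n_significant":
                                 int((assoc[env]["p"] <= thr).sum()) if thr else 0}
                sig = assoc[env][assoc[env]["p"] <= thr] if thr else assoc[env].iloc[0:0]
                mapped[env] = set(zip(sig["gene"], sig["variant"]))
                models[env] = {}
                for gene, grp in sig.groupby("gene"):
                    models[env][gene] = eq.forward_select(
                        gene, pd.Index(grp["variant"]), blups[env].loc[gene],
                        genos_f, entry_p=config.entry_p, environment=env)
                model_rows = [
                    {"gene": g, "environment": env, "variant": v,
                     "effect": m.effects[v], "t": m.tstats[v], "p": m.pvalues[v]}
                    for g, m in models[env].items() for v in m.variants]
                _write_tsv(pd.DataFrame(model_rows,
                                        columns=["gene", "environment", "variant", "effect", "t", "p"]),
                           outdir / f"eqtl_models_{env}.tsv")
            sharing_table, summary = eq.classify_sharing(
                models[env_treat], models[env_base], mapped[env_treat], mapped[env_base],
                env_treat, env_base)
            sharing_table = eq.effect_pairs(sharing_table, assoc[env_treat], assoc[env_base],
                                            env_treat, env_base)
            _write_tsv(sharing_table, outdir / "eqtl_sharing.tsv")
            pred = eq.cross_env_predict(models[env_base], genos_f, blups[env_treat])
            pred.rename_axis("gene").reset_index().to_csv(
                outdir / "cross_env_prediction.tsv", sep="\t", index=False, float_format="%.10g")
            report["stages"]["eqtl"] = {"fdr": fdr_info, **summary,
                                        "predicted_genes": int(len(pred))}

        if "tfbs" in config.stages and sites is not None and sharing_table is not None \
                and len(sharing_table):
            # variant-level classes; "shared" takes precedence for variants
            # attached to several genes
            cls_order = ["shared", f"{env_treat}-specific", f"{env_base}-specific"]
            classes = {}
            seen = set()
            for cls in cls_order:
                vids = [v for v in sharing_table.loc[sharing_table["class"] == cls, "variant"].unique()
                        if v not in seen]
                seen.update(vids)
                if vids:
                    classes[cls] = vids
            pool = genos.filter_maf(config.maf).calls.index
            tf_table = tf.permutation_enrichment(classes, pool, genos, sites,
                                                 n_draws=config.n_draws, seed=config.seed + 30)
            _write_tsv(tf_table, outdir / "tfbs_enrichment.tsv")
            report["stages"]["tfbs"] = {
                "classes": {k: len(v) for k, v in classes.items()},
                "tests": int(len(tf_table)),
                "significant": int((tf_table["q"] <= config.alpha).sum()),
            }

        if "network" in config.stages and combined is not None:
            line_means = {}
            for env in envs:
                sub = study.subset_samples(study.meta["environment"] == env)
                line_means[env] = sub.expr.T.groupby(sub.meta["line"]).mean().T
            comb = combined.set_index("gene")
            gxe_genes = comb.index[(comb["q_GE"] <= config.alpha)].tolist()
            subset = gxe_genes if len(gxe_genes) >= 3 else None
            dr = net.delta_r_test(line_means[env_base], line_means[env_treat],
                                  gene_subset=subset, n_sim=config.n_sim,
                                  seed=config.seed + 40)
            conn = net.connectivity(net.correlation_matrix(line_means[env_base]))
            net_report = {"delta_r_observed_variance": dr.observed_variance,
                          "delta_r_p": dr.pvalue, "delta_r_genes": len(dr.genes),
                          "gxe_subset_used": subset is not None}
            if sel is not None:
                groups = pd.Series(np.where(comb["q_GE"] <= config.alpha, "GxE", "no GxE"),
                                   index=comb.index)
                cs = net.connectivity_selection_correlation(conn, sel, groups)
                _write_tsv(cs, outdir / "connectivity_selection.tsv")
                net_report["connectivity_selection"] = cs.to_dict(orient="records")
            report["stages"]["network"] = net_report

        if truth is not None and combined is not None:
            report["recovery"] = _recovery_metrics(truth, combined, models, env_treat, env_base)
    except Exception as exc:  # record partial completion, then re-raise
        report["error"] = f"{type(exc).__name__}: {exc}"
        gio.write_json(report, outdir / "report.json")
        raise
    gio.write_json(report, outdir / "report.json")
    return report


def _recovery_metrics(truth, combined: pd.DataFrame, models: dict,
                      env_treat: str, env_base: str) -> dict:
    """Bias of variance-component estimates and realized FDP of eQTL calls
    against the generator's ground truth."""
    gp = truth.gene_params
    shared = (0.5 * (gp["sigma2_G_envA"] + gp["sigma2_G_envB"]) - gp["sigma2_GE"]).to_numpy()
    comb = combined.set_index("gene").loc[gp.index]
    out = {
        "bias_sigma2_G": float(np.mean(comb["sigma2_G"].to_numpy() - shared)),
        "bias_sigma2_GE": float(np.mean(comb["sigma2_GE"].to_numpy() - gp["sigma2_GE"].to_numpy())),
        "bias_sigma2_e": float(np.mean(comb["sigma2_e"].to_numpy() - gp["sigma2_e"].to_numpy())),
    }
    true_pairs = {(g, v) for g, vs in truth.causal_variants.items() for v, *_ in vs}
    called = set()
    for env_models in models.values():
        for g, m in env_models.items():
            called.update((g, v) for v in m.variants)
    if called:
        # a call is "true" if the gene has any causal variant (LD proxies count
        # toward discoveries of the gene's signal but not toward exact FDP)
        exact = sum(1 for pair in called if pair in true_pairs)
        gene_hit = sum(1 for g, _ in called if g in truth.causal_variants)
        out["eqtl_calls"] = len(called)
        out["eqtl_exact_recovery"] = exact
        out["eqtl_gene_level_fdp"] = 1.0 - gene_hit / len(called)
    return out
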