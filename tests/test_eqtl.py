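"""BLUP shrinkage, single-variant association, permutation FDR, forward
selection against an exhaustive oracle, and cross-environment analysis."""

import numpy as np
import pandas as pd
import pytest

from gxepipe import eqtl as eq
from gxepipe import simulate as sim
from conftest import make_genotypes


def _study_for_blups(s2g, s2e, n_lines=50, seed=0):
    truth = sim.make_truth(20, sigma2_G=s2g, sigma2_GE=0.0, sigma2_e=s2e, seed=seed)
    return sim.generate_expression(sim.StudyDesign(n_lines=n_lines, n_reps=2, seed=seed + 1), truth)


class TestBlups:
    def test_no_noise_blups_equal_centered_line_means(self):
        study = _study_for_blups(1.0, 0.0, seed=2)
        blups = eq.estimate_line_blups(study)
        sub = study.subset_samples(study.meta["environment"] == "18C")
        lm = sub.expr.T.groupby(sub.meta["line"]).mean().T
        centered = lm.sub(lm.mean(axis=1), axis=0)
        np.testing.assert_allclose(blups["18C"].to_numpy(),
                                   centered[blups["18C"].columns].to_numpy(), atol=1e-8)

    def test_no_genetic_variance_blups_zero(self):
        study = _study_for_blups(0.0, 1.0, n_lines=80, seed=3)
        blups = eq.estimate_line_blups(study)
        # shrinkage pushes BLUPs well below raw line-mean deviations
        sub = study.subset_samples(study.meta["environment"] == "18C")
        lm = sub.expr.T.groupby(sub.meta["line"]).mean().T
        raw_sd = lm.sub(lm.mean(axis=1), axis=0).to_numpy().std()
        assert blups["18C"].to_numpy().std() < 0.35 * raw_sd

    def test_balanced_shrinkage_factor(self):
        # construct exact MS_within = 1 and MS_between = 3, so the fit gives
        # sigma2_e = 1, sigma2_G = (3-1)/2 = 1 and lambda = 1/(1+1/2) = 2/3;
        # a line sitting 3 units above the mean must get BLUP 2
        from gxepipe.datatypes import ExpressionStudy

        dev = np.array([3.0, -1.0, -1.0, -1.0])  # centered line means, var=16/3... scaled below
        # rescale deviations so sample variance of line means is 1.5
        dev = dev * np.sqrt(1.5 / np.var(dev, ddof=1))
        delta = 1.0 / np.sqrt(2.0)  # within-pair half-spread giving MS_w = 1
        lines = [f"l{i}" for i in range(4)]
        values = np.concatenate([[d - delta, d + delta] for d in dev])
        cols = [f"{l}_r{k}" for l in lines for k in (1, 2)]
        expr = pd.DataFrame([values], index=["g1"], columns=cols)
        meta = pd.DataFrame({
            "sample_id": cols,
            "line": np.repeat(lines, 2),
            "environment": "E",
            "sex": "F",
            "replicate": [1, 2] * 4,
        }).set_index("sample_id")
        study = ExpressionStudy(expr, meta)
        from gxepipe import varcomp as vc

        fit = vc.fit_single_env(values, np.repeat(lines, 2))
        assert fit.sigma2_e == pytest.approx(1.0)
        assert fit.sigma2_G == pytest.approx(1.0)
        blups = eq.estimate_line_blups(study)["E"]
        # every centered line mean shrinks by 2/3 (a deviation of 3 -> BLUP 2)
        np.testing.assert_allclose(blups.loc["g1"].to_numpy(), (2.0 / 3.0) * dev, atol=1e-10)


class TestAssociation:
    def test_hand_computed_t(self):
        g = make_genotypes([[0, 0, 1, 1]])
        blups = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["g1"], columns=g.lines)
        beta, t, p = eq.association_stats(blups, g)
        assert beta[0, 0] == pytest.approx(2.0)
        assert t[0, 0] == pytest.approx(2.8284271, abs=1e-6)
        assert p[0, 0] == pytest.approx(0.10557, abs=1e-4)

    def test_constant_blups(self):
        g = make_genotypes([[0, 1, 0, 1]])
        blups = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["g1"], columns=g.lines)
        beta, t, p = eq.association_stats(blups, g)
        assert beta[0, 0] == pytest.approx(0.0)
        assert t[0, 0] == 0.0 and p[0, 0] == 1.0

    def test_allele_relabeling_symmetry(self):
        g1 = make_genotypes([[0, 0, 1, 1, 0, 1]])
        g2 = make_genotypes([[1, 1, 0, 0, 1, 0]])
        rng = np.random.default_rng(0)
        blups = pd.DataFrame(rng.normal(0, 1, (3, 6)),
                             index=["a", "b", "c"], columns=g1.lines)
        b1, t1, p1 = eq.association_stats(blups, g1)
        b2, t2, p2 = eq.association_stats(blups, g2)
        np.testing.assert_allclose(b1, -b2)
        np.testing.assert_allclose(np.abs(t1), np.abs(t2))
        np.testing.assert_allclose(p1, p2)

    def test_t_equals_regression_slope_t(self):
        rng = np.random.default_rng(1)
        g = make_genotypes([rng.integers(0, 2, 30).tolist()])
        y = rng.normal(0, 1, 30)
        blups = pd.DataFrame([y], index=["g1"], columns=g.lines)
        _, t, _ = eq.association_stats(blups, g)
        import statsmodels.api as sm

        X = sm.add_constant(g.calls.iloc[0].to_numpy(dtype=float))
        ols = sm.OLS(y, X).fit()
        assert t[0, 0] == pytest.approx(ols.tvalues[1], abs=1e-8)

    def test_maf_filter_in_map(self):
        g = make_genotypes([[0, 0, 0, 1], [0, 1, 1, 0]])
        blups = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=["g1"], columns=g.lines)
        tab = eq.map_eqtl(blups, g, maf_min=0.3)
        assert set(tab["variant"]) == {"v1"}


class TestEmpiricalFdr:
    def test_estimator_arithmetic(self):
        # 200 observed below t, mean 10 permuted below t -> FDR 0.05
        obs = np.concatenate([np.full(200, 1e-4), np.full(800, 0.5)])
        perms = [np.concatenate([np.full(10, 1e-4), np.full(990, 0.6)])] * 5
        res = eq.empirical_fdr(obs, perms, alpha=0.05)
        row = res.curve.iloc[(res.curve["p_threshold"] - 1e-4).abs().argmin()]
        assert row["fdr"] == pytest.approx(0.05)
        assert res.threshold is not None

    def test_fully_null_data_fdr_near_one(self):
        rng = np.random.default_rng(2)
        truth = sim.make_truth(40, sigma2_G=1.0, sigma2_GE=0.0, sigma2_e=0.5, seed=3)
        study = sim.generate_expression(sim.StudyDesign(n_lines=80, n_reps=2, seed=4), truth)
        genos = sim.generate_genotypes(80, 100, maf_low=0.1, seed=5)
        blups = eq.estimate_line_blups(study)["18C"]
        _, _, p_obs = eq.association_stats(blups, genos)
        perms = []
        rng = np.random.default_rng(6)
        for _ in range(20):
            _, _, pp = eq.association_stats(eq.permute_blups(blups, rng), genos)
            perms.append(pp.ravel())
        res = eq.empirical_fdr(p_obs.ravel(), perms)
        mask = res.curve["n_observed"] >= 20
        assert res.curve.loc[mask, "fdr"].min() > 0.5

    def test_planted_signal_yields_threshold(self):
        genos = sim.generate_genotypes(120, 60, maf_low=0.2, seed=7)
        truth = sim.make_truth(30, sigma2_G=0.1, sigma2_GE=0.0, sigma2_e=0.2, seed=8)
        for i in range(10):
            truth.causal_variants[f"gene{i:05d}"] = [(genos.calls.index[i], 1.5, 1.5)]
        study = sim.generate_expression(sim.StudyDesign(n_lines=120, n_reps=2, seed=9), truth, genos)
        blups = eq.estimate_line_blups(study)["18C"]
        res = eq.eqtl_fdr_threshold(blups, genos, n_perm=20, alpha=0.05, maf_min=0.05, seed=10)
        assert res.threshold is not None and res.threshold > 0


class TestForwardSelection:
    def test_perfect_ld_pair_selects_one(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 2, 100)
        g = make_genotypes([base.tolist(), base.tolist(),
                            rng.integers(0, 2, 100).tolist()])
        y = 1.0 * base + 0.1 * rng.standard_normal(100)
        row = pd.Series(y, index=g.lines)
        model = eq.forward_select("g", g.calls.index, row, g, entry_p=1e-5)
        assert model.variants == ["v0"]  # earlier by position among the LD twins
        oracle = eq.best_subset_oracle("g", g.calls.index, row, g, entry_p=1e-5)
        assert set(model.variants) == oracle

    def test_two_independent_signals_both_selected(self):
        rng = np.random.default_rng(12)
        x1 = rng.integers(0, 2, 150)
        x2 = rng.integers(0, 2, 150)
        extra = [rng.integers(0, 2, 150).tolist() for _ in range(4)]
        g = make_genotypes([x1.tolist(), x2.tolist()] + extra)
        y = 1.0 * x1 + 0.8 * x2 + 0.15 * rng.standard_normal(150)
        row = pd.Series(y, index=g.lines)
        model = eq.forward_select("g", g.calls.index, row, g, entry_p=1e-5)
        oracle = eq.best_subset_oracle("g", g.calls.index, row, g, entry_p=1e-5)
        assert set(model.variants) == {"v0", "v1"}
        assert set(model.variants) == oracle

    def test_no_candidate_below_entry_gives_empty_model(self):
        rng = np.random.default_rng(13)
        g = make_genotypes([rng.integers(0, 2, 40).tolist()])
        row = pd.Series(rng.normal(0, 1, 40), index=g.lines)
        model = eq.forward_select("g", g.calls.index, row, g, entry_p=1e-5)
        assert len(model) == 0

    def test_oracle_agreement_randomized(self):
        rng = np.random.default_rng(14)
        agree = 0
        for rep in range(10):
            cols = [rng.integers(0, 2, 80).tolist() for _ in range(6)]
            g = make_genotypes(cols)
            X = np.asarray(cols, dtype=float)
            effects = np.array([1.2, 0.9, 0, 0, 0, 0])
            y = effects @ X + 0.2 * rng.standard_normal(80)
            row = pd.Series(y, index=g.lines)
            model = eq.forward_select("g", g.calls.index, row, g, entry_p=1e-5)
            oracle = eq.best_subset_oracle("g", g.calls.index, row, g, entry_p=1e-5)
            agree += set(model.variants) == oracle
        assert agree == 10


class TestSharingAndPrediction:
    def _models(self, pairs, env):
        out = {}
        for gene, vid, beta in pairs:
            m = eq.EqtlModel(gene, env)
            m.variants.append(vid)
            m.effects[vid] = beta
            out[gene] = m
        return out

    def test_identical_environments_all_shared(self):
        models = self._models([("g1", "v0", 1.0), ("g2", "v3", -0.5)], "A")
        mapped = {("g1", "v0"), ("g2", "v3")}
        table, summary = eq.classify_sharing(models, models, mapped, mapped, "A", "B")
        assert (table["class"] == "shared").all()
        assert summary["fraction_sharing"] == 1.0

    def test_env_specific_classification(self):
        m_a = self._models([("g1", "v0", 1.0)], "A")
        table, summary = eq.classify_sharing(m_a, {}, {("g1", "v0")}, set(), "A", "B")
        assert list(table["class"]) == ["A-specific"]
        assert np.isnan(summary["fraction_sharing"])

    def test_prediction_sign_limits(self):
        g = make_genotypes([[0, 1, 0, 1, 1, 0]])
        x = g.calls.iloc[0].to_numpy(dtype=float)
        models = self._models([("g1", "v0", 2.0)], "A")
        obs_same = pd.DataFrame([2.0 * x], index=["g1"], columns=g.lines)
        obs_flip = pd.DataFrame([-2.0 * x], index=["g1"], columns=g.lines)
        assert eq.cross_env_predict(models, g, obs_same)["g1"] == pytest.approx(1.0)
        assert eq.cross_env_predict(models, g, obs_flip)["g1"] == pytest.approx(-1.0)


class TestEndToEndFdp:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_realized_fdp_controlled_with_planted_signals(self, seed):
        """Strong eQTLs planted for 10% of genes: the gene-level false
        discovery proportion at the alpha = 0.05 empirical threshold stays
        at or below 0.1."""
        genos = sim.generate_genotypes(100, 150, maf_low=0.1, seed=seed)
        truth = sim.make_truth(150, sigma2_G=1.0, sigma2_GE=0.25, sigma2_e=0.5, seed=seed + 10)
        rng = np.random.default_rng(seed + 20)
        maf = genos.maf()
        vids = rng.choice(maf.index[maf > 0.1], 15, replace=False)
        planted_genes = rng.choice(truth.genes.to_numpy(), 15, replace=False)
        for g, v in zip(planted_genes, vids):
            truth.causal_variants[str(g)] = [(str(v), 2.0, 2.0)]
        study = sim.generate_expression(
            sim.StudyDesign(n_lines=100, n_reps=2, seed=seed + 30), truth, genos)
        blups = eq.estimate_line_blups(study)["18C"]
        gf = genos.filter_maf(0.05)
        fdr = eq.eqtl_fdr_threshold(blups, gf, n_perm=20, alpha=0.05, maf_min=0.0,
                                    seed=seed + 40)
        assert fdr.threshold is not None
        assoc = eq.map_eqtl(blups, gf, maf_min=0.0)
        sig = assoc[assoc["p"] <= fdr.threshold]
        models = {g: eq.forward_select(g, pd.Index(grp["variant"]), blups.loc[g],
                                       gf, entry_p=1e-5)
                  for g, grp in sig.groupby("gene")}
        calls = {(g, v) for g, m in models.items() for v in m.variants}
        assert calls
        fdp = 1 - sum(1 for g, _ in calls if g in truth.causal_variants) / len(calls)
        assert fdp <= 0.1
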