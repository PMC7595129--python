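"""Variance-component estimation: closed-form oracles, boundary tests,
heterogeneity LRTs and the BH/classification helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxepipe import simulate as sim
from gxepipe import varcomp as vc


class TestSingleEnv:
    @pytest.mark.parametrize(
        "values,lines,exp_g,exp_e",
        [
            # balanced one-way ANOVA closed form: MS_b=8*2/2=8, MS_w=0
            ([1, 1, 3, 3, 5, 5], list("aabbcc"), 4.0, 0.0),
            # all observations equal -> no variance anywhere
            ([2, 2, 2, 2], list("aabb"), 0.0, 0.0),
            # negative moment estimate truncated; sigma2_e stays MS_within
            ([0, 2, 0, 2], list("aabb"), 0.0, 2.0),
        ],
    )
    def test_anova_closed_form(self, values, lines, exp_g, exp_e):
        fit = vc.fit_single_env(values, lines)
        assert fit.sigma2_G == pytest.approx(exp_g, abs=1e-12)
        assert fit.sigma2_e == pytest.approx(exp_e, abs=1e-12)

    def test_boundary_lrt_zero_reports_p_one(self):
        fit = vc.fit_single_env([0, 2, 0, 2], list("aabb"))
        assert fit.lrt == 0.0
        assert fit.pvalue == 1.0

    def test_singleton_lines_error(self):
        with pytest.raises(ValueError, match="inestimable"):
            vc.fit_single_env([1.0, 2.0, 3.0], ["a", "b", "c"])

    def test_shift_and_order_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 40)
        lines = np.repeat([f"l{i}" for i in range(20)], 2)
        f1 = vc.fit_single_env(y, lines)
        f2 = vc.fit_single_env(y + 7.5, lines)
        perm = rng.permutation(40)
        f3 = vc.fit_single_env(y[perm], lines[perm])
        assert f2.sigma2_G == pytest.approx(f1.sigma2_G, rel=1e-9)
        assert f2.sigma2_e == pytest.approx(f1.sigma2_e, rel=1e-9)
        assert f3.sigma2_G == pytest.approx(f1.sigma2_G, rel=1e-9)

    def test_unbalanced_matches_balanced_on_balanced_data(self):
        rng = np.random.default_rng(1)
        lines = np.repeat([f"l{i}" for i in range(15)], 2)
        y = rng.normal(0, 1, 30) + np.repeat(rng.normal(0, 1, 15), 2)
        bal = vc.fit_single_env(y, lines)
        s2g, s2e, ll1, ll0 = vc._reml_oneway_unbalanced(y, np.ones((30, 1)), lines)
        assert s2g == pytest.approx(bal.sigma2_G, rel=1e-4, abs=1e-6)
        assert s2e == pytest.approx(bal.sigma2_e, rel=1e-4, abs=1e-6)

    def test_unbalanced_design_accepted(self):
        # a line with a single replicate contributes to G only
        y = [1.0, 1.2, 3.0, 3.1, 5.0]
        lines = ["a", "a", "b", "b", "c"]
        fit = vc.fit_single_env(y, lines)
        assert fit.sigma2_G > 0
        assert fit.sigma2_e >= 0

    def test_power_at_large_genetic_variance(self):
        truth = sim.make_truth(200, sigma2_G=1.0, sigma2_GE=0.0, sigma2_e=0.25, seed=3)
        study = sim.generate_expression(sim.StudyDesign(n_lines=100, n_reps=2, seed=4), truth)
        res = vc.varcomp_single_all(study)
        assert (res["pvalue"] <= 0.05).mean() > 0.99


class TestCombined:
    def test_recovery_means(self):
        truth = sim.make_truth(400, sigma2_G=1.0, sigma2_GE=0.5, sigma2_e=0.5, seed=20)
        study = sim.generate_expression(sim.StudyDesign(n_lines=200, n_reps=2, seed=21), truth)
        res = vc.varcomp_combined_all(study)
        # Monte-Carlo SE of the mean of 400 genes is small; 3 SE margins
        assert res["sigma2_G"].mean() == pytest.approx(1.0, abs=0.05)
        assert res["sigma2_GE"].mean() == pytest.approx(0.5, abs=0.03)
        assert res["sigma2_e"].mean() == pytest.approx(0.5, abs=0.02)
        assert res["gxe_index"].mean() == pytest.approx(1 / 3, abs=0.02)

    def test_null_ge_shrinks_to_zero(self):
        truth = sim.make_truth(300, sigma2_G=1.0, sigma2_GE=0.0, sigma2_e=0.5, seed=22)
        study = sim.generate_expression(sim.StudyDesign(n_lines=200, n_reps=2, seed=23), truth)
        res = vc.varcomp_combined_all(study)
        assert res["sigma2_GE"].mean() < 0.05

    def test_pure_interaction_recovered(self):
        truth = sim.make_truth(300, sigma2_G=0.0, sigma2_GE=1.0, sigma2_e=0.5, seed=24)
        study = sim.generate_expression(sim.StudyDesign(n_lines=200, n_reps=2, seed=25), truth)
        res = vc.varcomp_combined_all(study)
        assert res["sigma2_G"].mean() == pytest.approx(0.0, abs=0.05)
        assert res["sigma2_GE"].mean() == pytest.approx(1.0, abs=0.05)

    def test_single_line_unidentifiable(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            vc.fit_combined([1, 2, 1, 2], ["a", "a", "a", "a"],
                            ["E1", "E1", "E2", "E2"])

    def test_missing_environment_unidentifiable(self):
        with pytest.raises(ValueError):
            vc.fit_combined([1, 2, 1, 2, 3, 4, 3, 4],
                            ["a", "a", "a", "a", "b", "b", "b", "b"],
                            ["E1", "E1", "E2", "E2", "E1", "E1", "E1", "E1"])


class TestGxeIndex:
    @pytest.mark.parametrize("g,ge,expected", [(1.0, 0.0, 0.0), (0.0, 0.7, 1.0), (0.5, 0.5, 0.5)])
    def test_values(self, g, ge, expected):
        assert vc.gxe_index(g, ge) == pytest.approx(expected)

    def test_undefined_when_no_genetic_variance(self):
        assert np.isnan(vc.gxe_index(0.0, 0.0))

    @given(st.floats(0, 100, allow_nan=False), st.floats(1e-9, 100, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, g, ge):
        assert 0.0 <= vc.gxe_index(g, ge) <= 1.0


class TestHeterogeneity:
    def test_identical_environments_lrt_zero(self):
        rng = np.random.default_rng(30)
        y_env = rng.normal(0, 1, 40)
        y = np.concatenate([y_env, y_env])
        lines = list(np.repeat([f"l{i}" for i in range(20)], 2)) * 2
        envs = ["A"] * 40 + ["B"] * 40
        for comp in ("G", "e"):
            res = vc.test_variance_heterogeneity(y, lines, envs, comp)
            assert res.lrt == pytest.approx(0.0, abs=1e-5)
            assert res.pvalue > 0.99

    def test_fourfold_heterogeneity_detected(self):
        # independent line effects across envs with vB = 4 vA
        truth = sim.make_truth(60, sigma2_GE=2.5, sigma2_e=0.5,
                               sigma2_G_envA=1.0, sigma2_G_envB=4.0, seed=31)
        study = sim.generate_expression(sim.StudyDesign(n_lines=200, n_reps=2, seed=32), truth)
        res = vc.heterogeneity_all(study, "G")
        assert (res["pvalue"] <= 0.05).mean() > 0.8
        assert 3.0 <= res["fold_change"].median() <= 5.0

    def test_null_pvalues_uniform(self):
        truth = sim.make_truth(300, sigma2_G=0.0, sigma2_GE=1.0, sigma2_e=0.5, seed=33)
        study = sim.generate_expression(sim.StudyDesign(n_lines=100, n_reps=2, seed=34), truth)
        res = vc.heterogeneity_all(study, "e")
        from scipy.stats import kstest

        assert kstest(res["pvalue"], "uniform").pvalue > 0.01


class TestBH:
    def test_step_up_rule(self):
        np.testing.assert_allclose(vc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_degenerate(self):
        assert vc.bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(vc.bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_nan_propagates(self):
        q = vc.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, ps):
        q = vc.bh_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestClassification:
    def test_insignificant_heterogeneity_is_stable(self):
        assert vc.classify_canalization(0.5, 10.0, 4.0, 1.0, 0.001, 0.001) == "stable"

    def test_decanalized_and_canalized(self):
        assert vc.classify_canalization(0.01, 4.0, 4.0, 1.0, 0.01, 0.5) == "decanalized"
        assert vc.classify_canalization(0.01, 4.0, 1.0, 4.0, 0.5, 0.01) == "canalized"

    def test_fold_gate(self):
        assert vc.classify_canalization(0.01, 1.5, 1.5, 1.0, 0.01, 0.01) == "stable"

    def test_end_to_end_decanalization_call(self):
        truth = sim.make_truth(40, sigma2_GE=2.5, sigma2_e=0.3,
                               sigma2_G_envA=4.0, sigma2_G_envB=1.0, seed=40)
        study = sim.generate_expression(sim.StudyDesign(n_lines=200, n_reps=2, seed=41), truth)
        single = vc.varcomp_single_all(study)
        het = vc.heterogeneity_all(study, "G", treatment_env="18C", single_env_q=single)
        # envA of the generator is the first environment label (18C)
        assert (het["label"] == "decanalized").mean() > 0.8
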