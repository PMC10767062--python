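"""Mixed-model engine, elimination, follow-ups and the permutation null.

The crossed-random-intercepts fitter is cross-checked against two
independent implementations: statsmodels MixedLM (variance-components
route) and, where available, R's lmerTest via Rscript (Satterthwaite
t/df/p and REML variance components).
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import cortrack as ct
from cortrack.mixedlm import fit_mixed_lm, likelihood_ratio
from cortrack.simulate import simulate_accuracy_study
from cortrack.stats import (
    LMMSpec,
    build_design,
    compare_to_null,
    fit_lmm,
    follow_up_by_level,
    full_factorial_spec,
    likelihood_ratio_test,
    null_distribution,
    stepwise_backward,
)

FAM_SPEC = LMMSpec(fixed_terms=(("Familiarity",),))


@pytest.fixture(scope="module")
def acc_table():
    return simulate_accuracy_study(
        n_subjects=10, n_stimuli=6, familiarity_effect=0.02, seed=11
    )


class TestSpec:
    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="hierarchy"):
            LMMSpec(fixed_terms=((("Familiarity", "Repetition")),))

    def test_full_factorial_has_seven_terms(self):
        spec = full_factorial_spec()
        assert len(spec.fixed_terms) == 7
        assert spec.removable_terms() == [("Familiarity", "MindWandering", "Repetition")]

    def test_formula_rendering(self):
        assert FAM_SPEC.formula() == "accuracy ~ Familiarity + (1|Subject) + (1|Stimulus)"


class TestAgainstR(object):
    """Oracle: lmerTest's Satterthwaite machinery on the same data."""

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lmerTest(self, acc_table, tmp_path):
        fit = fit_lmm(FAM_SPEC, acc_table)
        csv = tmp_path / "d.csv"
        acc_table.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            """
            suppressMessages(library(lmerTest)); suppressMessages(library(jsonlite))
            d <- read.csv(commandArgs(TRUE)[1])
            d$fam <- as.numeric(d$coded_familiarity == 'High')
            m <- lmer(accuracy ~ fam + (1|subject_id) + (1|stimulus_id), data=d, REML=TRUE)
            co <- summary(m)$coefficients
            vc <- as.data.frame(VarCorr(m))
            cat(toJSON(list(beta=co[,1], se=co[,2], df=co[,3], p=co[,5],
                            vars=vc$vcov, loglik=as.numeric(logLik(m))), digits=12))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        import json

        ref = json.loads(out.stdout)
        ours = fit.coef.loc["Familiarity"]
        assert ours["estimate"] == pytest.approx(ref["beta"][1], rel=1e-4)
        assert ours["se"] == pytest.approx(ref["se"][1], rel=1e-3)
        assert ours["dof"] == pytest.approx(ref["df"][1], rel=1e-2)
        assert ours["p"] == pytest.approx(ref["p"][1], rel=1e-2, abs=1e-6)
        assert fit.random_variances["Subject"] == pytest.approx(ref["vars"][0], rel=1e-3, abs=1e-8)
        assert fit.random_variances["Stimulus"] == pytest.approx(ref["vars"][1], rel=1e-3, abs=1e-8)
        assert fit.loglik == pytest.approx(ref["loglik"][0], abs=1e-3)


class TestAgainstStatsmodels:
    def test_reml_surface_not_worse_than_mixedlm(self, acc_table):
        """Both maximize the same restricted likelihood; our optimum must not
        be inferior, and the fixed effects must agree closely."""
        smf = pytest.importorskip("statsmodels.formula.api")
        fit = fit_lmm(FAM_SPEC, acc_table)
        d = acc_table.copy()
        d["fam"] = (d.coded_familiarity == "High").astype(float)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "accuracy ~ fam",
                d,
                groups=np.ones(len(d)),
                vc_formula={
                    "Subject": "0 + C(subject_id)",
                    "Stimulus": "0 + C(stimulus_id)",
                },
            ).fit(reml=True)
        assert fit.loglik >= sm_fit.llf - 1e-4
        assert fit.coef.loc["Familiarity", "estimate"] == pytest.approx(
            sm_fit.fe_params.iloc[1], abs=2e-3
        )


class TestFitLMM:
    def test_zero_variance_components_recovered(self):
        """With no true Subject/Stimulus variance the REML estimates are
        negligible relative to the residual variance (the boundary estimate
        is 0 or a small positive sampling artefact)."""
        df = simulate_accuracy_study(
            n_subjects=10, subject_sd=0.0, stimulus_sd=0.0, resid_sd=0.05, seed=3
        )
        fit = fit_lmm(FAM_SPEC, df)
        assert fit.random_variances["Subject"] <= 0.02 * fit.sigma2
        assert fit.random_variances["Stimulus"] <= 0.02 * fit.sigma2
        assert fit.r2_conditional == pytest.approx(fit.r2_marginal, abs=0.05)

    def test_intercept_only_recovers_grand_mean(self, acc_table):
        ols = fit_lmm(LMMSpec(fixed_terms=(), random_intercepts=()), acc_table)
        assert ols.coef.loc["Intercept", "estimate"] == pytest.approx(
            acc_table["accuracy"].mean()
        )
        lmm = fit_lmm(LMMSpec(fixed_terms=()), acc_table)
        assert lmm.coef.loc["Intercept", "estimate"] == pytest.approx(
            acc_table["accuracy"].mean(), abs=0.02
        )

    def test_r2_ordering_and_ci_bracket(self, acc_table):
        for spec in (FAM_SPEC, full_factorial_spec()):
            fit = fit_lmm(spec, acc_table)
            assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0
            ok = (fit.coef["ci_low"] <= fit.coef["estimate"]) & (
                fit.coef["estimate"] <= fit.coef["ci_high"]
            )
            assert ok.all()
            assert (fit.coef["dof"] > 0).all() and np.isfinite(fit.coef["dof"]).all()

    def test_standardized_beta_scale_free(self, acc_table):
        fit = fit_lmm(FAM_SPEC, acc_table)
        scaled = acc_table.copy()
        scaled["accuracy"] = scaled["accuracy"] * 7.3 + 0.4
        fit2 = fit_lmm(FAM_SPEC, scaled)
        assert fit2.std_coef.loc["Familiarity", "estimate"] == pytest.approx(
            fit.std_coef.loc["Familiarity", "estimate"], rel=1e-6
        )

    def test_between_subject_term_gets_subject_level_dof(self):
        """A purely between-subject predictor must be tested against roughly
        (n_subjects - 2) denominator dof, not the epoch count."""
        df = simulate_accuracy_study(n_subjects=12, seed=8)
        fit = fit_lmm(LMMSpec(fixed_terms=(("MindWandering",),)), df)
        assert fit.coef.loc["MindWandering", "dof"] < 20

    def test_design_matrix_coding(self, acc_table):
        X, names = build_design(acc_table, full_factorial_spec())
        assert X.shape[1] == 8 and names[0] == "Intercept"
        assert set(np.unique(X)) <= {0.0, 1.0}
        Xs, _ = build_design(acc_table, full_factorial_spec(), standardized=True)
        assert set(np.unique(Xs[:, 1])) <= {-0.5, 0.5}


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, acc_table):
        a = fit_lmm(FAM_SPEC, acc_table, reml=False)
        chisq, dof, p = likelihood_ratio_test(a, a)
        assert chisq == 0.0 and p == 1.0

    def test_nested_comparison(self, acc_table):
        full = fit_lmm(FAM_SPEC, acc_table, reml=False)
        null = fit_lmm(LMMSpec(fixed_terms=()), acc_table, reml=False)
        chisq, dof, p = likelihood_ratio_test(full, null)
        assert dof == 1 and chisq >= 0.0 and 0.0 <= p <= 1.0

    def test_reml_ml_mixture_rejected(self, acc_table):
        a = fit_lmm(FAM_SPEC, acc_table, reml=True)
        b = fit_lmm(LMMSpec(fixed_terms=()), acc_table, reml=False)
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    def test_null_calibration_one_dof(self):
        """Under the null, the LRT statistic follows chi-square(1)."""
        rng = np.random.default_rng(0)
        chisqs = []
        for rep in range(200):
            n = 40
            y = rng.standard_normal(n)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([np.ones(n), rng.standard_normal(n)])
            f0 = fit_mixed_lm(y, X0, {}, reml=False)
            f1 = fit_mixed_lm(y, X1, {}, reml=False)
            chisqs.append(likelihood_ratio(f1, f0)[0])
        from scipy import stats as sps

        ks = sps.kstest(chisqs, sps.chi2(1).cdf)
        assert ks.pvalue > 0.01


class TestStepwise:
    def test_alpha_one_retains_everything(self, acc_table):
        spec, table = stepwise_backward(
            full_factorial_spec(), acc_table, alpha_fixed=1.0 + 1e-9, alpha_random=0.1
        )
        assert set(spec.fixed_terms) == set(full_factorial_spec().fixed_terms)

    def test_trace_reproducible(self, acc_table):
        s1, t1 = stepwise_backward(full_factorial_spec(), acc_table)
        s2, t2 = stepwise_backward(full_factorial_spec(), acc_table)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)

    def test_trace_has_both_sections(self, acc_table):
        _, table = stepwise_backward(full_factorial_spec(), acc_table)
        assert {"random", "fixed"} == set(table["section"])
        assert (table.loc[table.section == "fixed", "num_dof"] == 1).all()


class TestFollowUp:
    def test_identical_subsets_identical_fits(self):
        df = simulate_accuracy_study(n_subjects=6, seed=2)
        low = df.copy()
        low["coded_mw_group"] = "Low"
        high = df.copy()
        high["coded_mw_group"] = "High"
        both = pd.concat([low, high], ignore_index=True)
        fits = follow_up_by_level(both)
        pd.testing.assert_frame_equal(fits["Low"].coef, fits["High"].coef)

    def test_empty_level_rejected(self):
        df = simulate_accuracy_study(n_subjects=6, seed=2)
        df["coded_mw_group"] = "Low"
        with pytest.raises(ValueError):
            follow_up_by_level(df)


class TestNullComparison:
    def test_equal_arrays_give_zero(self):
        x = np.array([0.1, 0.2, 0.3])
        cmp = compare_to_null(x, x)
        assert cmp.t_statistic == 0.0 and cmp.cohens_d == 0.0 and cmp.p == 1.0

    def test_t_equals_d_times_sqrt_n(self):
        rng = np.random.default_rng(4)
        obs = 0.1 + rng.normal(0, 1e-3, 20)
        null = np.zeros(20)
        cmp = compare_to_null(obs, null)
        assert cmp.t_statistic == pytest.approx(cmp.cohens_d * np.sqrt(20))
        assert cmp.cohens_d > 50

    def test_degenerate_nonzero_difference_rejected(self):
        with pytest.raises(ValueError):
            compare_to_null(np.array([0.25, 0.5]), np.array([0.0, 0.25]))


class TestNullDistribution:
    def test_self_pairs_never_drawn(self):
        rng = np.random.default_rng(0)
        origs = [rng.standard_normal(100) for _ in range(2)]
        nulls = null_distribution({0: origs}, {0: origs}, n_permutations=50, seed=1)
        # with 2 epochs every mismatch scores epoch i against j != i; a
        # self-pair would produce r = 1 exactly
        assert nulls.loc[0, "observed_mean_r"] == pytest.approx(1.0)
        assert abs(nulls.loc[0, "null_mean_r"]) < 0.999

    def test_single_epoch_subject_rejected(self):
        x = [np.random.default_rng(0).standard_normal(50)]
        with pytest.raises(ValueError):
            null_distribution({0: x}, {0: x}, n_permutations=5, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        recs = {0: [rng.standard_normal(80) for _ in range(4)]}
        origs = {0: [rng.standard_normal(80) for _ in range(4)]}
        a = null_distribution(recs, origs, n_permutations=20, seed=7)
        b = null_distribution(recs, origs, n_permutations=20, seed=7)
        pd.testing.assert_frame_equal(a, b)
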