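import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from vocmotion.lmm import (ModelSpec, aic_from_loglik, anova_typeII,
                           bic_from_loglik, cohens_f_from_F, compare_models,
                           contrasts, emmeans, fit_model, lrt,
                           lrt_from_loglik, partial_eta_sq_from_F,
                           r2_nakagawa, ranova_random)


def sim_age_limb(n_inf=24, n_ev=6, sd_int=0.5, sd_slope=0.3, sd_resid=0.8,
                 effects=None, seed=0, response="median_pre",
                 unbalanced=True):
    """Small two-factor cohort with known structure."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    recs = []
    for i in range(n_inf):
        u0 = rng.normal(0, sd_int)
        u1 = rng.normal(0, sd_slope)
        for tp in (4, 6, 9, 12):
            if unbalanced and rng.random() < 0.12:
                continue
            for e in range(n_ev):
                for limb in ("arm", "leg"):
                    mu = (0.5 + u0 + (u1 if limb == "leg" else 0.0)
                          + effects.get((tp, limb), 0.0))
                    recs.append((f"i{i:02d}", tp, limb, e,
                                 mu + rng.normal(0, sd_resid)))
    return pd.DataFrame(recs, columns=["infant_id", "time_point", "limb",
                                       "event", response])


AGE_LIMB = ModelSpec(response="median_pre",
                     fixed="C(time_point) * C(limb)",
                     random="intercept_slope", method="reml",
                     factors=("time_point", "limb"))


class TestFitModel:
    def test_zero_variance_matches_ols(self):
        df = sim_age_limb(n_inf=30, sd_int=0.0, sd_slope=0.0, seed=1,
                          unbalanced=False)
        fit = fit_model(AGE_LIMB, df)
        import patsy
        y, X = patsy.dmatrices("median_pre ~ C(time_point) * C(limb)", df)
        ols = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()
        rel = np.abs(fit.beta.to_numpy() - ols.params) / (
            np.abs(ols.params) + 1e-8)
        assert np.max(rel) < 1e-4

    def test_refit_deterministic(self):
        df = sim_age_limb(seed=2)
        f1 = fit_model(AGE_LIMB, df)
        f2 = fit_model(AGE_LIMB, df)
        assert abs(f1.loglik - f2.loglik) < 1e-8

    def test_information_criterion_identities(self):
        df = sim_age_limb(seed=3)
        for random in ("intercept_slope", "intercept", "none"):
            fit = fit_model(AGE_LIMB.with_(random=random), df)
            assert fit.aic == pytest.approx(
                2 * fit.n_params - 2 * fit.loglik, abs=1e-6)
            assert fit.bic == pytest.approx(
                fit.n_params * np.log(fit.n_obs) - 2 * fit.loglik, abs=1e-6)

    def test_n_params_counts_variance_parameters(self):
        df = sim_age_limb(seed=4)
        p = 8  # 1 + 3 + 1 + 3 treatment-coded columns
        expect = {"intercept_slope": p + 4, "intercept": p + 2, "none": p + 1}
        for random, k in expect.items():
            assert fit_model(AGE_LIMB.with_(random=random), df).n_params == k


class TestEffectSizeArithmetic:
    def test_cohens_f_zero(self):
        assert cohens_f_from_F(0.0, 3, 100) == 0.0
        assert partial_eta_sq_from_F(0.0, 3, 100) == 0.0

    def test_f_eta_identity(self):
        # f^2 = eta2 / (1 - eta2) for the shared convention
        f = cohens_f_from_F(10.73, 3, 273.52)
        eta = partial_eta_sq_from_F(10.73, 3, 273.52)
        assert f ** 2 == pytest.approx(eta / (1 - eta), rel=1e-12)


class TestAnova:
    def test_one_way_matches_classical(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "infant_id": [f"i{k}" for k in range(120)],
            "time_point": np.repeat([4, 6, 9, 12], 30),
            "limb": "arm",
            "median_pre": rng.normal(0, 1, 120) +
            np.repeat([0.0, 0.3, 0.1, -0.2], 30)})
        spec = ModelSpec(response="median_pre", fixed="C(time_point)",
                         random="none", factors=("time_point",))
        fit = fit_model(spec, df)
        table = anova_typeII(fit).set_index("term")
        groups = [df.loc[df.time_point == t, "median_pre"] for t in
                  (4, 6, 9, 12)]
        F_classic, _ = sps.f_oneway(*groups)
        row = table.loc["C(time_point)"]
        assert row["F"] == pytest.approx(F_classic, rel=1e-3)
        assert row["DenDF"] == pytest.approx(116, abs=0.5)
        assert row["df_fallback"]

    def test_level_order_invariance(self):
        df = sim_age_limb(seed=6)
        fit1 = fit_model(AGE_LIMB, df)
        df2 = df.copy()
        df2["time_point"] = pd.Categorical(df2["time_point"],
                                           categories=[9, 12, 4, 6])
        df2["limb"] = pd.Categorical(df2["limb"],
                                     categories=["leg", "arm"])
        fit2 = fit_model(AGE_LIMB, df2)
        a1 = anova_typeII(fit1).sort_values("term").reset_index(drop=True)
        a2 = anova_typeII(fit2).sort_values("term").reset_index(drop=True)
        # equal up to optimizer tolerance (the random-slope indicator is
        # re-parameterised when the reference level changes)
        assert np.allclose(a1["F"], a2["F"], rtol=1e-4)
        assert np.allclose(a1["p"], a2["p"], rtol=1e-3, atol=1e-12)


class TestContrasts:
    def test_bonferroni_arithmetic(self):
        df = sim_age_limb(seed=7)
        fit = fit_model(AGE_LIMB, df)
        rows = contrasts(fit, "limb_within_timepoint")
        assert len(rows) == 4
        for _, r in rows.iterrows():
            assert r["p_bonferroni"] == pytest.approx(
                min(1.0, 4 * r["p"]), rel=1e-12)

    def test_balanced_cell_mean_oracle(self):
        df = sim_age_limb(n_inf=40, sd_int=0.0, sd_slope=0.0, seed=8,
                          unbalanced=False,
                          effects={(tp, "leg"): 0.4 for tp in (4, 6, 9, 12)})
        fit = fit_model(AGE_LIMB.with_(random="none"), df)
        rows = contrasts(fit, "limb_overall")
        cell = df.groupby("limb")["median_pre"].mean()
        want = cell["leg"] - cell["arm"]
        assert rows.loc[0, "estimate"] == pytest.approx(want, abs=1e-6)

    def test_crossover_sign_recovery(self):
        hits = 0
        effects = {(6, "leg"): 0.3, (9, "leg"): -0.3, (12, "leg"): -0.3}
        for seed in range(10):
            df = sim_age_limb(n_inf=40, n_ev=10, effects=effects, seed=seed)
            fit = fit_model(AGE_LIMB, df)
            rows = contrasts(fit, "limb_within_timepoint").set_index(
                "contrast")
            ok = (rows.loc["mo6 leg - mo6 arm", "estimate"] > 0
                  and rows.loc["mo9 leg - mo9 arm", "estimate"] < 0
                  and rows.loc["mo12 leg - mo12 arm", "estimate"] < 0)
            hits += ok
        assert hits >= 9

    def test_unknown_family_rejected(self):
        df = sim_age_limb(seed=9)
        fit = fit_model(AGE_LIMB, df)
        with pytest.raises(ValueError, match="unknown contrast family"):
            contrasts(fit, "nope")


class TestModelComparison:
    def test_identical_loglik_arithmetic(self):
        stat, df, p = lrt_from_loglik(-100.0, 5, -100.0, 4)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_aic_from_loglik(self):
        assert aic_from_loglik(-100.0, 5) == 210.0
        assert bic_from_loglik(-100.0, 5, 100) == pytest.approx(
            5 * np.log(100) + 200)

    def test_nested_lrt_nonnegative(self):
        df = sim_age_limb(seed=10)
        full = fit_model(AGE_LIMB.with_(method="ml"), df)
        reduced = fit_model(AGE_LIMB.with_(method="ml", fixed=
                            "C(time_point) + C(limb)"), df)
        stat, dof, p = lrt(full, reduced)
        assert stat >= 0.0 and dof == 3

    def test_non_nested_rejected(self):
        df = sim_age_limb(seed=11)
        f1 = fit_model(AGE_LIMB.with_(method="ml",
                                      fixed="C(time_point)"), df)
        f2 = fit_model(AGE_LIMB.with_(method="ml", fixed="C(limb)"), df)
        with pytest.raises(ValueError, match="not nested"):
            lrt(f1, f2)

    def test_compare_models_table(self):
        df = sim_age_limb(seed=12)
        fits = [fit_model(AGE_LIMB.with_(method="ml", random=r), df)
                for r in ("intercept", "intercept_slope")]
        table, lrts = compare_models(fits)
        assert len(table) == 2
        assert len(lrts) == 1
        assert lrts.loc[0, "df"] == 2  # slope variance + correlation


class TestRanova:
    def test_slope_test_df2(self):
        df = sim_age_limb(seed=13)
        with_slope = fit_model(AGE_LIMB, df)
        without = fit_model(AGE_LIMB.with_(random="intercept"), df)
        out = ranova_random(with_slope, without)
        assert out["df"] == 2
        assert "boundary" in out["note"]

    def test_mismatched_fixed_rejected(self):
        df = sim_age_limb(seed=14)
        a = fit_model(AGE_LIMB, df)
        b = fit_model(AGE_LIMB.with_(random="intercept",
                                     fixed="C(limb)"), df)
        with pytest.raises(ValueError, match="identical fixed"):
            ranova_random(a, b)

    def test_power_when_slope_present(self):
        # strong slope variance: the LRT should reject
        df = sim_age_limb(n_inf=40, sd_slope=0.5, seed=15)
        out = ranova_random(fit_model(AGE_LIMB, df),
                            fit_model(AGE_LIMB.with_(random="intercept"),
                                      df))
        assert out["p"] < 0.01


class TestR2Nakagawa:
    def test_no_random_equal(self):
        df = sim_age_limb(sd_int=0.0, sd_slope=0.0, seed=16)
        marg, cond = r2_nakagawa(fit_model(AGE_LIMB.with_(random="none"),
                                           df))
        assert marg == pytest.approx(cond)

    def test_null_fixed_zero_marginal(self):
        df = sim_age_limb(seed=17)
        fit = fit_model(AGE_LIMB.with_(fixed="1"), df)
        marg, _ = r2_nakagawa(fit)
        assert marg == pytest.approx(0.0, abs=1e-6)

    def test_known_variance_decomposition(self):
        # fixed var 1.0, random 0.5, residual 0.5 -> (0.50, 0.75)
        rng = np.random.default_rng(18)
        n_g, per = 250, 20
        x = np.tile(np.repeat([-1.0, 1.0], per // 2), n_g)
        g = np.repeat(np.arange(n_g), per)
        u = rng.normal(0, np.sqrt(0.5), n_g)
        y = x + u[g] + rng.normal(0, np.sqrt(0.5), n_g * per)
        df = pd.DataFrame({"infant_id": g.astype(str), "x": x,
                           "median_pre": y})
        spec = ModelSpec(response="median_pre", fixed="x",
                         random="intercept", factors=())
        marg, cond = r2_nakagawa(fit_model(spec, df))
        assert marg == pytest.approx(0.50, abs=0.03)
        assert cond == pytest.approx(0.75, abs=0.03)


R_SCRIPT = r"""
suppressMessages({library(lmerTest); library(emmeans); library(jsonlite)})
d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
d$time_point <- factor(d$time_point, levels=c(4,6,9,12))
d$limb <- factor(d$limb, levels=c("arm","leg"))
m <- lmer(median_pre ~ time_point*limb + (1+limb|infant_id), data=d,
          REML=TRUE, control=lmerControl(optimizer="bobyqa"))
a <- anova(m, type=2, ddf="Satterthwaite")
emm <- emmeans(m, ~ limb | time_point, lmer.df="satterthwaite")
ct <- as.data.frame(summary(contrast(emm,
        method=list("leg-arm"=c(-1,1))), adjust="none"))
cat(toJSON(list(logLik=as.numeric(logLik(m)), sigma2=sigma(m)^2,
  anova=list(F=a$`F value`, DenDF=a$DenDF, SS=a$`Sum Sq`),
  ct=list(est=ct$estimate, se=ct$SE, df=ct$df)), digits=10))
"""


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_against_lmerTest_reference(tmp_path):
    """Dual-route check: fit, Type-II Satterthwaite ANOVA and marginal-mean
    contrasts against lme4/lmerTest/emmeans on the same data."""
    df = sim_age_limb(n_inf=25, n_ev=6, seed=42,
                      effects={(6, "leg"): 0.2, (9, "leg"): -0.3,
                               (12, "leg"): -0.2})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rfile = tmp_path / "check.R"
    rfile.write_text(R_SCRIPT)
    out = subprocess.run(["Rscript", str(rfile), str(csv)],
                         capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    fit = fit_model(AGE_LIMB, df)
    assert fit.loglik == pytest.approx(ref["logLik"][0], abs=1e-3)
    assert fit.sigma2 == pytest.approx(ref["sigma2"][0], rel=1e-4)
    a = anova_typeII(fit)
    assert np.allclose(a["F"], ref["anova"]["F"], rtol=1e-4)
    assert np.allclose(a["DenDF"], ref["anova"]["DenDF"], rtol=1e-3)
    assert np.allclose(a["SumSq"], ref["anova"]["SS"], rtol=1e-4)
    ct = contrasts(fit, "limb_within_timepoint")
    assert np.allclose(ct["estimate"], ref["ct"]["est"], atol=1e-6)
    assert np.allclose(ct["SE"], ref["ct"]["se"], rtol=1e-4)
    assert np.allclose(ct["df"], ref["ct"]["df"], rtol=1e-3)
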