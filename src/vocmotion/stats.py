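"""The coupling analysis: four mixed-model families and their reports.

Given event-level window-summary rows (one median per vocalisation x limb x
window, infant as the grouping factor), this module fits

1. the global model  median ~ Time_Point * Time_Window * Limb with random
   intercepts and limb slopes by infant, selected among an eight-model
   lattice by AIC/BIC/log-likelihood and a likelihood-ratio test;
2. the window model  median ~ Time_Window * Time_Point (same random
   structure) with base/pre/during pairwise contrasts;
3. per-window models median_w ~ Time_Point * Limb for w in {base, pre,
   during}, with leg-arm contrasts within each age;
4. baseline-corrected models diff_pre / diff_during ~ Time_Point * Limb
   with intercept-only random effects.

Estimation follows standard practice: ML wherever models with different
structures are compared (AIC/BIC/LRT), REML refits for the reported
coefficients, Type-II ANOVA (Satterthwaite df) and contrasts.
"""
from __future__ import annotations

import warnings
from typing import Dict, List, Optional

import pandas as pd

from .lmm import (ModelSpec, MixedFit, anova_typeII, compare_models,
                  contrasts, fit_model, lrt, r2_nakagawa, ranova_random)

FULL_FIXED = "C(time_point) * C(window) * C(limb)"
WINDOW_FIXED = "C(window) * C(time_point)"
AGE_LIMB_FIXED = "C(time_point) * C(limb)"

#: fixed-effect lattice crossed with the two random structures = 8 models
FIXED_LATTICE = {
    "mains": "C(time_point) + C(window) + C(limb)",
    "mains+window:age": ("C(time_point) + C(window) + C(limb) "
                         "+ C(window):C(time_point)"),
    "two-way": ("(C(time_point) + C(window) + C(limb)) ** 2"),
    "triple": FULL_FIXED,
}


def global_spec(method: str = "reml") -> ModelSpec:
    return ModelSpec(response="median", fixed=FULL_FIXED,
                     random="intercept_slope", method=method, name="global")


def window_spec(method: str = "reml") -> ModelSpec:
    return ModelSpec(response="median", fixed=WINDOW_FIXED,
                     random="intercept_slope", method=method,
                     name="window_by_age")


def per_window_spec(window: str, method: str = "reml") -> ModelSpec:
    return ModelSpec(response="median", fixed=AGE_LIMB_FIXED,
                     random="intercept_slope", method=method,
                     factors=("time_point", "limb"),
                     name=f"age_by_limb[{window}]")


def diff_spec(which: str, method: str = "reml") -> ModelSpec:
    """Baseline-corrected response; random slopes were not supported for
    these data, so the random structure is intercept-only."""
    if which not in ("diff_pre", "diff_during"):
        raise ValueError("which must be 'diff_pre' or 'diff_during'")
    return ModelSpec(response=which, fixed=AGE_LIMB_FIXED,
                     random="intercept", method=method,
                     factors=("time_point", "limb"), name=which)


def fit_global_lattice(rows: pd.DataFrame) -> List[MixedFit]:
    """The eight candidate global models under ML, for model comparison."""
    fits = []
    for fname, fixed in FIXED_LATTICE.items():
        for random in ("intercept", "intercept_slope"):
            spec = ModelSpec(response="median", fixed=fixed, random=random,
                             method="ml", name=f"{fname}|{random}")
            fits.append(fit_model(spec, rows))
    return fits


def _family_report(fit: MixedFit, fit_no_slope: Optional[MixedFit],
                   contrast_families: List[str]) -> dict:
    rep = {
        "anova": anova_typeII(fit).to_dict(orient="records"),
        "loglik": fit.loglik, "AIC": fit.aic, "BIC": fit.bic,
        "n_params": fit.n_params, "n_obs": fit.n_obs,
        "sigma2": fit.sigma2,
        "re_sd_intercept": fit.re_sd_intercept,
        "re_sd_slope": fit.re_sd_slope,
        "re_corr": fit.re_corr,
        "converged": fit.converged,
        "coefficients": fit.beta.to_dict(),
    }
    if fit_no_slope is not None:
        rep["ranova"] = ranova_random(fit, fit_no_slope)
    rep["contrasts"] = {
        fam: contrasts(fit, fam).drop(columns=["df_fallback"])
        .to_dict(orient="records") for fam in contrast_families}
    return rep


def run_full_suite(event_rows: pd.DataFrame,
                   diff_rows: Optional[pd.DataFrame] = None,
                   lattice: bool = True) -> dict:
    """Fit all four model families and emit a machine-readable report.

    ``event_rows``: long event-level table (infant_id, time_point, limb,
    window, event, median).  ``diff_rows``: wide table with diff_pre /
    diff_during per event (computed from event_rows when omitted).
    """
    from .epoching import baseline_diffs
    if diff_rows is None:
        diff_rows = baseline_diffs(event_rows)
    report: Dict[str, dict] = {}

    # -- global triple-interaction family -------------------------------
    glob = {}
    if lattice:
        ml_fits = fit_global_lattice(event_rows)
        table, lrts = compare_models(ml_fits)
        best = table.sort_values("loglik", ascending=False).iloc[0]
        glob["lattice"] = table.to_dict(orient="records")
        glob["lattice_lrts"] = lrts.to_dict(orient="records")
        glob["best_by_loglik"] = str(best["model"])
        full_ml = next(f for f in ml_fits
                       if f.spec.name == "triple|intercept_slope")
        drop_ml = next(f for f in ml_fits
                       if f.spec.name == "two-way|intercept_slope")
        stat, df, p = lrt(full_ml, drop_ml)
        glob["triple_vs_twoway_lrt"] = {"LRT": stat, "df": df, "p": p}
    gfit = fit_model(global_spec("reml"), event_rows)
    marg, cond = r2_nakagawa(gfit)
    glob.update(anova=anova_typeII(gfit).to_dict(orient="records"),
                r2_marginal=marg, r2_conditional=cond,
                loglik=gfit.loglik, AIC=gfit.aic, n_params=gfit.n_params,
                converged=gfit.converged)
    report["global"] = glob

    # -- window x age family --------------------------------------------
    wfit = fit_model(window_spec("reml"), event_rows)
    wfit_ns = fit_model(window_spec("reml").with_(random="intercept"),
                        event_rows)
    report["window_by_age"] = _family_report(wfit, wfit_ns, ["window_pairs"])

    # -- per-window age x limb families ---------------------------------
    for window in ("pre", "during", "base"):
        sub = event_rows[event_rows["window"] == window]
        fit = fit_model(per_window_spec(window, "reml"), sub)
        fit_ns = fit_model(
            per_window_spec(window, "reml").with_(random="intercept"), sub)
        fams = (["limb_overall", "limb_age_block"] if window == "base"
                else ["limb_within_timepoint"])
        report[f"window[{window}]"] = _family_report(fit, fit_ns, fams)

    # -- baseline-corrected families ------------------------------------
    for which in ("diff_pre", "diff_during"):
        fit = fit_model(diff_spec(which, "reml"), diff_rows)
        fit_none = fit_model(diff_spec(which, "reml").with_(random="none"),
                             diff_rows)
        fams = (["limb_overall", "limb_age_block"] if which == "diff_during"
                else ["limb_age_block"])
        report[which] = _family_report(fit, fit_none, fams)
    return report
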