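"""Simulation studies that validate the pipeline's statistical behaviour.

These are the package's own calibration experiments: synchronisation
accuracy over random clock offsets, type-I error of the window test under
zero coupling, recovery of injected window ordering and limb-by-age
crossover, and Wald confidence-interval coverage.  They run on the
generator's distributional layer (:func:`vocmotion.synthetic.simulate_rows`)
except for the sync sweep, which synthesises full audio + accelerometer
sessions.
"""
from __future__ import annotations

import numpy as np

from .lmm import anova_typeII, contrasts, fit_model
from .stats import per_window_spec, window_spec
from .synthetic import SimConfig, simulate_rows, simulate_session
from . import sync_qc


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31, size=n)


def sync_lag_sweep(n_seeds: int = 50, seed: int = 0,
                   session_duration: float = 25.0) -> dict:
    """Recover audio-IMU lags drawn U(-2, 2) s from synthesised sessions.

    Returns per-seed absolute errors (s) and their maximum; the pipeline
    targets recovery within one 60 Hz sample.
    """
    errors = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        lag = float(rng.uniform(-2.0, 2.0))
        cfg = SimConfig(session_duration=session_duration, voc_rate=4.0,
                        lag_audio_imu=lag, n_artifacts=0, n_gaps=0,
                        n_rate_drops=0)
        sess, _ = simulate_session("x", 6, (0.0, 0.0), cfg,
                                   seed=int(s) % (2 ** 31))
        hands = [c for c in sess.channels
                 if c.placement.wearer == "caregiver"]
        est = sync_qc.estimate_lag(sess.audio, hands)
        errors.append(abs(est.lag - lag))
    return {"errors": errors, "max_abs_error": float(max(errors)),
            "n": n_seeds}


def type1_study(n_reps: int = 200, seed: int = 0, n_infants: int = 20,
                events_per_visit: int = 8, alpha: float = 0.05) -> dict:
    """Rejection rate of the Time_Window main effect under zero coupling.

    Cohorts keep the baseline and random-effect structure but carry no
    window increments; a calibrated test rejects at ~alpha.
    """
    cfg = SimConfig(n_infants=n_infants, events_per_visit=events_per_visit,
                    coupling_delta={})
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        rows, _ = simulate_rows(cfg, seed=int(s))
        fit = fit_model(window_spec("reml"), rows)
        table = anova_typeII(fit).set_index("term")
        rejections += table.loc["C(window)", "p"] < alpha
    # exact binomial central 95% acceptance region around alpha
    from scipy.stats import binom
    lo, hi = binom.ppf([0.025, 0.975], n_reps, alpha) / n_reps
    return {"rate": rejections / n_reps, "n": n_reps,
            "binomial_ci": (float(lo), float(hi))}


def window_recovery_study(n_reps: int = 50, seed: int = 0,
                          n_infants: int = 60,
                          events_per_visit: int = 40) -> dict:
    """Recovery of injected window ordering and limb-by-age crossover.

    Per replicate the window model must find all three pairwise window
    contrasts significant (Bonferroni p < 0.05) with base < pre < during,
    and the pre-window age-by-limb model must reproduce the injected
    crossover signs (legs above arms at 6 months, arms above legs at 9 and
    12 months).
    """
    cfg = SimConfig(n_infants=n_infants, events_per_visit=events_per_visit)
    order_hits = 0
    sign_hits = 0
    for s in _child_seeds(seed, n_reps):
        rows, _ = simulate_rows(cfg, seed=int(s))
        wfit = fit_model(window_spec("reml"), rows)
        ct = contrasts(wfit, "window_pairs").set_index("contrast")
        ordered = (ct.loc["base - pre", "estimate"] < 0
                   and ct.loc["pre - during", "estimate"] < 0
                   and ct.loc["base - during", "estimate"] < 0)
        significant = (ct["p_bonferroni"] < 0.05).all()
        order_hits += ordered and significant
        pre = rows[rows["window"] == "pre"]
        pfit = fit_model(per_window_spec("pre"), pre)
        pc = contrasts(pfit, "limb_within_timepoint").set_index("contrast")
        sign_hits += (pc.loc["mo6 leg - mo6 arm", "estimate"] > 0
                      and pc.loc["mo9 leg - mo9 arm", "estimate"] < 0
                      and pc.loc["mo12 leg - mo12 arm", "estimate"] < 0)
    return {"order_rate": order_hits / n_reps,
            "crossover_rate": sign_hits / n_reps, "n": n_reps}


def coverage_study(n_reps: int = 200, seed: int = 0, n_infants: int = 60,
                   events_per_visit: int = 8, sd_intercept: float = 0.3,
                   sd_slope: float = 0.2) -> dict:
    """95% Wald CI coverage of each fixed effect in the age-by-limb model.

    The pre-window model is saturated in (time point x limb), so the true
    coefficient vector solves the cell-mean system exactly.
    """
    import patsy

    cfg = SimConfig(n_infants=n_infants, events_per_visit=events_per_visit,
                    sd_intercept=sd_intercept, sd_slope_limb=sd_slope,
                    corr_int_slope=0.0)
    spec = per_window_spec("pre")
    hits = None
    true_beta = None
    for s in _child_seeds(seed, n_reps):
        rows, _ = simulate_rows(cfg, seed=int(s))
        pre = rows[rows["window"] == "pre"]
        fit = fit_model(spec, pre)
        if true_beta is None:
            import pandas as pd
            grid = pd.DataFrame(
                [(tp, limb) for tp in cfg.timepoints
                 for limb in ("arm", "leg")],
                columns=["time_point", "limb"])
            mu = np.array([cfg.cell_mean(tp, limb, "pre")
                           for tp, limb in grid.itertuples(index=False)])
            (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
            true_beta, *_ = np.linalg.lstsq(np.asarray(Xg), mu, rcond=None)
            hits = np.zeros(true_beta.size)
        se = np.sqrt(np.diag(fit.cov_beta))
        beta = fit.beta.to_numpy()
        hits += (np.abs(beta - true_beta) <= 1.96 * se)
    coverage = hits / n_reps
    return {"coverage": {name: float(c) for name, c in
                         zip(fit.beta.index, coverage)},
            "min": float(coverage.min()), "max": float(coverage.max()),
            "n": n_reps}
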