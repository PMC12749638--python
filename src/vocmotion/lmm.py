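"""Linear mixed-model fitting and the inference layer the analysis reports.

Fitting goes through :class:`statsmodels` MixedLM (ML or REML).  On top of
the fitted variance parameters this module provides the pieces statsmodels
does not: Satterthwaite denominator degrees of freedom, Type-II Wald F
tests, estimated-marginal-mean contrasts with Bonferroni correction,
random-effect likelihood-ratio tests, and Nakagawa marginal/conditional R².

Implementation notes
--------------------
With grouped random effects, V_i = sigma^2 I + Z_i G Z_i'.  All likelihood
quantities are evaluated from per-group sufficient statistics via the
Woodbury identity, so the REML/ML log-likelihood, its numerical Hessian
(the variance-parameter covariance A used by Satterthwaite), and the
perturbed fixed-effect covariances Phi(theta +/- h) are cheap regardless of
the number of observations.  For a contrast l the Satterthwaite df is
2*C^2 / (g' A g) with C = l' Phi l and g the numerical gradient of C in
theta; multi-df F tests combine one-df components exactly as lmerTest does.
The log-likelihood convention matches lme4 (REML criterion includes the
log|X'V^-1 X| and (n-p) log 2pi terms), and the parameter count is
p + #variance parameters (including sigma^2).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "ModelSpec", "MixedFit", "fit_model", "anova_typeII", "emmeans",
    "contrasts", "ranova_random", "compare_models", "lrt", "r2_nakagawa",
    "cohens_f_from_F", "partial_eta_sq_from_F", "aic_from_loglik",
    "bic_from_loglik", "lrt_from_loglik",
]

FACTOR_LEVELS = {
    "time_point": [4, 6, 9, 12],
    "window": ["base", "pre", "during"],
    "limb": ["arm", "leg"],
}


# --------------------------------------------------------------------------
# Pure arithmetic helpers (also the worked-example layer)
# --------------------------------------------------------------------------

def cohens_f_from_F(F: float, num_df: float, den_df: float) -> float:
    """Omnibus Cohen's f for an F test: sqrt(NumDF * F / DenDF)."""
    return float(np.sqrt(num_df * F / den_df))


def partial_eta_sq_from_F(F: float, num_df: float, den_df: float) -> float:
    """Partial eta^2 = NumDF*F / (NumDF*F + DenDF)."""
    return float(num_df * F / (num_df * F + den_df))


def aic_from_loglik(loglik: float, n_params: int) -> float:
    return 2.0 * n_params - 2.0 * loglik


def bic_from_loglik(loglik: float, n_params: int, n_obs: int) -> float:
    return n_params * np.log(n_obs) - 2.0 * loglik


def lrt_from_loglik(loglik_full: float, n_params_full: int,
                    loglik_reduced: float, n_params_reduced: int):
    """Likelihood-ratio chi-square between nested fits.

    Returns (statistic, df, p).  Statistics are reported as
    2*(ll_full - ll_reduced); tiny optimizer-noise negatives are clipped.
    """
    stat = 2.0 * (loglik_full - loglik_reduced)
    if -1e-6 < stat < 0:
        stat = 0.0
    df = n_params_full - n_params_reduced
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), p


# --------------------------------------------------------------------------
# Model specification and fitting
# --------------------------------------------------------------------------

RANDOM_STRUCTURES = ("intercept_slope", "intercept", "none")


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification over the window-summary factors."""

    response: str
    fixed: str                      # patsy right-hand side
    random: str = "intercept_slope"  # random structure by infant
    method: str = "reml"            # "reml" | "ml"
    group: str = "infant_id"
    slope_var: str = "limb"
    factors: Tuple[str, ...] = ("time_point", "window", "limb")
    name: str = ""

    def __post_init__(self):
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.method not in ("reml", "ml"):
            raise ValueError(f"unknown estimation method {self.method!r}")

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"

    def with_(self, **kw) -> "ModelSpec":
        d = self.__dict__ | kw
        return ModelSpec(**d)


@dataclass
class MixedFit:
    """A fitted mixed model plus everything the inference layer needs."""

    spec: ModelSpec
    beta: pd.Series
    cov_beta: np.ndarray            # Phi = (X' V^-1 X)^-1
    sigma2: float
    cov_re: np.ndarray              # G (q x q; empty for OLS)
    loglik: float
    n_params: int
    n_obs: int
    n_groups: int
    converged: bool
    design_info: object = field(repr=False, default=None)
    _suff: dict = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _sat: dict = field(repr=False, default=None)
    data: pd.DataFrame = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    Z: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def aic(self) -> float:
        return aic_from_loglik(self.loglik, self.n_params)

    @property
    def bic(self) -> float:
        return bic_from_loglik(self.loglik, self.n_params, self.n_obs)

    @property
    def re_sd_intercept(self) -> float:
        return float(np.sqrt(self.cov_re[0, 0])) if self.cov_re.size else 0.0

    @property
    def re_sd_slope(self) -> float:
        return (float(np.sqrt(self.cov_re[1, 1]))
                if self.cov_re.shape[0] > 1 else 0.0)

    @property
    def re_corr(self) -> float:
        if self.cov_re.shape[0] > 1:
            d = np.sqrt(self.cov_re[0, 0] * self.cov_re[1, 1])
            return float(self.cov_re[0, 1] / d) if d > 0 else 0.0
        return 0.0


def _prepare_data(spec: ModelSpec, rows: pd.DataFrame) -> pd.DataFrame:
    data = rows.copy()
    for col, levels in FACTOR_LEVELS.items():
        if col in data.columns and not isinstance(data[col].dtype,
                                                  pd.CategoricalDtype):
            present = [l for l in levels if l in set(data[col])]
            extra = [l for l in pd.unique(data[col]) if l not in present]
            data[col] = pd.Categorical(data[col],
                                       categories=present + sorted(extra))
    return data


def _random_design(spec: ModelSpec, data: pd.DataFrame) -> Optional[np.ndarray]:
    if spec.random == "none":
        return None
    n = len(data)
    if spec.random == "intercept":
        return np.ones((n, 1))
    lv = data[spec.slope_var]
    ref = lv.cat.categories[0] if hasattr(lv, "cat") else sorted(set(lv))[0]
    ind = (np.asarray(lv) != ref).astype(float)
    return np.column_stack([np.ones(n), ind])


def _suff_stats(y, X, Z, group_codes):
    """Per-group cross-products for Woodbury likelihood evaluations."""
    groups = {}
    order = np.argsort(group_codes, kind="stable")
    gc = group_codes[order]
    y, X = y[order], X[order]
    Z = Z[order] if Z is not None else None
    edges = np.flatnonzero(np.diff(gc)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [gc.size]))
    for a, b in zip(starts, ends):
        Xi, yi = X[a:b], y[a:b]
        d = {"n": b - a, "XtX": Xi.T @ Xi, "Xty": Xi.T @ yi,
             "yty": float(yi @ yi)}
        if Z is not None:
            Zi = Z[a:b]
            d.update(ZtZ=Zi.T @ Zi, ZtX=Zi.T @ Xi, Zty=Zi.T @ yi)
        groups[gc[a]] = d
    return groups


def _theta_to_G(theta: np.ndarray, q: int) -> np.ndarray:
    if q == 0:
        return np.empty((0, 0))
    if q == 1:
        return np.array([[theta[1]]])
    return np.array([[theta[1], theta[2]], [theta[2], theta[3]]])


def _gls_pieces(theta: np.ndarray, suff: dict, q: int):
    """(S, u, w, logdetV) with S = X'V^-1 X, u = X'V^-1 y, w = y'V^-1 y."""
    sigma2 = theta[0]
    G = _theta_to_G(theta, q)
    p = next(iter(suff.values()))["XtX"].shape[0]
    S = np.zeros((p, p))
    u = np.zeros(p)
    w = 0.0
    logdetV = 0.0
    for d in suff.values():
        logdetV += d["n"] * np.log(sigma2)
        if q:
            M = np.eye(q) + d["ZtZ"] @ G / sigma2
            sign, ld = np.linalg.slogdet(M)
            logdetV += ld
            K = G @ np.linalg.inv(sigma2 * M)  # = G (sigma2 I + ZtZ G)^-1
            S += (d["XtX"] - d["ZtX"].T @ K @ d["ZtX"]) / sigma2
            u += (d["Xty"] - d["ZtX"].T @ K @ d["Zty"]) / sigma2
            w += (d["yty"] - d["Zty"] @ K @ d["Zty"]) / sigma2
        else:
            S += d["XtX"] / sigma2
            u += d["Xty"] / sigma2
            w += d["yty"] / sigma2
    return S, u, w, logdetV


def _loglik(theta: np.ndarray, suff: dict, q: int, n_obs: int, p: int,
            reml: bool) -> float:
    if theta[0] <= 0:
        return -np.inf
    S, u, w, logdetV = _gls_pieces(theta, suff, q)
    beta = np.linalg.solve(S, u)
    quad = w - u @ beta
    if reml:
        sign, logdetS = np.linalg.slogdet(S)
        return -0.5 * ((n_obs - p) * np.log(2 * np.pi) + logdetV
                       + logdetS + quad)
    return -0.5 * (n_obs * np.log(2 * np.pi) + logdetV + quad)


def fit_model(spec: ModelSpec, rows: pd.DataFrame) -> MixedFit:
    """Fit one model specification on summary rows.

    Mixed structures are estimated with statsmodels MixedLM; the pure
    fixed-effects structure falls back to OLS.  The returned fit carries
    GLS fixed-effect covariance and the sufficient statistics needed for
    Satterthwaite df downstream.
    """
    data = _prepare_data(spec, rows)
    if data[spec.response].isna().any():
        data = data.dropna(subset=[spec.response])
    y_dm, X_dm = patsy.dmatrices(spec.formula, data,
                                 return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    design_info = X_dm.design_info
    p = X.shape[1]
    Z = _random_design(spec, data)
    groups, group_codes = np.unique(np.asarray(data[spec.group]),
                                    return_inverse=True)
    q = 0 if Z is None else Z.shape[1]
    suff = _suff_stats(y, X, Z, group_codes)
    reml = spec.method == "reml"

    if spec.random == "none":
        ols = sm.OLS(y, X).fit()
        # ML scale under ML, REML (residual-df) scale under REML, so that
        # LRTs against mixed fits compare matched criteria
        dof = (len(y) - p) if reml else len(y)
        theta = np.array([float(ols.ssr / dof)])
        converged = True
        cov_re = np.empty((0, 0))
    else:
        model = sm.MixedLM(y, X, groups=group_codes, exog_re=Z)
        res, last_exc = None, None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for opt in ("lbfgs", "bfgs", "cg", "nm", "powell"):
                try:
                    cand = model.fit(reml=reml, method=opt, maxiter=500)
                except Exception as exc:  # noqa: BLE001 - optimizer hiccup
                    last_exc = exc
                    continue
                if np.isfinite(cand.llf):
                    res = cand
                    if cand.converged:
                        break
        if res is None:
            raise RuntimeError(
                f"mixed-model fit failed for {spec.name or spec.fixed!r} "
                f"(n_obs={len(y)}, groups={len(np.unique(group_codes))}): "
                f"{last_exc}")
        converged = bool(res.converged)
        sigma2 = float(res.scale)
        G = np.atleast_2d(np.asarray(res.cov_re))
        if q == 1:
            theta = np.array([sigma2, G[0, 0]])
        else:
            theta = np.array([sigma2, G[0, 0], G[0, 1], G[1, 1]])
        cov_re = G

    S, u, w, _ = _gls_pieces(theta, suff, q)
    Phi = np.linalg.inv(S)
    beta = Phi @ u
    ll = _loglik(theta, suff, q, len(y), p, reml)
    n_params = p + theta.size
    fit = MixedFit(
        spec=spec, beta=pd.Series(beta, index=X_dm.columns),
        cov_beta=Phi, sigma2=float(theta[0]), cov_re=cov_re,
        loglik=float(ll), n_params=n_params, n_obs=len(y),
        n_groups=len(groups), converged=converged,
        design_info=design_info, _suff=suff, _theta=theta,
        data=data, X=X, Z=Z)
    return fit


# --------------------------------------------------------------------------
# Satterthwaite machinery
# --------------------------------------------------------------------------

def _sat_state(fit: MixedFit) -> dict:
    """Cache: variance-parameter covariance A and perturbed Phi matrices."""
    if fit._sat is not None:
        return fit._sat
    theta = fit._theta
    q = 0 if fit.Z is None else fit.Z.shape[1]
    p = fit.X.shape[1]
    reml = fit.spec.method == "reml"
    state = {"fallback": False, "df_residual": fit.n_obs - p}
    if q == 0:
        state["fallback"] = True
        fit._sat = state
        return state

    def ll(th):
        return _loglik(th, fit._suff, q, fit.n_obs, p, reml)

    h = np.maximum(1e-4 * np.abs(theta), 1e-7)
    k = theta.size
    H = np.zeros((k, k))
    f0 = ll(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (ll(tp) - 2 * f0 + ll(tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]; tpm[j] -= h[j]
                tmp[i] -= h[i]; tmp[j] += h[j]
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = ((ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm))
                                     / (4 * h[i] * h[j]))
    try:
        A = np.linalg.inv(-H)
        if not np.all(np.isfinite(A)) or np.any(np.diag(A) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        state["fallback"] = True
        fit._sat = state
        return state
    phis_p, phis_m = [], []
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        Sp, _, _, _ = _gls_pieces(tp, fit._suff, q)
        Sm, _, _, _ = _gls_pieces(tm, fit._suff, q)
        phis_p.append(np.linalg.inv(Sp))
        phis_m.append(np.linalg.inv(Sm))
    state.update(A=A, h=h, phis_p=phis_p, phis_m=phis_m)
    fit._sat = state
    return state


def satterthwaite_df(fit: MixedFit, l: np.ndarray) -> Tuple[float, bool]:
    """Denominator df for the one-df contrast l'beta.

    Returns (df, fallback_flag); the flag marks use of the residual-df
    approximation when the variance-parameter information is unavailable.
    """
    state = _sat_state(fit)
    if state["fallback"]:
        return float(state["df_residual"]), True
    C = float(l @ fit.cov_beta @ l)
    g = np.array([
        (float(l @ Pp @ l) - float(l @ Pm @ l)) / (2 * hi)
        for Pp, Pm, hi in zip(state["phis_p"], state["phis_m"], state["h"])
    ])
    denom = float(g @ state["A"] @ g)
    if denom <= 0:
        return float(state["df_residual"]), True
    return 2.0 * C ** 2 / denom, False


def _multi_df_F(fit: MixedFit, L: np.ndarray):
    """Wald F with Satterthwaite denominator df for a q-row hypothesis.

    Follows the lmerTest construction: diagonalise L Phi L', treat the
    scaled eigen-contrasts as independent one-df t^2 components, and
    combine their Satterthwaite dfs via 2E/(E - q), E = sum nu/(nu - 2).
    """
    beta = fit.beta.to_numpy()
    M = L @ fit.cov_beta @ L.T
    qdf = L.shape[0]
    Minv = np.linalg.pinv(M)
    F = float(beta @ L.T @ Minv @ L @ beta) / qdf
    evals, evecs = np.linalg.eigh(M)
    keep = evals > max(evals.max(), 0) * 1e-10
    fallback = False
    nus = []
    for lam, v in zip(evals[keep], evecs[:, keep].T):
        l1 = (v @ L) / np.sqrt(lam)
        nu, fb = satterthwaite_df(fit, l1)
        fallback |= fb
        nus.append(nu)
    nus = np.array(nus)
    good = nus > 2
    if not good.any():
        den_df = float(fit.n_obs - fit.X.shape[1])
        fallback = True
    else:
        E = float(np.sum(nus[good] / (nus[good] - 2)))
        den_df = (2 * E / (E - keep.sum())) if E > keep.sum() else \
            float(fit.n_obs - fit.X.shape[1])
    return F, qdf, den_df, fallback


# --------------------------------------------------------------------------
# Type-II ANOVA
# --------------------------------------------------------------------------

def _doolittle(M: np.ndarray, eps: float = 1e-6):
    """Doolittle LU with unit-lower L and rank-deficiency guard."""
    n = M.shape[0]
    L = np.eye(n)
    U = np.zeros((n, n))
    for i in range(n):
        U[i, i:] = M[i, i:] - L[i, :i] @ U[:i, i:]
        if i + 1 < n:
            col = M[i + 1:, i] - L[i + 1:, :i] @ U[:i, i]
            L[i + 1:, i] = 0.0 if abs(U[i, i]) < eps else col / U[i, i]
    L[np.abs(L) < eps] = 0.0
    return L, U


def _term_layout(design_info):
    """(name, factor-set, column-indices) per design term."""
    out = []
    for term, sl in design_info.term_slices.items():
        factors = frozenset(f.name() for f in term.factors)
        out.append((term.name(), factors, list(range(sl.start, sl.stop))))
    return out


def _type2_hypothesis(design_info, XtX: np.ndarray) -> Dict[str, np.ndarray]:
    """Type-II hypothesis matrix per term (lmerTest semantics).

    A term contained in no other term gets its raw coefficient rows
    (marginal contrast).  Any other term t is orthogonalised against every
    term not containing it: the columns of t and of its higher-order
    relatives are moved last, X'X is Doolittle-decomposed in that order,
    and the unit-triangular rows belonging to t's own columns form the
    hypothesis — the classic fitting-constants construction.
    """
    layout = _term_layout(design_info)
    p = XtX.shape[0]
    I_p = np.eye(p)
    hyps = {}
    for name, factors, cols in layout:
        if not factors:  # intercept
            continue
        rel_cols = [c for _, ofac, ocols in layout
                    if ofac > factors for c in ocols]
        if not rel_cols:
            hyps[name] = I_p[cols, :]
            continue
        last = cols + rel_cols
        others = [c for c in range(p) if c not in last]
        perm = others + last
        M = XtX[np.ix_(perm, perm)]
        Ld, _ = _doolittle(M)
        Lc = Ld.T  # unit upper triangular
        term_pos = [perm.index(c) for c in cols]
        rows = Lc[term_pos, :]
        out = np.zeros_like(rows)
        out[:, perm] = rows
        hyps[name] = out
    return hyps


def anova_typeII(fit: MixedFit) -> pd.DataFrame:
    """Type-II F table with Satterthwaite denominator df and effect sizes.

    Columns mirror the conventional mixed-model ANOVA print: SumSq, MeanSq,
    NumDF, DenDF, F, p, partial_eta2, cohens_f, plus a flag marking any
    residual-df fallback.
    """
    if not fit.converged:
        warnings.warn("ANOVA on a non-converged fit", stacklevel=2)
    XtX = sum(d["XtX"] for d in fit._suff.values())
    hyps = _type2_hypothesis(fit.design_info, XtX)
    rows = []
    for name, L in hyps.items():
        if L.shape[0] == 0:
            raise ValueError(f"rank-deficient term {name!r}")
        F, num_df, den_df, fb = _multi_df_F(fit, L)
        ss = F * num_df * fit.sigma2
        rows.append({
            "term": name, "SumSq": ss, "MeanSq": ss / num_df,
            "NumDF": num_df, "DenDF": den_df, "F": F,
            "p": float(sps.f.sf(F, num_df, den_df)),
            "partial_eta2": partial_eta_sq_from_F(F, num_df, den_df),
            "cohens_f": cohens_f_from_F(F, num_df, den_df),
            "df_fallback": fb,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Estimated marginal means and contrasts
# --------------------------------------------------------------------------

def _model_factors(fit: MixedFit) -> List[str]:
    used = set()
    for term in fit.design_info.term_slices:
        for f in term.factors:
            code = f.name()
            for col in fit.spec.factors:
                if col in code:
                    used.add(col)
    return [c for c in fit.spec.factors if c in used]


def _reference_grid(fit: MixedFit):
    factors = _model_factors(fit)
    levels = {f: list(fit.data[f].cat.categories) for f in factors}
    combos = list(product(*[levels[f] for f in factors]))
    grid = pd.DataFrame(combos, columns=factors)
    for f in factors:
        grid[f] = pd.Categorical(grid[f], categories=levels[f])
    (Xg,) = patsy.build_design_matrices([fit.design_info], grid)
    return grid, np.asarray(Xg), factors


def emmeans(fit: MixedFit, by: Sequence[str]) -> pd.DataFrame:
    """Estimated marginal means over the named factors.

    Reference-grid predictions averaged with equal weights over every
    model factor not named in ``by``.
    """
    grid, Xg, factors = _reference_grid(fit)
    unknown = [b for b in by if b not in factors]
    if unknown:
        raise ValueError(f"factors {unknown} not in model ({factors})")
    beta = fit.beta.to_numpy()
    rows = []
    for levels, sub in grid.groupby(list(by), observed=True, sort=False):
        if not isinstance(levels, tuple):
            levels = (levels,)
        l = Xg[sub.index].mean(axis=0)
        est = float(l @ beta)
        se = float(np.sqrt(l @ fit.cov_beta @ l))
        df, fb = satterthwaite_df(fit, l)
        rows.append(dict(zip(by, levels)) |
                    {"emmean": est, "SE": se, "df": df, "lrow": l,
                     "df_fallback": fb})
    return pd.DataFrame(rows)


def _pairwise(emm: pd.DataFrame, fit: MixedFit, pairs, labels,
              family_size: int = None) -> pd.DataFrame:
    rows = []
    m = family_size if family_size is not None else len(pairs)
    for (i, j), label in zip(pairs, labels):
        l = emm.loc[i, "lrow"] - emm.loc[j, "lrow"]
        est = float(l @ fit.beta.to_numpy())
        se = float(np.sqrt(l @ fit.cov_beta @ l))
        df, fb = satterthwaite_df(fit, l)
        t = est / se
        p = float(2 * sps.t.sf(abs(t), df))
        rows.append({
            "contrast": label, "estimate": est, "SE": se, "df": df,
            "t": t, "p": p, "p_bonferroni": min(1.0, m * p),
            "cohens_f": abs(t) / np.sqrt(fit.n_obs),
            "df_fallback": fb,
        })
    return pd.DataFrame(rows)


CONTRAST_FAMILIES = ("window_pairs", "limb_within_timepoint", "limb_overall",
                     "limb_age_block")


def contrasts(fit: MixedFit, family: str) -> pd.DataFrame:
    """Post-hoc contrast family on the fit's marginal means.

    Families (Bonferroni m = family size; estimate = first minus second
    level of each label):

    - ``window_pairs``: base-pre, base-during, pre-during (m=3)
    - ``limb_within_timepoint``: leg-arm at each time point (m=4)
    - ``limb_overall``: leg-arm averaged over age (m=1)
    - ``limb_age_block``: leg-arm per time point plus adjacent-age steps
      within each limb (m=10)

    Contrast-level Cohen's f uses |t|/sqrt(N_obs).
    """
    if family == "window_pairs":
        emm = emmeans(fit, ["window"]).set_index("window")
        pairs = [("base", "pre"), ("base", "during"), ("pre", "during")]
        labels = [f"{a} - {b}" for a, b in pairs]
        return _pairwise(emm.reset_index().set_index("window"), fit,
                         pairs, labels)
    if family == "limb_overall":
        emm = emmeans(fit, ["limb"]).set_index("limb")
        return _pairwise(emm, fit, [("leg", "arm")], ["leg - arm"])
    if family in ("limb_within_timepoint", "limb_age_block"):
        emm = emmeans(fit, ["time_point", "limb"])
        emm.index = pd.MultiIndex.from_frame(emm[["time_point", "limb"]])
        tps = list(fit.data["time_point"].cat.categories)
        pairs = [((tp, "leg"), (tp, "arm")) for tp in tps]
        labels = [f"mo{tp} leg - mo{tp} arm" for tp in tps]
        if family == "limb_age_block":
            for limb in ("leg", "arm"):
                for a, b in zip(tps, tps[1:]):
                    pairs.append(((a, limb), (b, limb)))
                    labels.append(f"mo{a} {limb} - mo{b} {limb}")
        return _pairwise(emm, fit, pairs, labels)
    raise ValueError(f"unknown contrast family {family!r}; "
                     f"choose one of {CONTRAST_FAMILIES}")


# --------------------------------------------------------------------------
# Model comparison, random-effect tests, R^2
# --------------------------------------------------------------------------

def _fixed_terms(fit: MixedFit) -> frozenset:
    return frozenset(t.name() for t in fit.design_info.term_slices)


def _is_nested(reduced: MixedFit, full: MixedFit) -> bool:
    if reduced.spec.response != full.spec.response:
        return False
    if reduced.n_obs != full.n_obs:
        return False
    rank = {s: i for i, s in enumerate(("none", "intercept",
                                        "intercept_slope"))}
    fixed_ok = _fixed_terms(reduced) <= _fixed_terms(full)
    random_ok = rank[reduced.spec.random] <= rank[full.spec.random]
    return fixed_ok and random_ok and reduced.n_params < full.n_params


def lrt(full: MixedFit, reduced: MixedFit):
    """Likelihood-ratio test of two nested fits (matched estimation)."""
    if full.spec.method != reduced.spec.method:
        raise ValueError("LRT requires fits with matched estimation method")
    if not _is_nested(reduced, full):
        raise ValueError("models are not nested; LRT is undefined")
    return lrt_from_loglik(full.loglik, full.n_params,
                           reduced.loglik, reduced.n_params)


def compare_models(fits: Sequence[MixedFit]) -> pd.DataFrame:
    """AIC/BIC/logLik table plus LRTs over every nested pair."""
    rows = [{"model": f.spec.name or f.spec.fixed,
             "random": f.spec.random, "method": f.spec.method,
             "n_params": f.n_params, "loglik": f.loglik,
             "AIC": f.aic, "BIC": f.bic, "converged": f.converged}
            for f in fits]
    table = pd.DataFrame(rows)
    lrts = []
    for a, b in combinations(range(len(fits)), 2):
        fu, re_ = ((fits[a], fits[b]) if fits[a].n_params > fits[b].n_params
                   else (fits[b], fits[a]))
        if fu.spec.method == re_.spec.method and _is_nested(re_, fu):
            stat, df, p = lrt(fu, re_)
            lrts.append({"full": fu.spec.name or fu.spec.fixed,
                         "reduced": re_.spec.name or re_.spec.fixed,
                         "LRT": stat, "df": df, "p": p})
    return table, pd.DataFrame(lrts)


def ranova_random(fit_with: MixedFit, fit_without: MixedFit) -> dict:
    """LRT for a random-effect component (matched fixed effects).

    The chi-square reference is conservative at the variance boundary;
    the returned metadata says so.
    """
    if _fixed_terms(fit_with) != _fixed_terms(fit_without):
        raise ValueError("ranova requires identical fixed effects")
    stat, df, p = lrt(fit_with, fit_without)
    return {"LRT": stat, "df": df, "p": p,
            "note": ("variance components lie on the boundary under H0; "
                     "the chi-square p-value is conservative")}


def r2_nakagawa(fit: MixedFit) -> Tuple[float, float]:
    """Marginal and conditional R² by variance decomposition.

    marginal = var(fixed) / (var(fixed) + var(random) + sigma^2);
    conditional adds the random-effect variance to the numerator.  The
    random-effect variance is the mean of diag(Z G Z') over observations.
    """
    var_f = float(np.var(fit.X @ fit.beta.to_numpy()))
    if fit.Z is not None and fit.cov_re.size:
        var_r = float(np.mean(np.einsum("ij,jk,ik->i", fit.Z, fit.cov_re,
                                        fit.Z)))
    else:
        var_r = 0.0
    total = var_f + var_r + fit.sigma2
    return var_f / total, (var_f + var_r) / total
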