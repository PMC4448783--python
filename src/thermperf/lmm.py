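"""Quadratic thermal-reaction-norm mixed models and the random-effect ladder.

The fixed structure is always the full quadratic reaction norm

    ucrit_z ~ sex + TT + TT^2 + AT + AT:TT + AT:TT^2

with test temperature TT centered at 28 °C and the acclimation treatment AT
coded 0 (cool) / 1 (warm). Eight nested per-fish random-effect structures are
compared: an intercept only; intercept plus acute slope, curvature, or both;
and intercept plus the acclimation shift, optionally with acclimation-specific
slope and curvature changes. Restricted maximum likelihood (REML) is used to
compare random structures (identical fixed parts) and full maximum likelihood
(ML) for fixed-effect inference.

Model fitting is delegated to :class:`statsmodels` ``MixedLM``;
:func:`dense_mvn_loglik` evaluates the marginal Gaussian likelihood directly
from the assembled per-fish covariance blocks as an independent cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .simulate import AT_CODE, FIXED_TERMS, SEX_CODE, TT_CENTER

log = logging.getLogger(__name__)

#: Per-fish random-effect terms of ladder models 1-8.
LADDER_RANDOM_TERMS = {
    1: ("intercept",),
    2: ("intercept", "TT"),
    3: ("intercept", "TT2"),
    4: ("intercept", "TT", "TT2"),
    5: ("intercept", "AT"),
    6: ("intercept", "AT", "AT:TT"),
    7: ("intercept", "AT", "AT:TT2"),
    8: ("intercept", "AT", "AT:TT", "AT:TT2"),
}

#: Likelihood-ratio comparisons performed by the ladder (alt vs reference).
LADDER_LRT_PAIRS = ((2, 1), (3, 1), (4, 1), (5, 1), (6, 5), (7, 5),
                    (8, 1), (8, 5), (8, 6), (8, 7))

#: Variance component smaller than BOUNDARY_TOL x residual variance flags a
#: boundary (singular) fit; LRT p-values there use the naive chi-square
#: reference and are conservative.
BOUNDARY_TOL = 1e-4

N_FIXED = len(FIXED_TERMS)


class DesignError(ValueError):
    """Missing columns, unknown model id, or degenerate response."""


@dataclass
class Design:
    """Numeric design matrices for one ladder model."""

    model_id: int
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    X: np.ndarray          # n x 7 fixed design
    Z: np.ndarray          # n x q per-fish random design
    y: np.ndarray          # standardized response
    groups: np.ndarray     # fish identifier per row

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_fish(self) -> int:
        return len(np.unique(self.groups))

    @property
    def n_re(self) -> int:
        return self.Z.shape[1]


@dataclass
class LMMFit:
    """A fitted mixed model with its information-criterion bookkeeping.

    ``n_params`` counts fixed effects plus free variance-covariance
    parameters (including the residual variance), the count used in
    ``aic = 2 * n_params - 2 * loglik``. ``n_varcomp`` counts only the
    variance-covariance parameters; differences of ``n_varcomp`` give the
    degrees of freedom of REML likelihood-ratio tests between random
    structures.
    """

    model_id: int
    method: str                      # "ML" or "REML"
    beta_hat: dict[str, float]
    se: dict[str, float]
    cov_re: np.ndarray               # q x q random-effect covariance
    resid_var: float
    loglik: float
    n_obs: int
    n_fish: int
    n_varcomp: int
    n_params: int
    converged: bool
    boundary: bool
    random_terms: tuple[str, ...] = ()

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


@dataclass
class LRTResult:
    """REML likelihood-ratio test of a richer random structure."""

    ref_model_id: int
    alt_model_id: int
    chi2: float
    df: int
    p: float
    boundary: bool = False


def standardize_response(table: pd.DataFrame,
                         source: str = "ucrit_bl_s",
                         target: str = "ucrit_z") -> pd.DataFrame:
    """Standardize performance to units of SD from the grand mean.

    Uses the sample SD (n - 1 denominator) over all retained observations.
    Returns a copy with the ``target`` column (re)filled.
    """
    if source not in table.columns:
        raise DesignError(f"column {source!r} missing")
    vals = pd.to_numeric(table[source], errors="raise").to_numpy(float)
    if len(vals) < 2 or np.unique(vals).size < 2:
        raise DesignError("response has fewer than 2 distinct values; "
                          "cannot standardize")
    sd = vals.std(ddof=1)
    out = table.copy()
    out[target] = (vals - vals.mean()) / sd
    return out


def _model_columns(table: pd.DataFrame) -> pd.DataFrame:
    required = {"fish_id", "sex", "accl_temp_c", "test_temp_c", "ucrit_z"}
    missing = required - set(table.columns)
    if missing:
        raise DesignError(f"missing columns: {sorted(missing)}")
    cols = pd.DataFrame(index=table.index)
    sex = table["sex"].astype(str).str.lower().map(SEX_CODE)
    if sex.isna().any():
        raise DesignError("sex must be 'female' or 'male'")
    at = table["accl_temp_c"].astype(float).map(AT_CODE)
    if at.isna().any():
        raise DesignError(f"acclimation temperature must be one of "
                          f"{sorted(AT_CODE)}")
    tt = table["test_temp_c"].astype(float) - TT_CENTER
    cols["intercept"] = 1.0
    cols["sex"] = sex.astype(float)
    cols["TT"] = tt
    cols["TT2"] = tt ** 2
    cols["AT"] = at.astype(float)
    cols["AT:TT"] = cols["AT"] * tt
    cols["AT:TT2"] = cols["AT"] * tt ** 2
    return cols


def build_design(table: pd.DataFrame, model_id: int) -> Design:
    """Assemble fixed and per-fish random design matrices for one model."""
    if model_id not in LADDER_RANDOM_TERMS:
        raise DesignError(f"unknown model_id {model_id}; valid ids are 1-8")
    cols = _model_columns(table)
    random_terms = LADDER_RANDOM_TERMS[model_id]
    return Design(
        model_id=model_id,
        fixed_terms=FIXED_TERMS,
        random_terms=random_terms,
        X=cols[list(FIXED_TERMS)].to_numpy(float),
        Z=cols[list(random_terms)].to_numpy(float),
        y=table["ucrit_z"].to_numpy(float),
        groups=table["fish_id"].to_numpy(),
    )


def _embed_start(fit: "LMMFit", random_terms: tuple[str, ...],
                 ) -> MixedLMParams:
    """Start values for a richer model from a nested fit.

    The nested covariance (rescaled by the residual variance, the
    parameterization the optimizer works in) is embedded at the positions of
    the shared random terms; new terms start at a small positive variance.
    """
    q = len(random_terms)
    G = np.eye(q) * 0.01
    pos = {t: i for i, t in enumerate(random_terms)}
    src = np.atleast_2d(fit.cov_re) / fit.resid_var
    for a, ta in enumerate(fit.random_terms):
        for b, tb in enumerate(fit.random_terms):
            if ta in pos and tb in pos:
                G[pos[ta], pos[tb]] = src[a, b]
    fe = np.array([fit.beta_hat[t] for t in FIXED_TERMS])
    return MixedLMParams.from_components(fe_params=fe, cov_re=G)


def fit_lmm(design: Design, method: str = "REML",
            start: "LMMFit | None" = None) -> LMMFit:
    """Fit the Gaussian LMM by (restricted) maximum likelihood.

    Variance parameters are optimized on the profiled deviance with the
    fixed effects profiled out; standard errors come from the fixed-effect
    information matrix at the optimum.

    The profiled surface can have flat ridges for the richer covariance
    structures, where a single gradient run stalls. The optimizer is
    therefore multi-started: a cold start, plus a warm start embedded from
    ``start`` (a fit of a nested structure) or, failing that, from a cheap
    random-intercept prefit; a derivative-free Powell rescue runs when the
    gradient starts disagree. The fit with the highest (restricted)
    likelihood is returned; non-convergence is reported through the
    ``converged`` flag, never silently.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if design.n_obs <= N_FIXED:
        raise DesignError("need more observations than fixed-effect terms")
    if design.n_fish < 2:
        raise DesignError("need at least 2 fish")
    reml = method == "REML"
    model = MixedLM(design.y, design.X, groups=design.groups,
                    exog_re=design.Z)
    q = design.n_re
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        caller_start = start is not None
        if q > 1:
            if start is None:
                intercept_design = Design(
                    model_id=1, fixed_terms=design.fixed_terms,
                    random_terms=("intercept",), X=design.X,
                    Z=design.Z[:, :1], y=design.y, groups=design.groups)
                start = fit_lmm(intercept_design, method=method)
            sp = _embed_start(start, design.random_terms)
            try:
                candidates.append(model.fit(reml=reml, maxiter=500,
                                            start_params=sp))
            except Exception as exc:
                log.debug("warm start failed for model %d: %s",
                          design.model_id, exc)
        warm_ok = bool(candidates) and candidates[0].converged
        # the cold start mainly guards against a poor warm path; for the
        # largest covariances it is slow, so skip it when the warm-started
        # run from a caller-supplied nested fit already converged
        if not (caller_start and warm_ok and q >= 4):
            try:
                candidates.append(model.fit(reml=reml, maxiter=500))
            except Exception as exc:
                log.debug("cold start failed for model %d: %s",
                          design.model_id, exc)
        # a nested submodel cannot out-fit its extension: a violation means
        # every gradient start stalled, so fall back to derivative-free powell
        best = max((c.llf for c in candidates), default=-np.inf)
        violated = start is not None and best < start.loglik - 1e-6
        if violated or not any(c.converged for c in candidates):
            try:
                candidates.append(model.fit(reml=reml, maxiter=2000,
                                            method=["powell"]))
            except Exception as exc:
                log.debug("powell rescue failed for model %d: %s",
                          design.model_id, exc)
        if not candidates:
            raise RuntimeError(
                f"all optimizer starts failed for model {design.model_id}")
        result = max(candidates, key=lambda c: c.llf)
    cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    resid_var = float(result.scale)
    n_varcomp = q * (q + 1) // 2 + 1
    boundary = bool(np.any(np.diag(cov_re) < BOUNDARY_TOL * resid_var))
    return LMMFit(
        model_id=design.model_id,
        method=method,
        beta_hat=dict(zip(design.fixed_terms, map(float, result.fe_params))),
        se=dict(zip(design.fixed_terms, map(float, result.bse_fe))),
        cov_re=cov_re,
        resid_var=resid_var,
        loglik=float(result.llf),
        n_obs=design.n_obs,
        n_fish=design.n_fish,
        n_varcomp=n_varcomp,
        n_params=N_FIXED + n_varcomp,
        converged=bool(result.converged),
        boundary=boundary,
        random_terms=design.random_terms,
    )


def dense_mvn_loglik(design: Design, cov_re: np.ndarray, resid_var: float,
                     method: str = "REML",
                     beta: np.ndarray | None = None) -> float:
    """Marginal Gaussian log-likelihood from explicit covariance blocks.

    Assembles V_j = Z_j G Z_j' + s^2 I per fish and evaluates the (restricted)
    log-density directly, independently of any fitting machinery. With
    ``beta`` omitted, the GLS estimate at the supplied variance parameters is
    profiled in. REML adds the -0.5 log|X' V^-1 X| adjustment and uses the
    (n - p) log 2*pi constant.
    """
    G = np.atleast_2d(np.asarray(cov_re, dtype=float))
    X, Z, y, groups = design.X, design.Z, design.y, design.groups
    n, p = X.shape
    uniq = pd.unique(groups)
    blocks = []
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for gid in uniq:
        idx = groups == gid
        Zj = Z[idx]
        Vj = Zj @ G @ Zj.T + resid_var * np.eye(idx.sum())
        Vinv = np.linalg.inv(Vj)
        blocks.append((idx, Vj, Vinv))
        xtvx += X[idx].T @ Vinv @ X[idx]
        xtvy += X[idx].T @ Vinv @ y[idx]
    if beta is None:
        beta = np.linalg.solve(xtvx, xtvy)
    logdet = 0.0
    quad = 0.0
    for idx, Vj, Vinv in blocks:
        r = y[idx] - X[idx] @ beta
        sign, ld = np.linalg.slogdet(Vj)
        logdet += ld
        quad += r @ Vinv @ r
    if method == "ML":
        return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    sign, ldx = np.linalg.slogdet(xtvx)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + ldx + quad)


def lrt(alt: LMMFit, ref: LMMFit) -> LRTResult:
    """Likelihood-ratio test of a nested random-structure pair.

    chi2 is clipped at zero; the degrees of freedom are the difference in
    variance-covariance parameter counts. Null variance components sit on
    the boundary of the parameter space, so the naive chi-square reference
    used here is conservative; such cases carry ``boundary=True``.
    """
    if alt.method != ref.method:
        raise ValueError("compared fits must use the same likelihood method")
    chi2 = max(0.0, 2.0 * (alt.loglik - ref.loglik))
    df = alt.n_varcomp - ref.n_varcomp
    if df < 1:
        df = 1 if alt.model_id != ref.model_id else 0
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(ref_model_id=ref.model_id, alt_model_id=alt.model_id,
                     chi2=chi2, df=df, p=p,
                     boundary=alt.boundary or ref.boundary)


def run_ladder(table: pd.DataFrame,
               model_ids: tuple[int, ...] = tuple(range(1, 9)),
               ) -> tuple[pd.DataFrame, dict[int, LMMFit]]:
    """Fit the random-effect ladder by REML and run its LRT comparisons.

    Returns a report table (one row per model with parameter counts, AIC,
    log-likelihood and the test against its reference model) plus the fits
    themselves. Fit failures are recorded per row rather than aborting the
    ladder.
    """
    fits: dict[int, LMMFit] = {}
    errors: dict[int, str] = {}
    for mid in sorted(model_ids):
        # warm-start each model from its best already-fitted nested submodel
        refs = [r for a, r in LADDER_LRT_PAIRS if a == mid and r in fits]
        start = None
        if refs:
            start = fits[max(refs, key=lambda r: (fits[r].n_varcomp,
                                                  fits[r].loglik))]
        try:
            fits[mid] = fit_lmm(build_design(table, mid), method="REML",
                                start=start)
        except DesignError:
            raise
        except Exception as exc:  # numerical failures recorded per row
            errors[mid] = f"{type(exc).__name__}: {exc}"

    rows = []
    for mid in model_ids:
        base = {"model_id": mid,
                "random_terms": "+".join(LADDER_RANDOM_TERMS[mid])}
        if mid in errors:
            rows.append({**base, "error": errors[mid]})
            continue
        f = fits[mid]
        row = {**base, "n_params": f.n_params, "n_varcomp": f.n_varcomp,
               "aic": f.aic, "loglik": f.loglik, "converged": f.converged,
               "boundary": f.boundary, "error": ""}
        refs = [r for a, r in LADDER_LRT_PAIRS if a == mid and r in fits]
        if refs:
            # primary reference: the largest nested sub-model present
            primary = max(refs, key=lambda r: fits[r].n_varcomp)
            t = lrt(f, fits[primary])
            row.update(ref_model_id=primary, chi2=t.chi2, lrt_df=t.df,
                       p=t.p)
        rows.append(row)
    report = pd.DataFrame(rows)
    return report, fits


def ladder_lrt_table(fits: dict[int, LMMFit]) -> pd.DataFrame:
    """All pairwise ladder LRTs (alt vs reference) as a tidy table."""
    rows = []
    for alt_id, ref_id in LADDER_LRT_PAIRS:
        if alt_id in fits and ref_id in fits:
            t = lrt(fits[alt_id], fits[ref_id])
            rows.append({"alt_model_id": alt_id, "ref_model_id": ref_id,
                         "chi2": t.chi2, "df": t.df, "p": t.p,
                         "boundary": t.boundary})
    return pd.DataFrame(rows)


def fixed_effect_table(fit: LMMFit, df_method: str = "residual",
                       ) -> pd.DataFrame:
    """Fixed-effect report (estimate, SE, df, t, p) for the model-1 ML fit.

    The degrees-of-freedom method is pluggable: the default ``"residual"``
    uses n_obs - n_fixed for every term; a callable mapping term name to df
    may be supplied instead. Estimates and SEs do not depend on this choice.
    """
    if fit.model_id != 1:
        raise ValueError("fixed-effect table is defined for model 1 "
                         f"(got model {fit.model_id})")
    if fit.method != "ML":
        raise ValueError("fixed-effect inference uses the ML fit")
    if callable(df_method):
        df_fun, df_name = df_method, getattr(df_method, "__name__", "custom")
    elif df_method == "residual":
        df_fun = lambda term: fit.n_obs - N_FIXED
        df_name = "residual"
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    rows = []
    for term in FIXED_TERMS:
        est, se = fit.beta_hat[term], fit.se[term]
        df = float(df_fun(term))
        t = est / se
        rows.append({"term": term, "estimate": est, "se": se, "df": df,
                     "t": t, "p": 2.0 * float(stats.t.sf(abs(t), df)),
                     "df_method": df_name})
    return pd.DataFrame(rows)
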