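"""AIC-based multimodel inference of temporal trends.

The workflow the analysis modules share:

1. :func:`enumerate_candidates` builds every marginality-respecting fixed-
   effect structure from a predictor list and a time term (all subsets of
   predictors, with or without time, with or without each predictor x time
   interaction; an interaction requires both parents).
2. :func:`fit_candidate` fits each structure by maximum likelihood: linear
   mixed models (Gaussian) or Poisson generalized linear mixed models, with
   plot nested within transect as random intercepts; a ``flat=True`` option
   degrades to OLS/GLM so closed-form oracles apply.
3. :func:`rank_and_select` ranks by AIC and keeps models with dAIC < 4
   (strict), renormalising Akaike weights over the selected set.
4. :func:`full_average` produces the full (zero-substitution) averaged
   coefficients with averaged standard errors and 95% confidence limits.
5. :func:`r_squared` gives marginal/conditional pseudo-R2 for Gaussian fits.

Gaussian mixed fits delegate to statsmodels MixedLM; Poisson mixed fits use
an in-package Laplace approximation (random intercepts only), cross-checked
against lme4's glmer in the test suite. The parameter count k includes
variance components (and the Gaussian residual variance).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import scipy.optimize
import scipy.special
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("floradyn")

__all__ = [
    "CandidateModel",
    "AveragedModel",
    "enumerate_candidates",
    "fit_candidate",
    "fit_all",
    "rank_and_select",
    "full_average",
    "r_squared",
]

Z_95 = 1.959963984540054


@dataclass
class CandidateModel:
    """One fitted candidate: term set, likelihood, AIC and coefficients."""

    model_id: int
    terms: frozenset
    formula: str
    family: str
    loglik: float
    k: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    fixed_var: float = np.nan     # population variance of the fixed-effect predictor
    re_var: float = np.nan        # summed random-intercept variances
    resid_var: float = np.nan     # residual variance (gaussian)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


def enumerate_candidates(predictors, time: str | None = "time") -> list:
    """All marginality-respecting term sets (as frozensets).

    With p predictors and a time term this yields 2^p + 3^p models: time
    absent -> any predictor subset; time present -> each predictor absent,
    main-effect-only, or main effect + its interaction with time. The empty
    set (intercept-only) is always included.
    """
    predictors = list(predictors)
    out = []
    for subset in itertools.chain.from_iterable(
            itertools.combinations(predictors, r) for r in range(len(predictors) + 1)):
        out.append(frozenset(subset))
    if time is not None:
        for assign in itertools.product((0, 1, 2), repeat=len(predictors)):
            terms = {time}
            for pred, a in zip(predictors, assign):
                if a >= 1:
                    terms.add(pred)
                if a == 2:
                    terms.add(f"{pred}:{time}")
            out.append(frozenset(terms))
    return out


def _formula(response: str, terms: frozenset) -> str:
    ordered = sorted(terms, key=lambda t: (t.count(":"), t))
    rhs = " + ".join(ordered) if ordered else "1"
    return f"{response} ~ {rhs}"


def fit_candidate(terms: frozenset, data: pd.DataFrame, response: str,
                  family: str = "gaussian", groups: tuple = ("transect", "plot"),
                  flat: bool = False, model_id: int = 0) -> CandidateModel:
    """ML fit of one candidate structure.

    ``groups`` names the (outer, inner) grouping columns for the nested
    random intercepts; with ``flat=True`` the model is an ordinary OLS
    (Gaussian) or Poisson GLM, which closed-form oracles can check.
    Non-convergence is flagged on the result, never raised.
    """
    if family not in ("gaussian", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    formula = _formula(response, terms)
    y = data[response].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise ValueError(f"non-finite response values in {response!r}")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("poisson family requires non-negative integer response")

    if flat:
        return _fit_flat(formula, terms, data, family, model_id)
    if family == "gaussian":
        return _fit_lmm(formula, terms, data, groups, model_id)
    return _fit_poisson_glmm(formula, terms, data, groups, model_id)


def _fit_flat(formula, terms, data, family, model_id) -> CandidateModel:
    if family == "gaussian":
        res = smf.ols(formula, data).fit()
        k = int(res.df_model) + 1 + 1          # coefficients + residual variance
        return CandidateModel(model_id, terms, formula, family, float(res.llf), k,
                              res.params, res.bse, True,
                              fixed_var=float(np.var(res.fittedvalues)),
                              re_var=0.0, resid_var=float(res.ssr / res.nobs))
    res = smf.glm(formula, data, family=sm.families.Poisson()).fit()
    eta = res.model.exog @ res.params.to_numpy()
    return CandidateModel(model_id, terms, formula, family, float(res.llf),
                          len(res.params), res.params, res.bse, True,
                          fixed_var=float(np.var(eta)), re_var=0.0, resid_var=np.nan)


def _fit_lmm(formula, terms, data, groups, model_id) -> CandidateModel:
    outer, inner = groups
    vcf = {inner: f"0 + C({inner})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mod = smf.mixedlm(formula, data, groups=data[outer],
                              re_formula="1", vc_formula=vcf)
            res = mod.fit(reml=False, method="lbfgs")
            # gradient methods stall on boundary fits (variance ~ 0); a
            # derivative-free refit usually reaches the ML optimum there
            if not res.converged:
                for alt in ("powell", "nm"):
                    res_alt = mod.fit(reml=False, method=alt)
                    if np.isfinite(res_alt.llf) and (not np.isfinite(res.llf)
                                                     or res_alt.llf >= res.llf):
                        res = res_alt
                    if res.converged:
                        break
            converged = bool(res.converged) and np.isfinite(res.llf)
        except Exception as exc:           # singular fits etc.
            logger.warning("LMM %s failed: %s", formula, exc)
            return CandidateModel(model_id, terms, formula, "gaussian",
                                  -np.inf, 0, pd.Series(dtype=float),
                                  pd.Series(dtype=float), False)
    fe = res.fe_params
    n_vc = 1 + len(res.vcomp)              # outer intercept + inner component
    k = len(fe) + n_vc + 1                 # + residual variance
    fixed = res.model.exog @ fe.to_numpy()
    re_var = float(np.asarray(res.cov_re).ravel()[0]) + float(np.sum(res.vcomp))
    return CandidateModel(model_id, terms, formula, "gaussian", float(res.llf), k,
                          fe, res.bse_fe, converged,
                          fixed_var=float(np.var(fixed)), re_var=re_var,
                          resid_var=float(res.scale))


# ---------------------------------------------------------------------------
# Poisson GLMM by Laplace approximation (random intercepts)
# ---------------------------------------------------------------------------


def _laplace_nll(params, y, X, Zs, q_sizes, logfact):
    """Negative Laplace log-likelihood at (beta, log sd per factor)."""
    p = X.shape[1]
    beta = params[:p]
    sds = np.exp(params[p:])
    d_inv = np.concatenate([np.full(q, 1.0 / max(s ** 2, 1e-12))
                            for q, s in zip(q_sizes, sds)])
    Z = Zs
    q = Z.shape[1]
    xb = X @ beta
    u = np.zeros(q)
    # Newton for the conditional mode (strictly concave)
    for _ in range(100):
        eta = xb + Z @ u
        mu = np.exp(np.clip(eta, -30, 30))
        grad = Z.T @ (y - mu) - d_inv * u
        H = (Z.T * mu) @ Z
        H[np.diag_indices_from(H)] += d_inv
        try:
            step = scipy.linalg.solve(H, grad, assume_a="pos")
        except scipy.linalg.LinAlgError:
            return np.inf
        u_new = u + step
        if not np.isfinite(u_new).all():
            return np.inf
        if np.max(np.abs(step)) < 1e-9:
            u = u_new
            break
        u = u_new
    eta = xb + Z @ u
    mu = np.exp(np.clip(eta, -30, 30))
    ll_pois = float(y @ eta - mu.sum() - logfact)
    H = (Z.T * mu) @ Z
    H[np.diag_indices_from(H)] += d_inv
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf
    logdet_D = float(np.sum(-np.log(d_inv)))
    ll = ll_pois - 0.5 * float(u @ (d_inv * u)) - 0.5 * logdet_D - 0.5 * logdet_H
    return -ll


def _fit_poisson_glmm(formula, terms, data, groups, model_id) -> CandidateModel:
    outer, inner = groups
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    y = y_dm.to_numpy(dtype=float).ravel()
    X = X_dm.to_numpy(dtype=float)
    names = list(X_dm.columns)

    # nested random intercepts: outer groups, and inner-within-outer groups
    outer_codes = pd.Categorical(data[outer]).codes
    inner_codes = pd.Categorical(
        data[outer].astype(str) + ":" + data[inner].astype(str)).codes
    Z_parts, q_sizes = [], []
    for codes in (outer_codes, inner_codes):
        qf = codes.max() + 1
        zi = np.zeros((len(y), qf))
        zi[np.arange(len(y)), codes] = 1.0
        Z_parts.append(zi)
        q_sizes.append(qf)
    Z = np.hstack(Z_parts)
    logfact = float(np.sum(scipy.special.gammaln(y + 1)))

    start_glm = smf.glm(formula, data, family=sm.families.Poisson()).fit()
    x0 = np.concatenate([start_glm.params.to_numpy(), np.log([0.3, 0.3])])
    obj = lambda par: _laplace_nll(par, y, X, Z, q_sizes, logfact)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = scipy.optimize.minimize(obj, x0, method="BFGS",
                                      options={"maxiter": 500, "gtol": 1e-6})
    converged = bool(np.isfinite(opt.fun))
    p = X.shape[1]
    beta = opt.x[:p]
    # observed information by central differences, beta block
    se = np.full(p, np.nan)
    try:
        hess = _num_hessian(obj, opt.x)
        cov = np.linalg.inv(hess)
        dg = np.diag(cov)[:p]
        se = np.sqrt(np.where(dg > 0, dg, np.nan))
    except Exception as exc:
        logger.warning("Poisson GLMM SE failed for %s: %s", formula, exc)
        converged = False
    sds = np.exp(opt.x[p:])
    k = p + len(q_sizes)
    return CandidateModel(model_id, terms, formula, "poisson", -float(opt.fun), k,
                          pd.Series(beta, index=names), pd.Series(se, index=names),
                          converged, fixed_var=float(np.var(X @ beta)),
                          re_var=float(np.sum(sds ** 2)), resid_var=np.nan)


def _num_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps ** 2)
    return h


# ---------------------------------------------------------------------------
# Ranking, selection, averaging
# ---------------------------------------------------------------------------


def fit_all(term_sets, data, response, family="gaussian",
            groups=("transect", "plot"), flat=False) -> list:
    """Fit every candidate; non-converged fits are kept but flagged."""
    return [fit_candidate(terms, data, response, family, groups, flat, mid)
            for mid, terms in enumerate(term_sets)]


@dataclass
class AveragedModel:
    """Selected candidate set with weights and full-averaged coefficients."""

    model_table: pd.DataFrame       # every converged candidate, ranked
    coefficients: pd.DataFrame      # term, estimate, se, abs_z, ci_lower, ci_upper
    selected: list = field(default_factory=list)   # CandidateModel, best first
    weights: np.ndarray = None


def rank_and_select(models: list, delta_threshold: float = 4.0) -> AveragedModel:
    """AIC-rank converged candidates and select dAIC < threshold (strict).

    Akaike weights are exp(-delta/2) renormalised over the selected set.
    Ties in AIC are broken by ascending parameter count, then model id.
    """
    conv = [m for m in models if m.converged]
    dropped = [m for m in models if not m.converged]
    for m in dropped:
        logger.info("dropped non-converged candidate %d (%s)", m.model_id, m.formula)
    if not conv:
        raise RuntimeError("no converged candidate model")
    conv = sorted(conv, key=lambda m: (m.aic, m.k, m.model_id))
    best = conv[0].aic
    deltas = np.array([m.aic - best for m in conv])
    sel_mask = deltas < delta_threshold
    selected = [m for m, s in zip(conv, sel_mask) if s]
    raw_w = np.exp(-deltas[sel_mask] / 2.0)
    weights = raw_w / raw_w.sum()
    table = pd.DataFrame({
        "model_id": [m.model_id for m in conv],
        "terms": [" + ".join(sorted(m.terms)) or "1" for m in conv],
        "k": [m.k for m in conv],
        "loglik": [m.loglik for m in conv],
        "aic": [m.aic for m in conv],
        "delta_aic": deltas,
        "selected": sel_mask,
        "weight": [weights[list(np.flatnonzero(sel_mask)).index(i)] if s else 0.0
                   for i, s in enumerate(sel_mask)],
    })
    return AveragedModel(table, pd.DataFrame(), selected, weights)


def full_average(selection: AveragedModel) -> AveragedModel:
    """Full (zero-substitution) model averaging over the selected set.

    Each coefficient is averaged over every selected model, substituting 0
    (with zero variance) where the term is absent. The averaged standard
    error uses the model-averaging variance formula with the between-model
    component: se = sum_i w_i sqrt(se_i^2 + (b_i - b_avg)^2). 95% CI is
    estimate +/- 1.96 se; the ``abs_z`` column is |estimate| / se.
    """
    models, weights = selection.selected, selection.weights
    if not models:
        raise ValueError("empty selection")
    names: list = []
    for m in models:
        for nm in m.params.index:
            if nm not in names:
                names.append(nm)
    est = np.zeros(len(names))
    for m, w in zip(models, weights):
        est += w * m.params.reindex(names).fillna(0.0).to_numpy()
    se = np.zeros(len(names))
    for m, w in zip(models, weights):
        b = m.params.reindex(names).fillna(0.0).to_numpy()
        s = m.bse.reindex(names).fillna(0.0).to_numpy()
        se += w * np.sqrt(s ** 2 + (b - est) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        absz = np.abs(np.where(se > 0, est / se, np.nan))
    coef = pd.DataFrame({
        "term": names, "estimate": est, "se": se, "abs_z": absz,
        "ci_lower": est - Z_95 * se, "ci_upper": est + Z_95 * se,
    })
    return AveragedModel(selection.model_table, coef, models, weights)


def r_squared(model: CandidateModel) -> tuple:
    """Marginal and conditional pseudo-R2 (variance-partition form).

    marginal = var_fixed / (var_fixed + var_random + var_resid); conditional
    adds var_random to the numerator. Gaussian fits only; the Poisson
    delta-method variant is not implemented.
    """
    if model.family != "gaussian":
        raise NotImplementedError("pseudo-R2 implemented for gaussian fits only")
    tot = model.fixed_var + model.re_var + model.resid_var
    if tot <= 0:
        return 0.0, 0.0
    return (model.fixed_var / tot, (model.fixed_var + model.re_var) / tot)
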