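"""Count GLMs relating true abundance to CPUE on the density scale.

Monthly abundance counts are regressed on CPUE (linear or quadratic) with a
log link and the enclosure area as exposure offset, so coefficients read on
the snakes-per-ha scale. Families: Poisson and NB2 negative binomial with
ML dispersion. Wald 95% intervals throughout; Pearson chi-square goodness of
fit; AIC-based term selection with a parsimony tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.discrete.discrete_model import NegativeBinomial, Poisson

FAMILIES = ("poisson", "negative_binomial")
TERMS = ("linear", "quadratic")

_RESPONSE_COL = {"total": "N_total", "gt900": "N_gt900"}
_PREDICTOR_COL = {"visual": "cpue_visual", "trap": "cpue_trap"}


class ConvergenceError(RuntimeError):
    """ML fit failed to converge; carries the optimizer trace."""

    def __init__(self, message, retvals=None):
        super().__init__(message)
        self.retvals = retvals


@dataclass
class GLMFit:
    """A fitted count GLM with Wald intervals, on the density scale."""

    family: str
    terms: str
    params: np.ndarray  # beta0, beta1[, beta2]
    bse: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    z: np.ndarray
    cov: np.ndarray  # covariance of the mean-model coefficients
    dispersion: float | None  # NB2 alpha; None for Poisson
    log_likelihood: float
    aic: float
    n_points: int
    area_ha: float
    cpue_range: tuple
    gof_chisq: float = np.nan
    gof_p: float = np.nan
    response: str = "total"
    predictor: str = "visual"
    _y: np.ndarray = field(default=None, repr=False)
    _x: np.ndarray = field(default=None, repr=False)

    @property
    def param_names(self):
        names = ["beta0", "beta1"] + (["beta2"] if self.terms == "quadratic" else [])
        return names

    @property
    def k_params(self) -> int:
        return len(self.params) + (1 if self.family == "negative_binomial" else 0)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "terms": self.terms,
            "response": self.response,
            "predictor": self.predictor,
            "coefficients": {
                name: {
                    "estimate": float(b),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "z": float(z),
                }
                for name, b, lo, hi, z in zip(
                    self.param_names, self.params, self.ci_lower, self.ci_upper, self.z
                )
            },
            "dispersion": None if self.dispersion is None else float(self.dispersion),
            "log_likelihood": float(self.log_likelihood),
            "aic": float(self.aic),
            "n_points": int(self.n_points),
            "gof_chisq": float(self.gof_chisq),
            "gof_p": float(self.gof_p),
            "area_ha": float(self.area_ha),
            "cpue_range": [float(v) for v in self.cpue_range],
        }
        return d


def _design(x: np.ndarray, terms: str) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if terms == "quadratic":
        cols.append(x**2)
    return np.column_stack(cols)


def _fit_ml(model, maxiter=200, start_params=None, n_mean_params=None):
    """Try a cascade of optimizers; accept the first converged fit whose
    mean-model standard errors are finite (the NB dispersion SE may be
    undefined at the alpha -> 0 boundary, which is still a valid ML solution)."""
    last = None
    if n_mean_params is None:
        n_mean_params = model.exog.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        attempts = [("newton", None), ("bfgs", None), ("nm", None)]
        if start_params is not None:
            attempts = [(m, start_params) for m, _ in attempts] + attempts
        for method, start in attempts:
            try:
                res = model.fit(
                    method=method, maxiter=maxiter, disp=0, start_params=start
                )
            except Exception:  # singular hessian etc.; try next optimizer
                continue
            last = res
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(np.asarray(res.bse)[:n_mean_params])
            ):
                return res
        raise ConvergenceError(
            f"GLM fit failed to converge after {maxiter} iterations",
            retvals=getattr(last, "mle_retvals", None),
        )


def fit_count_glm(
    panel: pd.DataFrame,
    response: str = "total",
    predictor: str = "visual",
    family: str = "poisson",
    terms: str = "linear",
    area_ha: float = 5.0,
) -> GLMFit:
    """Maximum-likelihood count regression of monthly abundance on CPUE.

    The response is the integer monthly count (``N_total`` or ``N_gt900``)
    with ``log(area_ha)`` as exposure offset; displayed coefficients therefore
    describe density = exp(beta0 + beta1*cpue [+ beta2*cpue^2]).
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if terms not in TERMS:
        raise ValueError(f"terms must be one of {TERMS}, got {terms!r}")
    ycol, xcol = _RESPONSE_COL[response], _PREDICTOR_COL[predictor]
    rows = panel[[ycol, xcol]].dropna()
    x = rows[xcol].to_numpy(float)
    y = rows[ycol].to_numpy(float)
    if not np.all(np.isfinite(x)) or (x < 0).any():
        raise ValueError(f"{xcol} must be finite and non-negative")
    n_coef = 2 if terms == "linear" else 3
    if terms == "quadratic" and len(y) < 5:
        raise ValueError(f"quadratic fit needs >= 5 panel rows, got {len(y)}")
    if len(y) < n_coef + 2:
        raise ValueError(f"need >= {n_coef + 2} usable panel rows, got {len(y)}")
    X = _design(x, terms)
    offset = np.full(len(y), np.log(area_ha))
    if family == "poisson":
        res = _fit_ml(Poisson(y, X, offset=offset))
        alpha = None
        mean_params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
    else:
        # seed from the Poisson solution: robust when alpha is near its
        # boundary (equidispersed data), where cold starts often fail
        pois = _fit_ml(Poisson(y, X, offset=offset))
        start = np.append(np.asarray(pois.params), 0.05)
        try:
            res = _fit_ml(
                NegativeBinomial(y, X, offset=offset, loglike_method="nb2"),
                start_params=start,
                n_mean_params=X.shape[1],
            )
            mean_params = np.asarray(res.params[:-1])
            alpha = float(res.params[-1])
            cov = np.asarray(res.cov_params())[:-1, :-1]
        except ConvergenceError:
            # equidispersed data pushes alpha to its 0 boundary, where the NB
            # MLE is exactly the Poisson fit; accept that solution, otherwise
            # re-raise
            mu = np.exp(X @ np.asarray(pois.params) + offset)
            pearson = float(np.sum((y - mu) ** 2 / mu)) / max(len(y) - X.shape[1], 1)
            if pearson > 1.2:
                raise
            res = pois
            mean_params = np.asarray(pois.params)
            alpha = 0.0
            cov = np.asarray(pois.cov_params())
    bse = np.sqrt(np.diag(cov))
    zcrit = st.norm.ppf(0.975)
    llf = float(res.llf)
    k_all = X.shape[1] + (1 if family == "negative_binomial" else 0)
    fit = GLMFit(
        family=family,
        terms=terms,
        params=mean_params,
        bse=bse,
        ci_lower=mean_params - zcrit * bse,
        ci_upper=mean_params + zcrit * bse,
        z=mean_params / bse,
        cov=cov,
        dispersion=alpha,
        log_likelihood=llf,
        aic=2 * k_all - 2 * llf,
        n_points=len(y),
        area_ha=area_ha,
        cpue_range=(float(x.min()), float(x.max())),
        response=response,
        predictor=predictor,
        _y=y,
        _x=x,
    )
    fit.gof_chisq, fit.gof_p = gof_chisq(fit)
    return fit


def gof_chisq(fit: GLMFit, panel: pd.DataFrame | None = None):
    """Pearson chi-square goodness of fit against the fitted family.

    X^2 = sum (obs - mu)^2 / var(mu) on n - k df, var = mu for Poisson and
    mu + alpha*mu^2 for NB2.
    """
    if panel is not None:
        ycol, xcol = _RESPONSE_COL[fit.response], _PREDICTOR_COL[fit.predictor]
        rows = panel[[ycol, xcol]].dropna()
        y = rows[ycol].to_numpy(float)
        x = rows[xcol].to_numpy(float)
    else:
        y, x = fit._y, fit._x
    X = _design(x, fit.terms)
    mu = np.exp(X @ fit.params + np.log(fit.area_ha))
    if np.any(mu <= 0):
        raise ValueError("zero fitted mean; Pearson statistic undefined")
    var = mu if fit.dispersion is None else mu + fit.dispersion * mu**2
    stat = float(np.sum((y - mu) ** 2 / var))
    df = max(len(y) - fit.k_params, 1)
    return stat, float(st.chi2.sf(stat, df))


def predict_density(fit: GLMFit, cpue_values) -> pd.DataFrame:
    """Predicted density with a Wald 95% interval on the mean.

    Density is exp(x'beta) (the area offset cancels); the interval is the
    exponentiated linear-predictor interval. Points outside the fitted CPUE
    range are returned flagged as extrapolation.
    """
    c = np.atleast_1d(np.asarray(cpue_values, float))
    X = _design(c, fit.terms)
    eta = X @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    zcrit = st.norm.ppf(0.975)
    lo_r, hi_r = fit.cpue_range
    return pd.DataFrame(
        {
            "cpue": c,
            "predicted_density": np.exp(eta),
            "ci_lower": np.exp(eta - zcrit * se),
            "ci_upper": np.exp(eta + zcrit * se),
            "extrapolated": (c < lo_r) | (c > hi_r),
        }
    )


def select_terms(
    panel: pd.DataFrame,
    family: str = "poisson",
    response: str = "total",
    predictor: str = "visual",
    area_ha: float = 5.0,
) -> dict:
    """Fit linear and quadratic CPUE terms; keep the lower-AIC model.

    Ties go to the linear model (parsimony). If one candidate fails, the
    survivor is returned with a warning.
    """
    fits, errors = {}, {}
    for terms in TERMS:
        try:
            fits[terms] = fit_count_glm(
                panel, response=response, predictor=predictor,
                family=family, terms=terms, area_ha=area_ha,
            )
        except (ConvergenceError, ValueError) as err:
            errors[terms] = err
    if not fits:
        raise ConvergenceError(f"both candidate fits failed: {errors}")
    if len(fits) == 1:
        (terms,) = fits
        warnings.warn(
            f"{[t for t in TERMS if t != terms][0]} fit failed ({errors}); using {terms}",
            stacklevel=2,
        )
        selected = terms
    else:
        selected = (
            "quadratic" if fits["quadratic"].aic < fits["linear"].aic else "linear"
        )
    return {"selected": selected, "fit": fits[selected], "fits": fits, "errors": errors}
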