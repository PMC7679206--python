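"""Beta regression of the user activity ratio on patient features.

The activity ratio is a proportion bounded in (0, 1), so engagement is
modelled with a mean-precision beta GLM: y ~ Beta(mu*phi, (1-mu)*phi) with
g(mu) = X beta and constant precision phi.  The link g is selected per
module by the smallest AIC among logit, probit, complementary log-log and
log.  Ratios of exactly 1 are clamped to 0.99 before fitting; zeros never
occur because a module fit includes only that module's users, whose ratio
is at least 1/180.

Effects are reported as average marginal effects (AMEs): for a factor
level, the sample-averaged difference in predicted mean activity between
the level and its reference; for the module count, the sample-averaged
numerical derivative.  Standard errors come from the delta method with a
numerical Jacobian.  An AME times the 180-day window translates the effect
into active-day equivalents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.genmod.families.links as sm_links
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

from .features import UNKNOWN

__all__ = [
    "clamp_uar", "build_design", "fit_beta", "select_link",
    "marginal_effects", "me_to_days", "sensitivity_fits",
    "BetaRegressionFit", "MarginalEffect",
    "LINKS", "REFERENCE_LEVELS", "FACTOR_LEVELS", "WINDOW_DAYS",
]

log = logging.getLogger(__name__)

WINDOW_DAYS = 180
ALPHA = 0.10           # the study's significance level; a flag, not a rule
CLAMP_VALUE = 0.99

LINKS = ("logit", "probit", "cloglog", "log")
_LINK_OBJS = {
    "logit": sm_links.Logit,
    "probit": sm_links.Probit,
    "cloglog": sm_links.CLogLog,
    "log": sm_links.Log,
}

# Factor levels in design order; first entry is the reference.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female", UNKNOWN),
    "age_group": ("30-40", "<30", "40-50", "50-60", "60-70", ">70", UNKNOWN),
    "bmi_group": ("normal", "underweight", "overweight", "obese", UNKNOWN),
    "diagnosis": ("t1d", "t2d", "prediabetes", "other", UNKNOWN),
    "recent": ("no", "yes", UNKNOWN),
    "insulin": ("noninsulin", "insulin", UNKNOWN),
    "bg_control": ("no", "yes", UNKNOWN),
}
REFERENCE_LEVELS = {f: levels[0] for f, levels in FACTOR_LEVELS.items()}
COUNT_COVARIATE = "n_modules_used"


def clamp_uar(u: float | np.ndarray) -> float | np.ndarray:
    """Map an activity ratio of exactly 1 to 0.99; identity elsewhere.

    A ratio of 0 is an upstream cohort bug (module fits only include module
    users) and raises.
    """
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("UAR must lie in (0, 1] before clamping")
    out = np.where(arr == 1.0, CLAMP_VALUE, arr)
    return float(out) if np.isscalar(u) else out


@dataclass
class BetaRegressionFit:
    module: str
    link: str
    coefficients: pd.Series
    precision: float
    log_likelihood: float
    aic: float
    bic: float
    n: int
    term_factors: dict[str, str] = field(default_factory=dict, repr=False)
    _result: object = field(default=None, repr=False)


@dataclass
class MarginalEffect:
    term: str
    me: float
    std_err: float
    p_value: float
    days: float
    significant: bool


def build_design(features: pd.DataFrame, include_count: bool = True,
                 drop_collinear: bool = False) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-coded design matrix from a feature table.

    Returns the design (intercept, one column per non-reference factor
    level present in the sample, plus the module count) and a map from
    column name to parent factor.  Unknown levels enter as ordinary
    levels.  Levels absent from the sample are dropped; any remaining
    collinearity raises with the offending columns named, or drops them
    with a log message when ``drop_collinear`` is set (small samples can
    make unknown levels of different factors coincide exactly).
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(features))}
    term_factors: dict[str, str] = {}
    for factor, levels in FACTOR_LEVELS.items():
        observed = set(features[factor].unique())
        bad = observed - set(levels)
        if bad:
            raise ValueError(f"unexpected {factor} levels: {sorted(bad)}")
        for level in levels[1:]:
            if level not in observed:
                continue
            name = f"{factor}[{level}]"
            cols[name] = (features[factor] == level).to_numpy(dtype=float)
            term_factors[name] = factor
    if include_count:
        cols[COUNT_COVARIATE] = features[COUNT_COVARIATE].to_numpy(dtype=float)
        term_factors[COUNT_COVARIATE] = COUNT_COVARIATE
    X = pd.DataFrame(cols, index=features.index)
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        dep = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        if not drop_collinear:
            raise ValueError(
                f"design matrix is rank deficient; collinear columns: {dep}")
        drop = dep[-1]  # keep earlier columns, drop the last dependent one
        log.info("dropping collinear design column %s", drop)
        X = X.drop(columns=[drop])
        term_factors.pop(drop, None)
    return X, term_factors


def fit_beta(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    link: str = "logit",
    module: str = "any",
    term_factors: dict[str, str] | None = None,
) -> BetaRegressionFit:
    """Maximum-likelihood beta regression with constant precision.

    Starts from a perturbed restart if the first optimisation fails; a fit
    that still does not converge raises.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("y must lie strictly inside (0, 1); clamp first")
    if link not in _LINK_OBJS:
        raise ValueError(f"unknown link {link!r}; choose from {LINKS}")
    model = BetaModel(y, X, link=_LINK_OBJS[link]())
    res = model.fit(disp=0, maxiter=500)
    if not res.mle_retvals.get("converged", False):
        start = np.asarray(res.params) + np.random.default_rng(0).normal(
            scale=0.1, size=len(res.params))
        res = model.fit(start_params=start, disp=0, maxiter=1000)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError(
                f"beta regression did not converge (link={link}): {res.mle_retvals}")
    params = np.asarray(res.params)
    k = len(params)
    n = len(y)
    coef = pd.Series(params[:-1], index=list(X.columns))
    return BetaRegressionFit(
        module=module,
        link=link,
        coefficients=coef,
        precision=float(np.exp(params[-1])),  # BetaModel models log-precision
        log_likelihood=float(res.llf),
        aic=float(-2 * res.llf + 2 * k),
        bic=float(-2 * res.llf + k * np.log(n)),
        n=n,
        term_factors=dict(term_factors or {}),
        _result=res,
    )


def select_link(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    candidates: Sequence[str] = LINKS,
    module: str = "any",
    term_factors: dict[str, str] | None = None,
) -> BetaRegressionFit:
    """Fit every candidate link and return the smallest-AIC fit.

    Ties go to the first candidate in the given order (logged); if AIC and
    BIC disagree on the winner, AIC decides and the disagreement is logged.
    Candidates that fail to converge are skipped; all failing is an error.
    """
    fits: list[BetaRegressionFit] = []
    for link in candidates:
        try:
            fits.append(fit_beta(y, X, link=link, module=module,
                                 term_factors=term_factors))
        except Exception as exc:  # noqa: BLE001 - candidate failure is expected
            log.warning("link %s failed for module %s: %s", link, module, exc)
    if not fits:
        raise RuntimeError(f"no candidate link converged for module {module}")
    best_aic = min(fits, key=lambda f: f.aic)
    best_bic = min(fits, key=lambda f: f.bic)
    if best_bic.link != best_aic.link:
        log.info("module %s: AIC selects %s but BIC selects %s; keeping AIC",
                 module, best_aic.link, best_bic.link)
    if sum(1 for f in fits if f.aic == best_aic.aic) > 1:
        log.info("module %s: AIC tie; keeping first candidate in order", module)
    return best_aic


def _predict_mean(result, X: np.ndarray) -> np.ndarray:
    beta = np.asarray(result.params)[:-1]
    link = result.model.link
    return link.inverse(X @ beta)


def _ame_vector(params: np.ndarray, fit: BetaRegressionFit, X: pd.DataFrame,
                terms: list[str]) -> np.ndarray:
    """AMEs for the given terms as a function of the full parameter vector
    (precision included, unused) — the delta method differentiates this."""
    beta = params[:-1]
    link = fit._result.model.link
    Xv = X.to_numpy()
    cols = {c: j for j, c in enumerate(X.columns)}
    out = np.empty(len(terms))
    for i, term in enumerate(terms):
        factor = fit.term_factors.get(term, term)
        if term == COUNT_COVARIATE:
            h = 1e-5
            Xp, Xm = Xv.copy(), Xv.copy()
            Xp[:, cols[term]] += h
            Xm[:, cols[term]] -= h
            out[i] = np.mean(link.inverse(Xp @ beta) - link.inverse(Xm @ beta)) / (2 * h)
        else:
            sibling_cols = [cols[c] for c, f in fit.term_factors.items() if f == factor]
            X1, X0 = Xv.copy(), Xv.copy()
            for j in sibling_cols:
                X1[:, j] = 0.0
                X0[:, j] = 0.0
            X1[:, cols[term]] = 1.0  # level on vs reference on
            out[i] = np.mean(link.inverse(X1 @ beta) - link.inverse(X0 @ beta))
    return out


def marginal_effects(fit: BetaRegressionFit, X: pd.DataFrame,
                     alpha: float = ALPHA,
                     window_days: int = WINDOW_DAYS) -> list[MarginalEffect]:
    """Average marginal effects with delta-method p-values.

    Each effect is also translated to an active-day equivalent over the
    observation window (me x 180 by default).
    """
    terms = [c for c in X.columns if c != "intercept"]
    params = np.asarray(fit._result.params)
    ame = _ame_vector(params, fit, X, terms)

    # numerical Jacobian of the AME vector w.r.t. the parameters
    eps = 1e-6
    J = np.empty((len(terms), len(params)))
    for j in range(len(params)):
        dp = np.zeros_like(params)
        dp[j] = eps
        J[:, j] = (_ame_vector(params + dp, fit, X, terms)
                   - _ame_vector(params - dp, fit, X, terms)) / (2 * eps)
    cov = np.asarray(fit._result.cov_params())
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, ame / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    return [
        MarginalEffect(
            term=t, me=float(m), std_err=float(s), p_value=float(pv),
            days=me_to_days(float(m), window_days), significant=bool(pv < alpha),
        )
        for t, m, s, pv in zip(terms, ame, se, p)
    ]


def me_to_days(me: float, window_days: int = WINDOW_DAYS) -> float:
    """Translate a marginal effect on the activity ratio into active-day
    equivalents over the observation window, rounded to 2 decimals."""
    return round(me * window_days, 2)


def sensitivity_fits(y: np.ndarray | pd.Series, X: pd.DataFrame,
                     beta_fit: BetaRegressionFit) -> pd.DataFrame:
    """Gamma GLM (log link) and log-OLS refits, with per-term AME sign
    agreement against the beta fit.

    Both alternatives model strictly positive proportions; their AMEs are
    computed the same way (sample-averaged predicted-mean contrasts on the
    response scale).
    """
    y = np.asarray(y, dtype=float)
    gamma_res = sm.GLM(y, X, family=sm.families.Gamma(link=sm_links.Log())).fit()
    ols_res = sm.OLS(np.log(y), X).fit()

    Xv = X.to_numpy()
    cols = {c: j for j, c in enumerate(X.columns)}
    terms = [c for c in X.columns if c != "intercept"]

    def ames(predict) -> dict[str, float]:
        out = {}
        for term in terms:
            factor = beta_fit.term_factors.get(term, term)
            if term == COUNT_COVARIATE:
                h = 1e-5
                Xp, Xm = Xv.copy(), Xv.copy()
                Xp[:, cols[term]] += h
                Xm[:, cols[term]] -= h
                out[term] = float(np.mean(predict(Xp) - predict(Xm)) / (2 * h))
            else:
                sib = [cols[c] for c, f in beta_fit.term_factors.items() if f == factor]
                X1, X0 = Xv.copy(), Xv.copy()
                for j in sib:
                    X1[:, j] = 0.0
                    X0[:, j] = 0.0
                X1[:, cols[term]] = 1.0
                out[term] = float(np.mean(predict(X1) - predict(X0)))
        return out

    beta_ames = {m.term: m.me for m in marginal_effects(beta_fit, X)}
    gamma_ames = ames(lambda M: np.exp(M @ gamma_res.params))
    ols_ames = ames(lambda M: np.exp(M @ ols_res.params))
    rows = []
    for term in terms:
        b = beta_ames[term]
        rows.append({
            "term": term,
            "me_beta": b,
            "me_gamma": gamma_ames[term],
            "me_log_ols": ols_ames[term],
            "sign_agree_gamma": bool(np.sign(b) == np.sign(gamma_ames[term])),
            "sign_agree_log_ols": bool(np.sign(b) == np.sign(ols_ames[term])),
        })
    return pd.DataFrame(rows)
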