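"""Mixed-effects models: binomial GLMM with a patient random intercept and
the linear mixed model for biopsy day.

The binomial GLMM maximizes the exact marginal likelihood by adaptive
Gauss-Hermite quadrature: for each patient the random-intercept integrand is
re-centred at its posterior mode and re-scaled by its curvature before the
Hermite rule is applied, so a modest number of nodes (default 15) integrates
accurately even for small clusters.  Laplace approximation is the 1-node
special case of the same rule.  Effects are reported as average marginal
effects (AMEs) on the probability scale: marginal event probabilities are
obtained by integrating the inverse-logit response over the estimated
random-intercept distribution, and level contrasts or numeric derivatives
are taken on that scale, with delta-method confidence intervals (a seeded
parametric bootstrap is available as a cross-check).

No installed Python package offers a frequentist GLMM with adaptive
quadrature, hence the from-scratch implementation; the linear mixed model
wraps statsmodels MixedLM (REML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools import numdiff

DEFAULT_NODES = 15
_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -10.0, 3.0
_MAX_OUTER_ITER = 200
#: Laplace fallback threshold: with this many large clusters the mode-based
#: approximation is already accurate and 15-node quadrature buys nothing
_FALLBACK_GROUPS, _FALLBACK_OBS = 50, 200


class GlmmError(RuntimeError):
    pass


def _softplus(x):
    return np.logaddexp(0.0, x)


@dataclass
class _Data:
    """Observations sorted by group, with reduceat boundaries."""

    y: np.ndarray
    X: np.ndarray
    group_idx: np.ndarray  # per-obs group code, sorted ascending
    starts: np.ndarray  # first index of each group
    n_groups: int

    @classmethod
    def build(cls, y, X, group):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        codes, _ = pd.factorize(np.asarray(group))
        order = np.argsort(codes, kind="stable")
        y, X, codes = y[order], X[order], codes[order]
        starts = np.searchsorted(codes, np.arange(codes.max() + 1))
        return cls(y, X, codes, starts, int(codes.max() + 1))


def _group_sum(v, data: _Data):
    return np.add.reduceat(v, data.starts)


def _posterior_modes(eta0, sigma, data: _Data):
    """Vectorized Newton search for each group's random-intercept mode and
    its negative log-integrand curvature."""
    inv_var = 1.0 / sigma**2
    b = np.zeros(data.n_groups)
    for _ in range(100):
        p = expit(eta0 + b[data.group_idx])
        grad = _group_sum(data.y - p, data) - b * inv_var
        hess = _group_sum(p * (1.0 - p), data) + inv_var
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b += step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = expit(eta0 + b[data.group_idx])
    hess = _group_sum(p * (1.0 - p), data) + inv_var
    return b, hess


def _marginal_loglik(params, data: _Data, n_nodes: int) -> float:
    """Marginal log-likelihood at (beta, log_sigma) by adaptive GHQ."""
    beta, log_sigma = params[:-1], params[-1]
    sigma = float(np.exp(np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)))
    eta0 = data.X @ beta
    if sigma < 1e-8:
        ll = data.y * eta0 - _softplus(eta0)
        return float(ll.sum())
    b_hat, hess = _posterior_modes(eta0, sigma, data)
    scale = 1.0 / np.sqrt(hess)
    z, w = hermgauss(n_nodes)
    log_terms = np.empty((n_nodes, data.n_groups))
    log_prior_const = -np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    for k in range(n_nodes):
        b_k = b_hat + np.sqrt(2.0) * scale * z[k]
        eta = eta0 + b_k[data.group_idx]
        obs_ll = _group_sum(data.y * eta - _softplus(eta), data)
        log_f = obs_ll - 0.5 * (b_k / sigma) ** 2 + log_prior_const
        log_terms[k] = np.log(w[k]) + z[k] ** 2 + log_f
    log_int = logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0) + np.log(scale)
    return float(log_int.sum())


def marginal_loglik(y, X, group, beta, sigma, n_nodes: int = DEFAULT_NODES) -> float:
    """Public marginal log-likelihood, for quadrature-refinement checks."""
    data = _Data.build(y, X, group)
    params = np.append(np.asarray(beta, dtype=float), np.log(max(sigma, 1e-12)))
    return _marginal_loglik(params, data, n_nodes)


def _build_design(x, reference=None):
    """Design matrix for a sole predictor: numeric column, or treatment-coded
    categorical with ``reference`` (default: 'Euploid' if present, else the
    first level) as baseline."""
    x = np.asarray(x)
    if x.dtype.kind in "OUS" or isinstance(x[0], str):
        levels = list(pd.unique(x))
        if reference is None:
            reference = "Euploid" if "Euploid" in levels else levels[0]
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not observed")
        levels = [reference] + [l for l in sorted(levels) if l != reference]
        X = np.column_stack(
            [np.ones(len(x))] + [(x == l).astype(float) for l in levels[1:]]
        )
        names = ["intercept"] + [str(l) for l in levels[1:]]
        return X, names, levels, True
    X = np.column_stack([np.ones(len(x)), x.astype(float)])
    return X, ["intercept", "slope"], None, False


@dataclass
class GlmmFit:
    """Fitted binomial GLMM with patient random intercept."""

    params: np.ndarray  # fixed effects + log_sigma (last entry)
    param_names: list
    sigma: float
    loglik: float
    cov: np.ndarray  # covariance of (beta, log_sigma)
    n_nodes: int
    converged: bool
    message: str
    levels: list | None  # categorical predictor levels (reference first)
    categorical: bool
    x: np.ndarray = field(repr=False, default=None)
    data: _Data = field(repr=False, default=None)

    @property
    def beta(self) -> np.ndarray:
        return self.params[:-1]

    def design_row(self, level) -> np.ndarray:
        """Fixed-effect covariate row for one categorical level."""
        row = np.zeros(len(self.beta))
        row[0] = 1.0
        if level != self.levels[0]:
            row[self.param_names.index(str(level))] = 1.0
        return row

    def marginal_probability(self, row: np.ndarray, params=None) -> float:
        """Population-averaged P(y=1 | row), integrating the inverse logit
        over the random-intercept distribution (collapses exactly to the
        plain logistic probability when sigma is 0)."""
        if params is None:
            params = self.params
        beta, sigma = params[:-1], float(np.exp(params[-1]))
        eta = float(row @ beta)
        if sigma < 1e-8:
            return float(expit(eta))
        z, w = hermgauss(self.n_nodes)
        return float(np.sum(w * expit(eta + np.sqrt(2.0) * sigma * z)) / np.sqrt(np.pi))

    def level_probabilities(self) -> pd.DataFrame:
        """Marginal probability per predictor level with delta-method 95% CI."""
        if not self.categorical:
            raise GlmmError("level probabilities require a categorical predictor")
        rows = []
        for level in self.levels:
            xrow = self.design_row(level)
            f = lambda p: self.marginal_probability(xrow, p)  # noqa: E731
            est = f(self.params)
            grad = numdiff.approx_fprime(self.params, lambda p: np.array([f(p)]), centered=True).ravel()
            se = float(np.sqrt(max(grad @ self.cov @ grad, 0.0)))
            rows.append(
                {
                    "level": level,
                    "probability": est,
                    "ci_low": max(est - 1.96 * se, 0.0),
                    "ci_high": min(est + 1.96 * se, 1.0),
                }
            )
        return pd.DataFrame(rows)


def fit_binomial_glmm(y, x, group, n_nodes: int = DEFAULT_NODES, reference=None) -> GlmmFit:
    """Fit a binomial GLMM with one predictor and a group random intercept.

    ``x`` may be numeric or categorical; ``group`` identifies patients.
    Falls back from adaptive quadrature to Laplace (1 node, with a warning)
    when more than 50 groups each exceed 200 observations.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise GlmmError("random intercept unidentifiable with a single group")
    X, names, levels, categorical = _build_design(x, reference)
    if categorical:
        counts = pd.Series(x).value_counts()
        if (counts < 1).any():
            raise GlmmError("every predictor level must be observed")
    data = _Data.build(y, X, group)

    sizes = np.diff(np.append(data.starts, len(data.y)))
    if int((sizes > _FALLBACK_OBS).sum()) > _FALLBACK_GROUPS:
        warnings.warn(
            "many large clusters: falling back to Laplace (1-node) approximation",
            RuntimeWarning,
        )
        n_nodes = 1

    start_glm = sm.GLM(data.y, data.X, family=sm.families.Binomial()).fit()
    x0 = np.append(start_glm.params, np.log(0.3))
    neg = lambda p: -_marginal_loglik(p, data, n_nodes)  # noqa: E731
    res = minimize(
        neg, x0, method="BFGS",
        options={"maxiter": _MAX_OUTER_ITER, "gtol": 1e-6},
    )
    if not res.success:  # one polish pass from the first optimum
        res2 = minimize(neg, res.x, method="Nelder-Mead",
                        options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    hess = numdiff.approx_hess(res.x, neg)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    converged = bool(np.isfinite(res.fun)) and (res.status in (0, 2) or res.fun < neg(x0))
    return GlmmFit(
        params=res.x,
        param_names=names + ["log_sigma"],
        sigma=float(np.exp(np.clip(res.x[-1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))),
        loglik=float(-res.fun),
        cov=cov,
        n_nodes=n_nodes,
        converged=converged,
        message=str(res.message),
        levels=levels,
        categorical=categorical,
        x=x,
        data=data,
    )


def _ame_value(fit: GlmmFit, level_or_delta, params) -> float:
    if fit.categorical:
        p1 = fit.marginal_probability(fit.design_row(level_or_delta), params)
        p0 = fit.marginal_probability(fit.design_row(fit.levels[0]), params)
        return p1 - p0
    # numeric predictor: average derivative of the marginal probability
    beta, sigma = params[:-1], float(np.exp(params[-1]))
    slope = beta[1]
    xs = np.unique(fit.x.astype(float))
    eta = beta[0] + slope * xs
    if sigma < 1e-8:
        derivs = expit(eta) * (1.0 - expit(eta)) * slope
    else:
        z, w = hermgauss(fit.n_nodes)
        e = eta[:, None] + np.sqrt(2.0) * sigma * z[None, :]
        p = expit(e)
        derivs = (w[None, :] * p * (1.0 - p)).sum(axis=1) / np.sqrt(np.pi) * slope
    weights = np.array([(fit.x.astype(float) == v).mean() for v in xs])
    return float(np.sum(weights * derivs))


@dataclass
class AmeResult:
    ame: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # 'delta' | 'bootstrap'


def average_marginal_effect(
    fit: GlmmFit,
    level_or_delta=None,
    bootstrap: int = 0,
    seed: int = 0,
) -> AmeResult:
    """Probability-scale AME of the predictor.

    Categorical: difference in population-averaged probability between
    ``level_or_delta`` and the reference level.  Numeric: the average
    derivative of the marginal probability over the observed predictor
    values.  CI by the delta method; ``bootstrap > 0`` switches to a seeded
    parametric bootstrap of the fitted model.
    """
    if not fit.converged:
        raise GlmmError("AME requested on a non-converged fit")
    if fit.categorical and level_or_delta is None:
        raise GlmmError("a predictor level is required for a categorical fit")
    if bootstrap < 0:
        raise ValueError("bootstrap draw count must be positive")
    est = _ame_value(fit, level_or_delta, fit.params)
    if bootstrap:
        rng = np.random.default_rng(seed)
        draws = []
        data = fit.data
        for _ in range(bootstrap):
            b = rng.normal(0.0, fit.sigma, size=data.n_groups)
            eta = data.X @ fit.beta + b[data.group_idx]
            y_sim = (rng.random(len(eta)) < expit(eta)).astype(float)
            try:
                refit = fit_binomial_glmm(
                    y_sim, fit.x, fit.data.group_idx, n_nodes=fit.n_nodes,
                    reference=fit.levels[0] if fit.categorical else None,
                )
            except GlmmError:
                continue
            if refit.converged:
                draws.append(_ame_value(refit, level_or_delta, refit.params))
        draws = np.asarray(draws)
        se = float(draws.std(ddof=1))
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return AmeResult(est, se, float(lo), float(hi), "bootstrap")
    f = lambda p: np.array([_ame_value(fit, level_or_delta, p)])  # noqa: E731
    grad = numdiff.approx_fprime(fit.params, f, centered=True).ravel()
    se = float(np.sqrt(max(grad @ fit.cov @ grad, 0.0)))
    return AmeResult(est, se, est - 1.96 * se, est + 1.96 * se, "delta")


# ---------------------------------------------------------------------------
# Linear mixed model (biopsy day)
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    fe_params: np.ndarray  # (intercept, predictor coefficient), days
    ame: float  # = predictor coefficient for a binary predictor
    se: float
    p: float
    group_sd: float
    resid_sd: float
    converged: bool


def fit_lmm(day, aneuploid, group) -> LmmFit:
    """REML linear mixed model of biopsy day on a binary aneuploidy
    indicator with a patient random intercept; the AME of a binary predictor
    equals its fixed coefficient."""
    day = np.asarray(day, dtype=float)
    x = np.asarray(aneuploid, dtype=float)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise GlmmError("random intercept unidentifiable with a single group")
    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(day, exog, groups=group)
        fit = model.fit(reml=True)
    coef = float(fit.fe_params[1])
    return LmmFit(
        fe_params=np.asarray(fit.fe_params),
        ame=coef,
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        group_sd=float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        resid_sd=float(np.sqrt(fit.scale)),
        converged=bool(fit.converged),
    )
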