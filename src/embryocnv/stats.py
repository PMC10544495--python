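"""Fixed-effects association statistics.

Contingency tests (Pearson chi-squared without continuity correction;
Fisher's exact test with the conditional-MLE odds ratio and its exact
conditional confidence interval) and quasi-likelihood trend models
(quasi-binomial for aneuploidy-vs-age, quasi-Poisson for aneuploidy
complexity), with dispersion estimated as Pearson chi-squared over residual
degrees of freedom.  No multiple-testing correction is applied anywhere;
reports carry unadjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero."""


@dataclass
class ContingencyResult:
    observed: np.ndarray
    statistic_name: str  # 'fisher_exact' | 'pearson_chi2'
    statistic: float  # chi2 statistic, or conditional-MLE OR for Fisher
    p: float
    df: int | None = None
    odds_ratio: float | None = None  # conditional MLE (2x2 only)
    sample_odds_ratio: float | None = None  # ad/bc, reported alongside
    ci95: tuple | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed)
        if (self.observed < 0).any():
            raise ValueError("cell counts must be nonnegative")


def pearson_chi_squared(table) -> ContingencyResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction; expected counts from the row/column margins.
    """
    table = np.asarray(table, dtype=float)
    if table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise DegenerateTableError("table has a zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ContingencyResult(table, "pearson_chi2", float(stat), float(p), df=int(df))


def fisher_exact(table, compute_ci: bool = True) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities no larger than that of the
    observed table; the reported odds ratio is the conditional maximum
    likelihood estimate under the noncentral hypergeometric distribution,
    with its exact conditional 95% CI.  With a zero cell the OR is reported
    on the extended scale (0 or inf) and the CI is one-sided.
    ``compute_ci=False`` skips the (root-finding) interval for bulk use.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    res = _odds_ratio(table, kind="conditional")
    if compute_ci:
        ci = res.confidence_interval(confidence_level=0.95)
        ci_tuple = (float(ci.low), float(ci.high))
    else:
        ci_tuple = None
    a, b, c, d = table.ravel()
    sample_or = np.inf if b * c == 0 else (a * d) / (b * c)
    # boundary conventions on the conditional support [lo, hi] of cell a
    lo, hi = max(0, a - d), min(a + b, a + c)
    if lo == hi:
        cmle = np.nan  # degenerate margin: OR unidentifiable
    elif a == lo:
        cmle = 0.0
    elif a == hi:
        cmle = np.inf
    else:
        cmle = float(res.statistic)
    return ContingencyResult(
        table,
        "fisher_exact",
        cmle,
        float(p),
        odds_ratio=cmle,
        sample_odds_ratio=float(sample_or),
        ci95=ci_tuple,
    )


@dataclass
class TrendFit:
    family: str  # 'quasi_binomial' | 'quasi_poisson'
    beta: float  # slope of the predictor of interest
    se: float
    dispersion: float
    p: float
    converged: bool = True
    separation: bool = False
    params: np.ndarray = field(default_factory=lambda: np.array([]))
    bse: np.ndarray = field(default_factory=lambda: np.array([]))


_FAMILIES = {
    "quasi_binomial": sm.families.Binomial,
    "quasi_poisson": sm.families.Poisson,
}

_SEPARATION_BOUND = 15.0  # |logit/log slope| beyond this flags separation


def fit_quasi_glm(response, predictor, family: str) -> TrendFit:
    """Quasi-binomial / quasi-Poisson GLM of a response on one predictor.

    ``response`` is either a 1-D array (binary outcomes or counts) or an
    (n, 2) array of per-group (successes, failures) — the aggregated
    per-cycle entry point.  ``predictor`` may be numeric (slope reported) or
    categorical (first non-reference level's coefficient reported).  Point
    estimates equal the ordinary GLM estimates; the dispersion (Pearson
    chi-squared / df) only rescales the standard errors.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    predictor = np.asarray(predictor)
    if len(np.unique(predictor)) < 2:
        raise ValueError("predictor must take at least 2 distinct values")
    if predictor.dtype.kind in "OUS":
        dummies = pd.get_dummies(pd.Series(predictor), drop_first=True, dtype=float)
        exog = sm.add_constant(dummies.to_numpy())
    else:
        exog = sm.add_constant(predictor.astype(float))
    endog = np.asarray(response, dtype=float)
    model = sm.GLM(endog, exog, family=_FAMILIES[family]())
    fit = model.fit(maxiter=200, tol=1e-10)

    # Pearson dispersion over rows (as R's quasi families): for grouped
    # (successes, failures) responses each row is one binomial observation
    mu = np.asarray(fit.fittedvalues, dtype=float)
    n_params = exog.shape[1]
    if endog.ndim == 2:
        trials = endog.sum(axis=1)
        ybar = endog[:, 0] / np.maximum(trials, 1)
        pearson = trials * (ybar - mu) ** 2 / np.maximum(mu * (1 - mu), 1e-12)
    elif family == "quasi_binomial":
        pearson = (endog - mu) ** 2 / np.maximum(mu * (1 - mu), 1e-12)
    else:
        pearson = (endog - mu) ** 2 / np.maximum(mu, 1e-12)
    df_resid = len(mu) - n_params
    dispersion = float(pearson.sum() / max(df_resid, 1))

    beta = float(fit.params[1])
    se = float(fit.bse[1]) * np.sqrt(dispersion)
    p = float(2.0 * sps.t.sf(abs(beta / se), df_resid)) if se > 0 else np.nan
    separation = bool(abs(beta) > _SEPARATION_BOUND or not np.isfinite(se))
    return TrendFit(
        family=family,
        beta=beta,
        se=se,
        dispersion=dispersion,
        p=p,
        converged=bool(fit.converged),
        separation=separation,
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse) * np.sqrt(dispersion),
    )


def results_to_frame(named_results: dict) -> pd.DataFrame:
    """Serialize a mapping of test name -> ContingencyResult/TrendFit into a
    tidy table (test_name, estimate, ci_low, ci_high, statistic, df, p)."""
    rows = []
    for name, r in named_results.items():
        if isinstance(r, ContingencyResult):
            ci = r.ci95 or (np.nan, np.nan)
            rows.append(
                {
                    "test_name": name,
                    "estimate": r.odds_ratio if r.odds_ratio is not None else np.nan,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "statistic": r.statistic,
                    "df": r.df if r.df is not None else np.nan,
                    "p": r.p,
                }
            )
        elif isinstance(r, TrendFit):
            rows.append(
                {
                    "test_name": name,
                    "estimate": r.beta,
                    "ci_low": r.beta - 1.96 * r.se,
                    "ci_high": r.beta + 1.96 * r.se,
                    "statistic": np.nan,
                    "df": np.nan,
                    "p": r.p,
                }
            )
        else:
            raise TypeError(f"unsupported result type for {name}: {type(r)}")
    return pd.DataFrame(rows)
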