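"""Goodness-of-fit battery and residual diagnostics for growth-curve fits.

The battery mirrors the statistics conventionally reported for livestock
growth-curve comparisons:

* ``R^2 = 1 - RSS/TSS`` and the adjusted form
  ``Radj^2 = 1 - [(n-1)/(n-p)] (1 - R^2)``;
* root mean square error ``sqrt(RSS/(n-p))`` ("table" mode; a
  ``sqrt(RSS/(n-p-1))`` "printed" mode is kept for completeness because the
  two denominators both circulate in this literature);
* the information criteria in their RSS forms, ``AIC = n ln(RSS) + 2p`` and
  ``BIC = n ln(RSS/n) + p ln(n)``.  Note the AIC deliberately does not
  divide RSS by n: the two criteria then differ by the constant
  ``n ln n + 2p - p ln n`` for any RSS, an identity that is useful as an
  internal consistency check;
* the Durbin-Watson statistic with a Savin-White 5% bounds classification;
* Shapiro-Wilk residual normality and White's heteroscedasticity test with
  the single-regressor auxiliary design (squared residuals on 1, t, t^2).

AIC/BIC require RSS > 0 and are reported as unavailable for an exactly
interpolating fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.stattools import durbin_watson as _sm_durbin_watson

from ._exceptions import GrowthCurvesError
from .fitting import FitResult
from .models import GrowthDataset

__all__ = [
    "GofReport",
    "r_squared",
    "rmse",
    "aic",
    "bic",
    "durbin_watson",
    "dw_classify",
    "shapiro_wilk",
    "white_test",
    "gof_report",
    "rank_models",
    "reports_to_wide",
    "reports_to_long",
]


# Savin-White 5% significance bounds (dL, dU) for one regressor.
DW_BOUNDS_ONE_REGRESSOR: dict[int, tuple[float, float]] = {
    12: (0.971, 1.331),
}


@dataclass(frozen=True)
class GofReport:
    """One goodness-of-fit table row for a model x dataset fit."""

    model_name: str
    n: int
    p: int
    r2: float
    r2_adj: float
    rmse: float
    dw: float
    dw_class: str
    shapiro_p: float
    white_p: float
    aic: float | None
    bic: float | None
    rss: float


def r_squared(observed, residuals, p: int) -> tuple[float, float]:
    """Coefficient of determination and its adjusted form.

    ``R^2 = 1 - RSS/TSS`` with TSS about the observed mean;
    ``Radj^2 = 1 - [(n-1)/(n-p)](1-R^2)``.  Both may be negative for fits
    worse than the mean.
    """
    y = np.asarray(observed, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("total sum of squares is zero (constant observations)")
    rss = float(e @ e)
    r2 = 1.0 - rss / tss
    if n <= p:
        raise ValueError("adjusted R^2 undefined for n <= p")
    r2_adj = 1.0 - ((n - 1) / (n - p)) * (1.0 - r2)
    return r2, r2_adj


def rmse(rss: float, n: int, p: int, denominator_mode: str = "table") -> float:
    """Root mean square error of a fit.

    ``denominator_mode="table"`` (default) uses ``n - p`` degrees of freedom;
    ``"printed"`` uses ``n - p - 1``.
    """
    if denominator_mode == "table":
        dof = n - p
    elif denominator_mode == "printed":
        dof = n - p - 1
    else:
        raise ValueError("denominator_mode must be 'table' or 'printed'")
    if dof <= 0:
        raise ValueError(f"nonpositive degrees of freedom ({dof})")
    return math.sqrt(rss / dof)


def aic(rss: float, n: int, p: int) -> float:
    """RSS-form Akaike criterion ``n ln(RSS) + 2p`` (requires RSS > 0)."""
    if rss <= 0:
        raise ValueError("AIC undefined for RSS <= 0")
    return n * math.log(rss) + 2 * p


def bic(rss: float, n: int, p: int) -> float:
    """RSS-form Bayesian criterion ``n ln(RSS/n) + p ln(n)``."""
    if rss <= 0:
        raise ValueError("BIC undefined for RSS <= 0")
    return n * math.log(rss / n) + p * math.log(n)


def durbin_watson(residuals) -> float:
    """First-order autocorrelation statistic, in age order, range [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two residuals")
    if np.all(e == 0):
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return float(_sm_durbin_watson(e))


def dw_classify(
    dw: float,
    n: int,
    regressors: int = 1,
    bounds: tuple[float, float] | None = None,
) -> str:
    """Classify a Durbin-Watson value against 5% significance bounds.

    ``dw < dL`` -> ``"positive"``; ``dw > 4 - dL`` -> ``"negative"``;
    ``dU < dw < 4 - dU`` -> ``"none"``; otherwise ``"inconclusive"``.
    Bounds default to the built-in Savin-White one-regressor table and can be
    supplied explicitly for sample sizes outside it.
    """
    if not (0.0 <= dw <= 4.0):
        raise ValueError("DW must lie in [0, 4]")
    if bounds is None:
        if regressors != 1 or n not in DW_BOUNDS_ONE_REGRESSOR:
            raise ValueError(
                f"no tabulated 5% bounds for n={n}, regressors={regressors}; "
                "pass bounds=(dL, dU) explicitly"
            )
        bounds = DW_BOUNDS_ONE_REGRESSOR[n]
    dl, du = bounds
    if dw < dl:
        return "positive"
    if dw > 4.0 - dl:
        return "negative"
    if du < dw < 4.0 - du:
        return "none"
    return "inconclusive"


def shapiro_wilk(residuals) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) via Royston's approximation."""
    e = np.asarray(residuals, dtype=float)
    if not (3 <= e.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(e == e[0]):
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(e)
    return float(res.statistic), float(res.pvalue)


def white_test(residuals, ages) -> tuple[float, float]:
    """White's heteroscedasticity LM test with auxiliary design (1, t, t^2).

    Regresses squared residuals on a constant, age and age squared; the
    statistic is ``n R^2`` of that auxiliary fit, referred to a chi-square
    distribution with 2 degrees of freedom.
    """
    e = np.asarray(residuals, dtype=float)
    t = np.asarray(ages, dtype=float)
    n = e.size
    if n < 4:
        raise ValueError("White's test needs at least four observations")
    if np.all(t == t[0]):
        raise ValueError("ages are collinear (all equal)")
    e2 = e**2
    X = np.column_stack([np.ones(n), t, t**2])
    beta, *_ = np.linalg.lstsq(X, e2, rcond=None)
    fitted = X @ beta
    tss = float(np.sum((e2 - e2.mean()) ** 2))
    if tss == 0:
        return 0.0, 1.0  # squared residuals constant: no heteroscedasticity signal
    r2_aux = 1.0 - float(np.sum((e2 - fitted) ** 2)) / tss
    lm = n * r2_aux
    return float(lm), float(stats.chi2.sf(lm, df=2))


def gof_report(
    fit: FitResult,
    data: GrowthDataset,
    rmse_mode: str = "table",
    dw_bounds: tuple[float, float] | None = None,
) -> GofReport:
    """Assemble the full statistic row for one fitted model."""
    if fit.n != data.n:
        raise GrowthCurvesError("fit and dataset sizes disagree")
    r2, r2_adj = r_squared(data.weights, fit.residuals, fit.p)
    try:
        dw = durbin_watson(fit.residuals)
        dw_class = dw_classify(dw, fit.n, bounds=dw_bounds)
    except ValueError:
        # all-zero residuals or no tabulated bounds for this sample size
        dw = durbin_watson(fit.residuals) if np.any(fit.residuals != 0) else math.nan
        dw_class = "inconclusive"
    try:
        _, sw_p = shapiro_wilk(fit.residuals)
    except ValueError:
        sw_p = math.nan  # constant residuals: normality test undefined
    _, wh_p = white_test(fit.residuals, data.ages)
    try:
        aic_val: float | None = aic(fit.rss, fit.n, fit.p)
        bic_val: float | None = bic(fit.rss, fit.n, fit.p)
    except ValueError:
        aic_val = bic_val = None  # exact interpolation: criteria unavailable
    return GofReport(
        model_name=fit.model_name,
        n=fit.n,
        p=fit.p,
        r2=r2,
        r2_adj=r2_adj,
        rmse=rmse(fit.rss, fit.n, fit.p, rmse_mode),
        dw=dw,
        dw_class=dw_class,
        shapiro_p=sw_p,
        white_p=wh_p,
        aic=aic_val,
        bic=bic_val,
        rss=fit.rss,
    )


_ASCENDING = {"aic": True, "bic": True, "rmse": True, "r2_adj": False}


def rank_models(reports: list[GofReport], criterion: str = "aic") -> list[GofReport]:
    """Order reports by one criterion (lower-is-better for aic/bic/rmse,
    higher-is-better for r2_adj), ties broken by model name."""
    if not reports:
        raise ValueError("no reports to rank")
    if criterion not in _ASCENDING:
        raise ValueError(f"criterion must be one of {sorted(_ASCENDING)}")
    asc = _ASCENDING[criterion]

    def key(rep: GofReport):
        val = getattr(rep, criterion)
        if val is None:  # unavailable criterion sorts best (perfect fit)
            val = -math.inf if asc else math.inf
        return (val if asc else -val, rep.model_name)

    return sorted(reports, key=key)


_STAT_ORDER = ["r2_adj", "dw", "shapiro_p", "white_p", "rmse", "aic", "bic"]


def reports_to_wide(reports: list[GofReport]) -> pd.DataFrame:
    """Statistics-by-model table (rows = statistics, columns = models)."""
    cols = {rep.model_name: [getattr(rep, s) for s in _STAT_ORDER] for rep in reports}
    return pd.DataFrame(cols, index=_STAT_ORDER)


def reports_to_long(reports: list[GofReport], dataset_label: str = "") -> pd.DataFrame:
    """Tidy long-format table (dataset, model, statistic, value)."""
    rows = [
        {
            "dataset": dataset_label,
            "model": rep.model_name,
            "statistic": s,
            "value": getattr(rep, s),
        }
        for rep in reports
        for s in _STAT_ORDER
    ]
    return pd.DataFrame(rows)
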