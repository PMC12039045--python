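"""Counterfactual construction and effect summaries.

The no-interruption counterfactual re-evaluates the fitted model with every
step, slope-change and outlier column set to zero, keeping the intercept,
trend and seasonal terms. Because the fitted and counterfactual linear
predictors share those terms, the log relative risk in month t is the
linear form c_t' beta where c_t keeps only the pandemic columns of x_t —
so the monthly RR, its geometric mean over a window (the headline "average
RR") and their confidence intervals all follow from normal theory on linear
functionals of beta under the HAC covariance. The rate difference at a
named month is nonlinear in beta and gets a delta-method CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calendar import StudyCalendar
from .model import DesignMatrix, FittedITSA, fit_itsa

__all__ = [
    "EffectEstimates",
    "counterfactual_rates",
    "monthly_rr",
    "average_rr",
    "rate_difference",
    "effect_estimates",
    "fit_subgroup_models",
    "SubgroupResult",
]

Z95 = 1.96


def _pandemic_contrast(design: DesignMatrix) -> np.ndarray:
    """Rows c_t: x_t with every non-pandemic column zeroed."""
    C = design.X.copy()
    keep = set(design.pandemic_columns)
    for col in C.columns:
        if col not in keep:
            C[col] = 0.0
    return C.to_numpy(dtype=float)


def counterfactual_rates(fitted: FittedITSA) -> np.ndarray:
    """Expected counts per month had the interruptions not happened."""
    cf = fitted.design.counterfactual()
    eta = cf.values() @ fitted.beta.to_numpy() + cf.offset
    return np.exp(eta)


def monthly_rr(fitted: FittedITSA, month: int | None = None) -> pd.DataFrame:
    """Fitted/counterfactual rate ratio per month with 95% CIs.

    Exactly 1 for every pre-interruption month (the pandemic columns are
    zero there). Returns all months, or the single requested month.
    """
    if fitted.cov_hac is None:
        raise ValueError("monthly RR needs the HAC covariance on the fit")
    C = _pandemic_contrast(fitted.design)
    beta = fitted.beta.to_numpy()
    log_rr = C @ beta
    var = np.einsum("ij,jk,ik->i", C, fitted.cov_hac, C)
    var = np.maximum(var, 0.0)
    se = np.sqrt(var)
    df = pd.DataFrame(
        {
            "month": fitted.design.X.index.to_numpy(),
            "rr": np.exp(log_rr),
            "ci_low": np.exp(log_rr - Z95 * se),
            "ci_high": np.exp(log_rr + Z95 * se),
        }
    )
    if month is not None:
        df = df[df["month"] == month].reset_index(drop=True)
        if df.empty:
            raise ValueError(f"month {month} not in the fitted window")
    return df


def average_rr(
    fitted: FittedITSA,
    window: tuple[int, int] | None = None,
    exclude_outliers: bool = False,
) -> tuple[float, float, float]:
    """Geometric-mean RR over a month window with its 95% CI.

    The geometric mean of the monthly ratios is exp of the arithmetic mean
    of the log RRs, i.e. exp(dbar' beta) with dbar the window average of the
    pandemic contrasts — a linear functional of beta, so the CI is exact
    normal theory under the HAC covariance: exp(dbar' beta +- 1.96 sqrt(
    dbar' V dbar)).

    ``window`` is (first, last) month index, inclusive; the default spans
    the first interruption to the window end (the post-restriction period).
    ``exclude_outliers`` drops the outlier-dummy months from the average.
    """
    if fitted.cov_hac is None:
        raise ValueError("average RR needs the HAC covariance on the fit")
    cal = fitted.design.calendar
    if window is None:
        window = (cal.interruption_1, cal.n_months - 1)
    lo, hi = window
    months = [t for t in range(lo, hi + 1)]
    if exclude_outliers:
        months = [t for t in months if t not in cal.outlier_indices]
    if not months:
        raise ValueError("empty averaging window")
    rows = fitted.design.X.index.get_indexer(months)
    if (rows < 0).any():
        raise ValueError(f"window {window} not contained in the fitted months")
    C = _pandemic_contrast(fitted.design)[rows]
    dbar = C.mean(axis=0)
    beta = fitted.beta.to_numpy()
    log_a = float(dbar @ beta)
    var = float(dbar @ fitted.cov_hac @ dbar)
    se = np.sqrt(max(var, 0.0))
    return (
        float(np.exp(log_a)),
        float(np.exp(log_a - Z95 * se)),
        float(np.exp(log_a + Z95 * se)),
    )


def rate_difference(
    fitted: FittedITSA, month: int
) -> tuple[float, float, float]:
    """Fitted-minus-counterfactual rate per 1000 at ``month``, with 95% CI.

    Delta = (mu_t - mu_cf,t) / N_t * 1000 = 1000 (exp(x_t'b) - exp(x_cf,t'b))
    since the offset is log N_t. The CI is the delta method: the gradient of
    that expression in beta, propagated through the HAC covariance.
    """
    if fitted.cov_hac is None:
        raise ValueError("rate difference needs the HAC covariance on the fit")
    idx = fitted.design.X.index.get_indexer([month])[0]
    if idx < 0:
        raise ValueError(f"month {month} not in the fitted window")
    beta = fitted.beta.to_numpy()
    x = fitted.design.values()[idx]
    x_cf = fitted.design.counterfactual().values()[idx]
    a, b = float(np.exp(x @ beta)), float(np.exp(x_cf @ beta))
    diff = 1000.0 * (a - b)
    grad = 1000.0 * (x * a - x_cf * b)
    var = float(grad @ fitted.cov_hac @ grad)
    se = np.sqrt(max(var, 0.0))
    return diff, diff - Z95 * se, diff + Z95 * se


@dataclass
class EffectEstimates:
    """All effect summaries for one fitted series."""

    counterfactual_mu: np.ndarray
    monthly: pd.DataFrame  # month, rr, ci_low, ci_high
    average_rr: tuple[float, float, float]
    rate_difference_last: tuple[float, float, float]
    window: tuple[int, int]


def effect_estimates(
    fitted: FittedITSA,
    window: tuple[int, int] | None = None,
    exclude_outliers: bool = False,
) -> EffectEstimates:
    cal = fitted.design.calendar
    if window is None:
        window = (cal.interruption_1, cal.n_months - 1)
    return EffectEstimates(
        counterfactual_mu=counterfactual_rates(fitted),
        monthly=monthly_rr(fitted),
        average_rr=average_rr(fitted, window, exclude_outliers),
        rate_difference_last=rate_difference(fitted, cal.n_months - 1),
        window=window,
    )


@dataclass
class SubgroupResult:
    subgroup: str
    fitted: FittedITSA
    effects: EffectEstimates


def fit_subgroup_models(
    series_by_subgroup: dict[str, pd.DataFrame],
    calendar: StudyCalendar,
    lag: int = 2,
    window: tuple[int, int] | None = None,
    **design_kwargs,
) -> tuple[dict[str, SubgroupResult], dict[str, Exception]]:
    """Fully independent fits per subgroup, with error isolation.

    A failure in one subgroup (all-zero counts, rank deficiency...) is
    recorded in the returned error map; the remaining subgroups still fit.
    """
    results: dict[str, SubgroupResult] = {}
    errors: dict[str, Exception] = {}
    for name, series in series_by_subgroup.items():
        try:
            fitted = fit_itsa(calendar, series, lag=lag, **design_kwargs)
            results[name] = SubgroupResult(
                subgroup=name,
                fitted=fitted,
                effects=effect_estimates(fitted, window),
            )
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            errors[name] = exc
    return results, errors
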