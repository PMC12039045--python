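"""Segmented Poisson regression with a log-population offset and HAC errors.

The monthly count y_t is modelled as Poisson with

    log mu_t = b0 + b1 t + b2 s1_t + b3 r1_t + b4 s2_t + b5 r2_t
               + g1 sin(2 pi t / 12) + g2 cos(2 pi t / 12)
               + sum_m d_m 1[t = m] + log N_t

where s1/s2 are step indicators at the two interruptions, r1/r2 the
post-interruption slope terms (value 1 in the interruption month itself),
one Fourier pair captures annual seasonality, the d_m are outlier-month
dummies and N_t the registered population. The fit is iteratively
reweighted least squares (Fisher scoring); uncertainty comes from the
Newey-West heteroscedasticity-and-autocorrelation-consistent sandwich with
Bartlett weights (lag 2 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .calendar import StudyCalendar

__all__ = [
    "DesignError",
    "SingularDesignError",
    "ConvergenceError",
    "DesignMatrix",
    "FittedITSA",
    "build_design_matrix",
    "fit_poisson_itsa",
    "newey_west_covariance",
    "fit_itsa",
    "coefficient_table",
    "SEGMENT_TERMS",
]

# model columns carrying interruption (pandemic) effects, outliers aside
SEGMENT_TERMS = ("step_restriction", "slope_restriction", "step_recovery", "slope_recovery")


class DesignError(ValueError):
    """Series unusable for model building (gaps, zero denominators...)."""


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class DesignMatrix:
    """Design matrix, offset and the bookkeeping the effects stage needs."""

    X: pd.DataFrame  # one row per month, index = month t
    offset: np.ndarray  # log denominator
    pandemic_columns: list[str]  # steps, slopes and outlier dummies
    calendar: StudyCalendar

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def counterfactual(self) -> "DesignMatrix":
        """Copy with every pandemic column zeroed (the no-interruption path)."""
        X = self.X.copy()
        X[self.pandemic_columns] = 0.0
        return DesignMatrix(X, self.offset, self.pandemic_columns, self.calendar)


def build_design_matrix(
    calendar: StudyCalendar,
    series: pd.DataFrame,
    fourier_pairs: int = 1,
    include_quadratic_trend: bool = False,
    slope_starts_at_one: bool = True,
) -> DesignMatrix:
    """Build the segmented design matrix from an aggregated monthly series.

    ``series`` must hold unredacted, unrounded integer counts with columns
    ``month``, ``numerator``, ``denominator`` covering every month of the
    window exactly once. ``slope_starts_at_one`` controls the slope-change
    coding: by default the slope term is 1 in the interruption month (so the
    step coefficient is the level shift at that month); the alternative
    starts it at 0 one month later.
    """
    s = series.sort_values("month").reset_index(drop=True)
    if "redacted" in s.columns and s["redacted"].any():
        raise DesignError("model input must be the unredacted series")
    t = s["month"].to_numpy()
    expected = np.arange(calendar.n_months)
    if len(t) != len(expected) or (t != expected).any():
        raise DesignError(
            "series must cover every month of the window exactly once "
            f"(got {len(t)} rows for a {calendar.n_months}-month window)"
        )
    den = s["denominator"].to_numpy(dtype=float)
    if (den <= 0).any():
        bad = int(t[np.argmax(den <= 0)])
        raise DesignError(f"zero denominator at month {calendar.month_of(bad)}")

    i1, i2 = calendar.interruption_1, calendar.interruption_2
    shift = 1 if slope_starts_at_one else 0
    tf = expected.astype(float)
    cols: dict[str, np.ndarray] = {
        "const": np.ones_like(tf),
        "time": tf,
        "step_restriction": (expected >= i1).astype(float),
        "slope_restriction": np.maximum(0.0, tf - i1 + shift),
        "step_recovery": (expected >= i2).astype(float),
        "slope_recovery": np.maximum(0.0, tf - i2 + shift),
    }
    if include_quadratic_trend:
        cols["time_sq"] = tf**2
    for k in range(1, fourier_pairs + 1):
        cols[f"season_sin{k}"] = np.sin(2 * np.pi * k * tf / 12.0)
        cols[f"season_cos{k}"] = np.cos(2 * np.pi * k * tf / 12.0)
    pandemic = list(SEGMENT_TERMS)
    for m in calendar.outlier_indices:
        name = f"outlier_{calendar.month_of(m)}"
        cols[name] = (expected == m).astype(float)
        pandemic.append(name)
    X = pd.DataFrame(cols, index=expected)
    return DesignMatrix(X, np.log(den), pandemic, calendar)


@dataclass
class FittedITSA:
    """A converged segmented Poisson fit."""

    beta: pd.Series
    fitted_mu: np.ndarray
    converged: bool
    n_iterations: int
    log_likelihood: float
    design: DesignMatrix
    counts: np.ndarray
    cov_hac: np.ndarray | None = None
    hac_lag: int | None = None

    def se(self) -> pd.Series:
        if self.cov_hac is None:
            raise ValueError("no covariance attached; run newey_west_covariance")
        return pd.Series(np.sqrt(np.diag(self.cov_hac)), index=self.beta.index)

    def score(self) -> np.ndarray:
        """Gradient of the Poisson log-likelihood at beta (should be ~0)."""
        X = self.design.values()
        return X.T @ (self.counts - self.fitted_mu)


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def fit_poisson_itsa(
    design: DesignMatrix,
    counts: np.ndarray | pd.Series,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedITSA:
    """Maximum-likelihood fit by iteratively reweighted least squares.

    Convergence is declared when the score (likelihood gradient) max-norm
    drops below ``tol``. Raises :class:`SingularDesignError` for rank
    deficiency and :class:`ConvergenceError` (with the score-norm trace)
    after ``max_iter`` iterations.
    """
    X = design.values()
    y = np.asarray(counts, dtype=float)
    if len(y) != X.shape[0]:
        raise DesignError("counts not aligned with design rows")
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise DesignError("counts must be non-negative integers")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix rank {np.linalg.matrix_rank(X)} < {X.shape[1]} columns"
        )

    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.sum(), 0.5) / np.exp(design.offset).sum())
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta + design.offset, -500, 500)
        mu = np.exp(eta)
        score = X.T @ (y - mu)
        norm = float(np.max(np.abs(score)))
        trace.append(norm)
        if norm < tol:
            return FittedITSA(
                beta=pd.Series(beta, index=design.columns),
                fitted_mu=mu,
                converged=True,
                n_iterations=it - 1,
                log_likelihood=_poisson_loglik(y, mu),
                design=design,
                counts=y,
            )
        info = (X * mu[:, None]).T @ X  # Fisher information
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(str(exc)) from exc
        beta = beta + step
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(final score max-norm {trace[-1]:.3g})",
        trace,
    )


def newey_west_covariance(
    fitted: FittedITSA, lag: int = 2
) -> np.ndarray:
    """Newey-West HAC covariance of the coefficient vector.

    V = B M B with bread B = (X' diag(mu) X)^-1 and Bartlett-weighted meat
    M = sum_t u_t u_t' + sum_{j=1..L} (1 - j/(L+1)) sum_t (u_t u_{t-j}' +
    u_{t-j} u_t'), where u_t = x_t (y_t - mu_t) are the score contributions.
    lag = 0 reduces exactly to the HC0 sandwich.
    """
    if not fitted.converged:
        raise ValueError("covariance requires a converged fit")
    X = fitted.design.values()
    n = X.shape[0]
    if lag >= n:
        raise ValueError(f"lag {lag} must be smaller than the series length {n}")
    u = X * (fitted.counts - fitted.fitted_mu)[:, None]
    bread = np.linalg.inv((X * fitted.fitted_mu[:, None]).T @ X)
    meat = u.T @ u
    for j in range(1, lag + 1):
        gamma = u[j:].T @ u[:-j]
        meat += (1.0 - j / (lag + 1.0)) * (gamma + gamma.T)
    V = bread @ meat @ bread
    return (V + V.T) / 2.0


def fit_itsa(
    calendar: StudyCalendar,
    series: pd.DataFrame,
    lag: int = 2,
    **design_kwargs,
) -> FittedITSA:
    """Convenience wrapper: design matrix + IRLS fit + HAC covariance."""
    design = build_design_matrix(calendar, series, **design_kwargs)
    fitted = fit_poisson_itsa(design, series.sort_values("month")["numerator"])
    fitted.cov_hac = newey_west_covariance(fitted, lag=lag)
    fitted.hac_lag = lag
    return fitted


_TERM_LABELS = {
    "time": "pre-period monthly slope",
    "step_restriction": "restrictions level shift",
    "slope_restriction": "restrictions slope change",
    "step_recovery": "recovery level shift",
    "slope_recovery": "recovery slope change",
}


def coefficient_table(fitted: FittedITSA, z: float = 1.96) -> pd.DataFrame:
    """Interruption coefficients as percentage effects with 95% CIs.

    Each coefficient b is reported as (exp(b) - 1) * 100, the percentage
    change in the rate, with the CI mapped through the same transform.
    """
    se = fitted.se()
    rows = []
    for term, label in _TERM_LABELS.items():
        b, s = fitted.beta[term], se[term]
        rows.append(
            {
                "term": label,
                "estimate_pct": (np.exp(b) - 1.0) * 100.0,
                "ci_low_pct": (np.exp(b - z * s) - 1.0) * 100.0,
                "ci_high_pct": (np.exp(b + z * s) - 1.0) * 100.0,
            }
        )
    return pd.DataFrame(rows)
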