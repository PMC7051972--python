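"""Estimators and models for right-censored time-to-event data.

The central primitive here is the null-model martingale residual

    M_i = delta_i - Lambda_hat(t_i),

where ``delta_i`` is the event indicator and ``Lambda_hat`` the Nelson-Aalen
cumulative-hazard estimate from the same sample.  With no covariates the Cox
model's cumulative hazard *is* the Nelson-Aalen estimator, so these residuals
can be computed in closed form, sum to zero exactly, and are bounded above
by +1 (a subject can contribute at most one more event than expected).  They
serve downstream as a censoring-aware continuous proxy for the outcome.

Cox partial-likelihood fitting (Efron ties, Newton-Raphson) is delegated to
lifelines; :func:`cox_fit` wraps it behind a small result object so the rest
of the package never touches a fitter directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.exceptions import ConvergenceError

__all__ = [
    "StepFunction",
    "CoxFit",
    "nelson_aalen",
    "kaplan_meier",
    "null_martingale_residuals",
    "null_partial_loglik",
    "logrank_test",
    "cox_fit",
    "breslow_cumhaz",
]


def _check_outcomes(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be aligned 1-d arrays")
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time < 0) or np.any(np.isnan(time)):
        raise ValueError("follow-up times must be nonnegative and non-missing")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous piecewise-constant function with jumps at ``times``.

    ``baseline`` is the value before the first jump (0 for a cumulative
    hazard, 1 for a survival curve).
    """

    times: np.ndarray
    values: np.ndarray
    baseline: float = 0.0

    def _eval(self, t, side: str):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.baseline)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.times, t, side=side) - 1
        out = np.where(idx < 0, self.baseline, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def __call__(self, t) -> np.ndarray | float:
        return self._eval(t, "right")

    def before(self, t) -> np.ndarray | float:
        """Left-continuous evaluation, i.e. the value just before ``t``."""
        return self._eval(t, "left")


def _event_table(time, event):
    """Distinct event times s with event counts d_s and at-risk counts n_s.

    At-risk uses the left-closed convention t_i >= s, so subjects with an
    event at t = 0 are at risk at their own event time.
    """
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    event_times = np.unique(time[event == 1])
    # subjects at risk at s: t_i >= s
    n_at_risk = time.size - np.searchsorted(time, event_times, side="left")
    d = np.array([int(event[time == s].sum()) for s in event_times])
    return event_times, d, n_at_risk


def nelson_aalen(time, event) -> StepFunction:
    """Nelson-Aalen cumulative hazard, aggregating ties as d_s / n_s."""
    time, event = _check_outcomes(time, event)
    s, d, n = _event_table(time, event)
    return StepFunction(times=s, values=np.cumsum(d / n), baseline=0.0)


def kaplan_meier(time, event) -> StepFunction:
    """Kaplan-Meier product-limit survival estimate."""
    time, event = _check_outcomes(time, event)
    s, d, n = _event_table(time, event)
    return StepFunction(times=s, values=np.cumprod(1.0 - d / n), baseline=1.0)


def null_martingale_residuals(time, event) -> np.ndarray:
    """Martingale residuals of the covariate-free (null) Cox model.

    Returns ``delta_i - Lambda_hat(t_i)``.  The residuals sum to zero exactly
    and no residual exceeds +1.
    """
    time, event = _check_outcomes(time, event)
    chaz = nelson_aalen(time, event)
    resid = event - chaz(time)
    return np.asarray(resid, dtype=float)


def null_partial_loglik(time, event) -> float:
    """Cox partial log-likelihood at beta = 0 (Efron tie handling).

    With all risk scores equal to 1, the Efron denominator for the l-th of
    d tied events is n_s - l, so the null log-likelihood reduces to
    ``-sum_s sum_{l=0}^{d_s-1} log(n_s - l)``.
    """
    time, event = _check_outcomes(time, event)
    s, d, n = _event_table(time, event)
    total = 0.0
    for d_s, n_s in zip(d, n):
        total -= np.log(n_s - np.arange(d_s)).sum()
    return float(total)


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Log-rank test across >= 2 groups.

    Returns ``(chi_square, p)`` with the p-value from the chi-square upper
    tail at (number of groups - 1) degrees of freedom.
    """
    time, event = _check_outcomes(time, event)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def breslow_cumhaz(time, event, linear_predictor=None) -> StepFunction:
    """Breslow estimate of the baseline cumulative hazard given risk scores.

    ``Lambda_0(t) = sum_{s <= t} d_s / sum_{i at risk at s} exp(lp_i)``;
    with all linear predictors zero this reduces to Nelson-Aalen.  A
    subject's event-by-horizon probability under the proportional-hazards
    model is then ``1 - exp(-Lambda_0(tau) * exp(lp_i))``.
    """
    time, event = _check_outcomes(time, event)
    lp = (np.zeros(time.size) if linear_predictor is None
          else np.asarray(linear_predictor, dtype=float))
    risk = np.exp(lp)
    s, d, _ = _event_table(time, event)
    denom = np.array([risk[time >= t].sum() for t in s])
    return StepFunction(times=s, values=np.cumsum(d / denom), baseline=0.0)


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``summary`` holds per-covariate hazard ratios with 95% CIs
    (columns: coef, se, hr, hr_lower, hr_upper).  A null fit has
    ``n_params == 0`` and an empty summary.
    """

    coefs: pd.Series
    log_likelihood: float
    n_params: int
    n_subjects: int
    n_events: int
    covariance: pd.DataFrame = field(default_factory=pd.DataFrame)
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        if self.n_params == 0:
            return np.zeros(len(X))
        return X[self.coefs.index].to_numpy(dtype=float) @ self.coefs.to_numpy()


def cox_fit(X: pd.DataFrame | None, time, event) -> CoxFit:
    """Fit a Cox model by maximum partial likelihood (Efron ties).

    ``X = None`` (or no columns) fits the null model: no parameters, with the
    partial log-likelihood evaluated at beta = 0.
    """
    time, event = _check_outcomes(time, event)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return CoxFit(
            coefs=pd.Series(dtype=float),
            log_likelihood=null_partial_loglik(time, event),
            n_params=0,
            n_subjects=time.size,
            n_events=int(event.sum()),
        )
    X = pd.DataFrame(X)
    if len(X) != time.size:
        raise ValueError("covariate rows must align with outcomes")
    if X.isna().any().any():
        raise ValueError("covariates contain missing values; impute first")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates cannot be fit: {constant}")

    df = X.copy()
    df["_time"], df["_event"] = time, event
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as err:
        raise RuntimeError(
            "Cox fit did not converge; a covariate that perfectly separates "
            "events (monotone likelihood) is the usual cause"
        ) from err
    summary = pd.DataFrame(
        {
            "coef": fitter.params_,
            "se": fitter.standard_errors_,
            "hr": np.exp(fitter.params_),
            "hr_lower": np.exp(fitter.params_ - 1.96 * fitter.standard_errors_),
            "hr_upper": np.exp(fitter.params_ + 1.96 * fitter.standard_errors_),
        }
    )
    return CoxFit(
        coefs=fitter.params_.copy(),
        log_likelihood=float(fitter.log_likelihood_),
        n_params=len(fitter.params_),
        n_subjects=time.size,
        n_events=int(event.sum()),
        covariance=fitter.variance_matrix_.copy(),
        summary=summary,
    )
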