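"""Model-comparison and prediction metrics for right-censored outcomes.

Covers information criteria (AIC and its small-sample correction AICc),
the likelihood-ratio test for nested Cox models, Harrell's concordance
index with the classical pair-evaluability rules, the inverse-probability-
of-censoring-weighted (IPCW) Brier score and cumulative/dynamic AUC at a
fixed horizon, the Nam-D'Agostino calibration statistic over risk deciles,
and the adjusted Rand index between partitions.

Censoring weights use the Kaplan-Meier estimate of the censoring
distribution (events and censorings swapped), evaluated left-continuously.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .survival import StepFunction, kaplan_meier

__all__ = [
    "aic_aicc",
    "meaningful_aic_improvement",
    "likelihood_ratio_test",
    "concordance_index",
    "brier_ipcw",
    "auc_at_horizon",
    "nam_dagostino",
    "adjusted_rand_index",
    "censoring_survival",
]

DEFAULT_HORIZON = 60.0  # months (5 years)


def aic_aicc(log_likelihood: float, n_params: int, n_subjects: int) -> tuple[float, float]:
    """AIC = 2p - 2 lnL and AICc = AIC + (2p^2 + 2p) / (n - p - 1)."""
    p, n = n_params, n_subjects
    if n <= p + 1:
        raise ValueError("AICc requires n > p + 1")
    aic = 2.0 * p - 2.0 * log_likelihood
    return aic, aic + (2.0 * p**2 + 2.0 * p) / (n - p - 1)


def meaningful_aic_improvement(delta_aic_negated: float, threshold: float = 3.0) -> bool:
    """Whether a negated AIC difference (positive = better) clears the
    conventional meaningful-difference threshold of 3."""
    return delta_aic_negated >= threshold


def likelihood_ratio_test(lnl_null: float, lnl_alt: float, df: int,
                          tol: float = 1e-8) -> tuple[float, float]:
    """LRT statistic -2(lnL_null - lnL_alt) with a chi-square upper-tail p."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    statistic = -2.0 * (lnl_null - lnl_alt)
    if statistic < -tol:
        raise ValueError("alternative model has lower likelihood; models not nested?")
    statistic = max(statistic, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


def concordance_index(risk, time, event) -> float:
    """Harrell's C: fraction of evaluable pairs ordered correctly by risk.

    Pair rules: both uncensored -> evaluable (unless their event times tie);
    both censored -> not evaluable; one censored -> evaluable iff the
    censored follow-up is at least the uncensored event time (at a tie the
    event is taken to occur first).  Concordant means the subject with the
    shorter uncensored survival has the higher risk; risk ties count 1/2.
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    # pair (i, j): i fails at time[i]; the partner must survive past it —
    # strictly later if they also fail (tied event times are not orderable),
    # at least as late if they are censored (the event is taken to be first)
    fails_later = (time[None, :] > time[:, None]) & (event[None, :] == 1)
    outlives = (time[None, :] >= time[:, None]) & (event[None, :] == 0)
    evaluable = (event[:, None] == 1) & (fails_later | outlives)
    np.fill_diagonal(evaluable, False)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError("no evaluable pairs")
    ordered = np.where(
        risk[:, None] > risk[None, :], 1.0,
        np.where(risk[:, None] == risk[None, :], 0.5, 0.0),
    )
    return float((evaluable * ordered).sum() / n_eval)


def censoring_survival(time, event) -> StepFunction:
    """Kaplan-Meier estimate of the censoring distribution G(t).

    Obtained by swapping the roles of events and censorings."""
    event = np.asarray(event).astype(int)
    return kaplan_meier(time, 1 - event)


def _ipcw_weights(time, event, horizon):
    """Graf-style IPCW weights at a horizon.

    Subjects with an observed event by the horizon weigh 1/G(t_i-); subjects
    still at risk past it weigh 1/G(horizon); subjects censored before it
    weigh 0.  G is evaluated left-continuously.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    G = censoring_survival(time, event)
    w = np.zeros(time.size)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    g_case = np.asarray(G.before(time[case]), dtype=float)
    g_horizon = float(G(horizon))
    if np.any(g_case <= 0) or (control.any() and g_horizon <= 0):
        raise ValueError("censoring survival hits 0 at a required time")
    w[case] = 1.0 / g_case
    if control.any():
        w[control] = 1.0 / g_horizon
    return w, case, control


def brier_ipcw(pred_event_prob, time, event, horizon: float = DEFAULT_HORIZON) -> float:
    """IPCW Brier score of predicted event-by-horizon probabilities.

    With no censoring this is the plain mean squared error between the 0/1
    horizon status and the prediction: 0 for a perfect model and 0.25 for a
    constant 1/2.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    pred = np.asarray(pred_event_prob, dtype=float)
    if np.any((pred < 0) | (pred > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    w, case, control = _ipcw_weights(time, event, horizon)
    sq = np.zeros_like(pred)
    sq[case] = (1.0 - pred[case]) ** 2
    sq[control] = pred[control] ** 2
    return float(np.sum(w * sq) / pred.size)


def auc_at_horizon(pred_risk, time, event, horizon: float = DEFAULT_HORIZON) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW case weights.

    Cases are subjects with an observed event by the horizon, controls those
    still at risk past it.  Cases are weighted 1/G(t_i-) (the shared control
    weight 1/G(horizon) cancels).  With no censoring this reduces to the
    Mann-Whitney statistic of the risk scores between the two status groups.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    pred = np.asarray(pred_risk, dtype=float)
    w, case, control = _ipcw_weights(np.asarray(time, float), event, horizon)
    if not case.any() or not control.any():
        raise ValueError("need at least one case and one control at the horizon")
    pc, wc = pred[case], w[case]
    pk = pred[control]
    greater = (pc[:, None] > pk[None, :]).astype(float)
    ties = (pc[:, None] == pk[None, :]).astype(float)
    numer = (wc[:, None] * (greater + 0.5 * ties)).sum()
    denom = wc.sum() * pk.size
    return float(numer / denom)


def nam_dagostino(pred_event_prob, time, event, horizon: float = DEFAULT_HORIZON,
                  n_bins: int = 10) -> tuple[float, float]:
    """Nam-D'Agostino calibration statistic over predicted-risk deciles.

    Subjects are binned by quantiles of predicted risk; within each bin the
    observed event proportion by the horizon is 1 - KM(horizon) and the
    expected proportion is the mean prediction.  The statistic
    sum_d n_d (O_d - E_d)^2 / (E_d (1 - E_d)) is referred to a chi-square
    with ``n_bins - 2`` degrees of freedom (10 bins -> 8 df).
    """
    pred = np.asarray(pred_event_prob, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if pred.size < 2 * n_bins:
        raise ValueError("too few subjects for the requested number of bins")
    bins = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    statistic = 0.0
    for b in np.unique(bins):
        sel = bins == b
        expected = float(pred[sel].mean())
        if expected <= 0.0 or expected >= 1.0:
            raise ValueError("a risk bin has degenerate expected probability")
        km = kaplan_meier(time[sel], event[sel])
        observed = 1.0 - float(km(horizon))
        n_d = int(sel.sum())
        statistic += n_d * (observed - expected) ** 2 / (expected * (1.0 - expected))
    df = n_bins - 2
    if df < 1:
        return float(statistic), float("nan")
    return float(statistic), float(stats.chi2.sf(statistic, df))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie chance-corrected Rand index between two partitions."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0 or labels_a.shape != labels_b.shape:
        raise ValueError("partitions must be non-empty and aligned")
    return float(adjusted_rand_score(labels_a, labels_b))
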