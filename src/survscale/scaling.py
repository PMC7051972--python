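"""Outcome-supervised scaling of a standardized feature space.

Clustering on its own is agnostic to the outcome.  To steer it, each
subject is first given a continuous, censoring-aware proxy for their
outcome — the martingale residual of a covariate-free Cox model — and an
ordinary least-squares regression of those residuals on the standardized
features is fit.  The magnitude of each fitted coefficient then multiplies
its feature column, so that Manhattan distances in the scaled space weight
features by how strongly they track excess risk.  Features unrelated to
the outcome get coefficients near zero and effectively drop out of the
geometry.

The magnitude (not the signed coefficient) is used: pairwise L1 distances
satisfy |w| * |x - y| regardless of sign, so a negative weight would only
flip a coordinate's orientation without changing any distance; using |w|
keeps the scaled matrix in the nonnegative orthant.  The intercept is
estimated but never applied — it shifts all points equally and cannot
affect a distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ScalingWeights", "SupervisedScaler", "fit_scaling_weights", "apply_scaling"]


@dataclass(frozen=True)
class ScalingWeights:
    """OLS fit of residuals on features: an intercept plus one slope per feature."""

    intercept: float
    coefficients: pd.Series

    def column_weights(self) -> pd.Series:
        return self.coefficients.abs()


class SupervisedScaler(TransformerMixin, BaseEstimator):
    """Scale feature columns by |OLS coefficient| against a continuous target.

    ``fit(X, y)`` solves the least-squares problem ``y ~ 1 + X`` (via QR on
    the economy SVD path of :func:`numpy.linalg.lstsq`); ``transform``
    multiplies column j by ``|coef_j|``.  A rank-deficient design is refused,
    naming the collinear columns, since its coefficients are not identified.
    """

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError("residuals must align with the feature rows")
        if n <= p:
            raise ValueError("need more subjects than features for OLS")
        design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(design)
        if rank < p + 1:
            collinear = self._collinear_columns(X)
            raise ValueError(
                f"design is rank-deficient; collinear features: {collinear}"
            )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.weights_ = ScalingWeights(
            intercept=float(beta[0]),
            coefficients=pd.Series(beta[1:], index=X.columns),
        )
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    @staticmethod
    def _collinear_columns(X: pd.DataFrame) -> list[str]:
        """Columns not reachable by a greedy rank-increasing sweep."""
        cols: list[str] = []
        basis = np.ones((len(X), 1))
        for c in X.columns:
            cand = np.column_stack([basis, X[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                basis = cand
            else:
                cols.append(c)
        return cols

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature names do not match the fitted scaler")
        return X * self.weights_.column_weights()


def fit_scaling_weights(X, residuals) -> ScalingWeights:
    """OLS of martingale residuals on standardized features."""
    return SupervisedScaler().fit(X, residuals).weights_


def apply_scaling(X: pd.DataFrame, weights: ScalingWeights) -> pd.DataFrame:
    """Multiply each column by the magnitude of its fitted coefficient."""
    X = pd.DataFrame(X)
    missing = [c for c in X.columns if c not in weights.coefficients.index]
    if missing:
        raise ValueError(f"no scaling weight for features: {missing}")
    return X * weights.column_weights()[X.columns]
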