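"""Imputation, standardization, redundancy filtering and RReliefF selection.

All four stages are scikit-learn style transformers so they compose in a
Pipeline, but each is fit strictly on training rows and applied to held-out
rows with the trained state only — ranges, donor pools and regression models
never see validation data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler

__all__ = ["RangeScaler", "PMMImputer", "VarianceCorrelationFilter", "RReliefF"]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class RangeScaler(TransformerMixin, BaseEstimator):
    """Min-max standardization onto [0, 1] with stored training ranges.

    Each column is affinely mapped so the training minimum hits 0 and the
    training maximum hits 1.  A constant column maps to 0.  New rows are
    transformed with the *training* ranges and clipped back into [0, 1], so
    Manhattan distances stay bounded for out-of-range validation values.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        if X.isna().any().any():
            raise ValueError("RangeScaler requires complete data; impute first")
        self.feature_names_in_ = np.asarray(X.columns)
        self._scaler = MinMaxScaler(feature_range=(0.0, 1.0), clip=True).fit(X)
        self.data_min_ = pd.Series(self._scaler.data_min_, index=X.columns)
        self.data_max_ = pd.Series(self._scaler.data_max_, index=X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature names do not match the fitted scaler")
        out = self._scaler.transform(X)
        return pd.DataFrame(out, index=X.index, columns=X.columns)

    @property
    def ranges_(self) -> pd.DataFrame:
        return pd.DataFrame({"min": self.data_min_, "max": self.data_max_})


class PMMImputer(TransformerMixin, BaseEstimator):
    """Chained-equations imputation by predictive mean matching.

    For each feature with missing cells, a least-squares linear model of
    that feature on all other (current-iteration) features is fit over the
    rows where the feature is observed.  Each missing cell is filled with
    the observed value of one of the ``k_donors`` rows whose model
    predictions are closest to the cell's own prediction, the donor drawn
    uniformly at random.  The cycle repeats ``n_cycles`` times.  Imputed
    values therefore always belong to the observed support of their column.

    ``transform`` imputes each new row individually against the completed
    training matrix only: rows never inform one another, and the result is
    invariant to the order rows are presented in (the per-row random stream
    is keyed by the row's index label).
    """

    def __init__(self, k_donors: int = 5, n_cycles: int = 5, random_state: int = 0):
        self.k_donors = k_donors
        self.n_cycles = n_cycles
        self.random_state = random_state

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        X = _as_frame(X).astype(float)
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")
        fully_missing = [c for c in X.columns if X[c].isna().all()]
        if fully_missing:
            raise ValueError(f"features entirely missing: {fully_missing}")
        self.feature_names_in_ = np.asarray(X.columns)
        self.observed_mask_ = X.notna()
        self.medians_ = X.median(skipna=True)

        rng = np.random.default_rng(self.random_state)
        completed = X.fillna(self.medians_)
        missing_cols = [c for c in X.columns if X[c].isna().any()]
        for _ in range(self.n_cycles):
            for c in missing_cols:
                obs = self.observed_mask_[c].to_numpy()
                beta = self._ols(completed, c, obs)
                pred = self._predict(completed, c, beta)
                donors_pred, donors_val = pred[obs], X[c].to_numpy()[obs]
                for i in np.flatnonzero(~obs):
                    completed.iloc[i, completed.columns.get_loc(c)] = self._draw(
                        pred[i], donors_pred, donors_val, rng
                    )
        self.completed_ = completed
        # final per-column models against the completed matrix, reused on
        # validation rows
        self.models_ = {}
        for c in X.columns:
            obs = self.observed_mask_[c].to_numpy()
            beta = self._ols(completed, c, obs)
            pred = self._predict(completed, c, beta)
            self.models_[c] = (beta, pred[obs], X[c].to_numpy()[obs])
        return completed.copy()

    @staticmethod
    def _ols(completed: pd.DataFrame, col: str, obs: np.ndarray) -> np.ndarray:
        others = completed.drop(columns=[col]).to_numpy(dtype=float)
        design = np.column_stack([np.ones(obs.sum()), others[obs]])
        beta, *_ = np.linalg.lstsq(design, completed[col].to_numpy()[obs], rcond=None)
        return beta

    @staticmethod
    def _predict(completed: pd.DataFrame, col: str, beta: np.ndarray) -> np.ndarray:
        others = completed.drop(columns=[col]).to_numpy(dtype=float)
        return np.column_stack([np.ones(len(others)), others]) @ beta

    def _draw(self, target_pred, donors_pred, donors_val, rng) -> float:
        k = min(self.k_donors, donors_pred.size)
        nearest = np.argsort(np.abs(donors_pred - target_pred), kind="stable")[:k]
        return float(donors_val[nearest[rng.integers(k)]])

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X).astype(float)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature names do not match the fitted imputer")
        out = X.copy()
        for label, row in X.iterrows():
            if row.isna().all():
                raise ValueError(f"row {label!r} is missing every feature")
            if not row.isna().any():
                continue
            out.loc[label] = self._impute_row(row)
        return out

    def _impute_row(self, row: pd.Series) -> pd.Series:
        # order-invariant stream: keyed by the base seed and the row label
        key = int(pd.util.hash_pandas_object(pd.Index([row.name])).iloc[0] % (2**31))
        rng = np.random.default_rng([self.random_state, key])
        missing = [c for c in row.index if pd.isna(row[c])]
        current = row.fillna(self.medians_)
        for _ in range(self.n_cycles):
            for c in missing:
                beta, donors_pred, donors_val = self.models_[c]
                others = current.drop(labels=[c]).to_numpy(dtype=float)
                pred = float(np.concatenate([[1.0], others]) @ beta)
                current[c] = self._draw(pred, donors_pred, donors_val, rng)
        return current


class VarianceCorrelationFilter(TransformerMixin, BaseEstimator):
    """Drop zero-variance, near-duplicate and anchor-redundant features.

    Three passes over the training matrix, in order: (1) remove columns with
    zero variance; (2) among pairs with \\|Pearson r\\| above ``dup_threshold``
    keep the column appearing earlier in the input order; (3) remove any
    non-anchor column whose \\|r\\| with one of the ``anchors`` exceeds
    ``anchor_threshold``.  Anchors are always retained.  ``report_`` maps
    every dropped column to the reason it was dropped.
    """

    def __init__(self, dup_threshold: float = 0.99, anchor_threshold: float = 0.80,
                 anchors: tuple = ()):
        self.dup_threshold = dup_threshold
        self.anchor_threshold = anchor_threshold
        self.anchors = anchors

    def fit(self, X, y=None):
        X = _as_frame(X)
        anchors = list(self.anchors)
        missing_anchors = [a for a in anchors if a not in X.columns]
        if missing_anchors:
            raise ValueError(f"anchor features not present: {missing_anchors}")
        report: dict[str, str] = {}

        kept = []
        for c in X.columns:
            if np.isclose(X[c].std(ddof=0), 0.0):
                if c in anchors:
                    raise ValueError(f"anchor feature {c!r} has zero variance")
                report[c] = "zero variance"
            else:
                kept.append(c)

        corr = X[kept].corr(method="pearson").abs()
        survivors: list[str] = []
        for c in kept:
            dup_of = next(
                (s for s in survivors if corr.loc[c, s] > self.dup_threshold
                 and c not in anchors),
                None,
            )
            if dup_of is not None:
                report[c] = f"duplicate of {dup_of} (|r| > {self.dup_threshold})"
            else:
                survivors.append(c)

        final = []
        for c in survivors:
            if c in anchors:
                final.append(c)
                continue
            hit = next(
                (a for a in anchors if corr.loc[c, a] > self.anchor_threshold),
                None,
            )
            if hit is not None:
                report[c] = f"correlated with anchor {hit} (|r| > {self.anchor_threshold})"
            else:
                final.append(c)

        self.selected_features_ = final
        self.report_ = report
        return self

    def transform(self, X) -> pd.DataFrame:
        X = _as_frame(X)
        return X[self.selected_features_]


class RReliefF(BaseEstimator):
    """Regression ReliefF feature weighting against a continuous target.

    Repeatedly samples an instance, finds its ``k_neighbors`` nearest
    neighbours by Manhattan distance, and accumulates the probabilities of
    a feature differing given that the target does or does not differ,
    weighting neighbours by an exponentially decaying function of their
    distance rank (``exp(-(rank / sigma)^2)``, normalized).  The resulting
    weight per feature A is

        W[A] = N_dC&dA / N_dC  -  (N_dA - N_dC&dA) / (m - N_dC),

    a difference of two conditional probabilities, hence always in [-1, 1].
    Features carrying no information about the target get weights near 0;
    a constant feature gets exactly 0.
    """

    def __init__(self, n_iterations: int = 1000, k_neighbors: int = 10,
                 sigma: float = 20.0, random_state: int = 0):
        self.n_iterations = n_iterations
        self.k_neighbors = k_neighbors
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if y.shape != (n,):
            raise ValueError("target must align with the feature rows")
        if self.k_neighbors >= n:
            raise ValueError("k_neighbors must be smaller than the sample size")
        self.feature_names_in_ = np.asarray(X.columns)

        values = X.to_numpy(dtype=float)
        feat_range = values.max(axis=0) - values.min(axis=0)
        feat_range[feat_range == 0] = 1.0  # constant feature: diff stays 0
        y_range = y.max() - y.min()
        if y_range == 0:
            self.feature_importances_ = pd.Series(np.zeros(p), index=X.columns)
            return self

        rng = np.random.default_rng(self.random_state)
        m = self.n_iterations
        ranks = np.arange(1, self.k_neighbors + 1)
        influence = np.exp(-((ranks / self.sigma) ** 2))
        influence = influence / influence.sum()

        n_dc = 0.0
        n_da = np.zeros(p)
        n_dcda = np.zeros(p)
        for _ in range(m):
            i = int(rng.integers(n))
            dist = np.abs(values - values[i]).sum(axis=1)
            dist[i] = np.inf
            nb = np.argsort(dist, kind="stable")[: self.k_neighbors]
            d_y = np.abs(y[nb] - y[i]) / y_range
            d_a = np.abs(values[nb] - values[i]) / feat_range  # k x p
            n_dc += influence @ d_y
            n_da += influence @ d_a
            n_dcda += (influence * d_y) @ d_a
        with np.errstate(invalid="ignore", divide="ignore"):
            w = n_dcda / n_dc - (n_da - n_dcda) / (m - n_dc)
        self.feature_importances_ = pd.Series(np.nan_to_num(w), index=X.columns)
        return self

    def top_features(self, m: int) -> list[str]:
        """Names of the ``m`` highest-weight features, best first."""
        order = self.feature_importances_.sort_values(ascending=False, kind="stable")
        return list(order.index[:m])
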