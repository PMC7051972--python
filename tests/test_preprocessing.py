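"""Range scaling, PMM imputation, redundancy filter, RReliefF."""

import numpy as np
import pandas as pd
import pytest

from survscale.preprocessing import (
    PMMImputer,
    RangeScaler,
    RReliefF,
    VarianceCorrelationFilter,
)


class TestRangeScaler:
    def test_training_columns_map_to_unit_interval(self):
        X = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0]})
        out = RangeScaler().fit_transform(X)
        assert np.allclose(out["a"], [0.0, 0.5, 1.0])
        assert np.allclose(out["b"], 0.0)  # constant column maps to 0

    def test_validation_rows_use_training_ranges_then_clip(self):
        sc = RangeScaler().fit(pd.DataFrame({"a": [2.0, 6.0]}))
        # (8-2)/4 = 1.5, clipped to 1; (0-2)/4 < 0, clipped to 0
        out = sc.transform(pd.DataFrame({"a": [8.0, 0.0, 4.0]}))
        assert np.allclose(out["a"], [1.0, 0.0, 0.5])

    def test_extremes_and_midpoint(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        sc = RangeScaler().fit(X)
        assert np.allclose(sc.transform(pd.DataFrame([sc.data_min_])), 0.0)
        assert np.allclose(sc.transform(pd.DataFrame([sc.data_max_])), 1.0)
        mid = (sc.data_min_ + sc.data_max_) / 2
        assert np.allclose(sc.transform(pd.DataFrame([mid])), 0.5)

    def test_idempotent_on_training_data(self, rng):
        X = pd.DataFrame(rng.uniform(2, 9, size=(20, 2)), columns=["x", "y"])
        sc = RangeScaler().fit(X)
        once = sc.transform(X)
        again = RangeScaler().fit(once).transform(once)
        pd.testing.assert_frame_equal(once, again)

    def test_feature_mismatch_rejected(self, rng):
        sc = RangeScaler().fit(pd.DataFrame({"a": [0.0, 1.0]}))
        with pytest.raises(ValueError):
            sc.transform(pd.DataFrame({"b": [0.5]}))


class TestPMMImputer:
    def test_complete_matrix_returned_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        pd.testing.assert_frame_equal(PMMImputer().fit_transform(X), X)

    def test_single_cell_with_perfect_predictor_takes_nearest_donor(self):
        # b = 2a exactly, so the missing b at a = 3 predicts 6; the donor
        # with the closest prediction is the row with b = 4 (distance 2,
        # against 3 for b = 9), and k_donors = 1 makes the copy deterministic
        X = pd.DataFrame({"a": [1.0, 2, 3, 4.5, 5], "b": [2.0, 4, np.nan, 9, 10]})
        out = PMMImputer(k_donors=1, random_state=0).fit_transform(X)
        assert out.loc[2, "b"] == 4.0

    def test_imputed_values_stay_in_observed_support(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        mask = rng.random(X.shape) < 0.15
        X = X.mask(mask)
        X.iloc[0] = rng.normal(size=4)  # keep at least one complete row
        out = PMMImputer(random_state=3).fit_transform(X)
        for c in X.columns:
            support = set(X[c].dropna())
            assert set(out[c]) <= support | set(X[c].dropna())

    def test_validation_rows_deterministic_and_order_invariant(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        X.iloc[5, 0] = np.nan
        imp = PMMImputer(random_state=1).fit(X)
        rows = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"),
                            index=[10, 11, 12, 13])
        rows.iloc[0, 1] = np.nan
        rows.iloc[2, 2] = np.nan
        fwd = imp.transform(rows)
        rev = imp.transform(rows.iloc[::-1]).iloc[::-1]
        pd.testing.assert_frame_equal(fwd, rev)
        pd.testing.assert_frame_equal(fwd, imp.transform(rows))

    def test_fully_observed_validation_row_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        X.iloc[2, 1] = np.nan
        imp = PMMImputer(random_state=0).fit(X)
        row = pd.DataFrame(rng.normal(size=(1, 3)), columns=list("abc"))
        pd.testing.assert_frame_equal(imp.transform(row), row)

    def test_error_cases(self, rng):
        X = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            PMMImputer().fit(X)
        Y = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [1.0, 3.0, 2.0]})
        imp = PMMImputer().fit(Y)
        empty = pd.DataFrame({"a": [np.nan], "b": [np.nan]})
        with pytest.raises(ValueError, match="missing every feature"):
            imp.transform(empty)


class TestVarianceCorrelationFilter:
    def test_zero_variance_duplicates_and_anchor_redundancy(self, rng):
        n = 50
        anchor = rng.normal(size=n)
        X = pd.DataFrame({
            "anchor": anchor,
            "x": rng.normal(size=n),
            "dup_of_x": None,
            "near_anchor": anchor + 0.3 * rng.normal(size=n),
            "weak": 0.5 * anchor + np.sqrt(1 - 0.25) * rng.normal(size=n),
            "const": 1.0,
        })
        X["dup_of_x"] = X["x"]
        r_near = abs(np.corrcoef(X["near_anchor"], anchor)[0, 1])
        r_weak = abs(np.corrcoef(X["weak"], anchor)[0, 1])
        assert 0.80 < r_near < 0.99 and r_weak < 0.80  # fixture preconditions
        f = VarianceCorrelationFilter(anchors=("anchor",)).fit(X)
        assert f.selected_features_ == ["anchor", "x", "weak"]
        assert f.report_["const"] == "zero variance"
        assert "duplicate of x" in f.report_["dup_of_x"]
        assert "anchor" in f.report_["near_anchor"]

    def test_duplicate_tie_keeps_earlier_column(self, rng):
        v = rng.normal(size=30)
        X = pd.DataFrame({"first": v, "second": v.copy()})
        f = VarianceCorrelationFilter().fit(X)
        assert f.selected_features_ == ["first"]

    def test_missing_anchor_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="anchor"):
            VarianceCorrelationFilter(anchors=("gone",)).fit(X)


class TestRReliefF:
    def test_constant_feature_gets_zero_weight(self, rng):
        X = pd.DataFrame({"c": np.ones(50), "x": rng.uniform(size=50)})
        rr = RReliefF(n_iterations=100, k_neighbors=5, random_state=0).fit(
            X, rng.uniform(size=50)
        )
        assert rr.feature_importances_["c"] == 0.0

    def test_signal_feature_dominates_noise(self, rng):
        n = 300
        X = pd.DataFrame(
            rng.uniform(size=(n, 11)), columns=[f"f{i}" for i in range(11)]
        )
        y = X["f0"].to_numpy()
        rr = RReliefF(n_iterations=500, random_state=0).fit(X, y)
        assert rr.top_features(1) == ["f0"]
        assert rr.feature_importances_.abs().max() <= 1.0

    def test_signal_ranked_first_in_most_replicates(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(
                r.uniform(size=(300, 6)), columns=[f"f{i}" for i in range(6)]
            )
            rr = RReliefF(n_iterations=300, random_state=seed).fit(
                X, X["f3"].to_numpy()
            )
            wins += rr.top_features(1) == ["f3"]
        assert wins >= 19  # >= 95% of replicates

    def test_too_many_neighbors_rejected(self, rng):
        X = pd.DataFrame(rng.uniform(size=(5, 2)))
        with pytest.raises(ValueError):
            RReliefF(k_neighbors=5).fit(X, np.arange(5.0))
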