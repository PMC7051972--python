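"""Information criteria, LRT, C-index, IPCW Brier/AUC, calibration, ARI."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from survscale.metrics import (
    adjusted_rand_index,
    aic_aicc,
    auc_at_horizon,
    brier_ipcw,
    concordance_index,
    likelihood_ratio_test,
    meaningful_aic_improvement,
    nam_dagostino,
)


class TestInformationCriteria:
    def test_null_model_has_no_small_sample_correction(self):
        aic, aicc = aic_aicc(-100.0, 0, 50)
        assert aic == aicc == 200.0

    def test_hand_computed_aicc(self):
        aic, aicc = aic_aicc(-100.0, 3, 10)
        assert aic == 206.0
        assert aicc == 210.0  # 206 + 24/6

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(ValueError):
            aic_aicc(-100.0, 3, 4)

    def test_meaningful_improvement_threshold(self):
        assert meaningful_aic_improvement(3.0)
        assert not meaningful_aic_improvement(2.9)


class TestLikelihoodRatioTest:
    def test_equal_likelihoods_give_null_result(self):
        stat, p = likelihood_ratio_test(-50.0, -50.0, 1)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_chi_square_tail(self):
        stat, p = likelihood_ratio_test(-105.0, -100.0, 1)
        assert stat == 10.0
        assert p == pytest.approx(0.00157, abs=1e-5)

    def test_alternative_below_null_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-100.0, -105.0, 1)

    def test_zero_degrees_of_freedom_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(-105.0, -100.0, 0)


class TestConcordanceIndex:
    def test_perfectly_ordered_risks(self):
        assert concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
        assert concordance_index([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_censored_pair_rules_hand_example(self):
        # A fails at 1 (risk 3), B censored at 2 (risk 1), C fails at 3
        # (risk 2): evaluable pairs {A,B}, {A,C}; B-C not evaluable since
        # B's censoring precedes C's event; both evaluable pairs concordant
        assert concordance_index([3, 1, 2], [1, 2, 3], [1, 0, 1]) == 1.0

    def test_risk_ties_count_half(self):
        assert concordance_index([1, 1], [1, 2], [1, 1]) == 0.5

    def test_all_censored_has_no_evaluable_pairs(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1, 2], [0, 0])

    def test_random_risks_concordance_near_half(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            t = r.exponential(20, 200)
            e = r.integers(0, 2, 200)
            if e.sum() == 0:
                continue
            vals.append(concordance_index(r.normal(size=200), t, e))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestBrier:
    def test_uninformative_constant_half_scores_quarter(self):
        t = np.arange(1, 11, dtype=float)
        assert brier_ipcw(np.full(10, 0.5), t, np.ones(10), horizon=60) == 0.25

    def test_perfect_predictions_score_zero(self):
        t = np.arange(1, 11, dtype=float)
        status = (t <= 5).astype(float)
        assert brier_ipcw(status, t, np.ones(10), horizon=5) == 0.0

    def test_four_subject_ipcw_hand_computation(self):
        # subjects (t, e): (2,1), (4,0), (6,1), (8,0); horizon 5.
        # censoring KM: drops at 4 (to 2/3) and 8; weights: subject 1 ->
        # 1/G(2-) = 1, subject 2 -> 0, subjects 3,4 -> 1/G(5) = 3/2.
        pred = np.array([0.8, 0.5, 0.4, 0.1])
        got = brier_ipcw(pred, [2, 4, 6, 8.0], [1, 0, 1, 0], horizon=5)
        expected = ((1 - 0.8) ** 2 + 1.5 * 0.4**2 + 1.5 * 0.1**2) / 4
        assert got == pytest.approx(expected, abs=1e-12)

    def test_no_censoring_reduces_to_mean_squared_error(self, rng):
        t = rng.exponential(10, 60)
        pred = rng.uniform(size=60)
        status = (t <= 8).astype(float)
        got = brier_ipcw(pred, t, np.ones(60), horizon=8)
        assert got == pytest.approx(np.mean((status - pred) ** 2))


class TestAUC:
    def test_perfect_and_anti_separation(self):
        t = np.array([1, 2, 20, 30.0])
        e = np.ones(4)
        assert auc_at_horizon([0.9, 0.8, 0.1, 0.2], t, e, horizon=10) == 1.0
        assert auc_at_horizon([0.1, 0.2, 0.9, 0.8], t, e, horizon=10) == 0.0

    def test_no_censoring_equals_rank_sum_auc(self, rng):
        t = rng.exponential(10, 60)
        pred = rng.uniform(size=60)
        status = (t <= 8).astype(int)
        got = auc_at_horizon(pred, t, np.ones(60), horizon=8)
        assert got == pytest.approx(roc_auc_score(status, pred))

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            auc_at_horizon([0.5, 0.5], [20, 30.0], [1, 1], horizon=10)


class TestCalibration:
    def test_exactly_calibrated_bins_give_zero(self):
        # two risk groups whose predictions equal the observed proportions
        t = np.array([1.0] * 1 + [20.0] * 4 + [2.0] * 4 + [25.0] * 1)
        e = np.ones(10)
        pred = np.array([0.2] * 5 + [0.8] * 5)
        stat, _ = nam_dagostino(pred, t, e, horizon=10, n_bins=2)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_computation(self):
        t = np.array([1.0] * 1 + [20.0] * 4 + [2.0] * 4 + [25.0] * 1)
        e = np.ones(10)
        pred = np.array([0.3] * 5 + [0.7] * 5)
        stat, _ = nam_dagostino(pred, t, e, horizon=10, n_bins=2)
        expected = 5 * (0.2 - 0.3) ** 2 / (0.3 * 0.7) + 5 * (0.8 - 0.7) ** 2 / (0.7 * 0.3)
        assert stat == pytest.approx(expected, abs=1e-12)

    def test_statistic_nonnegative_with_ten_bins(self, rng):
        n = 400
        t = rng.exponential(30, n)
        e = rng.integers(0, 2, n)
        pred = rng.uniform(0.05, 0.95, n)
        stat, p = nam_dagostino(pred, t, e, horizon=20)
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_single_cluster_partition_is_chance_level(self, rng):
        a = rng.integers(1, 3, 30)
        assert adjusted_rand_index(a, np.ones(30)) == 0.0

    def test_hand_computed_negative_value(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_symmetry_and_label_permutation_invariance(self, rng):
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        remap = np.vectorize({0: 2, 1: 0, 2: 1}.get)
        assert adjusted_rand_index(remap(a), b) == pytest.approx(
            adjusted_rand_index(a, b)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([], [])
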