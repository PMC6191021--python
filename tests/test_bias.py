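import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbccv import (
    ACCURACY,
    BootstrapPlan,
    FoldPartition,
    PredictionTensor,
    bbc_estimate,
    bbc_repeated,
    percentile_ci,
    tt_estimate,
)
from bbccv.metrics import UndefinedMetricError


def bbc_oracle(values, y, plan):
    """Independent double-loop re-implementation of bootstrap bias
    correction with 0-1 loss: explicit row resampling, per-column mean
    losses, first-index arg-min, out-of-bag scoring."""
    n, c = values.shape
    losses, sels = [], []
    for b in range(plan.n_bootstraps):
        idx = plan.index_matrix[b]
        col_losses = [np.mean(values[idx, j] != y[idx]) for j in range(c)]
        sel = int(np.argmin(col_losses))
        oob = np.setdiff1d(np.arange(n), idx)
        losses.append(float(np.mean(values[oob, sel] != y[oob])))
        sels.append(sel)
    return losses


def bbc_oracle_repeated(values, y, plan):
    """Oracle over an (N, C, R) tensor: a resampled instance carries all
    its per-repeat predictions, pooled for selection and scoring."""
    n, c, r = values.shape
    losses = []
    for b in range(plan.n_bootstraps):
        idx = plan.index_matrix[b]
        y_in = np.tile(y[idx], r)
        col = [
            np.mean(np.concatenate([values[idx, j, t] for t in range(r)]) != y_in)
            for j in range(c)
        ]
        sel = int(np.argmin(col))
        oob = np.setdiff1d(np.arange(n), idx)
        y_out = np.tile(y[oob], r)
        pooled = np.concatenate([values[oob, sel, t] for t in range(r)])
        losses.append(float(np.mean(pooled != y_out)))
    return losses


class TestTT:
    def test_pathological_loo_doubles_the_loss(self, tt_pathology):
        tensor, y = tt_pathology
        res = tt_estimate(tensor, y, metric=ACCURACY)
        assert res.selected == 0
        assert res.cvt_loss == pytest.approx(0.7)
        assert res.tt_bias == pytest.approx(0.7)
        assert res.loss == pytest.approx(1.4)

    def test_zero_bias_when_fold_winners_coincide(self, rng):
        good = rng.integers(0, 2, 20)
        y = good.copy()  # config 0 perfect, best in every fold
        bad = 1 - y
        tensor = PredictionTensor.from_matrix(
            np.column_stack([good, bad]), np.arange(20) % 4
        )
        res = tt_estimate(tensor, y, metric=ACCURACY)
        assert res.tt_bias == 0.0
        assert res.loss == res.cvt_loss

    def test_two_fold_hand_example(self):
        y = np.array([1, 1, 0, 0])
        table = np.array([[1, 1], [0, 1], [0, 1], [0, 0]])
        part = FoldPartition(np.array([0, 0, 1, 1]), 2)
        tensor = PredictionTensor.from_matrix(table, part.assignments)
        res = tt_estimate(tensor, y, part, ACCURACY)
        assert res.selected == 0  # tie at pooled loss 0.25 breaks low
        assert res.tt_bias == pytest.approx(0.25)
        assert res.loss == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(6, 30), st.integers(1, 6), st.integers(2, 5), st.integers(0, 10**6))
    def test_bounds(self, n, c, k, seed):
        """0 <= TTBias <= L_CVT, hence L_CVT <= L_TT <= 2 L_CVT."""
        rng = np.random.default_rng(seed)
        if k > n:
            k = n
        y = rng.integers(0, 2, n)
        tensor = PredictionTensor.from_matrix(
            rng.integers(0, 2, (n, c)), np.arange(n) % k
        )
        res = tt_estimate(tensor, y, metric=ACCURACY)
        assert 0 <= res.tt_bias <= res.cvt_loss + 1e-12
        assert res.cvt_loss - 1e-12 <= res.loss <= 2 * res.cvt_loss + 1e-12


class TestPercentileCI:
    def test_order_statistics_25_975(self):
        losses = np.arange(1, 1001, dtype=float)
        assert percentile_ci(losses, 0.95) == (25.0, 975.0)

    def test_constant_population(self):
        assert percentile_ci([0.3] * 100, 0.9) == (0.3, 0.3)

    def test_one_to_hundred_level_90(self):
        assert percentile_ci(np.arange(1, 101, dtype=float), 0.90) == (5.0, 95.0)

    def test_nesting_across_levels(self, rng):
        losses = rng.uniform(size=500)
        lo90, hi90 = percentile_ci(losses, 0.90)
        lo95, hi95 = percentile_ci(losses, 0.95)
        assert lo95 <= lo90 and hi90 <= hi95

    def test_empty_and_too_small_rejected(self):
        with pytest.raises(ValueError):
            percentile_ci([], 0.95)
        with pytest.raises(ValueError):
            percentile_ci([0.1, 0.2], 0.95)


class TestBBC:
    def test_matches_oracle_bitwise(self, rng):
        values = rng.integers(0, 2, (30, 5))
        y = rng.integers(0, 2, 30)
        plan = BootstrapPlan.create(50, 30, seed=99)
        tensor = PredictionTensor.from_matrix(values, np.arange(30) % 5)
        est = bbc_estimate(tensor, y, ACCURACY, plan)
        oracle = bbc_oracle(values, y, plan)
        assert est.bootstrap_losses.tolist() == oracle
        assert est.loss == np.mean(oracle)

    def test_repeated_matches_oracle(self, rng):
        values = rng.integers(0, 2, (20, 4, 3))
        y = rng.integers(0, 2, 20)
        fold_of = np.stack([np.arange(20) % 4] * 3, axis=1)
        plan = BootstrapPlan.create(40, 20, seed=7)
        tensor = PredictionTensor(values, fold_of)
        est = bbc_repeated(tensor, y, ACCURACY, plan)
        oracle = bbc_oracle_repeated(values, y, plan)
        np.testing.assert_allclose(est.bootstrap_losses, oracle, atol=1e-12)

    def test_duplicated_repeats_equal_single_repeat(self, rng):
        values = rng.integers(0, 2, (15, 3))
        y = rng.integers(0, 2, 15)
        plan = BootstrapPlan.create(60, 15, seed=3)
        single = bbc_estimate(
            PredictionTensor.from_matrix(values, np.arange(15) % 3),
            y, ACCURACY, plan,
        )
        stacked = np.repeat(values[:, :, None], 4, axis=2)
        fold_of = np.stack([np.arange(15) % 3] * 4, axis=1)
        rep = bbc_repeated(PredictionTensor(stacked, fold_of), y, ACCURACY, plan)
        assert rep.loss == pytest.approx(single.loss)

    def test_perfect_predictions_give_zero_loss(self):
        y = np.array([0, 1] * 10)
        values = np.column_stack([y, y, y])
        plan = BootstrapPlan.create(50, 20, seed=0)
        est = bbc_estimate(
            PredictionTensor.from_matrix(values, np.arange(20) % 4),
            y, ACCURACY, plan,
        )
        assert est.loss == 0.0
        assert est.ci == (1.0, 1.0)

    def test_single_configuration_approaches_cvt(self, rng):
        """With C=1 there is no selection, so BBC converges to the plain
        pooled loss as B grows."""
        col = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        cvt_loss = (col != y).mean()
        plan = BootstrapPlan.create(10_000, 60, seed=5)
        est = bbc_estimate(
            PredictionTensor.from_matrix(col[:, None], np.arange(60) % 10),
            y, ACCURACY, plan,
        )
        mc_se = np.std(est.bootstrap_losses) / np.sqrt(plan.n_bootstraps)
        assert abs(est.loss - cvt_loss) < max(4 * mc_se, 5e-3)

    def test_permutation_equivariance_on_tie_free_input(self, rng):
        """Permuting configuration columns permutes selections but leaves
        the bootstrap loss population unchanged when no ties occur."""
        y = rng.integers(0, 2, 21)
        # distinct column losses: flip a growing number of labels
        values = np.column_stack([y] * 4)
        for j in range(4):
            values[: 3 * j + 1, j] = 1 - values[: 3 * j + 1, j]
        plan = BootstrapPlan.create(60, 21, seed=11)
        base = bbc_estimate(
            PredictionTensor.from_matrix(values, np.arange(21) % 3),
            y, ACCURACY, plan,
        )
        perm = [2, 0, 3, 1]
        permuted = bbc_estimate(
            PredictionTensor.from_matrix(values[:, perm], np.arange(21) % 3),
            y, ACCURACY, plan,
        )
        np.testing.assert_array_equal(
            base.bootstrap_losses, permuted.bootstrap_losses
        )

    def test_plan_size_mismatch_rejected(self, rng):
        plan = BootstrapPlan.create(10, 8, seed=0)
        tensor = PredictionTensor.from_matrix(
            rng.integers(0, 2, (9, 2)), np.arange(9) % 3
        )
        with pytest.raises(ValueError, match="different sample count"):
            bbc_estimate(tensor, rng.integers(0, 2, 9), ACCURACY, plan)


class TestJensenOptimism:
    """Selecting the empirical best of noisy estimates is optimistic."""

    @pytest.mark.parametrize("p", [(0.5, 0.5), (0.6, 0.7), (0.9, 0.3)])
    def test_exhaustive_two_configuration_tables(self, p):
        from itertools import product
        from bbccv import cvt_from_predictions

        n = 5
        expected_bias = 0.0
        for table in product([0, 1], repeat=2 * n):
            pi = np.array(table).reshape(n, 2)
            prob = 1.0
            for j in range(2):
                correct = pi[:, j].sum()
                prob *= p[j] ** correct * (1 - p[j]) ** (n - correct)
            tensor = PredictionTensor.from_matrix(pi, np.arange(n))
            est = cvt_from_predictions(tensor, np.ones(n, dtype=int), ACCURACY)
            expected_bias += prob * (est.point - p[est.selected])
        assert expected_bias >= -1e-12


def test_tt_rejects_single_class_fold_for_auc(rng):
    from bbccv import AUC

    y = np.array([1, 1, 0, 0, 1, 0])
    scores = rng.uniform(size=(6, 2))
    part = FoldPartition(np.array([0, 0, 1, 1, 2, 2]), 3)
    tensor = PredictionTensor.from_matrix(scores, part.assignments)
    with pytest.raises(UndefinedMetricError, match="per-fold"):
        tt_estimate(tensor, y, part, AUC)
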