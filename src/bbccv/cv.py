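"""Cross-validation engines: plain CV with tuning (CVT) and nested CV.

CVT cross-validates every configuration on a shared fold partition,
pools the out-of-sample predictions into a :class:`PredictionTensor`,
selects the arg-min-loss configuration and trains it on all rows:
``K*C + 1`` training calls.  The pooled estimate of the winner is
optimistically biased — that is what :mod:`bbccv.bias` corrects.

Nested CV treats the whole tuning procedure as the learning method and
cross-validates it: ``K^2*C + K + 1`` training calls when the inner loop
reuses the outer folds (the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any, Callable, Optional, Sequence

import numpy as np
from sklearn.base import clone

from .containers import FoldPartition, PerformanceEstimate, PredictionTensor
from .metrics import Metric, UndefinedMetricError, css, pooled_column_losses, set_loss


class Learner:
    """Adapter around a pair of train/predict callables.

    ``train(X, y, config) -> model`` must never see held-out rows;
    ``predict(model, X) -> predictions``.  Training invocations are
    counted, which the test-suite uses to verify the model-count
    identities of each protocol.
    """

    def __init__(self, train: Callable, predict: Callable):
        self._train = train
        self._predict = predict
        self.n_train_calls = 0

    def fit(self, X, y, config) -> Any:
        self.n_train_calls += 1
        return self._train(X, y, config)

    def predict(self, model, X):
        return self._predict(model, X)


class SklearnLearner(Learner):
    """Learner over scikit-learn estimators.

    ``build(config)`` returns an unfitted estimator; predictions use
    ``predict`` by default or ``predict_proba`` scores of the positive
    class when ``scores=True`` (for AUC-type metrics).
    """

    def __init__(self, build: Callable, scores: bool = False):
        def train(X, y, config):
            est = clone(build(config))
            return est.fit(X, y)

        def predict(model, X):
            if scores:
                return model.predict_proba(X)[:, -1]
            return model.predict(X)

        super().__init__(train, predict)


def _take(X, idx):
    if hasattr(X, "iloc"):
        return X.iloc[idx]
    return np.asarray(X)[idx]


@dataclass
class CVTResult:
    """Outcome of cross-validation with tuning."""

    model: Any
    estimate: PerformanceEstimate
    tensor: PredictionTensor
    partition: FoldPartition

    @property
    def selected(self) -> int:
        return self.estimate.selected


def cvt(
    learner: Learner,
    X,
    y,
    partition: FoldPartition,
    configs: Sequence,
    metric: Metric,
) -> CVTResult:
    """Cross-validation with tuning (the uncorrected protocol).

    Every configuration is trained on each fold complement and predicts
    the held-out fold; the configuration minimising the pooled loss is
    selected and retrained on all rows.  The returned estimate is the
    selected column's pooled loss — optimistic whenever ``C > 1``.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if partition.n_samples != n:
        raise ValueError("partition does not cover the dataset rows")
    n_configs = len(configs)
    if n_configs < 1:
        raise ValueError("need at least one configuration")
    pi = np.empty((n, n_configs), dtype=object)
    for k in range(partition.n_folds):
        test_idx = partition.indices(k)
        train_idx = np.nonzero(partition.assignments != k)[0]
        for j, theta in enumerate(configs):
            try:
                model = learner.fit(_take(X, train_idx), y[train_idx], theta)
                preds = np.asarray(learner.predict(model, _take(X, test_idx)))
            except Exception as exc:
                raise RuntimeError(
                    f"learner failed on fold {k}, configuration index {j}"
                ) from exc
            for t, i in enumerate(test_idx):
                pi[i, j] = preds[t]
    values = np.array(pi.tolist())
    tensor = PredictionTensor.from_matrix(values, partition.assignments)
    selected = css(values, y, metric)
    loss = float(pooled_column_losses(values, y, metric)[selected])
    final_model = learner.fit(X, y, configs[selected])
    estimate = PerformanceEstimate("CVT", metric, loss, selected)
    return CVTResult(final_model, estimate, tensor, partition)


def _inner_partition(outer: FoldPartition, held_out: int) -> FoldPartition:
    """Regroup the outer folds other than ``held_out`` as inner folds."""
    keep = outer.assignments != held_out
    inner = outer.assignments[keep].copy()
    remaining = np.setdiff1d(np.unique(outer.assignments), [held_out])
    relabel = {old: new for new, old in enumerate(remaining)}
    inner = np.array([relabel[f] for f in inner])
    return FoldPartition(inner, len(remaining))


@dataclass
class NCVResult:
    model: Any
    estimate: PerformanceEstimate
    inner: CVTResult  # the all-data CVT that produced the final model

    @property
    def selected(self) -> int:
        return self.inner.selected


def ncv(
    learner: Learner,
    X,
    y,
    partition: FoldPartition,
    configs: Sequence,
    metric: Metric,
) -> NCVResult:
    """Nested cross-validation.

    Each outer fold is held out while CVT runs on the rest (inner folds
    are the remaining outer folds regrouped, so the inner loop has
    ``K - 1`` folds); the single model CVT returns is scored on the
    held-out fold and fold losses are averaged.  The final model and
    selected configuration come from CVT on all data, so NCV returns the
    same model as CVT, with an (almost) unbiased estimate.
    """
    y = np.asarray(y)
    fold_losses = []
    for k in range(partition.n_folds):
        test_idx = partition.indices(k)
        train_idx = np.nonzero(partition.assignments != k)[0]
        res = cvt(
            learner,
            _take(X, train_idx),
            y[train_idx],
            _inner_partition(partition, k),
            configs,
            metric,
        )
        preds = learner.predict(res.model, _take(X, test_idx))
        try:
            fold_losses.append(set_loss(y[test_idx], preds, metric))
        except UndefinedMetricError:
            warnings.warn(
                f"outer fold {k} is single-class; dropped from the NCV average",
                stacklevel=2,
            )
    if not fold_losses:
        raise UndefinedMetricError("no outer fold admits the metric")
    final = cvt(learner, X, y, partition, configs, metric)
    estimate = PerformanceEstimate(
        "NCV", metric, float(np.mean(fold_losses)), final.selected
    )
    return NCVResult(final.model, estimate, final)


def cvt_from_predictions(
    tensor: PredictionTensor, y, metric: Metric
) -> PerformanceEstimate:
    """The uncorrected CVT estimate from a recorded prediction tensor:
    select the pooled-loss winner and report its pooled loss."""
    y = np.asarray(y)
    selected = css(tensor.values, y, metric, tensor.missing_mask)
    loss = float(
        pooled_column_losses(tensor.values, y, metric, tensor.missing_mask)[selected]
    )
    return PerformanceEstimate("CVT", metric, loss, selected)


def ncv_from_predictions(
    tensor: PredictionTensor,
    y,
    partition: Optional[FoldPartition] = None,
    metric: Metric = None,
) -> PerformanceEstimate:
    """Nested CV replayed on a recorded prediction matrix.

    For each outer fold, the best configuration is selected from the
    pooled losses over the *other* folds' predictions and scored on the
    held-out fold; fold losses are averaged.  Equivalent to :func:`ncv`
    when the learner replays recorded predictions, at zero training
    cost — this is how the simulation study evaluates NCV.
    """
    if tensor.n_repeats != 1:
        raise ValueError("ncv_from_predictions expects a single repeat")
    if not tensor.is_complete:
        raise ValueError("prediction tensor must be complete")
    if partition is None:
        partition = tensor.partition()
    y = np.asarray(y)
    values = tensor.matrix()
    fold_losses = []
    for k in range(partition.n_folds):
        held = partition.assignments == k
        sel = css(values[~held], y[~held], metric)
        try:
            fold_losses.append(set_loss(y[held], values[held, sel], metric))
        except UndefinedMetricError:
            warnings.warn(
                f"outer fold {k} is single-class; dropped from the NCV average",
                stacklevel=2,
            )
    if not fold_losses:
        raise UndefinedMetricError("no outer fold admits the metric")
    selected = css(values, y, metric)
    return PerformanceEstimate("NCV", metric, float(np.mean(fold_losses)), selected)
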