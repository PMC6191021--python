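"""Early dropping of inferior configurations during cross-validation.

After each completed fold, the pooled out-of-sample predictions so far
are bootstrapped; a configuration whose in-bag loss strictly exceeds the
current best configuration's in a fraction of draws above the threshold
``alpha`` is dropped and never trained again on later folds.  Ties do
not count against a configuration, so an exact duplicate of the current
best is always retained.

The driver :func:`bbcd_cv` combines dropping with a final BBC estimate
over the surviving configurations; :func:`bbcd_from_predictions`
replays the same schedule on a recorded prediction matrix, which is how
the simulation harness evaluates the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, List, Optional, Sequence, Tuple

import numpy as np

from .bootstrap import BootstrapPlan
from .containers import FoldPartition, PerformanceEstimate, PredictionTensor
from .cv import Learner, _take
from .bias import bbc_estimate, samplewise_loss_matrix
from .folds import as_rng
from .metrics import SAMPLEWISE, Metric, UndefinedMetricError, css, set_loss


@dataclass
class DroppingState:
    """Mutable record of which configurations are still in the race.

    Once a configuration is inactive it never reactivates; the current
    best configuration is always active.  ``drop_log`` accumulates
    ``(fold, configuration_index, p_hat)`` triples.
    """

    active: np.ndarray
    p_hat: np.ndarray
    alpha: float = 0.99
    min_predictions: int = 50
    folds_completed: int = 0
    drop_log: List[Tuple[int, int, float]] = field(default_factory=list)

    @classmethod
    def init(
        cls, n_configurations: int, alpha: float = 0.99, min_predictions: int = 50
    ) -> "DroppingState":
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        return cls(
            active=np.ones(n_configurations, dtype=bool),
            p_hat=np.zeros(n_configurations),
            alpha=alpha,
            min_predictions=min_predictions,
        )

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _bootstrap_inbag_losses(values, y, metric, w):
    """In-bag pooled losses, ``(B, C)``, for multiplicity matrix ``w``."""
    n = values.shape[0]
    if metric.kind == SAMPLEWISE:
        losses = metric.samplewise_loss(
            np.broadcast_to(np.asarray(y)[:, None], values.shape), values
        )
        return (w @ losses) / n
    out = np.empty((w.shape[0], values.shape[1]))
    for b in range(w.shape[0]):
        idx = np.repeat(np.arange(n), w[b].astype(int))
        for j in range(values.shape[1]):
            try:
                out[b, j] = set_loss(np.asarray(y)[idx], values[idx, j], metric)
            except UndefinedMetricError:
                out[b, j] = np.nan
        if np.isnan(out[b]).any():
            out[b] = np.nan  # degenerate draw: ignore whole row
    return out


def drop_test(
    values,
    y,
    state: DroppingState,
    metric: Metric,
    plan: Optional[BootstrapPlan] = None,
    rng=None,
    n_bootstraps: int = 1000,
) -> DroppingState:
    """One round of the bootstrap dropping test; mutates and returns ``state``.

    ``values`` holds the pooled out-of-sample predictions accrued so
    far: one row per sample with predictions, one column per
    configuration (inactive columns are ignored).  For each active
    configuration other than the current best, ``p_hat`` is the fraction
    of bootstrap draws in which its in-bag loss strictly exceeds the
    best's; configurations with ``p_hat > alpha`` are deactivated.
    """
    values = np.asarray(values)
    y = np.asarray(y)
    n = values.shape[0]
    state.folds_completed += 1
    if state.n_active < 2 or n < max(state.min_predictions, 2):
        return state
    idx = np.nonzero(state.active)[0]
    sub = values[:, idx]
    if sub.dtype == object:  # inactive columns may hold unfilled entries
        sub = np.array(sub.tolist())
    best = css(sub, y, metric)
    if plan is not None:
        if plan.n_samples != n:
            raise ValueError("plan drawn for a different number of rows")
        w = plan.multiplicities()
    else:
        rng = as_rng(rng)
        w = rng.multinomial(n, np.full(n, 1.0 / n), size=n_bootstraps).astype(float)
    inbag = _bootstrap_inbag_losses(sub, y, metric, w)
    valid = ~np.isnan(inbag[:, 0])
    if not valid.any():
        return state
    p = (inbag[valid] > inbag[valid][:, [best]]).mean(axis=0)
    p[best] = 0.0
    state.p_hat[idx] = p
    for local_j in np.nonzero(p > state.alpha)[0]:
        j = int(idx[local_j])
        state.active[j] = False
        state.drop_log.append((state.folds_completed, j, float(p[local_j])))
    return state


@dataclass
class BBCDResult:
    model: Any
    estimate: PerformanceEstimate
    state: DroppingState
    tensor: PredictionTensor  # ragged: dropped configurations stop at their fold

    @property
    def selected(self) -> int:
        return self.estimate.selected


def _final_bbc(values, y, partition, metric, state, plan, ci_level):
    """Select among survivors and bias-correct their complete columns."""
    idx = np.nonzero(state.active)[0]
    sub_values = values[:, idx]
    if sub_values.dtype == object:  # survivors' columns are fully observed
        sub_values = np.array(sub_values.tolist())
    sub = PredictionTensor.from_matrix(sub_values, partition.assignments)
    est = bbc_estimate(sub, y, metric, plan, ci_level)
    est.method = "BBCD"
    est.selected = int(idx[est.selected])
    return est


def bbcd_cv(
    learner: Learner,
    X,
    y,
    partition: FoldPartition,
    configs: Sequence,
    metric: Metric,
    alpha_drop: float = 0.99,
    min_predictions: int = 50,
    plan: Optional[BootstrapPlan] = None,
    n_bootstraps: int = 1000,
    seed=None,
    ci_level: Optional[float] = 0.95,
) -> BBCDResult:
    """Cross-validation with tuning, early dropping and BBC estimation.

    Folds are visited in order; only active configurations are trained,
    so at most ``K*C + 1`` models are fitted, with equality exactly when
    nothing is dropped (``alpha_drop=1`` disables dropping and makes the
    run identical to CVT followed by BBC with the same plan).  Dropping
    starts once at least ``min_predictions`` pooled out-of-sample
    predictions are available.
    """
    y = np.asarray(y)
    n, n_configs = y.shape[0], len(configs)
    rng = as_rng(seed)
    drop_b = plan.n_bootstraps if plan is not None else n_bootstraps
    state = DroppingState.init(n_configs, alpha_drop, min_predictions)
    values = np.empty((n, n_configs), dtype=object)
    missing = np.ones((n, n_configs), dtype=bool)
    for k in range(partition.n_folds):
        test_idx = partition.indices(k)
        train_idx = np.nonzero(partition.assignments != k)[0]
        for j in np.nonzero(state.active)[0]:
            try:
                model = learner.fit(_take(X, train_idx), y[train_idx], configs[j])
                preds = np.asarray(learner.predict(model, _take(X, test_idx)))
            except Exception as exc:
                raise RuntimeError(
                    f"learner failed on fold {k}, configuration index {j}"
                ) from exc
            for t, i in enumerate(test_idx):
                values[i, j] = preds[t]
                missing[i, j] = False
        rows = np.nonzero(partition.assignments <= k)[0]
        drop_test(
            values[rows],
            y[rows],
            state,
            metric,
            rng=rng,
            n_bootstraps=drop_b,
        )
    if plan is None:
        plan = BootstrapPlan.create(n_bootstraps, n, rng)
    estimate = _final_bbc(values, y, partition, metric, state, plan, ci_level)
    final_model = learner.fit(X, y, configs[estimate.selected])
    tensor = PredictionTensor.from_matrix(
        np.where(missing, 0, values), partition.assignments, missing_mask=missing
    )
    return BBCDResult(final_model, estimate, state, tensor)


def bbcd_from_predictions(
    tensor: PredictionTensor,
    y,
    partition: Optional[FoldPartition] = None,
    metric: Metric = None,
    alpha_drop: float = 0.99,
    min_predictions: int = 0,
    n_bootstraps: int = 1000,
    seed=None,
    ci_level: Optional[float] = 0.95,
) -> Tuple[PerformanceEstimate, DroppingState]:
    """Replay the dropping schedule on a recorded prediction matrix.

    Folds are revealed in id order; after each reveal the drop test runs
    on the rows seen so far (restricted to configurations still active).
    The returned estimate is the BBC estimate over the survivors.
    """
    if tensor.n_repeats != 1:
        raise ValueError("dropping replay expects a single repeat")
    if not tensor.is_complete:
        raise ValueError("prediction tensor must be complete")
    if partition is None:
        partition = tensor.partition()
    y = np.asarray(y)
    values = tensor.matrix()
    rng = as_rng(seed)
    state = DroppingState.init(tensor.n_configurations, alpha_drop, min_predictions)
    for k in range(partition.n_folds):
        rows = np.nonzero(partition.assignments <= k)[0]
        drop_test(
            values[rows], y[rows], state, metric, rng=rng, n_bootstraps=n_bootstraps
        )
    plan = BootstrapPlan.create(n_bootstraps, tensor.n_samples, rng)
    estimate = _final_bbc(values, y, partition, metric, state, plan, ci_level)
    return estimate, state
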