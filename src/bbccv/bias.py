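"""Bias-corrected performance estimates from pooled out-of-sample predictions.

Two corrections of the optimistic CVT estimate are implemented, neither
of which trains any additional model:

* the Tibshirani–Tibshirani (TT) correction, which treats each fold as
  an independent replicate of the selection process and adds the average
  per-fold selection optimism back onto the CVT loss, and
* bootstrap bias correction (BBC), which resamples the *rows* of the
  prediction matrix, re-runs the configuration selection on each in-bag
  draw and scores the in-bag winner on its out-of-bag rows.

The mean of the B out-of-bag losses is the BBC point estimate; the same
bootstrap population yields percentile confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, floor
from typing import Optional, Tuple

import numpy as np

from .bootstrap import BootstrapPlan
from .containers import FoldPartition, PerformanceEstimate, PredictionTensor
from .folds import as_rng
from .metrics import (
    SAMPLEWISE,
    Metric,
    UndefinedMetricError,
    css,
    set_loss,
)


def samplewise_loss_matrix(tensor: PredictionTensor, y, metric: Metric) -> np.ndarray:
    """Per-sample losses, ``(N, C)``, averaged over repeats.

    Missing entries are excluded from the repeat average; a sample with
    no observed prediction for a configuration yields NaN there.
    """
    if metric.kind != SAMPLEWISE:
        raise ValueError("loss matrix only defined for samplewise metrics")
    v = tensor.values
    y = np.asarray(y)
    losses = metric.samplewise_loss(np.broadcast_to(y[:, None, None], v.shape), v)
    losses = np.where(tensor.missing_mask, np.nan, losses)
    with np.errstate(invalid="ignore"):
        return np.nanmean(losses, axis=2)


# ---------------------------------------------------------------------------
# TT correction


@dataclass
class TTResult:
    """TT-corrected estimate: ``L_TT = L_CVT + TTBias``.

    ``tt_bias`` is the average, over folds, of the selected
    configuration's fold loss minus the best fold loss, so
    ``0 <= tt_bias <= cvt_loss`` and ``cvt_loss <= loss <= 2*cvt_loss``.
    """

    tt_bias: float
    cvt_loss: float
    estimate: PerformanceEstimate

    @property
    def loss(self) -> float:
        return self.estimate.loss

    @property
    def selected(self) -> int:
        return self.estimate.selected


def tt_estimate(
    tensor: PredictionTensor,
    y,
    partition: Optional[FoldPartition] = None,
    metric: Metric = None,
) -> TTResult:
    """The fold-wise selection-bias correction.

    Requires the metric to be computable inside every fold; with a
    setwise metric and small or single-class folds this fails, which is
    the method's documented weakness.
    """
    if tensor.n_repeats != 1:
        raise ValueError("tt_estimate expects a single repeat")
    if not tensor.is_complete:
        raise ValueError("prediction tensor must be complete")
    if partition is None:
        partition = tensor.partition()
    y = np.asarray(y)
    values = tensor.matrix()
    selected = css(values, y, metric)
    sel_losses = np.empty(partition.n_folds)
    min_losses = np.empty(partition.n_folds)
    for k in range(partition.n_folds):
        rows = partition.indices(k)
        try:
            sel_losses[k] = set_loss(y[rows], values[rows, selected], metric)
            min_losses[k] = min(
                set_loss(y[rows], values[rows, j], metric)
                for j in range(tensor.n_configurations)
            )
        except UndefinedMetricError as exc:
            raise UndefinedMetricError(
                f"{metric.name} is undefined inside fold {k}; the TT "
                "correction needs per-fold metric values — use larger "
                "stratified folds or a samplewise metric"
            ) from exc
    cvt_loss = float(sel_losses.mean())
    tt_bias = float((sel_losses - min_losses).mean())
    est = PerformanceEstimate("TT", metric, cvt_loss + tt_bias, selected)
    return TTResult(tt_bias, cvt_loss, est)


# ---------------------------------------------------------------------------
# Percentile confidence intervals


def percentile_ci(bootstrap_losses, level: float = 0.95) -> Tuple[float, float]:
    """Percentile interval on the ascending bootstrap order statistics.

    Returns ``[L_(ceil(a/2*B)), L_(floor((1-a/2)*B))]`` with
    ``a = 1 - level`` — for B=1000 at the 95% level, the 25th and 975th
    order statistics.
    """
    losses = np.sort(np.asarray(bootstrap_losses, dtype=float))
    n = losses.shape[0]
    if n == 0:
        raise ValueError("empty bootstrap population")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    if n < 2.0 / alpha:
        raise ValueError(
            f"B={n} too small for level {level}: need B >= {ceil(2 / alpha)}"
        )
    eps = 1e-9  # guard against float noise in alpha/2 * B
    lo = max(ceil(alpha / 2.0 * n - eps), 1)
    hi = min(floor((1.0 - alpha / 2.0) * n + eps), n)
    return float(losses[lo - 1]), float(losses[hi - 1])


# ---------------------------------------------------------------------------
# BBC


def _bbc_losses_samplewise(loss_matrix: np.ndarray, plan: BootstrapPlan):
    """Bootstrap out-of-bag losses for a complete samplewise loss matrix.

    Weighted in-bag column means reproduce explicit resampling exactly
    (sums of per-sample losses with integer multiplicities).
    """
    n = loss_matrix.shape[0]
    w = plan.multiplicities()
    inbag = (w @ loss_matrix) / n
    sel = np.argmin(inbag, axis=1)
    m = plan.oob_mask().astype(float)
    oob_sums = m @ loss_matrix
    counts = m.sum(axis=1)
    losses = oob_sums[np.arange(plan.n_bootstraps), sel] / counts
    return losses, sel


def _bbc_losses_samplewise_ragged(
    loss_matrix: np.ndarray, plan: BootstrapPlan, max_redraw: int = 100
):
    """As above with NaN (missing) entries excluded per bootstrap draw.

    Draws where the in-bag winner has no out-of-bag support are redrawn
    up to ``max_redraw`` times, then skipped with a warning.
    """
    n = loss_matrix.shape[0]
    avail = (~np.isnan(loss_matrix)).astype(float)
    filled = np.where(np.isnan(loss_matrix), 0.0, loss_matrix)
    w = plan.multiplicities()
    redraw_rng = as_rng(None if plan.seed is None else plan.seed + 1_000_003)

    def evaluate(w_rows):
        num = w_rows @ filled
        den = w_rows @ avail
        with np.errstate(invalid="ignore", divide="ignore"):
            inbag = num / den
        inbag[den == 0] = np.inf  # no in-bag support: never selected
        sel = np.argmin(inbag, axis=1)
        m = (w_rows == 0).astype(float)
        onum = m @ filled
        oden = m @ avail
        b = np.arange(w_rows.shape[0])
        return onum[b, sel] / np.where(oden[b, sel] > 0, oden[b, sel], np.nan), sel

    losses, sel = evaluate(w)
    skipped = 0
    bad = np.isnan(losses)
    for b in np.nonzero(bad)[0]:
        ok = False
        for _ in range(max_redraw):
            row = np.zeros((1, n))
            np.add.at(row, (0, redraw_rng.integers(0, n, size=n)), 1.0)
            if not (row == 0).any():
                continue
            l_b, s_b = evaluate(row)
            if not np.isnan(l_b[0]):
                losses[b], sel[b] = l_b[0], s_b[0]
                ok = True
                break
        if not ok:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap draw(s)", stacklevel=3)
    return losses[~np.isnan(losses)], sel


def _bbc_losses_setwise(
    tensor: PredictionTensor, y, metric: Metric, plan: BootstrapPlan, max_redraw=100
):
    """Loop implementation for setwise metrics (AUC), pooling repeats.

    In-bag or out-of-bag sets on which the metric is undefined
    (single-class) trigger a redraw of that bootstrap row.
    """
    y = np.asarray(y)
    n, c, r = tensor.values.shape
    if tensor.missing_mask.any():
        raise ValueError("setwise BBC requires a complete tensor")
    redraw_rng = as_rng(None if plan.seed is None else plan.seed + 1_000_003)
    all_idx = np.arange(n)
    losses, sels = [], []
    skipped = 0
    for b in range(plan.n_bootstraps):
        idx = plan.index_matrix[b]
        for _ in range(max_redraw):
            oob = np.setdiff1d(all_idx, idx)
            if (
                np.unique(y[idx]).size == 2
                and oob.size >= 2
                and np.unique(y[oob]).size == 2
            ):
                break
            idx = redraw_rng.integers(0, n, size=n)
        else:
            skipped += 1
            continue
        y_in = np.repeat(y[idx], r)
        col_losses = [
            set_loss(y_in, tensor.values[idx, j, :].ravel(), metric) for j in range(c)
        ]
        sel = int(np.argmin(col_losses))
        y_out = np.repeat(y[oob], r)
        losses.append(set_loss(y_out, tensor.values[oob, sel, :].ravel(), metric))
        sels.append(sel)
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap draw(s)", stacklevel=3)
    if not losses:
        raise UndefinedMetricError("every bootstrap draw was degenerate")
    return np.asarray(losses), np.asarray(sels)


def _finish(method, metric, losses, selected, plan, ci_level):
    est = PerformanceEstimate(
        method,
        metric,
        float(np.mean(losses)),
        int(selected),
        ci_loss=percentile_ci(losses, ci_level) if ci_level else None,
        ci_level=ci_level,
        n_bootstraps=plan.n_bootstraps,
        seed=plan.seed,
        bootstrap_losses=losses,
    )
    return est


def bbc_estimate(
    tensor: PredictionTensor,
    y,
    metric: Metric,
    plan: BootstrapPlan,
    ci_level: Optional[float] = 0.95,
) -> PerformanceEstimate:
    """Bootstrap bias-corrected estimate from a single-repeat tensor.

    For each bootstrap draw the configuration selection runs on the
    in-bag rows and the winner is scored on the out-of-bag rows; the
    mean of the B out-of-bag losses is the point estimate.  No models
    are trained.  ``selected`` on the returned estimate is the css
    winner on the full (non-bootstrapped) tensor — the configuration of
    the deployed model.
    """
    if isinstance(tensor, np.ndarray):
        raise TypeError("pass a PredictionTensor (use PredictionTensor.from_matrix)")
    if tensor.n_repeats != 1:
        raise ValueError("use bbc_repeated for multi-repeat tensors")
    return bbc_repeated(tensor, y, metric, plan, ci_level)


def bbc_repeated(
    tensor: PredictionTensor,
    y,
    metric: Metric,
    plan: BootstrapPlan,
    ci_level: Optional[float] = 0.95,
) -> PerformanceEstimate:
    """BBC over a multi-repeat tensor (reduces to plain BBC at R=1).

    Resampling operates on *instance* indexes: a resampled sample
    carries all its R per-repeat predictions, which are pooled both for
    in-bag selection and out-of-bag scoring (per-sample losses averaged
    over repeats for samplewise metrics).
    """
    y = np.asarray(y)
    if plan.n_samples != tensor.n_samples:
        raise ValueError("bootstrap plan drawn for a different sample count")
    if metric.kind == SAMPLEWISE:
        lm = samplewise_loss_matrix(tensor, y, metric)
        if np.isnan(lm).any():
            losses, _ = _bbc_losses_samplewise_ragged(lm, plan)
        else:
            losses, _ = _bbc_losses_samplewise(lm, plan)
    else:
        losses, _ = _bbc_losses_setwise(tensor, y, metric, plan)
    selected = css(tensor.values, y, metric, tensor.missing_mask)
    return _finish("BBC", metric, losses, selected, plan, ci_level)
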