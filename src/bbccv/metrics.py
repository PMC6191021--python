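"""Performance metrics and the configuration selection strategy.

All internal computation is done in *loss* orientation (lower is better).
Higher-is-better metrics such as classification accuracy and AUC are
complemented on the way in (0-1 loss, 1 - AUC) and converted back for
reporting.  Metrics come in two kinds:

``samplewise``
    the loss decomposes into a per-prediction term ``l(y_j, yhat_j)``
    (0-1 loss, squared error, ...); set losses are means of sample losses.
``setwise``
    the loss is only defined on a *set* of at least two predictions that
    contains both classes (AUC and friends).  Callers decide what to do
    when a subset is degenerate; we raise :class:`UndefinedMetricError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from sklearn.metrics import roc_auc_score

SAMPLEWISE = "samplewise"
SETWISE = "setwise"


class UndefinedMetricError(ValueError):
    """A setwise metric was evaluated on a set where it is not defined."""


@dataclass(frozen=True)
class Metric:
    """A loss/performance definition.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"accuracy"``.
    kind : {"samplewise", "setwise"}
        Whether the loss decomposes per prediction.
    higher_is_better : bool
        If True, the native direction is performance and internal losses
        are complements (``native = 1 - loss``).
    mode : {"pooled", "per_fold"}
        Preferred aggregation across folds.  Pooled metrics are computed
        on all out-of-sample predictions at once; per-fold metrics are
        computed within each fold and averaged.
    samplewise_loss : callable, optional
        Vectorised ``(y, yhat) -> losses`` for samplewise metrics.
    setwise_loss : callable, optional
        ``(y, scores) -> scalar loss`` for setwise metrics.
    """

    name: str
    kind: str
    higher_is_better: bool
    mode: str = "pooled"
    samplewise_loss: Optional[Callable] = None
    setwise_loss: Optional[Callable] = None

    def to_native(self, loss: float) -> float:
        """Convert an internal loss to the metric's reporting direction."""
        return 1.0 - loss if self.higher_is_better else loss

    def from_native(self, value: float) -> float:
        return 1.0 - value if self.higher_is_better else value


def _zero_one(y, yhat):
    return (np.asarray(y) != np.asarray(yhat)).astype(float)


def _auc_loss(y, scores):
    return 1.0 - roc_auc_score(np.asarray(y), np.asarray(scores, dtype=float))


ACCURACY = Metric("accuracy", SAMPLEWISE, True, "pooled", samplewise_loss=_zero_one)
AUC = Metric("auc", SETWISE, True, "pooled", setwise_loss=_auc_loss)

_REGISTRY = {"accuracy": ACCURACY, "auc": AUC}


def register_metric(metric: Metric) -> None:
    """Register a user-defined metric under ``metric.name``."""
    _REGISTRY[metric.name] = metric


def get_metric(name: str) -> Metric:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown metric {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def samplewise_losses(y, yhat, metric: Metric) -> np.ndarray:
    """Per-prediction losses ``l(y_j, yhat_j)``.

    Only defined for samplewise metrics; for 0-1 loss each element is 0
    or 1.
    """
    if metric.kind != SAMPLEWISE:
        raise ValueError(
            f"metric {metric.name!r} is {metric.kind}; samplewise losses undefined"
        )
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape[0] != yhat.shape[0]:
        raise ValueError(f"length mismatch: {y.shape[0]} labels, {yhat.shape[0]} predictions")
    return metric.samplewise_loss(y, yhat)


def set_loss(y, yhat, metric: Metric) -> float:
    """Loss of a set of predictions, in loss orientation.

    Samplewise metrics return the mean of :func:`samplewise_losses`.
    Setwise metrics require at least two predictions spanning both
    classes and raise :class:`UndefinedMetricError` otherwise.
    """
    y = np.asarray(y)
    if metric.kind == SAMPLEWISE:
        return float(np.mean(samplewise_losses(y, yhat, metric)))
    if y.shape[0] < 2 or np.unique(y).size < 2:
        raise UndefinedMetricError(
            f"{metric.name} needs >= 2 predictions from both classes "
            f"(got {y.shape[0]} labels, {np.unique(y).size} class(es))"
        )
    return float(metric.setwise_loss(y, yhat))


def pooled_column_losses(values, y, metric: Metric, missing_mask=None) -> np.ndarray:
    """Pooled loss of every configuration column.

    ``values`` is an ``(N, C)`` prediction matrix or an ``(N, C, R)``
    tensor; repeats are pooled.  Missing entries (``missing_mask`` True)
    are excluded.  A column with no observed prediction yields NaN.
    """
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, None]
    if missing_mask is None:
        missing = np.zeros(values.shape, dtype=bool)
    else:
        missing = np.asarray(missing_mask, dtype=bool)
        if missing.ndim == 2:
            missing = missing[:, :, None]
    y = np.asarray(y)
    n, c, r = values.shape
    out = np.empty(c)
    if metric.kind == SAMPLEWISE:
        # broadcast labels across configurations and repeats
        losses = metric.samplewise_loss(
            np.broadcast_to(y[:, None, None], values.shape), values
        )
        losses = np.where(missing, np.nan, losses)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(losses, axis=(0, 2))
        return out
    for j in range(c):
        obs = ~missing[:, j, :]
        if not obs.any():
            out[j] = np.nan
            continue
        rows, reps = np.nonzero(obs)
        out[j] = set_loss(y[rows], values[rows, j, reps], metric)
    return out


def css(values, y, metric: Metric, missing_mask=None) -> int:
    """Configuration selection strategy: arg-min pooled loss.

    Ties break to the smallest configuration index.  Raises on an empty
    tensor or on a column with no observed predictions.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("cannot select a configuration from an empty tensor")
    losses = pooled_column_losses(values, y, metric, missing_mask)
    if np.isnan(losses).any():
        raise ValueError("a configuration column has no observed predictions")
    return int(np.argmin(losses))
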