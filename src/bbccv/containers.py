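"""In-memory containers shared by all estimation protocols.

The central object is :class:`PredictionTensor`, the pooled out-of-sample
prediction array Pi: entry ``(i, j, k)`` is configuration ``j``'s
prediction on sample ``i`` in repeat ``k``, always produced by a model
that did not train on sample ``i``.  Fold ids are 0-based internally;
the on-disk table format uses 1-based ids (see :mod:`bbccv.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .metrics import Metric


@dataclass(frozen=True)
class FoldPartition:
    """A partition of sample indexes 0..N-1 into K disjoint folds.

    ``assignments[i]`` is the fold id of sample ``i``, in ``0..K-1``.
    Fold sizes differ by at most one when built by the constructors in
    :mod:`bbccv.folds`.
    """

    assignments: np.ndarray
    n_folds: int

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        present = np.unique(a)
        if present.size and (present.min() < 0 or present.max() >= self.n_folds):
            raise ValueError("fold assignments outside 0..K-1")

    @property
    def n_samples(self) -> int:
        return self.assignments.shape[0]

    def indices(self, fold: int) -> np.ndarray:
        return np.nonzero(self.assignments == fold)[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_folds)


@dataclass
class PredictionTensor:
    """Out-of-sample predictions, ``(N, C, R)``.

    Attributes
    ----------
    values : ndarray (N, C, R)
        Predicted labels (0-1 loss) or scores (AUC-type metrics).
    fold_of : ndarray (N, R)
        Per-repeat fold id of each sample, 0-based.
    configuration_ids : list
        C descriptors; indexing order is meaningful (tie-breaks).
    missing_mask : ndarray (N, C, R), bool
        True where a prediction was never produced (incomplete CV,
        dropped configuration).
    """

    values: np.ndarray
    fold_of: np.ndarray
    configuration_ids: list = field(default_factory=list)
    missing_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError("values must be (N, C) or (N, C, R)")
        self.values = v
        f = np.asarray(self.fold_of, dtype=int)
        if f.ndim == 1:
            f = f[:, None]
        if f.shape != (v.shape[0], v.shape[2]):
            raise ValueError("fold_of must be (N, R)")
        self.fold_of = f
        if self.missing_mask is None:
            self.missing_mask = np.zeros(v.shape, dtype=bool)
        else:
            m = np.asarray(self.missing_mask, dtype=bool)
            if m.ndim == 2:
                m = m[:, :, None]
            if m.shape != v.shape:
                raise ValueError("missing_mask shape mismatch")
            self.missing_mask = m
        if not self.configuration_ids:
            self.configuration_ids = [f"config_{j + 1}" for j in range(v.shape[1])]
        if len(self.configuration_ids) != v.shape[1]:
            raise ValueError("configuration_ids length mismatch")

    @classmethod
    def from_matrix(cls, values, fold_of, configuration_ids=None, missing_mask=None):
        """Single-repeat constructor from an ``(N, C)`` matrix."""
        return cls(
            np.asarray(values),
            np.asarray(fold_of),
            list(configuration_ids) if configuration_ids is not None else [],
            missing_mask,
        )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_configurations(self) -> int:
        return self.values.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[2]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def matrix(self, repeat: int = 0) -> np.ndarray:
        """The ``(N, C)`` prediction matrix of one repeat."""
        return self.values[:, :, repeat]

    def partition(self, repeat: int = 0) -> FoldPartition:
        f = self.fold_of[:, repeat]
        return FoldPartition(f, int(f.max()) + 1)


@dataclass
class PerformanceEstimate:
    """A point estimate with provenance.

    The internal ``loss`` is always in loss orientation; :attr:`point`
    and :attr:`ci` convert to the metric's native direction (so for
    accuracy a lower/upper *loss* pair maps to an upper/lower accuracy
    pair, kept sorted).
    """

    method: str
    metric: Metric
    loss: float
    selected: int
    ci_loss: Optional[Tuple[float, float]] = None
    ci_level: Optional[float] = None
    n_bootstraps: int = 0
    seed: Optional[int] = None
    bootstrap_losses: Optional[np.ndarray] = None

    @property
    def point(self) -> float:
        """Estimate in the metric's native direction."""
        return self.metric.to_native(self.loss)

    @property
    def ci(self) -> Optional[Tuple[float, float]]:
        if self.ci_loss is None:
            return None
        lo, hi = (self.metric.to_native(v) for v in self.ci_loss)
        return (min(lo, hi), max(lo, hi))

    def __repr__(self):  # compact, for CLI reports
        s = f"{self.method}: {self.metric.name}={self.point:.4f}"
        if self.ci is not None:
            s += f" CI{self.ci_level:.0%}=({self.ci[0]:.4f}, {self.ci[1]:.4f})"
        return f"<{s} selected={self.selected}>"
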