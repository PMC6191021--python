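"""Fold construction.

Stratified partitions shuffle each class with the seeded generator and
deal samples round-robin across folds with a running pointer, so total
fold sizes differ by at most one and each class's per-fold counts differ
by at most one.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import FoldPartition


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept a seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stratified_partition(y, n_folds: int, seed=None) -> FoldPartition:
    """Seeded stratified K-fold partition of the samples.

    Parameters
    ----------
    y : array-like
        Class labels, length N.
    n_folds : int
        K, with ``2 <= K <= N``.
    seed : int, Generator or None
        Randomness source; a given seed is fully reproducible.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError(f"need 2 <= K <= N, got K={n_folds}, N={n}")
    rng = as_rng(seed)
    assignments = np.empty(n, dtype=int)
    pointer = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if idx.size < n_folds:
            warnings.warn(
                f"class {cls!r} has {idx.size} member(s) < K={n_folds}; "
                "stratification is best-effort",
                stacklevel=2,
            )
        idx = rng.permutation(idx)
        for i in idx:
            assignments[i] = pointer % n_folds
            pointer += 1
    return FoldPartition(assignments, n_folds)


def plain_partition(n_samples: int, n_folds: int, seed=None) -> FoldPartition:
    """Unstratified equal-size random partition (for label-free data)."""
    if not 2 <= n_folds <= n_samples:
        raise ValueError(f"need 2 <= K <= N, got K={n_folds}, N={n_samples}")
    rng = as_rng(seed)
    assignments = np.empty(n_samples, dtype=int)
    assignments[rng.permutation(n_samples)] = np.arange(n_samples) % n_folds
    return FoldPartition(assignments, n_folds)
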