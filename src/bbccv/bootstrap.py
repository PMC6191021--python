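"""Bootstrap resampling plans over sample indexes.

A plan fixes the full ``B x N`` matrix of in-bag indexes up front, so
that a point estimate and its confidence interval come from one and the
same bootstrap population, and so that two estimators given the same
plan resample identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .folds import as_rng


@dataclass
class BootstrapPlan:
    """``B`` uniform-with-replacement draws of ``N`` sample indexes.

    Rows whose in-bag set covers every sample (empty out-of-bag set) are
    redrawn at construction, so every row has at least one out-of-bag
    sample.
    """

    n_bootstraps: int
    n_samples: int
    seed: Optional[int]
    index_matrix: np.ndarray
    _mult: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @classmethod
    def create(cls, n_bootstraps: int, n_samples: int, seed=None) -> "BootstrapPlan":
        if n_bootstraps < 1 or n_samples < 2:
            raise ValueError("need B >= 1 and N >= 2")
        rng = as_rng(seed)
        idx = rng.integers(0, n_samples, size=(n_bootstraps, n_samples))
        # redraw rows with an empty out-of-bag set (a row drawing every
        # sample exactly once, i.e. a permutation)
        for _ in range(100):
            bad = ~(np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n_samples, size=(int(bad.sum()), n_samples))
        return cls(
            n_bootstraps,
            n_samples,
            seed if not isinstance(seed, np.random.Generator) else None,
            idx,
        )

    def multiplicities(self) -> np.ndarray:
        """``(B, N)`` float matrix of in-bag counts per sample."""
        if self._mult is None:
            w = np.zeros((self.n_bootstraps, self.n_samples))
            rows = np.repeat(np.arange(self.n_bootstraps), self.n_samples)
            np.add.at(w, (rows, self.index_matrix.ravel()), 1.0)
            self._mult = w
        return self._mult

    def oob_mask(self) -> np.ndarray:
        """``(B, N)`` bool matrix, True where a sample is out-of-bag."""
        return self.multiplicities() == 0
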