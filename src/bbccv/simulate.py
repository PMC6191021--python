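"""Synthetic prediction matrices with known true accuracies.

The generator produces binary-classification out-of-sample prediction
matrices without simulating any training: each of C configurations gets
a true accuracy ``P_j`` drawn from a Beta(a, b) distribution, and its
prediction on sample ``i`` is correct with probability ``P_j``
(``Pi_ij = 1(r_ij < P_j)`` with uniform draws r).  Because Pi is a
correctness indicator, the harness scores it against an all-ones label
vector with 0-1 loss, so a column's accuracy is simply its mean.

The harness then applies the estimation protocols (CVT, TT, NCV, BBC,
BBCD) to the *same* matrix and fold split within each repetition and
records the estimation bias ``P_hat - P``, where ``P`` is the true
accuracy of the configuration each protocol selected.  Averaged over
repetitions this reproduces the optimism of uncorrected tuning — worst
at small N and many configurations — and the behaviour of each
correction.

By default the uniform draws are independent across configurations.  A
``shared_difficulty`` mode reuses one draw ``r_i`` per sample across all
configurations, which induces strong positive correlation between
columns; under that regime the empirical ranking of configurations is
monotone in the true one and selection optimism all but vanishes, so it
is offered for ablation only.
"""

from __future__ import annotations

import itertools
import sys
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bootstrap import BootstrapPlan
from .containers import PredictionTensor
from .cv import cvt_from_predictions, ncv_from_predictions
from .bias import bbc_estimate, tt_estimate
from .dropping import bbcd_from_predictions
from .folds import as_rng, plain_partition
from .metrics import ACCURACY

GRID_N = (20, 40, 60, 80, 100, 500, 1000)
GRID_C = (50, 100, 200, 300, 500, 1000, 2000)
GRID_BETA = ((9, 6), (14, 6), (24, 6), (54, 6))
PROTOCOLS = ("cvt", "tt", "ncv", "bbc", "bbcd")


def beta_moments(a: float, b: float) -> Tuple[float, float]:
    """Mean and variance of a Beta(a, b) distribution."""
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    return mean, var


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the simulation grid.

    Defaults correspond to the full-scale study: 500 repetitions,
    K=10 folds, B=1000 bootstraps, dropping threshold 0.99 with no
    minimum-prediction gate.
    """

    n_samples: int
    n_configurations: int
    beta_params: Tuple[float, float] = (9, 6)
    repetitions: int = 500
    n_folds: int = 10
    n_bootstraps: int = 1000
    alpha_drop: float = 0.99
    min_predictions: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_samples < self.n_folds:
            raise ValueError("need N >= K")
        if self.n_configurations < 1 or self.repetitions < 1:
            raise ValueError("need C >= 1 and repetitions >= 1")
        beta_moments(*self.beta_params)  # validates positivity


@dataclass
class SimulatedPredictionSet:
    """A generated correctness matrix with its ground truth."""

    pi: np.ndarray  # (N, C) 0/1 correctness indicators
    true_performance: np.ndarray  # (C,) accuracies P_j
    y: np.ndarray  # implied all-ones label vector
    difficulty: Optional[np.ndarray] = None  # the uniform draws r


def generate_predictions(
    setting: SimulationSetting,
    rng=None,
    p_override=None,
    shared_difficulty: bool = False,
) -> SimulatedPredictionSet:
    """Draw one correctness matrix for a simulation cell.

    ``p_override`` fixes the true accuracies instead of drawing them
    from the Beta distribution (length C, or broadcastable).
    """
    rng = as_rng(rng if rng is not None else setting.seed)
    n, c = setting.n_samples, setting.n_configurations
    if p_override is not None:
        p = np.broadcast_to(np.asarray(p_override, dtype=float), (c,)).copy()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("true performances must lie in [0, 1]")
    else:
        a, b = setting.beta_params
        p = rng.beta(a, b, size=c)
    if shared_difficulty:
        r = rng.uniform(size=n)
        pi = (r[:, None] < p[None, :]).astype(np.int8)
    else:
        r = rng.uniform(size=(n, c))
        pi = (r < p[None, :]).astype(np.int8)
    return SimulatedPredictionSet(pi, p, np.ones(n, dtype=np.int8), r)


def _apply_protocols(pred, setting, protocols, rng):
    """Apply the requested protocols to one generated matrix.

    All protocols share the same fold partition; BBC and BBCD each draw
    bootstraps from the shared repetition stream.  Returns
    ``{protocol: (estimated accuracy, selected index)}``.
    """
    partition = plain_partition(setting.n_samples, setting.n_folds, rng)
    tensor = PredictionTensor.from_matrix(pred.pi, partition.assignments)
    y, metric = pred.y, ACCURACY
    out = {}
    for proto in protocols:
        if proto == "cvt":
            est = cvt_from_predictions(tensor, y, metric)
        elif proto == "tt":
            est = tt_estimate(tensor, y, partition, metric).estimate
        elif proto == "ncv":
            est = ncv_from_predictions(tensor, y, partition, metric)
        elif proto == "bbc":
            plan = BootstrapPlan.create(setting.n_bootstraps, setting.n_samples, rng)
            est = bbc_estimate(tensor, y, metric, plan, ci_level=None)
        elif proto == "bbcd":
            est, _ = bbcd_from_predictions(
                tensor,
                y,
                partition,
                metric,
                alpha_drop=setting.alpha_drop,
                min_predictions=setting.min_predictions,
                n_bootstraps=setting.n_bootstraps,
                seed=rng,
                ci_level=None,
            )
        else:
            raise ValueError(f"unknown protocol {proto!r}; choose from {PROTOCOLS}")
        out[proto] = (est.point, est.selected)
    return out


def run_protocols(
    setting: SimulationSetting,
    protocols: Sequence[str] = PROTOCOLS,
    rng=None,
    shared_difficulty: bool = False,
) -> pd.DataFrame:
    """Estimate the bias of each protocol on one simulation cell.

    Returns a tidy frame with one row per protocol: the mean bias
    ``P_hat - P`` over repetitions, its Monte-Carlo standard error, and
    the mean true accuracy of the selected configurations.
    """
    rng = as_rng(rng if rng is not None else setting.seed)
    bias = {p: [] for p in protocols}
    true_perf = {p: [] for p in protocols}
    for _ in range(setting.repetitions):
        pred = generate_predictions(setting, rng, shared_difficulty=shared_difficulty)
        results = _apply_protocols(pred, setting, protocols, rng)
        for proto, (estimate, selected) in results.items():
            truth = float(pred.true_performance[selected])
            bias[proto].append(estimate - truth)
            true_perf[proto].append(truth)
    rows = []
    for proto in protocols:
        arr = np.asarray(bias[proto])
        rows.append(
            {
                "n_samples": setting.n_samples,
                "n_configurations": setting.n_configurations,
                "beta_a": setting.beta_params[0],
                "beta_b": setting.beta_params[1],
                "protocol": proto,
                "bias": float(arr.mean()),
                "bias_se": float(arr.std(ddof=1) / np.sqrt(arr.size))
                if arr.size > 1
                else float("nan"),
                "mean_true_performance": float(np.mean(true_perf[proto])),
                "repetitions": setting.repetitions,
                "n_folds": setting.n_folds,
                "n_bootstraps": setting.n_bootstraps,
            }
        )
    return pd.DataFrame(rows)


def full_grid(
    n_values: Iterable[int] = GRID_N,
    c_values: Iterable[int] = GRID_C,
    betas: Iterable[Tuple[float, float]] = GRID_BETA,
    **overrides,
) -> list:
    """The simulation settings of the full study grid (7 x 7 x 4 = 196)."""
    return [
        SimulationSetting(n, c, beta, **overrides)
        for n, c, beta in itertools.product(n_values, c_values, betas)
    ]


def grid(
    protocols: Sequence[str] = PROTOCOLS,
    n_values: Iterable[int] = GRID_N,
    c_values: Iterable[int] = GRID_C,
    betas: Iterable[Tuple[float, float]] = ((9, 6),),
    repetitions: int = 500,
    n_bootstraps: int = 1000,
    scale_reps: float = 1.0,
    seed=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the protocol comparison over a (sub)grid of cells.

    ``scale_reps`` multiplies the repetition count (floor, minimum 2) so
    desk-scale replications can trade precision for time.
    """
    reps = max(int(repetitions * scale_reps), 2)
    rng = as_rng(seed)
    frames = []
    settings = full_grid(
        n_values,
        c_values,
        betas,
        repetitions=reps,
        n_bootstraps=n_bootstraps,
    )
    for i, setting in enumerate(settings):
        frames.append(run_protocols(setting, protocols, rng))
        if progress:
            print(
                f"[{i + 1}/{len(settings)}] N={setting.n_samples} "
                f"C={setting.n_configurations} Be{setting.beta_params} done",
                file=sys.stderr,
                flush=True,
            )
    return pd.concat(frames, ignore_index=True)
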