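import numpy as np
import pytest

from bbccv import Learner, PredictionTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tt_pathology():
    """Leave-one-out tensor where some configuration is right in every
    fold but the overall winner is wrong on 7 of 10 samples."""
    values = np.zeros((10, 8), dtype=int)
    values[:3, 0] = 1  # winner: correct on 3 samples, 0-1 loss 0.7
    for t, i in enumerate(range(3, 10)):
        values[i, 1 + t] = 1  # each remaining sample covered by one config
    y = np.ones(10, dtype=int)
    tensor = PredictionTensor.from_matrix(values, np.arange(10))
    return tensor, y


class CountingLearner(Learner):
    """Majority-vote learner that records its training-row sets."""

    def __init__(self):
        self.train_rows = []

        def train(X, y, config):
            self.train_rows.append(frozenset(np.asarray(X)[:, 0].tolist()))
            vals, counts = np.unique(y, return_counts=True)
            return vals[np.argmax(counts)]

        def predict(model, X):
            return np.full(len(X), model)

        super().__init__(train, predict)


@pytest.fixture
def counting_learner():
    return CountingLearner()


def replay_learner(table):
    """Learner whose configurations replay the columns of a recorded
    prediction table; X must carry the original row index in column 0."""

    def train(X, y, config):
        return config

    def predict(config, X):
        rows = np.asarray(X)[:, 0].astype(int)
        return table[rows, config]

    return Learner(train, predict)
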