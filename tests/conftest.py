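import numpy as np
import pytest

from spo2cast import LSTMForecaster, SyntheticCohortConfig, generate_cohort


def make_recurrence_data(n_seq: int, length: int, seed: int):
    """Noiseless lag-2 linear recurrence p_t = 0.6 p_{t-1} + 0.4 p_{t-2}.

    Sequences start from random pairs in the transform range so the
    transient (eigenvalue -0.4) gives persistence a nonzero error; an
    exact one-step predictor can reach zero error. Returns (X, Y) lag
    rows pooled over sequences.
    """
    rng = np.random.default_rng(seed)
    X, Y = [], []
    for _ in range(n_seq):
        p = list(rng.uniform(0.3, 0.9, 2))
        for _ in range(length - 2):
            p.append(0.6 * p[-1] + 0.4 * p[-2])
        p = np.asarray(p)
        for t in range(2, len(p)):
            X.append(p[t - 2 : t])
            Y.append(p[t])
    return np.asarray(X), np.asarray(Y)


@pytest.fixture(scope="session")
def recurrence_split():
    Xtr, ytr = make_recurrence_data(400, 6, seed=1)
    Xte, yte = make_recurrence_data(100, 6, seed=2)
    return Xtr, ytr, Xte, yte


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (module defaults, fixed seed)."""
    return generate_cohort(SyntheticCohortConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_trained_forecaster(recurrence_split):
    """A small, quickly trained forecaster reused across tests."""
    Xtr, ytr, _, _ = recurrence_split
    est = LSTMForecaster(
        lstm_widths=(8, 4), epochs=15, batch_size=128, dropout=0.1,
        learning_rate=0.01, seed=5,
    )
    return est.fit(Xtr, ytr)
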