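import numpy as np
import pytest

from tvrnn import ChirpSpec, generate_chirp_trials
from tvrnn.models import RNNParams, TVWeights


@pytest.fixture(scope="session")
def small_chirp():
    """Reduced chirp dataset shared across tests (40 trials keeps it fast)."""
    return generate_chirp_trials(ChirpSpec(n_trials=40, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rnn(rng, n_hidden=3, n_channels=2, scale=0.5):
    p = RNNParams.glorot(n_hidden, n_channels, rng)
    p.W_h *= scale
    return p


def random_tv(rng, n_windows=3, window=2, n_hidden=3, n_channels=2):
    T = n_windows * window
    return TVWeights(
        [random_rnn(rng, n_hidden, n_channels) for _ in range(n_windows)], window, T
    )


def scalar_loop_forward(params_of_t, X):
    """Independent per-time-step scalar-loop oracle for the recurrence.

    ``params_of_t(t)`` returns the RNNParams active at 0-based time t.
    """
    B, T, R = X.shape
    y = np.zeros((B, T))
    for b in range(B):
        h = np.zeros(params_of_t(0).n_hidden)
        for t in range(T):
            p = params_of_t(t)
            h = np.tanh(p.W_h @ h + p.W_x @ X[b, t] + p.b_h)
            z = float((p.W_y @ h)[0] + p.b_y)
            y[b, t] = 1.0 / (1.0 + np.exp(-z))
    return y


def numerical_gradient(f, arr, eps=1e-6):
    """Central-difference gradient of scalar f with respect to arr (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        lp = f()
        arr[i] = old - eps
        lm = f()
        arr[i] = old
        g[i] = (lp - lm) / (2 * eps)
    return g


def separable_trials(rng, n=200, T=20, R=4, offset=0.5):
    """Noise-free linearly separable toy data: the label is the sign of the
    per-trial channel mean."""
    labels = np.repeat([0, 1], n // 2)
    X = np.full((n, T, R), -offset)
    X[labels == 1] = offset
    X += 0.01 * rng.standard_normal((n, 1, R))  # tiny per-trial jitter
    order = rng.permutation(n)
    return X[order], labels[order].astype(np.int8)
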