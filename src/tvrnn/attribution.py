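"""Time x channel importance via integrated-gradient SHAP approximation.

Signed attributions follow the straight-path integrated-gradients rule

    IG_i(x) = (x_i - x'_i) * integral_0^1 dF(x' + a (x - x')) / dx_i da

with F the model's sigmoid output at one chosen output time and x' an
all-zeros baseline trial (for which F is near 0.5).  The integral is a
trapezoid rule over the path.  The importance of feature (t, channel) is
the mean absolute attribution across test trials; the signed mean is also
exposed.  Completeness — sum of attributions equals F(x) - F(x') — is the
built-in correctness check.

For ``<= 12`` total features an exact Shapley enumeration over feature
coalitions is provided as an independent oracle (test use only; exponential
in the number of features).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from . import _transformer as _tf
from .data import TrialSet, ValidationError
from .models import RNNParams, TVWeights, _as_array, rnn_forward, tvrnn_forward
from .training import rnn_input_gradient, tvrnn_input_gradient


def _model_forward_y(model, X: np.ndarray) -> np.ndarray:
    """[B, T] sigmoid outputs for any supported model object."""
    if isinstance(model, RNNParams):
        return rnn_forward(model, X, return_hidden=False).y
    if isinstance(model, TVWeights):
        return tvrnn_forward(model, X, return_hidden=False).y
    if isinstance(model, dict):  # transformer parameter dict
        return _tf.transformer_forward(model, X)[0]
    if isinstance(model, tuple) and len(model) == 2:  # (forward, input_grad)
        return model[0](X)
    raise ValidationError(f"unsupported model type {type(model).__name__}")


def _model_input_gradient(model, X: np.ndarray, output_time: int) -> np.ndarray:
    """dF/dX with F = sigmoid output at ``output_time``; [B, T, R]."""
    if isinstance(model, RNNParams):
        return rnn_input_gradient(model, X, output_time)
    if isinstance(model, TVWeights):
        return tvrnn_input_gradient(model, X, output_time)
    if isinstance(model, dict):
        y, cache = _tf.transformer_forward(model, X, need_cache=True)
        t0 = output_time % X.shape[1]
        dZ = np.zeros_like(y)
        dZ[:, t0] = y[:, t0] * (1.0 - y[:, t0])
        _, dX = _tf.transformer_backward(model, cache, dZ)
        return dX
    if isinstance(model, tuple) and len(model) == 2:
        return model[1](X, output_time)
    raise ValidationError(f"unsupported model type {type(model).__name__}")


@dataclasses.dataclass
class AttributionMatrix:
    """Signed attributions per trial and their trial-averaged importance."""

    phi: np.ndarray  # [trials, T, R] signed
    output_time: int
    baseline: str
    baseline_value: float  # F(x') at the output time

    @property
    def importance(self) -> np.ndarray:
        """[T, R] mean absolute attribution across trials (non-negative)."""
        return np.abs(self.phi).mean(axis=0)

    @property
    def signed_mean(self) -> np.ndarray:
        return self.phi.mean(axis=0)


def integrated_gradients(
    model,
    x: np.ndarray,
    x_prime: np.ndarray | None = None,
    output_time: int = -1,
    steps: int = 128,
) -> np.ndarray:
    """Signed attribution [T, R] (or [B, T, R] for batched x).

    Trapezoid rule over ``steps`` intervals on the straight line from the
    baseline ``x_prime`` (zeros by default) to ``x``.
    """
    if steps < 1:
        raise ValidationError(f"steps must be >= 1, got {steps}")
    x = np.asarray(x, dtype=np.float64)
    batched = x.ndim == 3
    if not batched:
        x = x[None]
    if x_prime is None:
        x_prime = np.zeros_like(x[0])
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x_prime.shape != x.shape[1:]:
        raise ValidationError(
            f"baseline shape {x_prime.shape} does not match trial shape {x.shape[1:]}"
        )
    B, T, R = x.shape
    alphas = np.linspace(0.0, 1.0, steps + 1)
    weights = np.full(steps + 1, 1.0 / steps)
    weights[[0, -1]] = 0.5 / steps
    diff = x - x_prime[None]
    grad_acc = np.zeros_like(x)
    # evaluate all path points of all trials in one batched forward/backward
    pts = x_prime[None, None] + alphas[None, :, None, None] * diff[:, None]
    pts = pts.reshape(B * (steps + 1), T, R)
    g = _model_input_gradient(model, pts, output_time)
    if not np.all(np.isfinite(g)):
        bad = np.argwhere(~np.isfinite(g.reshape(B, steps + 1, T, R)))[0]
        raise ValidationError(f"non-finite gradient at path alpha={alphas[bad[1]]:.4f}")
    g = g.reshape(B, steps + 1, T, R)
    grad_acc = np.einsum("s,bstr->btr", weights, g)
    phi = diff * grad_acc
    return phi if batched else phi[0]


def baseline_output(model, output_time: int = -1, like: np.ndarray | None = None,
                    n_timepoints: int | None = None, n_channels: int | None = None) -> float:
    """F(x') on the all-zero baseline trial at the requested output time."""
    if like is not None:
        T, R = like.shape[-2], like.shape[-1]
    else:
        T, R = n_timepoints, n_channels
    if isinstance(model, RNNParams):
        R = R or model.n_channels
    elif isinstance(model, TVWeights):
        T, R = model.T, model.n_channels
    if T is None or R is None:
        raise ValidationError("provide `like` or n_timepoints/n_channels")
    z = np.zeros((1, T, R))
    return float(_model_forward_y(model, z)[0, output_time])


def completeness_residual(
    model, x: np.ndarray, x_prime: np.ndarray | None = None,
    output_time: int = -1, steps: int = 128,
) -> float:
    """|sum_i IG_i - (F(x) - F(x'))| for one trial; O(1/steps) on smooth models."""
    x = np.asarray(x, dtype=np.float64)
    phi = integrated_gradients(model, x, x_prime, output_time, steps)
    if x_prime is None:
        x_prime = np.zeros_like(x)
    fx = float(_model_forward_y(model, x[None])[0, output_time])
    fx0 = float(_model_forward_y(model, x_prime[None])[0, output_time])
    return abs(float(phi.sum()) - (fx - fx0))


def importance_matrix(
    model,
    test_trials: TrialSet | np.ndarray,
    output_time: int = -1,
    steps: int = 128,
    baseline: str = "zeros",
    chunk: int = 4096,
) -> AttributionMatrix:
    """Attribution of every test trial against the zero (or class-mean)
    baseline at one output time; importance = mean |phi| across trials."""
    X = _as_array(test_trials)
    B, T, R = X.shape
    t0 = output_time if output_time >= 0 else output_time + T
    if not 0 <= t0 < T:
        raise ValidationError(f"output_time {output_time} outside trial of length {T}")
    if baseline == "zeros":
        x_prime = np.zeros((T, R))
    elif baseline == "mean":
        x_prime = X.mean(axis=0)
    else:
        raise ValidationError(f"unknown baseline {baseline!r}")
    phi = np.empty_like(X)
    per = max(1, chunk // (steps + 1))
    for s in range(0, B, per):
        phi[s:s + per] = integrated_gradients(model, X[s:s + per], x_prime, t0, steps)
    fx0 = float(_model_forward_y(model, x_prime[None])[0, t0])
    return AttributionMatrix(phi=phi, output_time=t0, baseline=baseline, baseline_value=fx0)


# ---------------------------------------------------------------------------
# exact Shapley enumeration (tiny problems; independent oracle)
# ---------------------------------------------------------------------------

def exact_shapley(model, x: np.ndarray, x_prime: np.ndarray | None = None,
                  output_time: int = -1) -> np.ndarray:
    """Exact Shapley values over (time, channel) features by coalition
    enumeration, with absent features set to the baseline.  Exponential;
    refuses more than 12 features."""
    x = np.asarray(x, dtype=np.float64)
    T, R = x.shape
    n = T * R
    if n > 12:
        raise ValidationError(f"exact enumeration limited to 12 features, got {n}")
    if x_prime is None:
        x_prime = np.zeros_like(x)
    feats = list(range(n))
    # value of a coalition: model output with only those features present
    cache: dict[frozenset, float] = {}

    def value(S: frozenset) -> float:
        if S not in cache:
            z = x_prime.copy().ravel()
            idx = np.array(sorted(S), dtype=int)
            if idx.size:
                z[idx] = x.ravel()[idx]
            cache[S] = float(_model_forward_y(model, z.reshape(1, T, R))[0, output_time])
        return cache[S]

    phi = np.zeros(n)
    fact = math.factorial
    for i in feats:
        rest = [f for f in feats if f != i]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                S = frozenset(S)
                wgt = fact(len(S)) * fact(n - len(S) - 1) / fact(n)
                phi[i] += wgt * (value(S | {i}) - value(S))
    return phi.reshape(T, R)
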