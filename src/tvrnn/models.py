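"""Forward computation for recurrent decoders with static or time-varying weights.

The recurrence is the vanilla tanh RNN with a per-time-point sigmoid readout

    h_t = tanh(W_h h_{t-1} + W_x x_t + b_h),   h_0 = 0
    y_t = sigmoid(W_y h_t + b_y)

and class call ``0 if y_t < 0.5 else 1``.  A time-varying model keeps one
parameter bundle per window of ``w`` time points (window k = ceil(t/w),
1-based t) and switches bundles at window boundaries while the hidden state
flows through uninterrupted.  All arrays are numpy; trials are batched along
the leading axis.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data import TrialSet, ValidationError


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclasses.dataclass
class RNNParams:
    """One parameter bundle: input, recurrent and output weights plus biases."""

    W_x: np.ndarray  # [N, R]
    W_h: np.ndarray  # [N, N]
    W_y: np.ndarray  # [1, N]
    b_h: np.ndarray  # [N]
    b_y: float

    def __post_init__(self) -> None:
        self.W_x = np.asarray(self.W_x, dtype=np.float64)
        self.W_h = np.asarray(self.W_h, dtype=np.float64)
        self.W_y = np.asarray(self.W_y, dtype=np.float64).reshape(1, -1)
        self.b_h = np.asarray(self.b_h, dtype=np.float64).ravel()
        self.b_y = float(self.b_y)
        N, R = self.W_x.shape
        if self.W_h.shape != (N, N):
            raise ValidationError(f"W_h must be [{N},{N}], got {self.W_h.shape}")
        if self.W_y.shape != (1, N):
            raise ValidationError(f"W_y must be [1,{N}], got {self.W_y.shape}")
        if self.b_h.shape != (N,):
            raise ValidationError(f"b_h must be [{N}], got {self.b_h.shape}")
        for name in ("W_x", "W_h", "W_y", "b_h"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains non-finite values")
        if not math.isfinite(self.b_y):
            raise ValidationError("b_y is non-finite")

    @property
    def n_hidden(self) -> int:
        return self.W_x.shape[0]

    @property
    def n_channels(self) -> int:
        return self.W_x.shape[1]

    def copy(self) -> "RNNParams":
        return RNNParams(
            self.W_x.copy(), self.W_h.copy(), self.W_y.copy(), self.b_h.copy(), self.b_y
        )

    @classmethod
    def glorot(cls, n_hidden: int, n_channels: int, rng: np.random.Generator) -> "RNNParams":
        """Uniform fan-based (Glorot) initialization, zero biases."""

        def u(fan_in, fan_out, shape):
            lim = math.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        return cls(
            W_x=u(n_channels, n_hidden, (n_hidden, n_channels)),
            W_h=u(n_hidden, n_hidden, (n_hidden, n_hidden)),
            W_y=u(n_hidden, 1, (1, n_hidden)),
            b_h=np.zeros(n_hidden),
            b_y=0.0,
        )


@dataclasses.dataclass
class TVWeights:
    """Per-window parameter bundles of a time-varying RNN.

    ``windows[k-1]`` is active for 1-based time points t with ceil(t/w) == k.
    The last window is truncated when w does not divide T.
    """

    windows: list[RNNParams]
    window_size: int
    T: int

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValidationError(f"window_size must be >= 1, got {self.window_size}")
        expected = math.ceil(self.T / self.window_size)
        if len(self.windows) != expected:
            raise ValidationError(
                f"expected {expected} windows for T={self.T}, w={self.window_size}; "
                f"got {len(self.windows)}"
            )
        N = self.windows[0].n_hidden
        R = self.windows[0].n_channels
        for k, p in enumerate(self.windows):
            if p.n_hidden != N or p.n_channels != R:
                raise ValidationError(f"window {k + 1} has inconsistent shapes")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_hidden(self) -> int:
        return self.windows[0].n_hidden

    @property
    def n_channels(self) -> int:
        return self.windows[0].n_channels

    def copy(self) -> "TVWeights":
        return TVWeights([p.copy() for p in self.windows], self.window_size, self.T)

    def window_slices(self) -> list[slice]:
        """0-based time slices covered by each window, in order."""
        return [
            slice(k * self.window_size, min((k + 1) * self.window_size, self.T))
            for k in range(self.n_windows)
        ]


@dataclasses.dataclass
class OutputTrajectory:
    """Per-time-point sigmoid outputs and optional hidden trajectory."""

    y: np.ndarray  # [trials, T] in (0, 1)
    h: np.ndarray | None = None  # [trials, T, N]

    @property
    def class_calls(self) -> np.ndarray:
        """Thresholded class per trial and time point (tie at 0.5 -> class 1)."""
        return (self.y >= 0.5).astype(np.int8)


def window_index(t: int, w: int) -> int:
    """Window k = ceil(t/w) of 1-based time point t (window size w)."""
    if w < 1:
        raise ValidationError(f"window size must be >= 1, got {w}")
    if t < 1:
        raise IndexError(f"time index must be >= 1 (1-based), got {t}")
    return -(-t // w)


def _as_array(trials: TrialSet | np.ndarray) -> np.ndarray:
    if isinstance(trials, TrialSet):
        return trials.data
    x = np.asarray(trials, dtype=np.float64)
    if x.ndim != 3:
        raise ValidationError(f"expected [trials, time, channels] array, got ndim={x.ndim}")
    return x


def rnn_forward(
    params: RNNParams, trials: TrialSet | np.ndarray, return_hidden: bool = True
) -> OutputTrajectory:
    """Run the static-weight recurrence over full trials (h_0 = 0)."""
    X = _as_array(trials)
    B, T, R = X.shape
    if R != params.n_channels:
        raise ValidationError(
            f"trials have {R} channels but params expect {params.n_channels}"
        )
    N = params.n_hidden
    H = np.empty((B, T, N))
    pre = X @ params.W_x.T + params.b_h  # [B, T, N]
    h = np.zeros((B, N))
    WhT = params.W_h.T
    for t in range(T):
        h = np.tanh(pre[:, t] + h @ WhT)
        H[:, t] = h
    y = sigmoid(H @ params.W_y[0] + params.b_y)
    return OutputTrajectory(y=y, h=H if return_hidden else None)


def tvrnn_forward(
    tv: TVWeights, trials: TrialSet | np.ndarray, return_hidden: bool = True
) -> OutputTrajectory:
    """Run the recurrence with per-window weights; hidden state is carried
    across window boundaries, never reset."""
    X = _as_array(trials)
    B, T, R = X.shape
    if T != tv.T:
        raise ValidationError(f"trials have T={T} but weights expect T={tv.T}")
    if R != tv.n_channels:
        raise ValidationError(f"trials have {R} channels but params expect {tv.n_channels}")
    N = tv.n_hidden
    H = np.empty((B, T, N))
    y = np.empty((B, T))
    h = np.zeros((B, N))
    for k, sl in enumerate(tv.window_slices()):
        p = tv.windows[k]
        pre = X[:, sl] @ p.W_x.T + p.b_h
        WhT = p.W_h.T
        for j in range(sl.stop - sl.start):
            h = np.tanh(pre[:, j] + h @ WhT)
            H[:, sl.start + j] = h
        y[:, sl] = sigmoid(H[:, sl] @ p.W_y[0] + p.b_y)
    return OutputTrajectory(y=y, h=H if return_hidden else None)


def classify(traj: OutputTrajectory, t: int) -> np.ndarray:
    """Class call at 0-based time index t: 0 iff y_t < 0.5, else 1."""
    T = traj.y.shape[1]
    if not -T <= t < T:
        raise IndexError(f"time index {t} out of range for T={T}")
    return (traj.y[:, t] >= 0.5).astype(np.int8)
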