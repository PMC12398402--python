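"""BPTT optimization of the decoders, cross-validation splitting, and
per-window baseline classifiers.

Two loss strategies train the static RNN: S1 places binary cross-entropy on
the final output y_T only; S2 aggregates it over every time point (mean over
time so the scale is comparable across sequence lengths).  The time-varying
model is trained end-to-end with the aggregate loss: every window's
parameter bundle receives gradients in every batch, flowing backwards
through the shared hidden state.  Gradients are computed by hand-written
backpropagation through time on numpy arrays and checked against numerical
differentiation in the tests.

Gradient values of the recurrent weights are recorded every epoch, with
vanishing (|g| < 1e-7) and exploding (|g| > 1e2) flags, to support the
gradient-stability diagnostics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from . import _transformer as _tf
from .data import TrialSet, ValidationError
from .models import (
    OutputTrajectory,
    RNNParams,
    TVWeights,
    _as_array,
    rnn_forward,
    sigmoid,
    tvrnn_forward,
)

VANISH_THRESHOLD = 1e-7
EXPLODE_THRESHOLD = 1e2
_EPS = 1e-12


class TrainingDivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the gradient trace."""

    def __init__(self, message: str, trace: "GradientTrace"):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _bce(y: np.ndarray, labels: np.ndarray) -> np.ndarray:
    eps = max(_EPS, float(np.finfo(np.asarray(y).dtype).eps))
    yc = np.clip(y, eps, 1.0 - eps)
    return -(labels * np.log(yc) + (1.0 - labels) * np.log1p(-yc))


def loss_s1(traj: OutputTrajectory, labels: np.ndarray) -> float:
    """Binary cross-entropy on the final output only, mean over trials."""
    return float(_bce(traj.y[:, -1], np.asarray(labels, dtype=np.float64)).mean())


def loss_s2(traj: OutputTrajectory, labels: np.ndarray) -> float:
    """Binary cross-entropy at every time point, mean over time and trials."""
    lab = np.asarray(labels, dtype=np.float64)[:, None]
    return float(_bce(traj.y, lab).mean())


def _loss_and_dz(y: np.ndarray, labels: np.ndarray, strategy: str) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. the pre-sigmoid output z (stable form:
    dL/dz = (sigmoid(z) - label) / #terms for sigmoid + cross-entropy)."""
    B, T = y.shape
    lab = np.asarray(labels, dtype=np.float64)
    dZ = np.zeros_like(y)
    if strategy == "s1":
        loss = float(_bce(y[:, -1], lab).mean())
        dZ[:, -1] = (y[:, -1] - lab) / B
    else:  # aggregate over time (S2 / time-varying training)
        loss = float(_bce(y, lab[:, None]).mean())
        dZ[:] = (y - lab[:, None]) / (B * T)
    return loss, dZ


# ---------------------------------------------------------------------------
# backward passes (BPTT)
# ---------------------------------------------------------------------------

def rnn_backward(
    params: RNNParams, X: np.ndarray, H: np.ndarray, dZ: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of a static RNN given dL/dz_y per (trial, time)."""
    B, T, N = H.shape
    dW_y = np.einsum("bt,btn->n", dZ, H)[None, :]
    db_y = dZ.sum()
    dH_out = dZ[:, :, None] * params.W_y[0]
    dPre = np.empty_like(H)
    carry = np.zeros((B, N))
    for t in range(T - 1, -1, -1):
        dh = dH_out[:, t] + carry
        dpre = dh * (1.0 - H[:, t] ** 2)
        dPre[:, t] = dpre
        carry = dpre @ params.W_h
    dW_h = np.einsum("btn,btm->nm", dPre[:, 1:], H[:, :-1])
    dW_x = np.einsum("btn,btr->nr", dPre, X)
    db_h = dPre.sum((0, 1))
    return {"W_x": dW_x, "W_h": dW_h, "W_y": dW_y, "b_h": db_h, "b_y": np.array([db_y])}


def rnn_input_gradient(
    params: RNNParams, X: np.ndarray, output_time: int, wrt: str = "y"
) -> np.ndarray:
    """dF/dX for F = output at one time point (sigmoid output by default).

    Shape matches X; entries at times after ``output_time`` are exactly zero
    (the recurrence is causal).
    """
    traj = rnn_forward(params, X)
    return _input_gradient_from(params, None, X, traj, output_time, wrt)


def tvrnn_input_gradient(
    tv: TVWeights, X: np.ndarray, output_time: int, wrt: str = "y"
) -> np.ndarray:
    traj = tvrnn_forward(tv, X)
    return _input_gradient_from(None, tv, X, traj, output_time, wrt)


def _input_gradient_from(params, tv, X, traj, output_time, wrt) -> np.ndarray:
    B, T, R = X.shape
    t0 = output_time % T
    y = traj.y[:, t0]
    dZ = y * (1.0 - y) if wrt == "y" else np.ones(B)
    H = traj.h
    dX = np.zeros_like(X)

    def win(t):
        if tv is None:
            return params
        return tv.windows[t // tv.window_size]

    p = win(t0)
    carry = (dZ[:, None] * p.W_y[0]) * (1.0 - H[:, t0] ** 2)
    dX[:, t0] = carry @ p.W_x
    for t in range(t0 - 1, -1, -1):
        carry = (carry @ win(t + 1).W_h) * (1.0 - H[:, t] ** 2)
        dX[:, t] = carry @ win(t).W_x
    return dX


def tvrnn_backward(
    tv: TVWeights, X: np.ndarray, H: np.ndarray, dZ: np.ndarray
) -> list[dict[str, np.ndarray]]:
    """Per-window gradients of a time-varying RNN (end-to-end BPTT)."""
    B, T, N = H.shape
    slices = tv.window_slices()
    dH_out = np.empty_like(H)
    for k, sl in enumerate(slices):
        dH_out[:, sl] = dZ[:, sl, None] * tv.windows[k].W_y[0]
    dPre = np.empty_like(H)
    carry = np.zeros((B, N))
    w = tv.window_size
    for t in range(T - 1, -1, -1):
        dpre = (dH_out[:, t] + carry) * (1.0 - H[:, t] ** 2)
        dPre[:, t] = dpre
        carry = dpre @ tv.windows[t // w].W_h
    Hprev = np.concatenate([np.zeros((B, 1, N)), H[:, :-1]], axis=1)
    grads = []
    for k, sl in enumerate(slices):
        grads.append(
            {
                "W_x": np.einsum("btn,btr->nr", dPre[:, sl], X[:, sl]),
                "W_h": np.einsum("btn,btm->nm", dPre[:, sl], Hprev[:, sl]),
                "W_y": np.einsum("bt,btn->n", dZ[:, sl], H[:, sl])[None, :],
                "b_h": dPre[:, sl].sum((0, 1)),
                "b_y": np.array([dZ[:, sl].sum()]),
            }
        )
    return grads


# ---------------------------------------------------------------------------
# fast time-major training path (same recursion, contiguous time slices)
# ---------------------------------------------------------------------------

def _loss_and_dz_T(yT: np.ndarray, labels: np.ndarray, strategy: str) -> tuple[float, np.ndarray]:
    """Time-major twin of :func:`_loss_and_dz`; yT and dZ are [T, B]."""
    T, B = yT.shape
    lab = np.asarray(labels, dtype=yT.dtype)
    dZ = np.zeros_like(yT)
    if strategy == "s1":
        loss = float(_bce(yT[-1], lab).mean())
        dZ[-1] = (yT[-1] - lab) / B
    else:
        loss = float(_bce(yT, lab[None, :]).mean())
        dZ[:] = (yT - lab[None, :]) / (B * T)
    return loss, dZ


def _cast_rnn(p: RNNParams, dt) -> tuple:
    """(W_x^T, W_h, W_h^T, W_y row, b_h, b_y) in the compute dtype."""
    return (
        np.ascontiguousarray(p.W_x.T, dtype=dt),
        np.ascontiguousarray(p.W_h, dtype=dt),
        np.ascontiguousarray(p.W_h.T, dtype=dt),
        p.W_y[0].astype(dt),
        p.b_h.astype(dt),
        dt(p.b_y),
    )


def _fast_rnn_forward(p: RNNParams, XT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """XT is [T, B, R] contiguous; returns (H [T,B,N], y [T,B]) in XT's dtype."""
    from ._kernels import fwd_block

    dt = XT.dtype.type
    WxT, _, WhT, Wy0, bh, by = _cast_rnn(p, dt)
    T, B, R = XT.shape
    N = p.n_hidden
    pre = (XT.reshape(T * B, R) @ WxT).reshape(T, B, N) + bh
    H = np.empty((T, B, N), dtype=dt)
    fwd_block(pre, WhT, np.zeros((B, N), dtype=dt), H)
    yT = sigmoid((H.reshape(T * B, N) @ Wy0).reshape(T, B) + by)
    return H, yT


def _fast_rnn_backward(p: RNNParams, XT, H, dZT) -> dict[str, np.ndarray]:
    from ._kernels import bwd_block

    dt = XT.dtype.type
    _, Wh, _, Wy0, _, _ = _cast_rnn(p, dt)
    T, B, N = H.shape
    R = XT.shape[2]
    dW_y = (dZT.ravel() @ H.reshape(T * B, N))[None, :]
    db_y = dZT.sum()
    dHout = dZT[:, :, None] * Wy0
    A = 1.0 - H * H
    dPre = np.empty_like(H)
    bwd_block(A, dHout, Wh, np.zeros((B, N), dtype=dt), dPre)
    dW_h = dPre[1:].reshape(-1, N).T @ H[:-1].reshape(-1, N)
    dW_x = dPre.reshape(-1, N).T @ XT.reshape(-1, R)
    db_h = dPre.reshape(-1, N).sum(axis=0)
    return {"W_x": dW_x, "W_h": dW_h, "W_y": dW_y, "b_h": db_h,
            "b_y": np.array([db_y])}


def _fast_tv_forward(tv: TVWeights, XT: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from ._kernels import fwd_block

    dt = XT.dtype.type
    T, B, R = XT.shape
    N = tv.n_hidden
    H = np.empty((T, B, N), dtype=dt)
    yT = np.empty((T, B), dtype=dt)
    h = np.zeros((B, N), dtype=dt)
    for k, sl in enumerate(tv.window_slices()):
        WxT, _, WhT, Wy0, bh, by = _cast_rnn(tv.windows[k], dt)
        nb = sl.stop - sl.start
        pre = (XT[sl].reshape(nb * B, R) @ WxT).reshape(nb, B, N) + bh
        h = fwd_block(pre, WhT, h, H[sl])
        yT[sl] = sigmoid((H[sl].reshape(nb * B, N) @ Wy0).reshape(nb, B) + by)
    return H, yT


def _fast_tv_backward(tv: TVWeights, XT, H, dZT) -> list[dict[str, np.ndarray]]:
    from ._kernels import bwd_block

    dt = XT.dtype.type
    T, B, N = H.shape
    R = XT.shape[2]
    slices = tv.window_slices()
    casts = [_cast_rnn(w, dt) for w in tv.windows]
    dHout = np.empty_like(H)
    for k, sl in enumerate(slices):
        dHout[sl] = dZT[sl, :, None] * casts[k][3]
    A = 1.0 - H * H
    dPre = np.empty_like(H)
    carry = np.zeros((B, N), dtype=dt)
    for k in range(len(slices) - 1, -1, -1):
        carry = bwd_block(A[slices[k]], dHout[slices[k]], casts[k][1], carry, dPre[slices[k]])
    Hprev = np.concatenate([np.zeros((1, B, N), dtype=dt), H[:-1]], axis=0)
    grads = []
    for k, sl in enumerate(slices):
        grads.append(
            {
                "W_x": dPre[sl].reshape(-1, N).T @ XT[sl].reshape(-1, R),
                "W_h": dPre[sl].reshape(-1, N).T @ Hprev[sl].reshape(-1, N),
                "W_y": (dZT[sl].ravel() @ H[sl].reshape(-1, N))[None, :],
                "b_h": dPre[sl].reshape(-1, N).sum(axis=0),
                "b_y": np.array([dZT[sl].sum()]),
            }
        )
    return grads


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam on a flat dict of arrays (in-place updates)."""

    def __init__(self, shapes: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.v = {k: np.zeros_like(v) for k, v in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            params[k] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


# ---------------------------------------------------------------------------
# configuration, trace, splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    """Optimization settings.  ``strategy``: 's1', 's2', 'tv' or
    'transformer'.  Defaults mirror the reference training recipe
    (64 hidden units, 1000 epochs, Adam at 1e-4)."""

    strategy: str = "s1"
    epochs: int = 1000
    learning_rate: float = 1e-4
    batch_size: int = 64
    seed: int = 0
    hidden_size: int = 64
    window_size: int = 30
    warm_start: bool = False
    # transformer-only widths
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    dropout: float = 0.1
    record_gradients: bool = True
    # single precision for the recurrent training path (standard for NN
    # optimization); parameters and all analysis paths stay double
    dtype: str = "float32"

    def validate(self) -> None:
        if self.strategy not in {"s1", "s2", "tv", "transformer"}:
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.epochs < 0:
            raise ValidationError(f"epochs must be >= 0, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.strategy == "tv" and self.window_size < 1:
            raise ValidationError(f"window_size must be >= 1, got {self.window_size}")


_HIST_EDGES = np.concatenate([[0.0], np.logspace(-12, 3, 16)])


@dataclasses.dataclass
class GradientTrace:
    """Per-epoch record of an example recurrent-weight gradient, loss, and
    vanishing/exploding flags (diagnostic only; training is never clipped)."""

    epochs: list[int] = dataclasses.field(default_factory=list)
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    grad_example: list[float] = dataclasses.field(default_factory=list)
    n_vanishing: list[int] = dataclasses.field(default_factory=list)
    n_exploding: list[int] = dataclasses.field(default_factory=list)
    hist_counts: list[np.ndarray] = dataclasses.field(default_factory=list)
    hist_edges: np.ndarray = dataclasses.field(default_factory=lambda: _HIST_EDGES.copy())

    def record(self, epoch: int, train_loss: float, val_loss: float,
               recurrent_grad: np.ndarray) -> None:
        a = np.abs(recurrent_grad)
        self.epochs.append(epoch)
        self.train_loss.append(train_loss)
        self.val_loss.append(val_loss)
        self.grad_example.append(float(recurrent_grad.flat[0]))
        self.n_vanishing.append(int((a < VANISH_THRESHOLD).sum()))
        self.n_exploding.append(int((a > EXPLODE_THRESHOLD).sum()))
        self.hist_counts.append(np.histogram(a, bins=self.hist_edges)[0])


@dataclasses.dataclass
class CVSplit:
    """Stratified K-fold assignment with a nested validation split."""

    folds: list[dict[str, np.ndarray]]
    n_folds: int
    validation_rate: float

    def check_partition(self, n_trials: int) -> None:
        test = np.concatenate([f["test"] for f in self.folds])
        if len(np.unique(test)) != n_trials or len(test) != n_trials:
            raise ValidationError("test folds do not partition the trials")
        for f in self.folds:
            roles = np.concatenate([f["train"], f["val"], f["test"]])
            if len(np.unique(roles)) != len(roles):
                raise ValidationError("an index appears in two roles within a fold")


def make_cv_splits(
    labels: np.ndarray | Sequence[int],
    n_folds: int = 5,
    validation_rate: float = 0.2,
    seed: int = 0,
) -> CVSplit:
    """Stratified K-fold test partition; the remainder of each fold splits
    into train/validation at ``validation_rate``, stratified by label."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    if len(labels) < n_folds:
        raise ValidationError("fewer trials than folds")
    if not 0 < validation_rate < 1:
        raise ValidationError(f"validation_rate must be in (0,1), got {validation_rate}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    try:
        for i, (rest, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            train, val = train_test_split(
                rest,
                test_size=validation_rate,
                stratify=labels[rest],
                random_state=seed + 1000 + i,
            )
            folds.append(
                {"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)}
            )
    except ValueError as e:  # a class missing from some fold
        raise ValidationError(f"stratification failed: {e}") from e
    split = CVSplit(folds=folds, n_folds=n_folds, validation_rate=validation_rate)
    split.check_partition(len(labels))
    return split


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainResult:
    params: object  # RNNParams | TVWeights | dict (transformer), best-validation checkpoint
    final_params: object  # last-epoch weights
    trace: GradientTrace
    history: list[dict]
    config: TrainConfig


def _rnn_to_dict(p: RNNParams) -> dict[str, np.ndarray]:
    return {"W_x": p.W_x, "W_h": p.W_h, "W_y": p.W_y, "b_h": p.b_h,
            "b_y": np.array([p.b_y])}


def _dict_to_rnn(d: dict[str, np.ndarray]) -> RNNParams:
    return RNNParams(d["W_x"].copy(), d["W_h"].copy(), d["W_y"].copy(),
                     d["b_h"].copy(), float(d["b_y"][0]))


def train_model(
    config: TrainConfig,
    trials: TrialSet | np.ndarray,
    labels: np.ndarray | None = None,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
    init: RNNParams | None = None,
) -> TrainResult:
    """Optimize one model on the given train/validation indices.

    For 's1'/'s2' a single parameter bundle is trained under the respective
    loss; for 'tv' all windows are optimized jointly in every batch under
    the aggregate loss (optionally warm-started from an S1-trained static
    RNN copied into every window); 'transformer' trains the causal
    attention baseline.  Deterministic given the seed.
    """
    config.validate()
    if isinstance(trials, TrialSet):
        X_all, y_all = trials.data, trials.labels.astype(np.float64)
    else:
        X_all = _as_array(trials)
        y_all = np.asarray(labels, dtype=np.float64)
    n = X_all.shape[0]
    if train_idx is None:
        train_idx = np.arange(n)
    if val_idx is None:
        val_idx = train_idx
    if config.strategy == "transformer":
        return _train_transformer(config, X_all, y_all, train_idx, val_idx)
    return _train_recurrent(config, X_all, y_all, train_idx, val_idx, init)


def _train_recurrent(config, X_all, y_all, train_idx, val_idx, init):
    rng = np.random.default_rng(config.seed)
    T, R = X_all.shape[1], X_all.shape[2]
    N = config.hidden_size
    tv_mode = config.strategy == "tv"
    loss_strategy = "s1" if config.strategy == "s1" else "s2"

    if tv_mode:
        n_windows = math.ceil(T / config.window_size)
        if config.warm_start and init is None:
            warm_cfg = dataclasses.replace(config, strategy="s1", warm_start=False)
            init = train_model(warm_cfg, X_all, y_all, train_idx, val_idx).params
        if init is not None:
            windows = [init.copy() for _ in range(n_windows)]
        else:
            windows = [RNNParams.glorot(N, R, rng) for _ in range(n_windows)]
        tv = TVWeights(windows, config.window_size, T)
        pdict = {}
        for k, w in enumerate(tv.windows):
            for name, arr in _rnn_to_dict(w).items():
                pdict[f"{name}@{k}"] = arr
    else:
        p = init.copy() if init is not None else RNNParams.glorot(N, R, rng)
        pdict = _rnn_to_dict(p)

    def rebuild():
        if tv_mode:
            return TVWeights(
                [
                    _dict_to_rnn({name: pdict[f"{name}@{k}"] for name in
                                  ("W_x", "W_h", "W_y", "b_h", "b_y")})
                    for k in range(len(tv.windows))
                ],
                config.window_size,
                T,
            )
        return _dict_to_rnn(pdict)

    def forward_obj():
        # live view over the arrays being optimized
        if tv_mode:
            return tv
        return p

    def sync():
        # refresh dataclass floats that are not array views (b_y)
        if tv_mode:
            for k, w in enumerate(tv.windows):
                w.b_y = float(pdict[f"b_y@{k}"][0])
        else:
            p.b_y = float(pdict["b_y"][0])

    opt = Adam(pdict, lr=config.learning_rate)
    trace = GradientTrace()
    history: list[dict] = []
    best = rebuild()
    best_val = math.inf

    # time-major layout: each time slice of a batch is contiguous
    dt = np.float32 if config.dtype == "float32" else np.float64
    X_allT = np.ascontiguousarray(X_all.transpose(1, 0, 2), dtype=dt)
    XT_val, y_val = np.ascontiguousarray(X_allT[:, val_idx]), y_all[val_idx]
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        last_Wh_grad = None
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            XTb, yb = X_allT[:, idx], y_all[idx]
            sync()
            if tv_mode:
                H, yTb = _fast_tv_forward(tv, XTb)
                loss, dZT = _loss_and_dz_T(yTb, yb, loss_strategy)
                gradw = _fast_tv_backward(tv, XTb, H, dZT)
                grads = {}
                for k, g in enumerate(gradw):
                    for name, arr in g.items():
                        grads[f"{name}@{k}"] = arr
                last_Wh_grad = gradw[0]["W_h"]
            else:
                H, yTb = _fast_rnn_forward(p, XTb)
                loss, dZT = _loss_and_dz_T(yTb, yb, loss_strategy)
                grads = _fast_rnn_backward(p, XTb, H, dZT)
                last_Wh_grad = grads["W_h"]
            if not math.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch}", trace
                )
            losses.append(loss)
            opt.step(pdict, grads)
        sync()
        model = forward_obj()
        _, yv = (_fast_tv_forward(tv, XT_val) if tv_mode
                 else _fast_rnn_forward(p, XT_val))
        vloss, _ = _loss_and_dz_T(yv, y_val, loss_strategy)
        vacc = float(((yv[-1] >= 0.5) == (y_val == 1)).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": vloss, "val_acc_final": vacc})
        if config.record_gradients and last_Wh_grad is not None:
            trace.record(epoch, float(np.mean(losses)), vloss, last_Wh_grad)
        if vloss < best_val:
            best_val = vloss
            best = rebuild()
    sync()
    return TrainResult(params=best if config.epochs else rebuild(),
                       final_params=rebuild(), trace=trace,
                       history=history, config=config)


def _train_transformer(config, X_all, y_all, train_idx, val_idx):
    rng = np.random.default_rng(config.seed)
    T, R = X_all.shape[1], X_all.shape[2]
    params = _tf.init_transformer_params(
        R, T, d_model=config.d_model, n_layers=config.n_layers,
        n_heads=config.n_heads, d_ff=config.d_ff, rng=rng,
    )
    opt_params = {k: v for k, v in params.items() if k != "_meta"}
    opt = Adam(opt_params, lr=config.learning_rate)
    trace = GradientTrace()
    history: list[dict] = []
    best = {k: v.copy() for k, v in params.items()}
    best_val = math.inf
    X_val, y_val = X_all[val_idx], y_all[val_idx]
    loss_strategy = "s2"
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        last_grad = None
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, yb = X_all[idx], y_all[idx]
            y, cache = _tf.transformer_forward(
                params, Xb, dropout=config.dropout, rng=rng, need_cache=True
            )
            loss, dZ = _loss_and_dz(y, yb, loss_strategy)
            if not math.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}", trace)
            grads, _ = _tf.transformer_backward(params, cache, dZ)
            losses.append(loss)
            opt.step(opt_params, grads)
            last_grad = grads["Wq0"]
        yv, _ = _tf.transformer_forward(params, X_val)
        vloss, _ = _loss_and_dz(yv, y_val, loss_strategy)
        vacc = float(((yv[:, -1] >= 0.5) == (y_val == 1)).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": vloss, "val_acc_final": vacc})
        if config.record_gradients and last_grad is not None:
            trace.record(epoch, float(np.mean(losses)), vloss, last_grad)
        if vloss < best_val:
            best_val = vloss
            best = {k: v.copy() for k, v in params.items()}
    return TrainResult(params=best, final_params={k: v.copy() for k, v in params.items()},
                       trace=trace, history=history, config=config)


# ---------------------------------------------------------------------------
# sliding-window baselines
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SlidingBaseline:
    """Independent per-window classifiers (no shared state across windows)."""

    kind: str
    window_slices: list[slice]
    models: list[object]  # RNNParams or fitted SVC per window

    def predict_proba_trajectory(self, X: np.ndarray) -> np.ndarray:
        """[trials, T] outputs.  RNN windows emit per-time-point outputs from
        a zero hidden state at the window start; SVM windows emit one
        decision per window, broadcast across the window (the convention is
        to read it at the window's last time point)."""
        X = _as_array(X)
        B, T, _ = X.shape
        out = np.full((B, T), 0.5)
        for sl, model in zip(self.window_slices, self.models):
            if self.kind.startswith("independent_rnn"):
                out[:, sl] = rnn_forward(model, X[:, sl], return_hidden=False).y
            else:
                flat = X[:, sl].reshape(B, -1)
                out[:, sl] = sigmoid(model.decision_function(flat))[:, None]
        return out

    def window_accuracies(self, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Accuracy of each window read at its last time point."""
        y = self.predict_proba_trajectory(X)
        lab = np.asarray(labels)
        return np.array(
            [((y[:, sl.stop - 1] >= 0.5) == (lab == 1)).mean() for sl in self.window_slices]
        )


def train_sliding_baselines(
    kind: str,
    trials: TrialSet | np.ndarray,
    labels: np.ndarray | None = None,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
    window_len: int = 30,
    config: TrainConfig | None = None,
    svm_kernel: str = "rbf",
) -> SlidingBaseline:
    """Train independent per-window classifiers.

    ``kind``: 'independent_rnn_s1', 'independent_rnn_s2' (fresh RNN per
    window, zero initial hidden state) or 'svm' (SVC on the flattened
    ``[#trials, #timepoints * #channels]`` window array).
    """
    if kind not in {"independent_rnn_s1", "independent_rnn_s2", "svm"}:
        raise ValidationError(f"unknown sliding baseline kind {kind!r}")
    if isinstance(trials, TrialSet):
        X_all, y_all = trials.data, trials.labels
    else:
        X_all, y_all = _as_array(trials), np.asarray(labels)
    n, T, _ = X_all.shape
    if train_idx is None:
        train_idx = np.arange(n)
    if window_len < 1 or window_len > T:
        raise ValidationError(f"window_len must be in [1, {T}], got {window_len}")
    slices = [slice(s, min(s + window_len, T)) for s in range(0, T, window_len)]
    models: list[object] = []
    cfg = config or TrainConfig(epochs=200, hidden_size=32)
    for w_i, sl in enumerate(slices):
        Xw = X_all[:, sl]
        if kind == "svm":
            clf = SVC(kernel=svm_kernel)
            clf.fit(Xw[train_idx].reshape(len(train_idx), -1), y_all[train_idx])
            models.append(clf)
        else:
            sub = dataclasses.replace(
                cfg, strategy="s1" if kind.endswith("s1") else "s2",
                seed=cfg.seed + w_i,
            )
            res = train_model(sub, Xw, y_all.astype(np.float64), train_idx, val_idx)
            models.append(res.params)
    return SlidingBaseline(kind=kind, window_slices=slices, models=models)
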