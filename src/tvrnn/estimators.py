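"""Scikit-learn style estimators over the trial-tensor decoders.

All estimators take ``X`` of shape ``[trials, time, channels]`` and binary
``y``, follow the fit/predict/predict_proba contract with
``get_params``/``set_params`` from :class:`~sklearn.base.BaseEstimator`,
and expose the full per-time-point output through
``predict_proba_trajectory``.  ``predict`` reads the final time point (the
whole-sequence class call).

An internal stratified validation split (``validation_rate``) monitors
over-fitting: the kept weights are the epoch with the lowest validation
loss.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import _transformer as _tf
from .data import ValidationError
from .models import _as_array, rnn_forward, tvrnn_forward
from .training import TrainConfig, train_model, train_sliding_baselines


class _TrajectoryClassifier(ClassifierMixin, BaseEstimator):
    """Shared fitting plumbing for the trajectory decoders."""

    def _check_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = _as_array(X)
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if fitted and X.shape[2] != self.n_channels_:
            raise ValidationError(
                f"X has {X.shape[2]} channels, fit saw {self.n_channels_}"
            )
        return X

    def _check_y(self, y: np.ndarray, n: int) -> np.ndarray:
        y = np.asarray(y)
        if y.shape != (n,):
            raise ValidationError(f"y must have shape ({n},), got {y.shape}")
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all() or len(classes) != 2:
            raise ValidationError("y must contain both binary classes 0 and 1")
        return y.astype(np.float64)

    def _split(self, y: np.ndarray):
        rng_seed = self.random_state or 0
        idx = np.arange(len(y))
        if self.validation_rate and 0 < self.validation_rate < 1:
            train, val = train_test_split(
                idx, test_size=self.validation_rate, stratify=y,
                random_state=rng_seed,
            )
            return np.sort(train), np.sort(val)
        return idx, idx

    def _config(self, strategy: str) -> TrainConfig:
        return TrainConfig(
            strategy=strategy,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            seed=self.random_state or 0,
            hidden_size=getattr(self, "hidden_size", 64),
            window_size=getattr(self, "window_size", 30),
            warm_start=getattr(self, "warm_start_s1", False),
            d_model=getattr(self, "d_model", 64),
            n_layers=getattr(self, "n_layers", 2),
            n_heads=getattr(self, "n_heads", 4),
            d_ff=getattr(self, "d_ff", 128),
            dropout=getattr(self, "dropout", 0.1),
        )

    # --- shared inference ----------------------------------------------
    def predict_proba_trajectory(self, X: np.ndarray) -> np.ndarray:
        """[trials, T] probability of class 1 at every time point."""
        check_is_fitted(self, "model_")
        X = self._check_X(X, fitted=True)
        return self._forward(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        yT = self.predict_proba_trajectory(X)[:, -1]
        return np.column_stack([1.0 - yT, yT])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class at the final time point (tie at 0.5 -> class 1)."""
        yT = self.predict_proba_trajectory(X)[:, -1]
        return self.classes_[(yT >= 0.5).astype(int)]

    def _fit_common(self, X, y, strategy: str):
        X = self._check_X(X)
        yv = self._check_y(y, X.shape[0])
        self.classes_ = np.array([0, 1])
        self.n_channels_ = X.shape[2]
        self.n_timepoints_ = X.shape[1]
        train_idx, val_idx = self._split(yv)
        res = train_model(self._config(strategy), X, yv, train_idx, val_idx)
        self.model_ = res.params
        self.final_model_ = res.final_params
        self.trace_ = res.trace
        self.history_ = res.history
        return self


class RNNClassifier(_TrajectoryClassifier):
    """Static-weight recurrent decoder.

    Parameters
    ----------
    strategy : {'s1', 's2'}
        Loss placement: final output only ('s1') or every time point ('s2').
    hidden_size : int, default 64
    epochs, learning_rate, batch_size : Adam/BPTT settings
        (defaults 1000, 1e-4, 64).
    validation_rate : float, default 0.2
        Fraction held out internally to pick the best-validation epoch.
    random_state : int or None
    """

    def __init__(self, strategy: str = "s1", hidden_size: int = 64,
                 epochs: int = 1000, learning_rate: float = 1e-4,
                 batch_size: int = 64, validation_rate: float = 0.2,
                 random_state: int | None = 0):
        self.strategy = strategy
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_rate = validation_rate
        self.random_state = random_state

    def fit(self, X, y):
        if self.strategy not in {"s1", "s2"}:
            raise ValidationError(f"strategy must be 's1' or 's2', got {self.strategy!r}")
        return self._fit_common(X, y, self.strategy)

    def _forward(self, X):
        return rnn_forward(self.model_, X, return_hidden=False).y


class TVRNNClassifier(_TrajectoryClassifier):
    """Time-varying recurrent decoder: one weight bundle per window of
    ``window_size`` time points, trained end-to-end under the aggregate
    (every-time-point) loss; the hidden state is continuous across windows.

    ``warm_start_s1=True`` first trains a static RNN under the final-output
    loss and copies it into every window before the joint optimization.
    """

    def __init__(self, window_size: int = 30, hidden_size: int = 64,
                 epochs: int = 1000, learning_rate: float = 1e-4,
                 batch_size: int = 64, validation_rate: float = 0.2,
                 warm_start_s1: bool = False, random_state: int | None = 0):
        self.window_size = window_size
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_rate = validation_rate
        self.warm_start_s1 = warm_start_s1
        self.random_state = random_state

    def fit(self, X, y):
        return self._fit_common(X, y, "tv")

    def _forward(self, X):
        return tvrnn_forward(self.model_, X, return_hidden=False).y

    @property
    def n_windows_(self) -> int:
        check_is_fitted(self, "model_")
        return self.model_.n_windows


class CausalTransformerClassifier(_TrajectoryClassifier):
    """Causally masked self-attention baseline with a per-time-point
    sigmoid head; the output at time t depends only on inputs up to t."""

    def __init__(self, d_model: int = 64, n_layers: int = 2, n_heads: int = 4,
                 d_ff: int = 128, dropout: float = 0.1,
                 epochs: int = 1000, learning_rate: float = 1e-4,
                 batch_size: int = 64, validation_rate: float = 0.2,
                 random_state: int | None = 0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.d_ff = d_ff
        self.dropout = dropout
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_rate = validation_rate
        self.random_state = random_state

    def fit(self, X, y):
        return self._fit_common(X, y, "transformer")

    def _forward(self, X):
        return _tf.transformer_forward(self.model_, X)[0]


class SlidingWindowClassifier(_TrajectoryClassifier):
    """Independent per-window baselines: a fresh standard RNN (zero initial
    hidden state) or an SVM on the flattened window, one per block of
    ``window_len`` time points.  Window accuracy is read at the last time
    point of each window."""

    def __init__(self, kind: str = "svm", window_len: int = 30,
                 hidden_size: int = 32, epochs: int = 200,
                 learning_rate: float = 1e-4, batch_size: int = 64,
                 validation_rate: float = 0.2, svm_kernel: str = "rbf",
                 random_state: int | None = 0):
        self.kind = kind
        self.window_len = window_len
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.validation_rate = validation_rate
        self.svm_kernel = svm_kernel
        self.random_state = random_state

    def fit(self, X, y):
        X = self._check_X(X)
        yv = self._check_y(y, X.shape[0])
        self.classes_ = np.array([0, 1])
        self.n_channels_ = X.shape[2]
        self.n_timepoints_ = X.shape[1]
        train_idx, val_idx = self._split(yv)
        cfg = TrainConfig(
            epochs=self.epochs, learning_rate=self.learning_rate,
            batch_size=self.batch_size, seed=self.random_state or 0,
            hidden_size=self.hidden_size,
        )
        self.model_ = train_sliding_baselines(
            self.kind, X, yv, train_idx, val_idx,
            window_len=self.window_len, config=cfg, svm_kernel=self.svm_kernel,
        )
        return self

    def _forward(self, X):
        return self.model_.predict_proba_trajectory(X)

    def window_accuracies(self, X, y) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.window_accuracies(self._check_X(X, fitted=True), y)
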