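"""Gradient-stability and mechanism diagnostics.

During backpropagation through time, the gradient reaching time t' from
time t is proportional to the product of recurrent weight matrices over the
horizon t - t'.  With a single static matrix the product is a matrix power,
so its norm grows or shrinks exponentially at a rate set by that one
matrix; with per-window matrices drawn from the same distribution the
growth rate is bounded by the mean log-norm, which (by submultiplicativity
and Jensen) cannot exceed the static rate.  These functions measure the
effect empirically: induced-1-norm Jacobian products, a fitted Lyapunov
exponent, a Monte-Carlo comparison of static vs time-varying ensembles,
plus the weight-distance maps and output-trajectory summaries used to
inspect what a trained time-varying decoder learned.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .data import TrialSet, ValidationError
from .models import OutputTrajectory, RNNParams, TVWeights, rnn_forward, tvrnn_forward


def induced_1_norm(M: np.ndarray) -> float:
    """Max absolute column sum; submultiplicative, so products are bounded
    by products of norms."""
    return float(np.abs(M).sum(axis=0).max())


@dataclasses.dataclass
class JacobianProductSummary:
    horizons: np.ndarray
    log_norms: np.ndarray  # log ||prod W|| at each horizon
    lyapunov: float  # least-squares slope of log-norm vs horizon
    spectral_radius: float | None  # of the static matrix (None for window lists)
    norm_kind: str = "induced_1"


def jacobian_product_norms(
    weights: np.ndarray | Sequence[np.ndarray],
    horizons: Sequence[int] | None = None,
) -> JacobianProductSummary:
    """Norms of recurrent-weight products over increasing horizons.

    ``weights`` is either one square matrix (static: product = matrix power)
    or a sequence of square matrices applied cyclically (time-varying).  The
    Lyapunov exponent is the least-squares slope of log-norm against
    horizon.
    """
    static = isinstance(weights, np.ndarray) and np.asarray(weights).ndim == 2
    if static:
        mats = [np.asarray(weights, dtype=np.float64)]
    else:
        mats = [np.asarray(w, dtype=np.float64) for w in weights]
    n = mats[0].shape[0]
    for m in mats:
        if m.ndim != 2 or m.shape != (n, n):
            raise ValidationError(f"weights must be square matrices of one size, got {m.shape}")
    if horizons is None:
        horizons = np.arange(1, 51)
    horizons = np.asarray(sorted(horizons), dtype=int)
    if horizons.min() < 1:
        raise ValidationError("horizons must be >= 1")
    log_norms = np.empty(len(horizons))
    prod = np.eye(n)
    h_done = 0
    out_i = 0
    for h in range(1, horizons.max() + 1):
        prod = mats[(h - 1) % len(mats)] @ prod
        h_done = h
        if out_i < len(horizons) and horizons[out_i] == h:
            log_norms[out_i] = np.log(induced_1_norm(prod))
            out_i += 1
    if len(horizons) > 1:
        lam = float(np.polyfit(horizons, log_norms, 1)[0])
    else:
        lam = float(log_norms[0] / horizons[0])
    rho = float(np.abs(np.linalg.eigvals(mats[0])).max()) if static else None
    return JacobianProductSummary(
        horizons=horizons, log_norms=log_norms, lyapunov=lam, spectral_radius=rho
    )


@dataclasses.dataclass
class GradientInequalityReport:
    """Monte-Carlo comparison of static vs time-varying product norms."""

    horizon: int
    n_draws: int
    static_log_norms: np.ndarray
    tv_log_norms: np.ndarray
    mean_static: float
    mean_tv: float
    p_value: float  # one-sided: mean TV < mean static

    @property
    def tv_slower(self) -> bool:
        return self.mean_tv <= self.mean_static


def gradient_inequality_experiment(
    n_hidden: int = 32,
    horizon: int = 50,
    n_draws: int = 200,
    n_windows: int | None = None,
    scale: float | None = None,
    seed: int = 0,
) -> GradientInequalityReport:
    """Sample static and per-step recurrent matrices i.i.d. from the same
    Gaussian ensemble (entries N(0, scale^2/N), default scale 1.2) and
    compare log product norms over the horizon.

    Per draw, the static product is W^horizon for one matrix W; the
    time-varying product chains ``n_windows`` (default: horizon, i.e. fresh
    weights each step) independent matrices.  Reports a one-sided test that
    the time-varying mean log-norm is below the static one.
    """
    if n_draws < 2:
        raise ValidationError("need n_draws >= 2")
    rng = np.random.default_rng(seed)
    if scale is None:
        scale = 1.2
    sd = scale / np.sqrt(n_hidden)
    n_windows = n_windows or horizon
    stat = np.empty(n_draws)
    tv = np.empty(n_draws)
    for d in range(n_draws):
        W = rng.normal(0.0, sd, (n_hidden, n_hidden))
        prod = np.eye(n_hidden)
        for _ in range(horizon):
            prod = W @ prod
        stat[d] = np.log(induced_1_norm(prod))
        mats = rng.normal(0.0, sd, (n_windows, n_hidden, n_hidden))
        prod = np.eye(n_hidden)
        for h in range(horizon):
            prod = mats[min(h * n_windows // horizon, n_windows - 1)] @ prod
        tv[d] = np.log(induced_1_norm(prod))
    if np.allclose(stat, tv):
        p = 1.0
    else:
        p = float(stats.ttest_ind(tv, stat, alternative="less", equal_var=False).pvalue)
    return GradientInequalityReport(
        horizon=horizon, n_draws=n_draws, static_log_norms=stat, tv_log_norms=tv,
        mean_static=float(stat.mean()), mean_tv=float(tv.mean()), p_value=p,
    )


@dataclasses.dataclass
class WeightDistanceMap:
    """Pairwise Frobenius distances between windows, per weight kind."""

    input_weights: np.ndarray  # [n_windows, n_windows]
    recurrent_weights: np.ndarray
    output_weights: np.ndarray


def weight_distance_map(tv: TVWeights) -> WeightDistanceMap:
    """Euclidean (Frobenius) distance between the per-window input,
    recurrent, and output weight matrices."""
    if tv.n_windows < 2:
        raise ValidationError("need at least 2 windows")
    maps = []
    for attr in ("W_x", "W_h", "W_y"):
        mats = [getattr(w, attr).ravel() for w in tv.windows]
        K = len(mats)
        D = np.zeros((K, K))
        for i in range(K):
            for j in range(i + 1, K):
                D[i, j] = D[j, i] = np.linalg.norm(mats[i] - mats[j])
        maps.append(D)
    return WeightDistanceMap(*maps)


@dataclasses.dataclass
class TrajectorySummary:
    """Class-conditional mean +/- sd of the output across time."""

    mean_behavior: np.ndarray  # [T]
    sd_behavior: np.ndarray
    mean_control: np.ndarray
    sd_control: np.ndarray
    divergence_index: int | None  # first t with |mean diff| > multiplier * pooled sd
    divergence_multiplier: float


def output_trajectories(
    model,
    trials: TrialSet,
    divergence_multiplier: float = 1.0,
) -> TrajectorySummary:
    """Average output of each class across time with a divergence time:
    the first time point where the class means separate by more than
    ``divergence_multiplier`` pooled standard deviations."""
    if isinstance(model, RNNParams):
        traj: OutputTrajectory = rnn_forward(model, trials, return_hidden=False)
    elif isinstance(model, TVWeights):
        traj = tvrnn_forward(model, trials, return_hidden=False)
    else:
        raise ValidationError(f"unsupported model type {type(model).__name__}")
    y = traj.y
    beh = trials.labels == 1
    ctl = trials.labels == 0
    if not beh.any() or not ctl.any():
        raise ValidationError("both classes must be present")
    m1, s1 = y[beh].mean(axis=0), y[beh].std(axis=0)
    m0, s0 = y[ctl].mean(axis=0), y[ctl].std(axis=0)
    pooled = np.sqrt(0.5 * (s1**2 + s0**2))
    gap = np.abs(m1 - m0) > divergence_multiplier * np.maximum(pooled, 1e-12)
    div = int(np.argmax(gap)) if gap.any() else None
    return TrajectorySummary(
        mean_behavior=m1, sd_behavior=s1, mean_control=m0, sd_control=s0,
        divergence_index=div, divergence_multiplier=divergence_multiplier,
    )
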