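"""Evaluation of temporal decoding: per-time-point accuracy across CV folds,
area under the accuracy curve (AUAC), and the earliest decoding time (EDT).

Temporal accuracy at time t is the fold-mean of
``(TP + TN) / (TP + TN + FP + FN)`` from the thresholded outputs at t.
AUAC integrates (accuracy - chance) over a time span in seconds
(trapezoidal; negative excursions are not clipped).  EDT is the earliest
time point from which decoding stays significantly above chance at every
time point up to behavior onset, using a one-tailed one-sample t-test over
the per-fold accuracies with Benjamini-Hochberg correction across time.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ValidationError


@dataclasses.dataclass
class TemporalAccuracyCurve:
    """Per-time-point, per-fold decoding accuracy with its chance level."""

    per_fold_accuracy: np.ndarray  # [K, T]
    chance_level: float
    time_axis_seconds: np.ndarray  # [T], strictly increasing
    confusion: np.ndarray | None = None  # [K, T, 4] = TP, TN, FP, FN

    def __post_init__(self) -> None:
        self.per_fold_accuracy = np.atleast_2d(np.asarray(self.per_fold_accuracy, dtype=np.float64))
        self.time_axis_seconds = np.asarray(self.time_axis_seconds, dtype=np.float64)
        if self.per_fold_accuracy.shape[1] != len(self.time_axis_seconds):
            raise ValidationError("time axis length does not match accuracy array")
        if np.any(np.diff(self.time_axis_seconds) <= 0):
            raise ValidationError("time axis must be strictly increasing")
        if np.any((self.per_fold_accuracy < 0) | (self.per_fold_accuracy > 1)):
            raise ValidationError("accuracies must lie in [0, 1]")

    @property
    def accuracy(self) -> np.ndarray:
        """Mean accuracy across folds, [T]."""
        return self.per_fold_accuracy.mean(axis=0)

    @property
    def n_folds(self) -> int:
        return self.per_fold_accuracy.shape[0]


@dataclasses.dataclass
class EarlyDecodingResult:
    """EDT with the per-time-point test behind it.  ``edt_index`` /
    ``edt_seconds`` are None when no time point qualifies."""

    edt_index: int | None
    edt_seconds: float | None
    p_values: np.ndarray
    significant: np.ndarray  # BH-adjusted calls
    alpha: float


def temporal_accuracy(
    fold_probas: Sequence[np.ndarray],
    fold_labels: Sequence[np.ndarray],
    chance_level: float | None = None,
    time_axis_seconds: np.ndarray | None = None,
) -> TemporalAccuracyCurve:
    """Build the accuracy curve from per-fold output trajectories.

    ``fold_probas[k]`` is the [trials_k, T] sigmoid-output array for the
    k-th fold's test trials; thresholding at 0.5 (tie -> class 1) yields the
    confusion counts.  ``chance_level`` defaults to the majority-class
    fraction over all folds (0.5 when balanced).
    """
    K = len(fold_probas)
    if K < 2:
        raise ValidationError("need at least 2 folds")
    if len(fold_labels) != K:
        raise ValidationError("fold_probas and fold_labels length mismatch")
    T = fold_probas[0].shape[1]
    acc = np.empty((K, T))
    conf = np.empty((K, T, 4))
    all_labels = np.concatenate([np.asarray(l) for l in fold_labels])
    if all_labels.size == 0 or any(len(l) == 0 for l in fold_labels):
        raise ValidationError("empty fold")
    for k, (proba, lab) in enumerate(zip(fold_probas, fold_labels)):
        lab = np.asarray(lab)
        calls = proba >= 0.5
        pos = lab == 1
        tp = (calls & pos[:, None]).sum(axis=0)
        tn = (~calls & ~pos[:, None]).sum(axis=0)
        fp = (calls & ~pos[:, None]).sum(axis=0)
        fn = (~calls & pos[:, None]).sum(axis=0)
        conf[k] = np.stack([tp, tn, fp, fn], axis=-1)
        acc[k] = (tp + tn) / len(lab)
    if chance_level is None:
        p1 = (all_labels == 1).mean()
        chance_level = float(max(p1, 1.0 - p1))
    if time_axis_seconds is None:
        time_axis_seconds = np.arange(T, dtype=np.float64)
    return TemporalAccuracyCurve(
        per_fold_accuracy=acc,
        chance_level=float(chance_level),
        time_axis_seconds=time_axis_seconds,
        confusion=conf,
    )


def auac(
    curve: TemporalAccuracyCurve,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Trapezoidal integral of (accuracy - chance) over ``[t_start, t_end]``
    seconds (defaults: full curve).  Units: accuracy x seconds."""
    t = curve.time_axis_seconds
    if t_start is None:
        t_start = t[0]
    if t_end is None:
        t_end = t[-1]
    if not t_start < t_end:
        raise ValidationError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    mask = (t >= t_start) & (t <= t_end)
    if mask.sum() < 2:
        raise ValidationError("fewer than 2 curve points inside the span")
    return float(np.trapezoid(curve.accuracy[mask] - curve.chance_level, t[mask]))


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-up Benjamini-Hochberg rejections at level alpha."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def earliest_decoding_time(
    curve: TemporalAccuracyCurve,
    alpha: float = 0.05,
    t_zero_index: int | None = None,
    max_gaps: int = 0,
) -> EarlyDecodingResult:
    """Earliest time point t* such that decoding is significantly above
    chance at every time point in [t*, t_zero] (allowing at most
    ``max_gaps`` non-significant points, default none).

    Per time point, a one-sample one-tailed t-test of the K per-fold
    accuracies against the chance level (alternative: greater), then BH
    correction across all time points.  A zero-variance time point is
    assigned p = 0 when its mean beats chance and p = 1 otherwise.
    """
    acc = curve.per_fold_accuracy
    K, T = acc.shape
    if K < 2:
        raise ValidationError("t-test needs at least 2 folds")
    if t_zero_index is None:
        t_zero_index = T - 1
    if not 0 <= t_zero_index < T:
        raise ValidationError(f"t_zero_index {t_zero_index} outside curve")
    p = np.empty(T)
    sd = acc.std(axis=0)
    for t in range(T):
        if sd[t] == 0.0:
            p[t] = 0.0 if acc[0, t] > curve.chance_level else 1.0
        else:
            p[t] = stats.ttest_1samp(
                acc[:, t], curve.chance_level, alternative="greater"
            ).pvalue
    sig = benjamini_hochberg(p, alpha=alpha)
    edt = None
    gaps = 0
    # scan backwards from behavior onset; stop once too many gaps accumulate
    for t in range(t_zero_index, -1, -1):
        if sig[t]:
            edt = t
        else:
            gaps += 1
            if gaps > max_gaps:
                break
    if edt is not None and not sig[edt]:
        edt = None
    return EarlyDecodingResult(
        edt_index=edt,
        edt_seconds=None if edt is None else float(curve.time_axis_seconds[edt]),
        p_values=p,
        significant=sig,
        alpha=alpha,
    )
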