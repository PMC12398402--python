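"""Simulated chirp dataset with a built-in temporal distribution shift.

The generator emulates multi-channel neural recordings in which the class
signal strengthens towards behavior onset: each 'behavior' trial carries a
linear frequency sweep (chirp) with a linearly increasing amplitude on every
channel, each channel scaled by a distinct coefficient; 'control' trials are
behavior trials with their time indices randomly permuted, which preserves
the per-channel value distribution while destroying temporal order.  A
classifier therefore has to exploit temporal structure, and the
discriminative information grows across the trial — the distribution shift
that motivates time-varying decoders.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .data import TrialSet, ValidationError


@dataclasses.dataclass
class ChirpSpec:
    """Parameters of the simulated chirp dataset.

    Frequencies are in cycles per trial; amplitudes are in signal units.
    ``coeff_range`` is an open interval from which the per-channel
    multipliers are taken (evenly spaced by default, uniform random with
    ``random_coeffs=True``); all coefficients must be distinct.
    """

    n_channels: int = 10
    n_timepoints: int = 300
    n_trials: int = 2000
    coeff_range: tuple[float, float] = (1.0, 4.0)
    freq_start: float = 2.0
    freq_end: float = 30.0
    amp_start: float = 0.2
    amp_end: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    random_coeffs: bool = False
    noise_before_scaling: bool = False
    joint_shuffle: bool = True
    sampling_rate: float = 30.0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValidationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.n_timepoints < 2:
            raise ValidationError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if self.n_trials < 2 or self.n_trials % 2:
            raise ValidationError(
                f"n_trials must be even and >= 2 (balanced classes), got {self.n_trials}"
            )
        lo, hi = self.coeff_range
        if lo <= 0:
            raise ValidationError(f"coeff_range lower bound must be > 0, got {lo}")
        if hi <= lo:
            raise ValidationError(
                f"coeff_range must be a non-empty open interval, got ({lo}, {hi})"
            )
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def channel_coefficients(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Distinct per-channel multipliers inside the open ``coeff_range``."""
        lo, hi = self.coeff_range
        if self.random_coeffs:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            coeffs = lo + (hi - lo) * rng.random(self.n_channels)
        else:
            # interior grid points of the open interval: deterministic & distinct
            i = np.arange(1, self.n_channels + 1)
            coeffs = lo + (hi - lo) * i / (self.n_channels + 1)
        if len(np.unique(coeffs)) != self.n_channels:
            raise ValidationError("coeff_range too narrow: channel coefficients collide")
        return coeffs


def _chirp_phase(spec: ChirpSpec) -> np.ndarray:
    """Cumulative phase (cycles) of a linear frequency sweep over the trial."""
    tau = np.arange(spec.n_timepoints) / spec.n_timepoints  # in [0, 1)
    return spec.freq_start * tau + 0.5 * (spec.freq_end - spec.freq_start) * tau**2


def _amp_ramp(spec: ChirpSpec) -> np.ndarray:
    tau = np.arange(spec.n_timepoints) / (spec.n_timepoints - 1)
    return spec.amp_start + (spec.amp_end - spec.amp_start) * tau


def raw_behavior_trials(
    spec: ChirpSpec,
    n: int,
    rng: np.random.Generator,
    coeffs: np.ndarray | None = None,
) -> np.ndarray:
    """Noisy behavior-style trials, shape ``[n, T, R]``.

    Each trial: per channel r, ``coeff_r * sin(2*pi*(phase + phi)) * amp(t)``
    plus Gaussian noise of sd ``noise_sd``; phi is an independent uniform
    initial phase per trial.  With ``noise_before_scaling`` the noise enters
    before the channel coefficient multiplies the signal.
    """
    if coeffs is None:
        coeffs = spec.channel_coefficients(rng)
    phase = _chirp_phase(spec)
    amp = _amp_ramp(spec)
    phi = rng.random(n)  # initial phase in cycles
    # carrier: [n, T]
    carrier = np.sin(2.0 * math.pi * (phase[None, :] + phi[:, None])) * amp[None, :]
    clean = carrier[:, :, None] * coeffs[None, None, :]
    if spec.noise_sd == 0:
        return clean
    if spec.noise_before_scaling:
        noise = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_timepoints, 1))
        return (carrier[:, :, None] + noise) * coeffs[None, None, :]
    return clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)


def generate_chirp_trials(spec: ChirpSpec) -> TrialSet:
    """Generate the balanced chirp dataset.

    Returns a :class:`TrialSet` whose first ``n_trials/2`` trials are
    'behavior' (label 1) and the rest 'control' (label 0).  Controls are
    freshly generated behavior-style trials whose time indices were permuted
    (jointly across channels by default).  ``meta`` carries the spec, the
    control permutations (``control_permutations``, one row per control
    trial) and the pre-shuffle sources (``control_sources``) so the shuffle
    round-trips exactly.  Identical specs (including seed) yield identical
    datasets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    half = spec.n_trials // 2

    coeffs = spec.channel_coefficients(rng)
    behavior = raw_behavior_trials(spec, half, rng, coeffs)
    sources = raw_behavior_trials(spec, half, rng, coeffs)

    T = spec.n_timepoints
    controls = np.empty_like(sources)
    if spec.joint_shuffle:
        perms = np.empty((half, T), dtype=np.int64)
        for i in range(half):
            perms[i] = rng.permutation(T)
            controls[i] = sources[i, perms[i], :]
    else:
        perms = np.empty((half, spec.n_channels, T), dtype=np.int64)
        for i in range(half):
            for r in range(spec.n_channels):
                perms[i, r] = rng.permutation(T)
                controls[i, :, r] = sources[i, perms[i, r], r]

    data = np.concatenate([behavior, controls], axis=0)
    labels = np.concatenate([np.ones(half, dtype=np.int8), np.zeros(half, dtype=np.int8)])
    return TrialSet(
        data=data,
        labels=labels,
        sampling_rate=spec.sampling_rate,
        t_zero_index=T - 1,
        channel_names=[f"ch{r}" for r in range(spec.n_channels)],
        meta={
            "spec": dataclasses.asdict(spec),
            "control_permutations": perms,
            "control_sources": sources,
        },
    )


def stft_magnitude(
    trial_set: TrialSet,
    channel: int,
    window_len: int = 50,
    hop: int = 10,
    class_label: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude of one channel, averaged across trials
    of one class — the distribution-shift diagnostic.

    Only frames fully inside the signal are returned (no edge padding), so
    the spectral ridge of a chirp reads cleanly left to right.

    Returns ``(freqs_hz, frame_times_s, magnitude[freq, frame])``.
    """
    T = trial_set.n_timepoints
    if not -trial_set.n_channels <= channel < trial_set.n_channels:
        raise IndexError(
            f"channel {channel} out of range for {trial_set.n_channels} channels"
        )
    if not 1 <= window_len <= T:
        raise ValidationError(f"window_len must be in [1, {T}], got {window_len}")
    if hop < 1:
        raise ValidationError(f"hop must be >= 1, got {hop}")
    mask = trial_set.labels == class_label
    if not mask.any():
        raise ValidationError(f"no trials with label {class_label}")
    x = trial_set.data[mask, :, channel]  # [n, T]

    sft = ShortTimeFFT(
        hann(window_len, sym=False),
        hop=hop,
        fs=trial_set.sampling_rate,
        mfft=window_len,
    )
    S = sft.stft(x, axis=-1)  # [n, freq, frames]
    mag = np.abs(S).mean(axis=0)
    p0 = sft.lower_border_end[1]
    p1 = sft.upper_border_begin(T)[1]
    frame_times = sft.t(T)[p0:p1]
    return sft.f, frame_times, mag[:, p0:p1]
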