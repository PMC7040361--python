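"""Canonical hemodynamic response function and task-locked model input.

The canonical HRF (cHRF) is a linear combination of three gamma-density
lobes: a negative early lobe (the initial dip), the positive main response,
and a negative late undershoot,

    h(t) = sum_j  A_j * t**(alpha_j - 1) * beta_j**alpha_j * exp(-beta_j t) / Gamma(alpha_j)

with time in seconds. Convolving h with the binary stimulation boxcar s(k)
yields the desired HRF (dHRF) u(k), the exogenous input of the brain-activity
model used for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "HrfParams",
    "StimulusSequence",
    "DhrfSeries",
    "canonical_hrf",
    "stimulus_boxcar",
    "desired_hrf",
]


@dataclass(frozen=True)
class HrfParams:
    """Three-gamma cHRF parameters.

    Defaults give a ~5 s main peak with an initial dip in the first two
    seconds and a late undershoot: amplitudes (-1.5, 7, -2), shapes
    (1.5, 6, 16), scales (1, 1, 1) s^-1.
    """

    amplitudes: tuple[float, float, float] = (-1.5, 7.0, -2.0)
    shapes: tuple[float, float, float] = (1.5, 6.0, 16.0)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.amplitudes) != 3 or len(self.shapes) != 3 or len(self.scales) != 3:
            raise ValueError("HrfParams requires exactly three gamma components")
        if any(a <= 0 for a in self.shapes):
            raise ValueError(f"shape parameters must be > 0, got {self.shapes}")
        if any(b <= 0 for b in self.scales):
            raise ValueError(f"scale parameters must be > 0, got {self.scales}")


@dataclass(frozen=True)
class StimulusSequence:
    """Binary task indicator s(k) on a uniform sampling grid."""

    values: np.ndarray
    fs: float
    blocks: tuple[tuple[float, float], ...] = ()  # (task_start_s, task_len_s)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("stimulus values must be binary 0/1")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", v.astype(float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DhrfSeries:
    """Desired HRF u(k): cHRF convolved with the stimulation boxcar."""

    values: np.ndarray
    fs: float
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.values)


def canonical_hrf(params: HrfParams, duration_s: float, fs: float) -> np.ndarray:
    """Sample the three-gamma cHRF at t = n/fs for n = 0..floor(duration*fs)-1.

    Each lobe is A_j * t**(a_j-1) * b_j**a_j * exp(-b_j*t) / Gamma(a_j),
    evaluated in log-space for numerical stability at large shape values.
    """
    if not isinstance(params, HrfParams):
        params = HrfParams(*params)
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(np.floor(duration_s * fs))
    t = np.arange(n) / fs
    h = np.zeros(n)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)
    for a_j, alpha_j, beta_j in zip(params.amplitudes, params.shapes, params.scales):
        log_term = (alpha_j - 1) * logt + alpha_j * np.log(beta_j) - beta_j * t - gammaln(alpha_j)
        term = np.where(np.isneginf(log_term), 0.0, np.exp(log_term))
        if alpha_j < 1:  # t^(alpha-1) diverges at t=0
            term[t == 0] = np.inf
        elif alpha_j == 1:
            term[t == 0] = beta_j
        h += a_j * term
    return h


def stimulus_boxcar(
    task_s: float,
    rest_s: float,
    n_trials: int,
    fs: float,
    *,
    start_s: float = 0.0,
) -> StimulusSequence:
    """Build the boxcar for n_trials of (task_s task + rest_s rest).

    Trials are concatenated blocks of floor((task_s+rest_s)*fs) samples; the
    first floor(task_s*fs) samples of each trial are task (s=1), the rest 0.
    An optional leading rest of floor(start_s*fs) samples precedes trial 1.
    With the study paradigm (6 trials of 10 s task + 20 s rest at 9.19 Hz)
    each trial is 275 samples, a session 1650.
    """
    if task_s < 0 or rest_s < 0 or start_s < 0:
        raise ValueError("durations must be nonnegative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_trials < 0:
        raise ValueError("n_trials must be nonnegative")
    n_task = int(np.floor(task_s * fs))
    n_trial = int(np.floor((task_s + rest_s) * fs))
    n_start = int(np.floor(start_s * fs))
    n = n_start + n_trials * n_trial
    s = np.zeros(n)
    blocks = []
    for i in range(n_trials):
        k0 = n_start + i * n_trial
        s[k0 : k0 + n_task] = 1.0
        blocks.append((k0 / fs, task_s))
    return StimulusSequence(values=s, fs=fs, blocks=tuple(blocks))


def stimulus_from_blocks(
    blocks: list[tuple[float, float]], n_samples: int, fs: float
) -> StimulusSequence:
    """Boxcar from explicit (task_start_s, task_len_s) blocks on an n-sample grid."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    ordered = sorted(blocks)
    for (s0, l0), (s1, _) in zip(ordered, ordered[1:]):
        if s0 + l0 > s1:
            raise ValueError(f"overlapping task blocks at {s1:.3f} s")
    t = np.arange(n_samples) / fs
    s = np.zeros(n_samples)
    for t0, length in ordered:
        s[(t >= t0) & (t < t0 + length)] = 1.0
    return StimulusSequence(values=s, fs=fs, blocks=tuple(ordered))


def desired_hrf(
    h: np.ndarray, s: StimulusSequence, *, normalize: bool = True, fs: float | None = None
) -> DhrfSeries:
    """Convolve the sampled cHRF with the stimulus: u(k) = sum_l h(l) s(k-l).

    The causal convolution is truncated to the stimulus length. With
    ``normalize`` the result is scaled to unit peak magnitude (a no-op on an
    all-zero u), so predictor coefficients absorb the response amplitude.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("cHRF must be nonempty")
    if fs is not None and not np.isclose(fs, s.fs):
        raise ValueError(f"sampling-rate mismatch: cHRF at {fs} Hz, stimulus at {s.fs} Hz")
    u = np.convolve(h, s.values)[: len(s)]
    normalized = False
    if normalize:
        peak = np.max(np.abs(u)) if u.size else 0.0
        if peak > 0:
            u = u / peak
            normalized = True
    return DhrfSeries(values=u, fs=s.fs, normalized=normalized)
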