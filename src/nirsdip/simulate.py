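"""Synthetic multi-channel fNIRS recordings with the finger-tapping paradigm.

Emulates the statistical structure the predictor and dip detector assume:
task-locked responses shaped by the three-gamma cHRF (including the
initial-dip lobe), sinusoidal physiological noise (cardiac ~1 Hz, Mayer
~0.1 Hz, respiration ~0.25 Hz), slow linear drift, and additive Gaussian
noise, sampled at 9.19 Hz over two sessions of six 30 s trials (10 s task +
20 s rest) preceded by a 30 s resting baseline, on a 36-channel montage.

The generated record is a pure function of (config, seed): every channel
and noise component draws from an independent ``numpy`` generator spawned
deterministically from the master seed via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hrf import HrfParams, canonical_hrf, desired_hrf, stimulus_boxcar
from .record import FnirsRecord, Paradigm

__all__ = [
    "SinusoidSpec",
    "NoiseParams",
    "ChannelSpec",
    "SimulationConfig",
    "generate_noise",
    "generate_channel",
    "generate_dataset",
    "dip_kernel",
]

#: Channel ids marked active in the default 36-channel montage: the motor
#: cortex channels that dominate dip detection in finger-tapping montages.
DEFAULT_ACTIVE_CHANNELS = (17, 18, 21, 29, 33)


@dataclass(frozen=True)
class SinusoidSpec:
    amplitude: float
    frequency_hz: float
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Physiological + instrumental noise model.

    Amplitudes are in signal units relative to a unit-peak hemodynamic
    response; frequencies sit in the standard physiological bands.
    ``random_phases`` draws each sinusoid's phase uniformly per channel so
    channels are not phase-locked to each other.
    """

    cardiac: SinusoidSpec = field(default_factory=lambda: SinusoidSpec(0.05, 1.0))
    mayer: SinusoidSpec = field(default_factory=lambda: SinusoidSpec(0.1, 0.1))
    respiration: SinusoidSpec = field(default_factory=lambda: SinusoidSpec(0.05, 0.25))
    gaussian_sd: float = 0.1
    drift_slope: float = 0.002  # units/s
    random_phases: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be nonnegative")


@dataclass(frozen=True)
class ChannelSpec:
    """Per-channel response parameters.

    Active channels carry a task response of amplitude ``hbo_gain`` plus an
    extra initial-dip component of magnitude ``dip_gain``; non-active
    channels have zero gains and carry noise only. ΔHbR mirrors ΔHbO at
    ``hbr_gain`` (canonically a negative fraction, default −0.3·hbo_gain).
    """

    channel: int
    active: bool
    hbo_gain: float = 0.0
    hbr_gain: float = 0.0
    dip_gain: float = 0.0
    onset_jitter_s: float = 0.0

    def __post_init__(self) -> None:
        if self.active and self.hbo_gain == 0:
            raise ValueError("active channels need a nonzero hbo_gain")
        if not self.active and self.hbo_gain != 0:
            raise ValueError("non-active channels must have hbo_gain 0")


def default_channel_spec(channel: int, active: bool) -> ChannelSpec:
    if not active:
        return ChannelSpec(channel=channel, active=False)
    return ChannelSpec(
        channel=channel, active=True, hbo_gain=1.0, hbr_gain=-0.3, dip_gain=0.4
    )


@dataclass(frozen=True)
class SimulationConfig:
    fs: float = 9.19
    n_channels: int = 36
    active_channels: tuple[int, ...] = DEFAULT_ACTIVE_CHANNELS
    paradigm: Paradigm = field(default_factory=Paradigm)
    hrf: HrfParams = field(default_factory=HrfParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    hbo_gain: float = 1.0
    hbr_gain_ratio: float = -0.3
    dip_gain: float = 0.4
    hrf_duration_s: float = 30.0

    def channel_specs(self) -> list[ChannelSpec]:
        specs = []
        for ch in range(1, self.n_channels + 1):
            if ch in self.active_channels:
                specs.append(
                    ChannelSpec(
                        channel=ch,
                        active=True,
                        hbo_gain=self.hbo_gain,
                        hbr_gain=self.hbr_gain_ratio * self.hbo_gain,
                        dip_gain=self.dip_gain,
                    )
                )
            else:
                specs.append(ChannelSpec(channel=ch, active=False))
        return specs


def generate_noise(
    params: NoiseParams, n: int, fs: float, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Sum of the three physiological sinusoids, linear drift and Gaussian noise."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    out = np.zeros(n)
    for sinusoid in (params.cardiac, params.mayer, params.respiration):
        phase = sinusoid.phase_rad
        if params.random_phases:
            phase = phase + rng.uniform(0, 2 * np.pi)
        out += sinusoid.amplitude * np.sin(2 * np.pi * sinusoid.frequency_hz * t + phase)
    out += params.drift_slope * t
    if params.gaussian_sd > 0:
        out += rng.normal(0.0, params.gaussian_sd, size=n)
    return out


def dip_kernel(params: HrfParams, duration_s: float, fs: float, *, window_s: float = 2.5) -> np.ndarray:
    """Initial-dip kernel: the negative early lobe of the three-gamma cHRF.

    The cHRF's own first lobe (A_1 < 0) is clipped to its negative part over
    the first ``window_s`` seconds and normalized to unit trough depth, so
    the dip injected into synthetic channels has exactly the shape the
    response model assumes rather than an ad-hoc one.
    """
    h = canonical_hrf(params, duration_s, fs)
    t = np.arange(len(h)) / fs
    early = np.where((t <= window_s) & (h < 0), h, 0.0)
    depth = np.max(np.abs(early))
    if depth > 0:
        early = early / depth
    return early


def _response_components(config: SimulationConfig):
    """dHRF u(k) and dip component d(k) on the full record grid."""
    p = config.paradigm
    n0 = p.rest_prefix_samples(config.fs)
    n_total = n0 + p.n_sessions * p.samples_per_session(config.fs)
    s_one = stimulus_boxcar(p.task_s, p.rest_s, p.n_trials, config.fs)
    h = canonical_hrf(config.hrf, config.hrf_duration_s, config.fs)
    u_one = desired_hrf(h, s_one, normalize=True).values
    d_one = np.convolve(dip_kernel(config.hrf, config.hrf_duration_s, config.fs), s_one.values)[
        : len(s_one)
    ]
    depth = np.max(np.abs(d_one))
    if depth > 0:
        d_one = d_one / depth
    u = np.zeros(n_total)
    d = np.zeros(n_total)
    for sess in range(p.n_sessions):
        k0 = n0 + sess * p.samples_per_session(config.fs)
        u[k0 : k0 + len(u_one)] = u_one
        d[k0 : k0 + len(d_one)] = d_one
    return u, d


def generate_channel(
    spec: ChannelSpec,
    u: np.ndarray,
    dip: np.ndarray,
    noise: NoiseParams,
    fs: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """One channel's (ΔHbO, ΔHbR) pair.

    ΔHbO = hbo_gain·u + dip_gain·d + noise; ΔHbR = hbr_gain·u mirrored-dip +
    independent noise. ``u`` is the unit-peak dHRF, ``dip`` the unit-trough
    dip component (negative during early task). The mirrored HbR dip is
    scaled by |hbr_gain/hbo_gain| so dip polarity is positive in ΔHbR.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_hbo, seed_hbr = ss.spawn(2)
    ratio = abs(spec.hbr_gain / spec.hbo_gain) if spec.hbo_gain else 0.3
    hbo = spec.hbo_gain * u + spec.dip_gain * dip + generate_noise(noise, len(u), fs, seed_hbo)
    hbr = (
        spec.hbr_gain * u
        - ratio * spec.dip_gain * dip
        + generate_noise(noise, len(u), fs, seed_hbr)
    )
    return hbo, hbr


def generate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> FnirsRecord:
    """Full synthetic record: resting prefix + sessions, all channels."""
    config = config or SimulationConfig()
    u, d = _response_components(config)
    specs = config.channel_specs()
    master = np.random.SeedSequence(seed)
    channel_seeds = master.spawn(len(specs))
    hbo = np.empty((len(u), len(specs)))
    hbr = np.empty((len(u), len(specs)))
    for j, (spec, ch_seed) in enumerate(zip(specs, channel_seeds)):
        hbo[:, j], hbr[:, j] = generate_channel(spec, u, d, config.noise, config.fs, ch_seed)
    return FnirsRecord(
        hbo=hbo,
        hbr=hbr,
        fs=config.fs,
        channels=[s.channel for s in specs],
        paradigm=config.paradigm,
        active_channels=[s.channel for s in specs if s.active],
        seed=seed,
    )
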