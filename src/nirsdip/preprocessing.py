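"""Band-limiting of fNIRS series.

Cardiac (~1 Hz), respiratory (~0.25 Hz) and low-frequency drift components
are removed with a cascade of 4th-order Butterworth low-pass (0.15 Hz) and
high-pass (0.01 Hz) sections. The default is causal (forward-only)
filtering, since the downstream predictor is an online algorithm; a
zero-phase mode (forward-backward) is available for offline work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .record import FnirsRecord

__all__ = ["FilterSpec", "bandpass", "bandpass_series"]


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 0.01
    high_hz: float = 0.15
    order: int = 4
    mode: str = "causal"  # "causal" | "zero-phase"

    def __post_init__(self) -> None:
        if self.low_hz <= 0 or self.high_hz <= 0:
            raise ValueError("cutoffs must be positive")
        if self.low_hz >= self.high_hz:
            raise ValueError("low cutoff must be below high cutoff")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cutoff {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


def _sections(spec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    lp = signal.butter(spec.order, spec.high_hz, btype="lowpass", fs=fs, output="sos")
    hp = signal.butter(spec.order, spec.low_hz, btype="highpass", fs=fs, output="sos")
    return lp, hp


def bandpass_series(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Filter one series through the low-pass then high-pass cascade."""
    spec = spec or FilterSpec()
    spec.validate_for(fs)
    lp, hp = _sections(spec, fs)
    sos = np.vstack([lp, hp])
    x = np.asarray(x, dtype=float)
    if spec.mode == "causal":
        return signal.sosfilt(sos, x, axis=0)
    return signal.sosfiltfilt(sos, x, axis=0)


def bandpass(record: FnirsRecord, spec: FilterSpec | None = None) -> FnirsRecord:
    """Filter every channel/chromophore independently; length is preserved."""
    spec = spec or FilterSpec()
    return FnirsRecord(
        hbo=bandpass_series(record.hbo, record.fs, spec),
        hbr=bandpass_series(record.hbr, record.fs, spec),
        fs=record.fs,
        channels=list(record.channels),
        paradigm=record.paradigm,
        active_channels=list(record.active_channels),
        seed=record.seed,
    )
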