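"""Multi-channel fNIRS record container and plain-text I/O.

A record holds index-aligned ΔHbO / ΔHbR series per channel (arbitrary
concentration units), the sampling rate, and segment annotations (resting
prefix and task sessions). On disk it is a wide CSV (``time_s``,
``ch01_hbo``, ``ch01_hbr``, ...) plus a JSON sidecar carrying the sampling
rate, paradigm, segment boundaries and generation seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Paradigm", "FnirsRecord", "read_record", "write_record"]


@dataclass(frozen=True)
class Paradigm:
    """Block-design experiment timing: trials of task followed by rest."""

    task_s: float = 10.0
    rest_s: float = 20.0
    n_trials: int = 6
    n_sessions: int = 2
    rest_prefix_s: float = 30.0

    def __post_init__(self) -> None:
        if self.task_s < 0 or self.rest_s < 0 or self.rest_prefix_s < 0:
            raise ValueError("durations must be nonnegative")
        if self.n_trials < 0 or self.n_sessions < 0:
            raise ValueError("counts must be nonnegative")

    def samples_per_trial(self, fs: float) -> int:
        return int(np.floor((self.task_s + self.rest_s) * fs))

    def samples_per_session(self, fs: float) -> int:
        return self.n_trials * self.samples_per_trial(fs)

    def rest_prefix_samples(self, fs: float) -> int:
        return int(np.floor(self.rest_prefix_s * fs))

    def task_samples(self, fs: float) -> int:
        return int(np.floor(self.task_s * fs))

    def to_dict(self) -> dict:
        return {
            "task_s": self.task_s,
            "rest_s": self.rest_s,
            "n_trials": self.n_trials,
            "n_sessions": self.n_sessions,
            "rest_prefix_s": self.rest_prefix_s,
        }


@dataclass
class FnirsRecord:
    """Aligned ΔHbO/ΔHbR time series for a set of channels.

    ``hbo`` and ``hbr`` are (n_samples, n_channels) arrays; ``channels`` are
    1-based channel ids. ``active_channels`` records which channels carry a
    task response (known for synthetic data, unknown for measured data).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channels: list[int]
    paradigm: Paradigm = field(default_factory=Paradigm)
    active_channels: list[int] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("ΔHbO and ΔHbR arrays must have equal shape")
        if self.hbo.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.hbo.shape[1]} series columns but {len(self.channels)} channel ids"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    # ---- segment bookkeeping -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def _col(self, channel: int) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"channel {channel} not in record") from None

    def series(self, channel: int, chromophore: str) -> np.ndarray:
        arr = {"hbo": self.hbo, "hbr": self.hbr}[chromophore]
        return arr[:, self._col(channel)]

    def resting_slice(self) -> slice:
        return slice(0, self.paradigm.rest_prefix_samples(self.fs))

    def session_slice(self, session: int) -> slice:
        """1-based session index into the sample axis."""
        if not 1 <= session <= self.paradigm.n_sessions:
            raise ValueError(f"session must be in 1..{self.paradigm.n_sessions}")
        n0 = self.paradigm.rest_prefix_samples(self.fs)
        per = self.paradigm.samples_per_session(self.fs)
        return slice(n0 + (session - 1) * per, n0 + session * per)

    def trial_slice(self, session: int, trial: int) -> slice:
        """1-based trial index within a session."""
        if not 1 <= trial <= self.paradigm.n_trials:
            raise ValueError(f"trial must be in 1..{self.paradigm.n_trials}")
        s = self.session_slice(session)
        per = self.paradigm.samples_per_trial(self.fs)
        return slice(s.start + (trial - 1) * per, s.start + trial * per)

    def stimulus(self) -> np.ndarray:
        """Binary task indicator aligned to the record's samples."""
        from .hrf import stimulus_boxcar

        p = self.paradigm
        s = np.zeros(self.n_samples)
        one = stimulus_boxcar(p.task_s, p.rest_s, p.n_trials, self.fs).values
        n0 = p.rest_prefix_samples(self.fs)
        for sess in range(p.n_sessions):
            k0 = n0 + sess * p.samples_per_session(self.fs)
            s[k0 : k0 + len(one)] = one
        return s

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time_s": self.time_s}
        for j, ch in enumerate(self.channels):
            cols[f"ch{ch:02d}_hbo"] = self.hbo[:, j]
            cols[f"ch{ch:02d}_hbr"] = self.hbr[:, j]
        return pd.DataFrame(cols)


def write_record(record: FnirsRecord, path: str | Path) -> None:
    """Write ``path`` (wide CSV) and ``path.with_suffix('.json')`` sidecar."""
    path = Path(path)
    record.to_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "fs_hz": record.fs,
        "channels": record.channels,
        "active_channels": record.active_channels,
        "seed": record.seed,
        "paradigm": record.paradigm.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_record(path: str | Path) -> FnirsRecord:
    """Read a record written by :func:`write_record`; lossless to 1e-12."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}: paradigm and sampling rate are required"
        )
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("record CSV is missing required column 'time_s'")
    channels = list(meta["channels"])
    hbo = np.empty((len(df), len(channels)))
    hbr = np.empty((len(df), len(channels)))
    for j, ch in enumerate(channels):
        for kind, arr in (("hbo", hbo), ("hbr", hbr)):
            col = f"ch{ch:02d}_{kind}"
            if col not in df.columns:
                raise ValueError(f"record CSV is missing required column '{col}'")
            arr[:, j] = df[col].to_numpy()
    return FnirsRecord(
        hbo=hbo,
        hbr=hbr,
        fs=float(meta["fs_hz"]),
        channels=channels,
        paradigm=Paradigm(**meta["paradigm"]),
        active_channels=list(meta.get("active_channels", [])),
        seed=meta.get("seed"),
    )
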