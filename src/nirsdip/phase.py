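"""Vector-phase analysis of (ΔHbO, ΔHbR) trajectories and initial-dip detection.

The phase plane uses ΔHbO and ΔHbR as orthogonal components; rotating the
axes 45° counterclockwise gives cerebral blood volume and oxygen exchange,

    ΔCBV = (ΔHbO + ΔHbR)/√2,    ΔCOE = (ΔHbR − ΔHbO)/√2.

Eight phases partition the plane by the signs/orderings of the four
indices; Phases 1–5 reflect rising ΔHbR or ΔCOE (initial-dip phases) and
Phases 6–8 the conventional hemodynamic response. Two calibrated threshold
circles gate detection: the inner radius r1 bounds resting-state
fluctuation, the outer radius r2 = r1 + 0.3(p1 + SD) bounds genuine dips
from large task fluctuations (p1 and SD are the peak and standard deviation
of the trial-averaged ΔHbO of the most-active channel). An initial dip is
called when the trajectory sits in Phases 3–5 between the circles early in
the task and later hands over to the hemodynamic-response Phases 7/8
without ever escaping the outer circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .record import FnirsRecord

__all__ = [
    "ThresholdCircles",
    "DipEvent",
    "DipParams",
    "to_cbv_coe",
    "magnitude_phase",
    "classify_phase",
    "select_most_active_channel",
    "calibrate_thresholds",
    "detect_dips",
    "VectorPhaseModel",
    "DipDetectionResults",
]

_SQRT2 = np.sqrt(2.0)

#: Phases whose presence opens a dip candidate (the detection rule names 3-5;
#: the full initial-dip family is 1-5 and can be configured via DipParams).
DIP_PHASES = frozenset({3, 4, 5})
HR_PHASES = frozenset({7, 8})


def to_cbv_coe(hbo, hbr):
    """45° counterclockwise rotation of (ΔHbO, ΔHbR)."""
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    return (hbo + hbr) / _SQRT2, (hbr - hbo) / _SQRT2


def magnitude_phase(hbo, hbr):
    """Vector magnitude and full-quadrant angle (degrees in (-180, 180]).

    The angle satisfies atan2(ΔHbR, ΔHbO) = atan(ΔCOE/ΔCBV) + 45° on the
    branch where ΔCBV > 0. It is NaN at the origin, where it is undefined.
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    mag = np.hypot(hbo, hbr)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(hbr, hbo))
    ang = np.where(mag == 0, np.nan, ang)
    if np.ndim(mag) == 0:
        return float(mag), float(ang)
    return mag, ang


def classify_phase(hbo: float, hbr: float) -> int | None:
    """Phase index 1..8, or None on a boundary (any tie) or at the origin.

    Phase 1: 0 < ΔHbR < ΔHbO, ΔCOE < 0 < ΔCBV    Phase 5: ΔHbO < ΔHbR < 0, ΔCBV < 0 < ΔCOE
    Phase 2: 0 < ΔHbO < ΔHbR, 0 < ΔCOE < ΔCBV    Phase 6: ΔHbR < ΔHbO < 0, ΔCBV < ΔCOE < 0
    Phase 3: ΔHbO < 0 < ΔHbR, 0 < ΔCBV < ΔCOE    Phase 7: ΔHbR < 0 < ΔHbO, ΔCOE < ΔCBV < 0
    Phase 4: ΔHbO < 0 < ΔHbR, ΔCBV < 0 < ΔCOE    Phase 8: ΔHbR < 0 < ΔHbO, ΔCOE < 0 < ΔCBV
    """
    cbv, coe = to_cbv_coe(hbo, hbr)
    predicates = {
        1: 0 < hbr < hbo and coe < 0 < cbv,
        2: 0 < hbo < hbr and 0 < coe < cbv,
        3: hbo < 0 < hbr and 0 < cbv < coe,
        4: hbo < 0 < hbr and cbv < 0 < coe,
        5: hbo < hbr < 0 and cbv < 0 < coe,
        6: hbr < hbo < 0 and cbv < coe < 0,
        7: hbr < 0 < hbo and coe < cbv < 0,
        8: hbr < 0 < hbo and coe < 0 < cbv,
    }
    hits = [ph for ph, ok in predicates.items() if ok]
    if len(hits) == 1:
        return hits[0]
    if len(hits) > 1:  # the eight predicate sets are mutually exclusive
        raise AssertionError(f"phase predicates overlap at ({hbo}, {hbr}): {hits}")
    return None


def classify_phases(hbo: np.ndarray, hbr: np.ndarray) -> np.ndarray:
    """Vectorized phase classification; 0 encodes 'none' (boundary/origin)."""
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    cbv, coe = to_cbv_coe(hbo, hbr)
    out = np.zeros(hbo.shape, dtype=int)
    conds = [
        (1, (0 < hbr) & (hbr < hbo) & (coe < 0) & (0 < cbv)),
        (2, (0 < hbo) & (hbo < hbr) & (0 < coe) & (coe < cbv)),
        (3, (hbo < 0) & (0 < hbr) & (0 < cbv) & (cbv < coe)),
        (4, (hbo < 0) & (0 < hbr) & (cbv < 0) & (0 < coe)),
        (5, (hbo < hbr) & (hbr < 0) & (cbv < 0) & (0 < coe)),
        (6, (hbr < hbo) & (hbo < 0) & (cbv < coe) & (coe < 0)),
        (7, (hbr < 0) & (0 < hbo) & (coe < cbv) & (cbv < 0)),
        (8, (hbr < 0) & (0 < hbo) & (coe < 0) & (0 < cbv)),
    ]
    for idx, mask in conds:
        out[mask] = idx
    return out


@dataclass(frozen=True)
class ThresholdCircles:
    """Calibrated detection radii with their provenance."""

    r1: float
    r2: float
    p1: float | None = None
    sd: float | None = None
    channel: int | None = None

    def __post_init__(self) -> None:
        if self.r1 < 0 or self.r2 < self.r1:
            raise ValueError("radii must satisfy 0 <= r1 <= r2")


@dataclass(frozen=True)
class DipParams:
    """Detection windows, in seconds from task onset.

    A candidate can open in (0, candidate_window_s]; it is confirmed by a
    transition into the hemodynamic-response phases at or after
    confirm_after_s. ``dip_phases`` defaults to the detection rule's {3,4,5}
    and can be widened to the full initial-dip family {1..5}.
    """

    candidate_window_s: float = 4.0
    confirm_after_s: float = 2.0
    search_until_s: float | None = None  # default: end of trial
    dip_phases: frozenset = DIP_PHASES


@dataclass
class DipEvent:
    channel: int
    trial: int
    detection_time_s: float
    phase: int
    confirmed: bool
    rejection_reason: str | None = None
    confirm_time_s: float | None = None

    @property
    def detection_time_display(self) -> float:
        """Truncated to 2 decimals, the convention used in reports."""
        return float(np.trunc(self.detection_time_s * 100) / 100)


def select_most_active_channel(record: FnirsRecord, *, session: int = 1) -> int:
    """Channel maximizing max(first-trial ΔHbO) - max(resting ΔHbO); ties -> lowest id."""
    rest = record.resting_slice()
    if rest.stop - rest.start == 0:
        raise ValueError("record has no resting segment")
    trial1 = record.trial_slice(session, 1)
    best_ch, best_diff = None, -np.inf
    for ch in record.channels:
        hbo = record.series(ch, "hbo")
        diff = float(hbo[trial1].max() - hbo[rest].max())
        if diff > best_diff:  # strict: first (lowest id) wins ties
            best_ch, best_diff = ch, diff
    return best_ch


def calibrate_thresholds(
    record: FnirsRecord,
    channel: int | None = None,
    *,
    session: int = 1,
    r1_channel: int | None = None,
) -> ThresholdCircles:
    """Dual-circle calibration from the resting segment and training session.

    r1 is the maximum resting-state vector magnitude on ``r1_channel``
    (default: the most-active channel); p1 and SD are the peak and standard
    deviation of the across-trials average ΔHbO trace of the most-active
    channel over the training session; r2 = r1 + 0.3 (p1 + SD).
    """
    rest = record.resting_slice()
    if rest.stop - rest.start == 0:
        raise ValueError("record has no resting segment to calibrate r1")
    if channel is None:
        channel = select_most_active_channel(record, session=session)
    if r1_channel is None:
        r1_channel = channel
    hbo_r = record.series(r1_channel, "hbo")[rest]
    hbr_r = record.series(r1_channel, "hbr")[rest]
    r1 = float(np.max(np.hypot(hbo_r, hbr_r)))
    per = record.paradigm.samples_per_trial(record.fs)
    trials = np.stack(
        [
            record.series(channel, "hbo")[record.trial_slice(session, t)]
            for t in range(1, record.paradigm.n_trials + 1)
        ]
    )
    avg = trials.mean(axis=0)
    p1 = float(avg.max())
    sd = float(avg.std(ddof=1))
    r2 = r1 + 0.3 * (p1 + sd)
    return ThresholdCircles(r1=r1, r2=max(r2, r1), p1=p1, sd=sd, channel=channel)


def detect_dips(
    hbo: np.ndarray,
    hbr: np.ndarray,
    fs: float,
    circles: ThresholdCircles,
    params: DipParams | None = None,
    *,
    channel: int = 0,
    trial: int = 0,
) -> list[DipEvent]:
    """Dual-threshold dip detection on one trial-aligned trajectory.

    ``hbo``/``hbr`` start at the task onset (t = 0). A candidate opens at the
    first sample in a dip phase with r1 < |p| <= r2 inside the candidate
    window; exceeding r2 inside the window rejects it as a false dip;
    a transition to Phase 7/8 at t >= confirm_after_s confirms it.
    """
    params = params or DipParams()
    hbo = np.asarray(hbo, dtype=float)
    hbr = np.asarray(hbr, dtype=float)
    t = np.arange(len(hbo)) / fs
    mag = np.hypot(hbo, hbr)
    phases = classify_phases(hbo, hbr)

    open_idx = None
    for k in range(len(t)):
        if t[k] <= 0 or t[k] > params.candidate_window_s:
            continue
        if phases[k] in params.dip_phases and circles.r1 < mag[k] <= circles.r2:
            open_idx = k
            break
    if open_idx is None:
        return []
    event = DipEvent(
        channel=channel,
        trial=trial,
        detection_time_s=float(t[open_idx]),
        phase=int(phases[open_idx]),
        confirmed=False,
    )
    # in-window escape above r2 voids the candidate
    window = (t > 0) & (t <= params.candidate_window_s)
    if np.any(mag[window] > circles.r2):
        event.rejection_reason = "false_dip"
        return [event]
    until = params.search_until_s if params.search_until_s is not None else t[-1]
    after = (t >= params.confirm_after_s) & (t <= until)
    hr_hits = np.where(after & np.isin(phases, list(HR_PHASES)))[0]
    if hr_hits.size:
        event.confirmed = True
        event.confirm_time_s = float(t[hr_hits[0]])
    else:
        event.rejection_reason = "no_hr_transition"
    return [event]


# --------------------------------------------------------------------------
# Model / Results façade
# --------------------------------------------------------------------------


class VectorPhaseModel:
    """Dip detection over a record (or predicted trajectories).

    Calibrates the dual threshold circles on the calibration record's
    resting segment and training session, then scans every test-session
    trial of the analysis channels. ``trajectories`` may override the
    signals scanned (e.g. q-step-ahead predictions aligned to the test
    session) while calibration still comes from the measured record.
    """

    def __init__(
        self,
        record: FnirsRecord,
        *,
        params: DipParams | None = None,
        train_session: int = 1,
        test_session: int = 2,
        channels: list[int] | None = None,
        circles: ThresholdCircles | None = None,
        per_channel_r1: bool = True,
    ) -> None:
        self.record = record
        self.params = params or DipParams()
        self.train_session = train_session
        self.test_session = test_session
        self.channels = channels or (record.active_channels or record.channels)
        self.circles = circles
        self.per_channel_r1 = per_channel_r1

    def circles_for(self, channel: int) -> ThresholdCircles:
        if self.circles is not None:
            return self.circles
        most_active = select_most_active_channel(self.record, session=self.train_session)
        r1_channel = channel if self.per_channel_r1 else most_active
        return calibrate_thresholds(
            self.record, most_active, session=self.train_session, r1_channel=r1_channel
        )

    def fit(
        self,
        trajectories: dict[int, tuple[np.ndarray, np.ndarray]] | None = None,
    ) -> "DipDetectionResults":
        """Detect dips per (channel, trial) of the test session.

        ``trajectories`` maps channel id -> (hbo, hbr) aligned to the test
        session; default is the record's measured series.
        """
        task_n = self.record.paradigm.task_samples(self.record.fs)
        per = self.record.paradigm.samples_per_trial(self.record.fs)
        sess = self.record.session_slice(self.test_session)
        events: list[DipEvent] = []
        for ch in self.channels:
            circles = self.circles_for(ch)
            if trajectories is not None:
                hbo_s, hbr_s = trajectories[ch]
            else:
                hbo_s = self.record.series(ch, "hbo")[sess]
                hbr_s = self.record.series(ch, "hbr")[sess]
            for trial in range(1, self.record.paradigm.n_trials + 1):
                k0 = (trial - 1) * per
                hbo_t = hbo_s[k0 : k0 + per]
                hbr_t = hbr_s[k0 : k0 + per]
                events.extend(
                    detect_dips(
                        hbo_t, hbr_t, self.record.fs, circles, self.params,
                        channel=ch, trial=trial,
                    )
                )
        return DipDetectionResults(self, events)


class DipDetectionResults:
    """Detected dip events with tabular and text summaries."""

    def __init__(self, model: VectorPhaseModel, events: list[DipEvent]) -> None:
        self.model = model
        self.events = events

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "channel": e.channel,
                "trial": e.trial,
                "detection_time_s": e.detection_time_display,
                "phase": e.phase,
                "confirmed": e.confirmed,
                "reason": e.rejection_reason or "",
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=["channel", "trial", "detection_time_s", "phase", "confirmed", "reason"],
        )

    def confirmed(self) -> list[DipEvent]:
        return [e for e in self.events if e.confirmed]

    def detection_time(self, channel: int, trial: int) -> float | None:
        for e in self.events:
            if e.channel == channel and e.trial == trial and e.confirmed:
                return e.detection_time_s
        return None

    def summary(self) -> str:
        conf = self.confirmed()
        lines = [
            "initial-dip detection",
            "=" * 40,
            f"channels scanned: {len(self.model.channels)}   "
            f"trials/channel: {self.model.record.paradigm.n_trials}",
            f"candidates: {len(self.events)}   confirmed: {len(conf)}",
        ]
        if conf:
            times = [e.detection_time_display for e in conf]
            lines.append(
                f"detection time (s): min {min(times):.2f}  "
                f"median {float(np.median(times)):.2f}  max {max(times):.2f}"
            )
        lines.append("=" * 40)
        return "\n".join(lines)
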