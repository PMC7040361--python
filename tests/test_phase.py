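"""Vector-phase geometry, threshold calibration and dip detection rules."""

import numpy as np
import pytest

from nirsdip import (
    DipParams,
    FnirsRecord,
    Paradigm,
    ThresholdCircles,
    calibrate_thresholds,
    classify_phase,
    detect_dips,
    magnitude_phase,
    select_most_active_channel,
    to_cbv_coe,
)
from nirsdip.phase import classify_phases

SQ2 = np.sqrt(2.0)


class TestRotation:
    @pytest.mark.parametrize(
        "hbo, hbr, cbv, coe",
        [
            (0.0, 0.0, 0.0, 0.0),
            (1.0, 1.0, SQ2, 0.0),
            (1.0, 0.0, 1 / SQ2, -1 / SQ2),
        ],
    )
    def test_hand_values(self, hbo, hbr, cbv, coe):
        got = to_cbv_coe(hbo, hbr)
        assert got[0] == pytest.approx(cbv, abs=1e-15)
        assert got[1] == pytest.approx(coe, abs=1e-15)

    def test_rotation_is_isometry(self):
        rng = np.random.default_rng(6)
        hbo = rng.normal(size=10_000)
        hbr = rng.normal(size=10_000)
        cbv, coe = to_cbv_coe(hbo, hbr)
        np.testing.assert_allclose(
            np.hypot(cbv, coe), np.hypot(hbo, hbr), atol=1e-12
        )


class TestMagnitudePhase:
    def test_pythagorean_magnitude(self):
        mag, _ = magnitude_phase(3.0, 4.0)
        assert mag == 5.0

    def test_diagonal_angle(self):
        _, ang = magnitude_phase(1.0, 1.0)
        assert ang == pytest.approx(45.0)

    def test_rotation_identity_hand_value(self):
        # atan(1/2) = 26.565...; atan(COE/CBV) + 45 = atan(-1/3) + 45, equal
        _, ang = magnitude_phase(2.0, 1.0)
        cbv, coe = to_cbv_coe(2.0, 1.0)
        assert ang == pytest.approx(np.degrees(np.arctan(1 / 2)))
        assert ang == pytest.approx(np.degrees(np.arctan(coe / cbv)) + 45.0)

    def test_rotation_identity_property(self):
        rng = np.random.default_rng(7)
        hbo = rng.normal(size=2000)
        hbr = rng.normal(size=2000)
        cbv, coe = to_cbv_coe(hbo, hbr)
        keep = cbv > 1e-9  # branch where atan (not atan2) applies
        _, ang = magnitude_phase(hbo[keep], hbr[keep])
        ident = np.degrees(np.arctan(coe[keep] / cbv[keep])) + 45.0
        diff = (ang - ident + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(diff, 0.0, atol=1e-9)

    def test_origin_angle_is_undefined(self):
        mag, ang = magnitude_phase(0.0, 0.0)
        assert mag == 0.0
        assert np.isnan(ang)


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "hbo, hbr, phase",
        [
            (2.0, 1.0, 1),
            (1.0, 2.0, 2),
            (-0.3, 1.0, 3),   # CBV > 0 branch of the HbO<0<HbR quadrant
            (-1.0, 0.5, 4),
            (-2.0, -1.0, 5),
            (-1.0, -2.0, 6),
            (1.0, -2.0, 7),
            (2.0, -1.0, 8),
        ],
    )
    def test_examples_cover_all_phases(self, hbo, hbr, phase):
        assert classify_phase(hbo, hbr) == phase

    @pytest.mark.parametrize(
        "hbo, hbr",
        [(0.0, 0.0), (1.0, 1.0), (1.0, 0.0), (0.0, 1.0), (-1.0, 1.0), (2.0, 2.0)],
    )
    def test_boundaries_classify_as_none(self, hbo, hbr):
        assert classify_phase(hbo, hbr) is None

    def test_partition_exclusive_and_exhaustive_off_boundaries(self):
        rng = np.random.default_rng(8)
        hbo = rng.normal(size=5000)
        hbr = rng.normal(size=5000)
        # random continuous points avoid ties almost surely
        scalar = np.array([classify_phase(a, b) for a, b in zip(hbo, hbr)])
        assert np.all((scalar >= 1) & (scalar <= 8))
        vector = classify_phases(hbo, hbr)
        np.testing.assert_array_equal(vector, scalar)

    def test_initial_dip_phases_have_positive_coe(self):
        rng = np.random.default_rng(9)
        hbo = rng.normal(size=2000)
        hbr = rng.normal(size=2000)
        phases = classify_phases(hbo, hbr)
        _, coe = to_cbv_coe(hbo, hbr)
        assert np.all(coe[np.isin(phases, (3, 4, 5))] > 0)


def _toy_record(gains, fs=10.0, noise=None, seed=0, dip=False):
    """Tiny record: 30 s rest prefix + 2 sessions of 6 trials, response ~ boxcar."""
    paradigm = Paradigm(task_s=10, rest_s=20, n_trials=6, n_sessions=2, rest_prefix_s=30)
    n = paradigm.rest_prefix_samples(fs) + 2 * paradigm.samples_per_session(fs)
    t = np.arange(n) / fs
    from nirsdip import FnirsRecord

    rng = np.random.default_rng(seed)
    hbo = np.zeros((n, len(gains)))
    hbr = np.zeros((n, len(gains)))
    stim = FnirsRecord(
        hbo=np.zeros((n, 1)), hbr=np.zeros((n, 1)), fs=fs, channels=[1], paradigm=paradigm
    ).stimulus()
    # smooth ramped response so the peak sits mid-task
    from scipy.ndimage import uniform_filter1d

    resp = uniform_filter1d(stim, size=int(5 * fs))
    for j, g in enumerate(gains):
        hbo[:, j] = g * resp
        hbr[:, j] = -0.3 * g * resp
        if noise:
            hbo[:, j] += rng.normal(0, noise, n)
            hbr[:, j] += rng.normal(0, noise, n)
    return FnirsRecord(
        hbo=hbo, hbr=hbr, fs=fs, channels=list(range(1, len(gains) + 1)),
        paradigm=paradigm,
    )


class TestMostActiveChannel:
    def test_single_responding_channel_wins(self):
        rec = _toy_record([0.0, 0.0, 1.0, 0.0])
        assert select_most_active_channel(rec) == 3

    def test_tie_break_prefers_lowest_id(self):
        rec = _toy_record([0.0, 1.0, 0.0, 1.0])
        assert select_most_active_channel(rec) == 2

    def test_three_channel_gain_ordering(self):
        rec = _toy_record([0.5, 2.0, 1.0])
        assert select_most_active_channel(rec) == 2

    def test_missing_resting_segment_is_error(self):
        rec = _toy_record([1.0])
        rec.paradigm = Paradigm(rest_prefix_s=0.0)
        with pytest.raises(ValueError, match="resting"):
            select_most_active_channel(rec)


class TestCalibrateThresholds:
    def test_r1_is_max_resting_norm(self):
        rec = _toy_record([1.0])
        # overwrite the resting prefix with the three hand points
        rest = rec.resting_slice()
        rec.hbo[rest], rec.hbr[rest] = 0.0, 0.0
        rec.hbo[:3, 0] = [0.1, 0.0, 0.1]
        rec.hbr[:3, 0] = [0.0, 0.2, 0.1]
        circles = calibrate_thresholds(rec, channel=1)
        assert circles.r1 == pytest.approx(0.2)

    def test_r2_hand_arithmetic(self):
        # r2 = r1 + 0.3*(p1 + SD) = 0.2 + 0.3*1.1 = 0.53
        c = ThresholdCircles(r1=0.2, r2=0.2 + 0.3 * (1.0 + 0.1), p1=1.0, sd=0.1)
        assert c.r2 == pytest.approx(0.53)

    def test_all_zero_record_gives_zero_circles(self):
        rec = _toy_record([0.0, 0.0])
        circles = calibrate_thresholds(rec, channel=1)
        assert circles.r1 == 0.0
        assert circles.r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_at_least_r1_on_random_records(self):
        for seed in range(5):
            rec = _toy_record([1.0, 0.5, 0.0], noise=0.2, seed=seed)
            circles = calibrate_thresholds(rec)
            assert circles.r2 >= circles.r1 >= 0

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            ThresholdCircles(r1=0.5, r2=0.2)


def _hand_trajectory(fs=10.0, escape=False):
    """Scripted trial: dip phase (3) inside the circles at t=0.1 s, HR phase (8)
    from t=2.5 s; optional mid-window escape above r2."""
    n = int(6 * fs)
    t = np.arange(n) / fs
    hbo = np.zeros(n)
    hbr = np.zeros(n)
    in_dip = (t >= 0.1) & (t < 2.5)
    # phase 3: HbO < 0 < HbR with CBV > 0 -> |HbR| slightly above |HbO|
    hbo[in_dip], hbr[in_dip] = -0.2, 0.3
    hr = t >= 2.5
    hbo[hr], hbr[hr] = 0.4, -0.1  # phase 8
    if escape:
        k = np.argmin(np.abs(t - 1.0))
        hbo[k], hbr[k] = -2.0, 3.0  # same phase, far outside r2
    return hbo, hbr, t


class TestDetectDips:
    CIRCLES = ThresholdCircles(r1=0.2, r2=1.0)

    def test_quiescent_trajectory_yields_no_events(self):
        n = 60
        hbo = np.full(n, 0.05)
        hbr = np.full(n, 0.02)
        assert detect_dips(hbo, hbr, 10.0, self.CIRCLES) == []

    def test_hand_trajectory_confirmed_at_first_suprathreshold_sample(self):
        hbo, hbr, _ = _hand_trajectory()
        events = detect_dips(hbo, hbr, 10.0, self.CIRCLES)
        assert len(events) == 1
        e = events[0]
        assert e.confirmed
        assert e.detection_time_s == pytest.approx(0.1)
        assert e.phase == 3
        assert e.confirm_time_s == pytest.approx(2.5)

    def test_escape_above_r2_rejected_as_false_dip(self):
        hbo, hbr, _ = _hand_trajectory(escape=True)
        events = detect_dips(hbo, hbr, 10.0, self.CIRCLES)
        assert len(events) == 1
        assert not events[0].confirmed
        assert events[0].rejection_reason == "false_dip"

    def test_no_hr_transition_leaves_candidate_unconfirmed(self):
        n = 60
        hbo = np.full(n, -0.2)
        hbr = np.full(n, 0.3)  # stays in phase 3 forever
        events = detect_dips(hbo, hbr, 10.0, self.CIRCLES)
        assert len(events) == 1
        assert not events[0].confirmed
        assert events[0].rejection_reason == "no_hr_transition"

    def test_candidate_window_is_configurable(self):
        hbo, hbr, _ = _hand_trajectory()
        params = DipParams(candidate_window_s=0.05)  # window closes before entry
        assert detect_dips(hbo, hbr, 10.0, self.CIRCLES, params) == []

    def test_detection_time_display_truncates(self):
        hbo, hbr, _ = _hand_trajectory(fs=9.19)
        events = detect_dips(hbo, hbr, 9.19, self.CIRCLES)
        e = events[0]
        assert e.detection_time_display == np.trunc(e.detection_time_s * 100) / 100
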