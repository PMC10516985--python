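"""Tests for dark-frame event classification and parameter estimation."""

import numpy as np
import pytest

import spadkit as sk
from spadkit.calibration import (
    classify_events, estimate_afterpulse_map, estimate_crosstalk_map,
    estimate_dcr_map, invert_event_rates,
)
from spadkit.noise_model import BinaryFrameStack

from conftest import brute_force_classify


def _stack(frames):
    return BinaryFrameStack(frames=np.asarray(frames, dtype=np.uint8))


class TestClassifyEvents:
    def test_all_zero_stack(self):
        ev = classify_events(_stack(np.zeros((10, 4, 4))))
        assert ev.i_ap.sum() == 0 and ev.i_ct.sum() == 0

    def test_consecutive_fires_are_afterpulse(self):
        frames = np.zeros((6, 5, 5))
        frames[3, 2, 2] = frames[4, 2, 2] = 1
        ev = classify_events(_stack(frames))
        assert ev.i_ap.sum() == 1 and ev.i_ap[4, 2, 2] == 1
        assert ev.i_ct.sum() == 0

    def test_adjacent_fires_are_crosstalk(self):
        frames = np.zeros((3, 5, 5))
        frames[1, 2, 2] = frames[1, 2, 3] = 1
        ev = classify_events(_stack(frames))
        assert ev.i_ap.sum() == 0
        assert ev.i_ct[1, 2, 2] == 1 and ev.i_ct[1, 2, 3] == 1

    def test_priority_rule_prefers_afterpulse(self):
        frames = np.zeros((3, 5, 5))
        frames[1, 2, 2] = 1
        frames[2, 2, 2] = frames[2, 2, 3] = 1  # both consecutive and adjacent
        ev = classify_events(_stack(frames))
        assert ev.i_ap[2, 2, 2] == 1 and ev.i_ct[2, 2, 2] == 0
        assert ev.i_ct[2, 2, 3] == 1

    def test_single_frame_stack_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            classify_events(_stack(np.zeros((1, 4, 4))))

    def test_matches_brute_force_oracle_on_random_stacks(self, rng):
        for _ in range(25):
            frames = (rng.random((50, 8, 8)) < rng.uniform(0.02, 0.3)).astype(np.uint8)
            ev = classify_events(_stack(frames))
            i_ap, i_ct = brute_force_classify(frames)
            assert np.array_equal(ev.i_ap, i_ap)
            assert np.array_equal(ev.i_ct, i_ct)

    def test_disjointness_and_conservation(self, rng):
        frames = (rng.random((200, 10, 10)) < 0.2).astype(np.uint8)
        stack = _stack(frames)
        ev = classify_events(stack)
        assert not np.any(ev.i_ap & ev.i_ct)
        residual = frames.sum(axis=0) - ev.n_afterpulse - ev.n_crosstalk
        assert np.all(residual >= 0)
        assert np.all(ev.i_ap <= frames) and np.all(ev.i_ct <= frames)


class TestRawEstimators:
    def test_zero_events_give_zero_maps(self):
        stack = _stack(np.zeros((20, 4, 4)))
        ev = classify_events(stack)
        assert np.all(estimate_afterpulse_map(stack, ev) == 0)
        assert np.all(estimate_crosstalk_map(stack, ev) == 0)
        assert np.all(estimate_dcr_map(stack, ev, 20) == 0)

    def test_afterpulse_hand_count(self):
        # 10 isolated fires + one consecutive pair that adds 2 afterpulses:
        # place 12 clean-candidate frames so numerator/denominator = 2/10
        frames = np.zeros((40, 3, 3))
        for t in [0, 3, 6, 9, 12, 15, 18, 21, 24]:  # 9 isolated clean fires
            frames[t, 1, 1] = 1
        frames[30, 1, 1] = frames[31, 1, 1] = frames[32, 1, 1] = 1
        # fires at 30,31,32: 31 and 32 are afterpulse-classified, 30 is clean,
        # so the pixel has 10 clean fires and 2 afterpulses -> 0.2
        stack = _stack(frames)
        ev = classify_events(stack)
        p_ap = estimate_afterpulse_map(stack, ev)
        assert p_ap[1, 1] == pytest.approx(0.2)
        assert ev.n_afterpulse[1, 1] == 2

    def test_crosstalk_hand_count(self):
        frames = np.zeros((40, 3, 3))
        for t in range(0, 16, 2):  # 8 isolated clean fires
            frames[t, 1, 1] = 1
        frames[20, 1, 1] = frames[20, 1, 2] = 1  # crosstalk pair
        frames[24, 1, 1] = frames[24, 0, 1] = 1  # second crosstalk pair
        stack = _stack(frames)
        ev = classify_events(stack)
        p_ct = estimate_crosstalk_map(stack, ev)
        assert ev.n_crosstalk[1, 1] == 2
        assert p_ct[1, 1] == pytest.approx(2 / 8)

    def test_dcr_arithmetic(self):
        frames = np.zeros((6000, 2, 2))
        idx = np.arange(0, 6000, 200)  # 30 isolated fires
        frames[idx, 0, 0] = 1
        stack = _stack(frames)
        ev = classify_events(stack)
        dcr = estimate_dcr_map(stack, ev, 6000)
        assert dcr[0, 0] == pytest.approx(30 / 6000)

    def test_n_total_mismatch_rejected(self):
        stack = _stack(np.zeros((20, 3, 3)))
        ev = classify_events(stack)
        with pytest.raises(ValueError, match="n_total"):
            estimate_dcr_map(stack, ev, 19)

    def test_chance_coincidence_bias_is_bounded(self):
        # with p_ap = 0 the raw afterpulse ratio is biased upward by the
        # chance of two independent dark events in a row (~ the dark rate)
        calib = sk.SensorCalibration(pde=1.0, dcr=0.02, p_ap=0.0, p_ct=0.0,
                                     shape=(12, 12))
        stack = sk.simulate_dark_frames(calib, 30000, seed=9)
        ev = classify_events(stack)
        raw = estimate_afterpulse_map(stack, ev)
        dark_rate = 1 - np.exp(-0.02)
        assert 0 < raw.mean() < 2 * dark_rate


class TestCalibrateFromDark:
    def test_all_zero_stack_gives_zero_noise(self):
        calib = sk.calibrate_from_dark(_stack(np.zeros((100, 6, 6))))
        assert calib.dcr.max() == 0
        assert calib.p_ap.max() == 0 and calib.p_ct.max() == 0
        assert np.all(calib.pde == 1.0)

    def test_round_trip_recovery(self):
        true = sk.SensorCalibration(pde=1.0, dcr=0.008, p_ap=0.1, p_ct=0.02,
                                    shape=(24, 24))
        stack = sk.simulate_dark_frames(true, 30000, seed=12)
        rec = sk.calibrate_from_dark(stack)
        assert rec.dcr.mean() == pytest.approx(0.008, rel=0.1)
        assert rec.p_ap.mean() == pytest.approx(0.1, rel=0.1)
        assert rec.p_ct.mean() == pytest.approx(0.02, rel=0.2)

    def test_raw_mode_reproduces_ratio_estimators(self):
        true = sk.SensorCalibration(pde=1.0, dcr=0.01, p_ap=0.05, p_ct=0.0,
                                    shape=(10, 10))
        stack = sk.simulate_dark_frames(true, 5000, seed=13)
        ev = classify_events(stack)
        raw = sk.calibrate_from_dark(stack, debias=False)
        assert np.allclose(raw.p_ap, estimate_afterpulse_map(stack, ev))
        assert np.allclose(raw.p_ct, estimate_crosstalk_map(stack, ev))

    def test_standard_error_scales_as_inverse_sqrt_n(self):
        # per-pixel scatter of the DCR map should shrink like 1/sqrt(n)
        true = sk.SensorCalibration(pde=1.0, dcr=0.01, p_ap=0.0, p_ct=0.0,
                                    shape=(20, 20))
        stds = []
        for n in (2000, 8000):
            stack = sk.simulate_dark_frames(true, n, seed=21)
            rec = sk.calibrate_from_dark(stack)
            stds.append(rec.dcr.std())
        assert stds[0] / stds[1] == pytest.approx(2.0, rel=0.35)

    def test_inversion_handles_silent_pixels(self):
        d, a, c = invert_event_rates(np.zeros((4, 4)), np.zeros((4, 4)),
                                     np.zeros((4, 4)))
        assert not np.any(d) and not np.any(a) and not np.any(c)
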