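"""Unit and property tests for the SPAD forward noise model."""

import numpy as np
import pytest

import spadkit as sk
from spadkit.noise_model import FluxImage, SensorCalibration, TimingConfig


class TestDetectionProbability:
    @pytest.mark.parametrize(
        "eta, chi, expected",
        [
            (1.0, 0.0, 0.0),                      # no photons -> no detections
            (1.0, np.log(2.0), 0.5),              # closed form 1 - e^{-ln 2}
            (0.5, 2.0, 1.0 - np.exp(-1.0)),       # thinning: eta*chi = 1
        ],
    )
    def test_closed_form(self, eta, chi, expected):
        calib = SensorCalibration(pde=eta, dcr=0.0, p_ap=0.0, p_ct=0.0,
                                  shape=(4, 4))
        flux = FluxImage(np.full((4, 4), chi))
        assert sk.detection_probability(flux, calib) == pytest.approx(
            np.full((4, 4), expected), abs=1e-12)

    def test_monotone_in_flux_and_pde(self):
        calib_lo = SensorCalibration(pde=0.3, dcr=0.0, p_ap=0.0, p_ct=0.0,
                                     shape=(3, 3))
        calib_hi = SensorCalibration(pde=0.6, dcr=0.0, p_ap=0.0, p_ct=0.0,
                                     shape=(3, 3))
        p1 = sk.detection_probability(FluxImage(np.full((3, 3), 1.0)), calib_lo)
        p2 = sk.detection_probability(FluxImage(np.full((3, 3), 2.0)), calib_lo)
        p3 = sk.detection_probability(FluxImage(np.full((3, 3), 2.0)), calib_hi)
        assert np.all(p1 <= p2) and np.all(p2 <= p3)

    def test_shape_mismatch_and_negative_flux_error(self):
        calib = SensorCalibration.ideal((4, 4))
        with pytest.raises(ValueError, match="shape"):
            sk.detection_probability(FluxImage(np.zeros((3, 4))), calib)
        with pytest.raises(ValueError, match="non-negative"):
            FluxImage(np.full((4, 4), -0.1))


class TestSimulateFrames:
    def test_no_sources_gives_all_zero_stack(self):
        calib = SensorCalibration(pde=1.0, dcr=0.0, p_ap=0.7, p_ct=0.9,
                                  shape=(8, 8))
        stack = sk.simulate_frames(FluxImage.zeros((8, 8)), calib, 50, seed=1)
        assert stack.frames.sum() == 0

    def test_dark_rate_matches_closed_form(self):
        lam = 0.01
        calib = SensorCalibration(pde=1.0, dcr=lam, p_ap=0.0, p_ct=0.0,
                                  shape=(16, 16))
        n = 20000
        stack = sk.simulate_dark_frames(calib, n, seed=2)
        p = 1.0 - np.exp(-lam)
        se = np.sqrt(p * (1 - p) / (n * 16 * 16))
        assert abs(stack.frames.mean() - p) < 4 * se

    def test_same_seed_bit_identical(self, small_calib):
        a = sk.simulate_dark_frames(small_calib, 200, seed=7)
        b = sk.simulate_dark_frames(small_calib, 200, seed=7)
        assert np.array_equal(a.frames, b.frames)
        c = sk.simulate_dark_frames(small_calib, 200, seed=8)
        assert not np.array_equal(a.frames, c.frames)

    def test_afterpulse_run_length_matches_geometric_oracle(self):
        # a fire persists with p = p_ap + (1-p_ap)*p_dark; run length after
        # an initial fire is geometric with mean 1/(1-p)
        p_ap, lam = 0.5, -np.log(1 - 0.05)
        calib = SensorCalibration(pde=1.0, dcr=lam, p_ap=p_ap, p_ct=0.0,
                                  shape=(1, 1))
        stack = sk.simulate_dark_frames(calib, 120000, seed=3)
        x = stack.frames[:, 0, 0]
        # run lengths of consecutive ones
        padded = np.concatenate([[0], x, [0]])
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        runs = ends - starts
        p_cont = p_ap + (1 - p_ap) * 0.05
        expected = 1.0 / (1.0 - p_cont)
        assert runs.mean() == pytest.approx(expected, rel=0.1)

    def test_expected_rate_monotone_in_each_parameter(self):
        base = dict(pde=0.5, dcr=0.01, p_ap=0.1, p_ct=0.05)
        flux = FluxImage(np.full((8, 8), 0.5))

        def rate(**overrides):
            params = {**base, **overrides}
            calib = SensorCalibration(shape=(8, 8), **params)
            return sk.simulate_frames(flux, calib, 3000, seed=11).frames.mean()

        r0 = rate()
        assert rate(pde=0.9) > r0
        assert rate(dcr=0.05) > r0
        assert rate(p_ap=0.5) > r0
        assert rate(p_ct=0.3) > r0

    def test_crosstalk_couples_neighbors(self):
        # one hot pixel with high flux; crosstalk should light its neighbours
        chi = np.zeros((5, 5))
        chi[2, 2] = 50.0
        calib = SensorCalibration(pde=1.0, dcr=0.0, p_ap=0.0, p_ct=0.2,
                                  shape=(5, 5))
        stack = sk.simulate_frames(FluxImage(chi), calib, 4000, seed=4)
        rates = stack.firing_rate()
        assert rates[2, 2] > 0.99
        for yx in ((1, 2), (3, 2), (2, 1), (2, 3)):
            assert rates[yx] == pytest.approx(0.2, abs=0.03)
        assert rates[0, 0] == 0.0  # beyond the 4-neighbourhood, single pass


class TestAccumulate:
    def test_bit_depth_subframe_convention(self):
        stack = sk.BinaryFrameStack(frames=np.ones((1024, 2, 2), dtype=np.uint8))
        img = sk.accumulate(stack, 10)
        assert img.n_subframes == 1024
        assert np.all(img.counts == 1024)

    def test_all_ones_and_alternating(self):
        ones = sk.BinaryFrameStack(frames=np.ones((16, 3, 3), dtype=np.uint8))
        assert np.all(sk.accumulate(ones, 4).counts == 16)
        alt = np.zeros((16, 3, 3), dtype=np.uint8)
        alt[::2] = 1
        assert np.all(sk.accumulate(sk.BinaryFrameStack(frames=alt), 4).counts == 8)

    def test_insufficient_frames_error_names_required_count(self):
        stack = sk.BinaryFrameStack(frames=np.zeros((10, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError, match="16"):
            sk.accumulate(stack, 4)

    def test_linear_in_frame_concatenation(self, rng):
        frames = (rng.random((32, 4, 4)) < 0.4).astype(np.uint8)
        whole = sk.accumulate(sk.BinaryFrameStack(frames=frames), 5)
        a = sk.accumulate(sk.BinaryFrameStack(frames=frames[:16]), 4)
        b = sk.accumulate(sk.BinaryFrameStack(frames=frames[16:]), 4)
        assert np.array_equal(whole.counts, a.counts + b.counts)


class TestTiming:
    def test_reference_timing_is_valid(self):
        assert sk.validate_timing(TimingConfig(20, 60, 80, 160)) == []

    def test_overlapping_deadtime_warns(self):
        warnings = sk.validate_timing(TimingConfig(20, 60, 80, 50))
        assert len(warnings) == 1 and "deadtime" in warnings[0]

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            TimingConfig(0, 60, 80, 160)
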