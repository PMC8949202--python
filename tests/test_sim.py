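"""Simulator: transfer function, calibration grids, protocol recordings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glovecal as gc
from glovecal.sim import _raw_values, response


class TestSimulateRaw:
    def test_flat_hand_returns_r_flat(self, affine_truth, neutral_fit):
        assert gc.simulate_raw(0.0, affine_truth, neutral_fit) == 1201

    def test_full_flexion_adds_gain(self, affine_truth, neutral_fit):
        # g(1) = 1, so raw = r_flat + gain
        assert gc.simulate_raw(95.0, affine_truth, neutral_fit) == 2701

    def test_full_flexion_adds_gain_curved(self, curved_truth, neutral_fit):
        # saturating map still has g(1) = 1
        assert gc.simulate_raw(105.0 / 105 * 95, curved_truth, neutral_fit) == 2701

    def test_affine_when_curvature_zero(self, affine_truth, neutral_fit):
        angles = np.linspace(0, 95, 20)
        raws = _raw_values(angles, affine_truth, neutral_fit, None)
        fitted = np.polyval(np.polyfit(angles, raws, 1), angles)
        assert np.max(np.abs(raws - fitted)) <= 0.5  # quantization only

    def test_negative_angle_rejected(self, affine_truth, neutral_fit):
        with pytest.raises(ValueError):
            gc.simulate_raw(-1.0, affine_truth, neutral_fit)

    def test_angle_beyond_margin_rejected(self, affine_truth, neutral_fit):
        with pytest.raises(ValueError):
            gc.simulate_raw(95.0 + 16.0, affine_truth, neutral_fit)

    def test_invalid_gain_rejected(self):
        with pytest.raises(ValueError):
            gc.SensorGroundTruth(sensor_id="index_mcp", r_flat=100, gain=0)

    @settings(max_examples=50, deadline=None)
    @given(
        curvature=st.floats(0, 10),
        gain=st.floats(100, 3000),
        r_flat=st.integers(0, 1000),
    )
    def test_monotone_in_angle(self, curvature, gain, r_flat):
        truth = gc.SensorGroundTruth(
            sensor_id="middle_pip", r_flat=r_flat, gain=gain, curvature=curvature
        )
        angles = np.linspace(0, truth.theta_max, 40)
        raws = _raw_values(angles, truth, gc.HandFitProfile.neutral(), None)
        assert np.all(np.diff(raws) >= 0)

    def test_quantized_range(self):
        truth = gc.SensorGroundTruth(
            sensor_id="index_mcp", r_flat=4000, gain=3000, noise_sd=500.0
        )
        rng = np.random.default_rng(0)
        raws = _raw_values(np.full(500, 50.0), truth, gc.HandFitProfile.neutral(), rng)
        assert raws.dtype.kind == "i"
        assert raws.min() >= 0 and raws.max() <= 4095


class TestResponseMap:
    def test_endpoints(self):
        for c in (0.0, 1.0, 3.0, 10.0):
            assert response(0.0, c) == 0.0
            assert response(1.0, c) == pytest.approx(1.0)

    def test_identity_at_zero_curvature(self):
        u = np.linspace(0, 1, 11)
        assert np.allclose(response(u, 0.0), u)


class TestTrainingSamples:
    def test_default_grid_sizes(self, neutral_fit):
        bank = gc.default_sensor_bank()
        mcp = gc.generate_training_samples(bank["index_mcp"], neutral_fit)
        pip = gc.generate_training_samples(bank["index_pip"], neutral_fit)
        assert len(mcp) == 13
        assert len(pip) == 14

    def test_single_point_grid(self, affine_truth, neutral_fit):
        # a grid of [0] gives exactly the flat-hand pair
        ts = gc.generate_training_samples(
            affine_truth, neutral_fit, angle_grid=[0.0]
        )
        assert ts.raws.tolist() == [1201]
        assert ts.angles.tolist() == [0.0]

    def test_unsorted_grid_rejected(self, affine_truth, neutral_fit):
        with pytest.raises(ValueError):
            gc.generate_training_samples(
                affine_truth, neutral_fit, angle_grid=[0, 30, 20]
            )
        with pytest.raises(ValueError):
            gc.generate_training_samples(
                affine_truth, neutral_fit, angle_grid=[0, 30, 30]
            )
        with pytest.raises(ValueError):
            gc.generate_training_samples(
                affine_truth, neutral_fit, angle_grid=[5, 30]
            )


class TestProtocols:
    def test_protocol_a_flat_segments(self, neutral_fit):
        bank = gc.default_sensor_bank()
        rec = gc.generate_protocol("A", bank, neutral_fit, cycles=10)
        flat = [s for s in rec.segments if s.label == "flat"]
        assert len(flat) == 10
        assert all(s.stop - s.start == 250 for s in flat)  # 5 s at 50 Hz

    def test_protocol_d_block_angles(self, neutral_fit):
        bank = gc.default_sensor_bank()
        rec = gc.generate_protocol("D", bank, neutral_fit)
        visited = sorted(set(rec.true_angles[:, 0]))
        assert visited == [0, 20, 45, 60, 70, 90]

    def test_protocol_c_no_drift_without_sd(self, neutral_fit):
        bank = gc.default_sensor_bank()  # noiseless
        rec = gc.generate_protocol("C", bank, neutral_fit, cycles=4)
        flats = [
            rec.raw[s.start:s.stop].mean(axis=0)
            for s in rec.segments
            if s.label == "flat"
        ]
        assert np.ptp(np.array(flats), axis=0).max() == 0

    def test_protocol_c_drift_with_sd(self):
        bank = gc.default_sensor_bank()
        fit = gc.HandFitProfile(hand_size=7.75, don_doff_sd=30.0)
        rec = gc.generate_protocol("C", bank, fit, cycles=6, seed=2)
        flats = np.array(
            [
                rec.raw[s.start:s.stop].mean(axis=0)
                for s in rec.segments
                if s.label == "flat"
            ]
        )
        assert np.ptp(flats, axis=0).max() > 10

    def test_unknown_protocol(self, neutral_fit):
        with pytest.raises(ValueError):
            gc.generate_protocol("Z", gc.default_sensor_bank(), neutral_fit)

    def test_seed_determinism(self):
        bank = gc.default_sensor_bank(curvature=1.0, noise_sd=5.0)
        fit = gc.HandFitProfile.for_hand_size(7.0, seed=4, don_doff_sd=20.0)
        r1 = gc.generate_protocol("C", bank, fit, seed=9)
        r2 = gc.generate_protocol("C", bank, fit, seed=9)
        assert np.array_equal(r1.raw, r2.raw)
        assert np.array_equal(r1.true_angles, r2.true_angles)

    def test_csv_round_trip(self, tmp_path, neutral_fit):
        bank = gc.default_sensor_bank(noise_sd=3.0)
        rec = gc.generate_protocol("D", bank, neutral_fit, seed=1)
        path = tmp_path / "rec.csv"
        rec.to_csv(path)
        back = gc.Recording.from_csv(path, protocol_id="D")
        assert back.sensor_ids == rec.sensor_ids
        assert np.array_equal(back.raw, rec.raw)
        assert len(back.segments) == len(rec.segments)
        assert back.segments[3].label == rec.segments[3].label


def test_profile_json_round_trip(tmp_path):
    from glovecal.sim import load_profiles, save_profiles

    bank = gc.default_sensor_bank(curvature=2.0, noise_sd=1.5)
    fit = gc.HandFitProfile.for_hand_size(8.0, seed=3, don_doff_sd=12.0)
    path = tmp_path / "profiles.json"
    save_profiles(path, bank, fit)
    bank2, fit2 = load_profiles(path)
    assert bank2.keys() == bank.keys()
    assert bank2["ring_pip"] == bank["ring_pip"]
    assert fit2.fit_offset == fit.fit_offset
    assert fit2.hand_size == 8.0
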