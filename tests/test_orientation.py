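"""Maximum-energy-channel calibration: energy oracle values, argmax and
rearrangement rules, thresholds, and the rotation-cancellation property."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emgshift import (
    DegenerateCalibrationError,
    EmgRecording,
    GestureClass,
    apply_simulated_rotation,
    calibrate,
    channel_energy,
    find_max_energy_channel,
    generate_sync_repetitions,
    mean_sync_energy,
    rearrange_channels,
    wrap_pod,
)
from emgshift.orientation import mean_sync_energies, sync_window
from emgshift.synth import DEFAULT_PROFILES, ROTATION_OFFSETS

from conftest import make_recording


def _rec_with_channel_energies(energies, n=1000):
    """Recording whose per-channel sync-window energy is analytically known.

    Channel k alternates +-a_k; the signed square alternates +-a_k^2 so
    each of the 199 in-window steps contributes 2 a_k^2: E = 398 a_k^2.
    """
    a = np.sqrt(np.asarray(energies, dtype=float) / 398.0)
    signs = np.tile([1.0, -1.0], n // 2)
    samples = a[:, None] * signs[None, :]
    return make_recording(samples, GestureClass.WAVE_OUT, ground_truth=(0, 500))


class TestChannelEnergy:
    def test_constant_vector_is_zero(self):
        assert channel_energy(np.full(50, 0.37)) == 0.0

    def test_hand_values(self):
        assert channel_energy(np.array([0.0, 1.0, -1.0])) == pytest.approx(3.0)
        assert channel_energy(np.array([0.0, 0.5])) == pytest.approx(0.25)

    def test_single_sample_is_zero(self):
        assert channel_energy(np.array([0.9])) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            channel_energy(np.array([]))

    @given(st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=30, deadline=None)
    def test_homogeneous_degree_two(self, alpha):
        x = np.array([0.0, 0.6, -0.4, 0.2, -0.9])
        assert channel_energy(alpha * x) == pytest.approx(alpha**2 * channel_energy(x))


class TestMeanSyncEnergy:
    def test_arithmetic_mean_of_two(self):
        r1 = _rec_with_channel_energies([3.0] * 8)
        r2 = _rec_with_channel_energies([5.0] * 8)
        assert mean_sync_energy([r1, r2], pod=1) == pytest.approx(4.0)

    def test_single_repetition_equals_window_energy(self, sync_reps):
        rec = sync_reps[0]
        win = sync_window(rec)
        for pod in (1, 4, 8):
            assert mean_sync_energy([rec], pod) == pytest.approx(
                channel_energy(win[pod - 1])
            )

    def test_matches_brute_force_recomputation(self, sync_reps):
        """Independent oracle: per-repetition energies summed then /T."""
        for pod in range(1, 9):
            manual = sum(
                channel_energy(sync_window(r)[pod - 1]) for r in sync_reps
            ) / len(sync_reps)
            assert mean_sync_energy(sync_reps, pod) == pytest.approx(manual, rel=1e-12)

    def test_sync_count_bounds(self, sync_reps):
        with pytest.raises(ValueError):
            mean_sync_energies([])
        with pytest.raises(ValueError):
            mean_sync_energies(sync_reps + sync_reps)


class TestFindMaxEnergyChannel:
    def test_argmax(self):
        assert find_max_energy_channel(np.array([1, 2, 9, 3, 0, 0, 0, 0.0])) == 3

    def test_tie_breaks_to_lowest_pod(self):
        assert find_max_energy_channel(np.ones(8)) == 1

    def test_nan_rejected(self):
        e = np.ones(8)
        e[3] = np.nan
        with pytest.raises(ValueError):
            find_max_energy_channel(e)


class TestRearrangeChannels:
    @pytest.mark.parametrize(
        "sx, expected",
        [
            (6, (6, 7, 8, 1, 2, 3, 4, 5)),
            (1, (1, 2, 3, 4, 5, 6, 7, 8)),
            (8, (8, 1, 2, 3, 4, 5, 6, 7)),
        ],
    )
    def test_circular_orders(self, sx, expected):
        assert rearrange_channels(sx).order == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rearrange_channels(0)
        with pytest.raises(ValueError):
            rearrange_channels(9)

    def test_identity_start_is_idempotent(self, fist_recording):
        order = rearrange_channels(1)
        once = fist_recording.rearranged(order)
        twice = once.rearranged(order)
        np.testing.assert_array_equal(once.samples, twice.samples)


class TestCalibrate:
    def test_threshold_arithmetic(self):
        rec = _rec_with_channel_energies([10, 10, 10, 10, 2, 2, 2, 2])
        cal = calibrate([rec], energy_fraction=0.17)
        assert cal.sx == 1
        assert cal.th_high == pytest.approx(0.17 * 10, rel=1e-6)
        assert cal.th_low == pytest.approx(0.17 * 2, rel=1e-6)

    def test_pod_order_starts_at_mec(self, sync_reps, calibration):
        energies = mean_sync_energies(sync_reps)
        assert calibration.sx == int(np.argmax(energies)) + 1
        assert calibration.pod_order.start == calibration.sx

    def test_all_zero_sync_is_degenerate(self):
        rec = make_recording(
            np.zeros((8, 1000)), GestureClass.WAVE_OUT, ground_truth=(0, 500)
        )
        with pytest.raises(DegenerateCalibrationError):
            calibrate([rec])

    def test_mec_follows_rotation(self):
        """Calibrating on rotated sync repetitions finds the rotated MEC:
        the waveOut locus lands at wrap(center - r)."""
        center = DEFAULT_PROFILES[GestureClass.WAVE_OUT].center_pod
        hits = total = 0
        for s in range(40):
            sync = generate_sync_repetitions(4, np.random.default_rng(500 + s), noise_snr_db=10)
            for r in (-3, 0, 2, 4):
                cal = calibrate([apply_simulated_rotation(x, r) for x in sync])
                hits += cal.sx == wrap_pod(center - r)
                total += 1
        assert hits / total >= 0.95

    def test_round_trip_json(self, calibration, tmp_path):
        calibration.save(tmp_path / "cal.json")
        back = type(calibration).load(tmp_path / "cal.json")
        assert back.sx == calibration.sx
        assert back.pod_order == calibration.pod_order
        assert back.th_high == pytest.approx(calibration.th_high)
        np.testing.assert_allclose(back.mean_energies, calibration.mean_energies)


class TestRotationCancellation:
    def test_exact_for_all_offsets(self, sync_reps, calibration, fist_recording):
        """Rearranging a rotated recording by the calibration computed from
        its rotated sync repetitions reproduces the unrotated+calibrated
        channel sequence exactly, for every donning offset."""
        base = fist_recording.rearranged(calibration.pod_order).samples
        for r in ROTATION_OFFSETS:
            sync_r = [apply_simulated_rotation(x, r) for x in sync_reps]
            cal_r = calibrate(sync_r)
            rot = apply_simulated_rotation(fist_recording, r)
            np.testing.assert_array_equal(rot.rearranged(cal_r.pod_order).samples, base)
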