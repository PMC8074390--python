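"""Oracle checks of the synthetic gait generator.

The ground-truth properties (sampling-rate arithmetic, envelope rank,
amplitude-gain equivariance, spectral compression, heel-strike statistics)
are all computed independently here — with numpy/scipy directly — rather
than through the generator's own helpers.
"""
from __future__ import annotations

import numpy as np
import pytest
from scipy import signal

from semgintent import synthetic
from semgintent.synthetic import (
    GaitParams,
    ShiftParams,
    generate_recording,
    make_subject_params,
    read_recording,
    true_synergies,
    write_recording,
)


class TestRates:
    def test_exact_rationals(self):
        assert synthetic.SEMG_RATE == pytest.approx(10000 / 9)
        assert synthetic.IMU_RATE == pytest.approx(4000 / 27)
        # 0.9 ms and 6.75 ms intervals; 15 and 2 samples both span 13.5 ms
        assert 15 * 1000 / synthetic.SEMG_RATE == pytest.approx(13.5)
        assert 2 * 1000 / synthetic.IMU_RATE == pytest.approx(13.5)

    def test_stream_lengths(self):
        rec = generate_recording(GaitParams(duration=9.0, seed=0))
        assert rec.n_semg_samples == round(9.0 * 10000 / 9)
        assert rec.n_imu_samples == round(9.0 * 4000 / 27)
        for arr in (rec.angle, rec.thigh_omega, rec.shank_omega,
                    rec.thigh_acc, rec.shank_acc):
            assert arr.shape == (rec.n_imu_samples,)
        assert rec.semg.shape == (9, rec.n_semg_samples)


class TestDeterminismAndShift:
    def test_same_seed_bit_identical(self):
        p = GaitParams(duration=5.0, seed=7)
        a, b = generate_recording(p), generate_recording(p)
        assert np.array_equal(a.semg, b.semg)
        assert np.array_equal(a.angle, b.angle)
        assert np.array_equal(a.heel_strikes, b.heel_strikes)

    def test_different_seed_differs(self):
        a = generate_recording(GaitParams(duration=5.0, seed=1))
        b = generate_recording(GaitParams(duration=5.0, seed=2))
        assert not np.array_equal(a.semg, b.semg)

    def test_amplitude_gain_exact_scaling(self):
        """Gain 2 doubles the sEMG exactly: the random draws are shared."""
        p = GaitParams(duration=5.0, seed=3)
        base = generate_recording(p)
        scaled = generate_recording(p, ShiftParams(amplitude_gain=2.0))
        np.testing.assert_allclose(scaled.semg, 2.0 * base.semg, rtol=1e-12)
        assert np.array_equal(scaled.heel_strikes, base.heel_strikes)

    def test_per_channel_gain_vector(self):
        p = GaitParams(duration=5.0, seed=3)
        gains = np.linspace(0.5, 2.0, 9)
        base = generate_recording(p)
        scaled = generate_recording(p, ShiftParams(amplitude_gain=gains))
        np.testing.assert_allclose(scaled.semg, gains[:, None] * base.semg, rtol=1e-12)

    def test_channel_swap_exchanges_rows_exactly(self):
        """Electrode remapping permutes channels; kinematics are untouched."""
        p = GaitParams(duration=5.0, seed=3)
        base = generate_recording(p)
        swapped = generate_recording(p, ShiftParams(channel_swap=((0, 4), (2, 6))))
        expect = base.semg.copy()
        expect[[0, 4]] = expect[[4, 0]]
        expect[[2, 6]] = expect[[6, 2]]
        np.testing.assert_array_equal(swapped.semg, expect)
        np.testing.assert_array_equal(swapped.angle, base.angle)

    def test_channel_swap_applies_before_gains(self):
        p = GaitParams(duration=5.0, seed=3)
        gains = np.linspace(0.5, 2.0, 9)
        base = generate_recording(p)
        shifted = generate_recording(
            p, ShiftParams(amplitude_gain=gains, channel_swap=((1, 7),)))
        expect = base.semg.copy()
        expect[[1, 7]] = expect[[7, 1]]
        np.testing.assert_allclose(shifted.semg, gains[:, None] * expect, rtol=1e-12)

    def test_spectral_compression_lowers_centroid(self):
        """Compressed carriers concentrate power at lower frequencies."""
        p = GaitParams(duration=10.0, seed=4)
        base = generate_recording(p)
        comp = generate_recording(p, ShiftParams(spectral_compression=0.7))

        def centroid(x):
            f, pxx = signal.welch(x, fs=synthetic.SEMG_RATE, nperseg=1024)
            return np.sum(f * pxx) / np.sum(pxx)

        c_base = np.mean([centroid(base.semg[c]) for c in range(9)])
        c_comp = np.mean([centroid(comp.semg[c]) for c in range(9)])
        assert c_comp < 0.85 * c_base

    def test_envelope_jitter_changes_cycle_amplitudes(self):
        p = GaitParams(duration=8.0, seed=5)
        a = generate_recording(p)
        b = generate_recording(p, ShiftParams(envelope_jitter=0.3))
        # same gait timing, different burst amplitudes
        assert np.array_equal(a.heel_strikes, b.heel_strikes)
        assert not np.allclose(a.semg, b.semg)


class TestStructure:
    def test_heel_strike_spacing(self):
        p = GaitParams(duration=20.0, seed=6, cycle_period_mean=1.1,
                       cycle_period_cv=0.03)
        rec = generate_recording(p)
        gaps = np.diff(rec.heel_strikes) / synthetic.IMU_RATE  # seconds
        assert np.all(np.diff(rec.heel_strikes) > 0)
        assert abs(gaps.mean() - 1.1) < 0.1
        assert np.all(gaps > 0.8) and np.all(gaps < 1.5)

    def test_semg_zero_mean_and_scale(self):
        rec = generate_recording(GaitParams(duration=10.0, seed=7))
        means = rec.semg.mean(axis=1)
        rms = np.sqrt((rec.semg**2).mean(axis=1))
        assert np.all(np.abs(means) < 0.05 * rms)
        assert np.all(rms > 1e-4) and np.all(rms < 10.0)

    def test_envelope_rank_at_most_r(self):
        """The true envelope matrix is an exact rank-≤5 product."""
        p = GaitParams(duration=5.0, seed=8)
        truth = true_synergies(p)
        v = truth.W @ truth.H
        s = np.linalg.svd(v, compute_uv=False)
        assert s[5] / s[0] < 1e-10
        assert np.all(v >= 0)

    def test_true_synergies_match_recording_scale(self):
        """|sEMG| tracks the true envelope: correlation per channel."""
        p = GaitParams(duration=8.0, seed=9)
        rec = generate_recording(p)
        truth = true_synergies(p)
        env_true = (truth.W @ truth.H).T
        for c in range(9):
            r = np.corrcoef(np.abs(rec.semg[c]), env_true[c])[0, 1]
            assert r > 0.5

    def test_knee_angle_range(self):
        rec = generate_recording(GaitParams(duration=10.0, seed=10))
        assert rec.angle.min() > -5.0
        assert 40.0 < rec.angle.max() < 90.0


class TestValidation:
    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            GaitParams(duration=1.0)

    def test_too_many_synergies_rejected(self):
        with pytest.raises(ValueError):
            GaitParams(n_synergies=10)

    def test_bad_gain_rejected(self):
        with pytest.raises(ValueError):
            ShiftParams(amplitude_gain=0.0)

    def test_bad_compression_rejected(self):
        with pytest.raises(ValueError):
            ShiftParams(spectral_compression=1.5)
        with pytest.raises(ValueError):
            ShiftParams(spectral_compression=0.0)

    def test_overlapping_swap_pairs_rejected(self):
        with pytest.raises(ValueError):
            ShiftParams(channel_swap=((0, 4), (4, 6)))


class TestIO:
    def test_round_trip(self, tmp_path):
        rec = generate_recording(GaitParams(duration=4.0, seed=11))
        write_recording(rec, tmp_path / "rec")
        back = read_recording(tmp_path / "rec")
        np.testing.assert_allclose(back.semg, rec.semg, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(back.angle, rec.angle, rtol=1e-5, atol=1e-8)
        assert np.array_equal(back.heel_strikes, rec.heel_strikes)
        assert back.channel_names == rec.channel_names
        assert back.semg_rate == rec.semg_rate


class TestPopulation:
    def test_subjects_differ(self):
        pa, sa = make_subject_params(0, base_seed=1, duration=5.0)
        pb, sb = make_subject_params(1, base_seed=1, duration=5.0)
        assert pa.seed != pb.seed
        assert not np.allclose(sa.amplitude_gain, sb.amplitude_gain)

    def test_reproducible(self):
        pa, sa = make_subject_params(3, base_seed=9, duration=5.0)
        pb, sb = make_subject_params(3, base_seed=9, duration=5.0)
        assert pa == pb
        np.testing.assert_array_equal(sa.amplitude_gain, sb.amplitude_gain)
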