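"""Framing, per-frame features, column contracts, and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painreact import (FramingSpec, extract_features, frame_energy,
                       spectral_entropy, stft_frame_energy,
                       time_domain_stats, derivative_stats, zscore_by_subject)
from painreact.feature_extraction import FeatureMatrix, entropy_bits
from painreact.scattering import FilterBankConfig, align_frames, \
    scattering_transform


class TestFraming:
    @pytest.mark.parametrize("duration,expected", [
        (4.0, 1), (6.0, 2), (90.0, 44), (180.0, 89), (179.9, 88)])
    def test_frame_count_rule(self, duration, expected):
        assert FramingSpec().n_frames(duration) == expected

    def test_validation(self):
        with pytest.raises(ValueError):
            FramingSpec(window_s=0.0)
        with pytest.raises(ValueError):
            FramingSpec(window_s=4.0, hop_s=5.0)


class TestSpectralEntropy:
    def test_uniform_spectrum_is_log2_n(self):
        assert entropy_bits(np.ones(8)) == pytest.approx(3.0)
        assert entropy_bits(np.ones(16)) == pytest.approx(4.0)

    def test_delta_spectrum_is_zero(self):
        p = np.zeros(10)
        p[3] = 5.0
        assert entropy_bits(p) == 0.0

    def test_two_equal_bins_one_bit(self):
        assert entropy_bits(np.array([0.5, 0.5, 0.0, 0.0])) == pytest.approx(1.0)

    def test_all_zero_frame_defined_as_zero(self):
        h = spectral_entropy(np.zeros(64), 8.0, FramingSpec())
        assert np.all(h == 0.0)

    def test_tone_below_noise(self):
        rng = np.random.default_rng(0)
        fs = 64.0
        t = np.arange(0, 12, 1 / fs)
        h_tone = spectral_entropy(np.sin(2 * np.pi * 8 * t), fs, FramingSpec())
        h_noise = spectral_entropy(rng.standard_normal(t.size), fs,
                                   FramingSpec())
        assert h_tone.mean() < h_noise.mean()


class TestTimeDomainStats:
    def test_constant_frame(self):
        vals, names = time_domain_stats(np.full(64, 2.5), 8.0, FramingSpec())
        assert names == ["max", "median", "sd", "amplitude"]
        assert np.allclose(vals, [[2.5, 2.5, 0.0, 0.0]] * vals.shape[0])

    def test_hand_arithmetic_oracle(self):
        # frame (1, 2, 3, 4): max 4, median 2.5, sample sd, range 3
        vals, _ = time_domain_stats(np.array([1.0, 2.0, 3.0, 4.0]), 1.0,
                                    FramingSpec(window_s=4.0, hop_s=4.0))
        assert np.allclose(vals[0], [4.0, 2.5, np.std([1, 2, 3, 4], ddof=1),
                                     3.0])
        assert vals[0][2] == pytest.approx(1.2910, abs=1e-4)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(80)
        a, _ = time_domain_stats(x, 8.0, FramingSpec())
        b, _ = time_domain_stats(-x, 8.0, FramingSpec())
        assert np.allclose(a[:, 3], b[:, 3])  # amplitude unchanged
        # new max is the negated old min
        mins = [x[sl].min() for sl in FramingSpec().frame_slices(80, 8.0)]
        assert np.allclose(b[:, 0], -np.asarray(mins))


class TestDerivativeStats:
    def test_constant_frame(self):
        vals, names = derivative_stats(np.full(64, 1.0), 8.0, FramingSpec())
        assert names == ["d1_max", "d1_mean", "d1_sd"]
        assert np.allclose(vals, 0.0)

    def test_linear_ramp(self):
        fs, k = 8.0, 0.75
        t = np.arange(0, 8, 1 / fs)
        vals, _ = derivative_stats(k * t, fs, FramingSpec())
        assert np.allclose(vals[:, 0], k, atol=1e-9)
        assert np.allclose(vals[:, 1], k, atol=1e-9)
        assert np.allclose(vals[:, 2], 0.0, atol=1e-9)

    def test_alternating_oracle(self):
        # diffs of (0,1,0,1) at fs=1 are (1,-1,1): max 1, mean 1/3, sd 1.1547
        vals, _ = derivative_stats(np.array([0.0, 1.0, 0.0, 1.0]), 1.0,
                                   FramingSpec(window_s=4.0, hop_s=4.0))
        assert vals[0][0] == pytest.approx(1.0)
        assert vals[0][1] == pytest.approx(1 / 3)
        assert vals[0][2] == pytest.approx(1.1547, abs=1e-4)


class TestSTFTEnergy:
    def test_zero_signal(self):
        assert np.all(stft_frame_energy(np.zeros(64), 8.0, FramingSpec()) == 0)

    def test_parseval_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(128)
        e = stft_frame_energy(x, 8.0, FramingSpec())
        for val, sl in zip(e, FramingSpec().frame_slices(128, 8.0)):
            frame = x[sl]
            direct = np.sum((frame * np.hanning(frame.size)) ** 2)
            assert val == pytest.approx(direct, rel=0.01)

    def test_amplitude_doubling_quadruples_energy(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(96)
        assert np.allclose(stft_frame_energy(2 * x, 8.0, FramingSpec()),
                           4 * stft_frame_energy(x, 8.0, FramingSpec()))


class TestFrameEnergyColumns:
    @pytest.mark.parametrize("fs,qs,expected_cols", [
        (64.0, (8, 4, 1), 6), (8.0, (8, 1), 4)])
    def test_energy_column_count(self, fs, qs, expected_cols):
        rng = np.random.default_rng(4)
        cfg = FilterBankConfig(fs=fs, voices_per_octave=qs)
        out = scattering_transform(rng.standard_normal(int(20 * fs)), cfg)
        energies, names = frame_energy(align_frames(out, out.n_frames))
        assert energies.shape[1] == expected_cols
        assert len(names) == expected_cols
        assert np.all(energies >= 0)

    def test_zero_output_zero_energy(self):
        cfg = FilterBankConfig(fs=8.0, voices_per_octave=(8, 1))
        out = scattering_transform(np.zeros(8 * 20), cfg)
        energies, _ = frame_energy(align_frames(out, out.n_frames))
        assert np.all(energies == 0)

    def test_coefficient_scaling_quadratic(self):
        rng = np.random.default_rng(5)
        cfg = FilterBankConfig(fs=8.0, voices_per_octave=(8, 1))
        x = rng.standard_normal(8 * 20)
        e1, _ = frame_energy(align_frames(scattering_transform(x, cfg), 9))
        e2, _ = frame_energy(align_frames(scattering_transform(2 * x, cfg), 9))
        assert np.allclose(e2, 4 * e1, rtol=1e-9)


class TestExtractFeatures:
    def test_default_mode_yields_33_columns(self, prepped_recording):
        fm = extract_features(prepped_recording, "scattering")
        assert fm.values.shape[1] == 33
        assert len(set(fm.feature_names)) == 33

    def test_stft_mode_yields_17_columns(self, prepped_recording):
        fm = extract_features(prepped_recording, "stft")
        assert fm.values.shape[1] == 17

    def test_modes_share_frame_grid(self, prepped_recording):
        a = extract_features(prepped_recording, "scattering")
        b = extract_features(prepped_recording, "stft")
        assert a.n_frames == b.n_frames
        assert np.array_equal(a.frame_starts, b.frame_starts)

    def test_deterministic(self, prepped_recording):
        a = extract_features(prepped_recording, "stft")
        b = extract_features(prepped_recording, "stft")
        assert np.array_equal(a.values, b.values)

    def test_unknown_mode_rejected(self, prepped_recording):
        with pytest.raises(ValueError):
            extract_features(prepped_recording, "mfcc")


class TestZScore:
    def make_matrix(self, values, subject="A"):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(values=values,
                             feature_names=tuple(f"f{i}" for i in
                                                 range(values.shape[1])),
                             subject_id=subject,
                             frame_starts=2.0 * np.arange(values.shape[0]))

    def test_normalized_moments(self):
        rng = np.random.default_rng(6)
        fm = self.make_matrix(rng.standard_normal((40, 5)) * 3 + 7)
        z = zscore_by_subject(fm)
        assert np.allclose(z.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_zero_variance_column_becomes_zero(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0)])
        z = zscore_by_subject(self.make_matrix(vals))
        assert np.all(z.values[:, 0] == 0.0)

    def test_offset_subjects_normalize_identically(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((30, 4))
        a = self.make_matrix(base, "A")
        b = self.make_matrix(base + 11.0, "B")
        za, zb = zscore_by_subject([a, b])
        assert np.allclose(za.values, zb.values, atol=1e-9)

    def test_single_frame_subject_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            zscore_by_subject(self.make_matrix(np.ones((1, 3))))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2,
                max_size=16))
def test_entropy_nonnegative_and_bounded(power):
    p = np.abs(np.asarray(power))
    h = entropy_bits(p)
    assert 0.0 <= h <= np.log2(p.size) + 1e-9
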