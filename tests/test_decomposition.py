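import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emdcombine import SiftConfig, eemd, emd, envelope_mean, is_imf, sift_imf
from emdcombine.decomposition import (
    clamp_extend,
    find_local_extrema,
    mirror_extend,
    zero_crossings,
)


class TestFindLocalExtrema:
    def test_alternating_example(self):
        e = find_local_extrema([1, 3, 2, 4, 1])
        assert e.max_positions.tolist() == [1, 3]
        assert e.max_values.tolist() == [3, 4]
        assert e.min_positions.tolist() == [2]
        assert e.min_values.tolist() == [2]

    def test_monotone_has_no_interior_extrema(self):
        e = find_local_extrema([1, 2, 3])
        assert e.n_max == 0 and e.n_min == 0

    def test_plateau_counts_once_at_left_biased_midpoint(self):
        e = find_local_extrema([0, 2, 2, 0])
        assert e.max_positions.tolist() == [1]
        e3 = find_local_extrema([0, 2, 2, 2, 0])
        assert e3.max_positions.tolist() == [2]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_local_extrema([1, 2])

    @settings(deadline=None, max_examples=50)
    @given(
        arrays(
            float,
            st.integers(min_value=3, max_value=40),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_positions_increasing_and_disjoint(self, x):
        e = find_local_extrema(x)
        pos_max, pos_min = e.max_positions, e.min_positions
        assert np.all(np.diff(pos_max) > 0) and np.all(np.diff(pos_min) > 0)
        assert not set(pos_max.tolist()) & set(pos_min.tolist())
        # extrema are interior
        all_pos = np.concatenate([pos_max, pos_min])
        if all_pos.size:
            assert all_pos.min() >= 1 and all_pos.max() <= x.size - 2


class TestMirrorExtend:
    def test_reflection_at_start(self):
        # first max at p=1 (v=3), first min at p=2 (v=2) -> prepended min at
        # 2*1-2 = 0 with value 2
        x = np.array([1.0, 3, 2, 4, 1, 5, 0, 4, 1])
        e = mirror_extend(x, find_local_extrema(x))
        assert e.min_positions[0] == 0.0
        assert e.min_values[0] == 2.0

    def test_reflection_at_end(self):
        # last min at p=7, last max before it at p=5 (v=4) -> appended max at
        # 2*7-5 = 9 with value 4
        x = np.array([0.0, 2, 1, 3, 0, 4, 2, -1, 0])
        e = mirror_extend(x, find_local_extrema(x))
        assert e.max_positions[-1] == 9.0
        assert e.max_values[-1] == 4.0

    def test_idempotent_on_extended_set(self):
        x = np.array([1.0, 3, 2, 4, 1, 5, 0, 4, 1])
        once = mirror_extend(x, find_local_extrema(x))
        twice = mirror_extend(x, once)
        assert twice.n_max == once.n_max and twice.n_min == once.n_min

    def test_falls_back_without_both_extrema_kinds(self, caplog):
        x = np.array([0.0, 1, 0])  # one max, no interior min
        with caplog.at_level("WARNING"):
            e = mirror_extend(x, find_local_extrema(x))
        assert e.extended
        assert e.n_min >= 2  # endpoints clamped in


class TestEnvelopeMean:
    def test_upper_envelope_interpolates_maxima(self):
        x = np.sin(2 * np.pi * np.arange(64) / 16)
        ext = mirror_extend(x, find_local_extrema(x))
        env = envelope_mean(x, ext)
        interior = find_local_extrema(x)
        for p, v in zip(interior.max_positions.astype(int), interior.max_values):
            assert env.upper[p] == pytest.approx(v, abs=1e-9)

    def test_sine_mean_envelope_small_in_interior(self):
        x = np.sin(2 * np.pi * np.arange(256) / 20)
        env = envelope_mean(x, mirror_extend(x, find_local_extrema(x)))
        inner = slice(13, 243)
        assert np.max(np.abs(env.mean[inner])) < 0.05

    def test_symmetric_extrema_give_zero_mean(self):
        # triangle wave: maxima all +1, minima all -1, evenly spaced
        t = np.arange(128)
        x = 2 * np.abs((t / 16) % 2 - 1) - 1
        env = envelope_mean(x, mirror_extend(x, find_local_extrema(x)))
        assert np.max(np.abs(env.mean)) < 1e-8

    def test_mean_is_exact_midpoint(self):
        x = np.sin(np.arange(64) * 0.4) * np.linspace(1, 3, 64)
        env = envelope_mean(x, mirror_extend(x, find_local_extrema(x)))
        np.testing.assert_array_equal(env.mean, 0.5 * (env.upper + env.lower))


class TestIsImf:
    def test_pure_tone_is_imf(self):
        assert is_imf(np.sin(2 * np.pi * np.arange(100) / 20))[0]

    def test_offset_tone_fails_envelope_condition(self):
        ok, diag = is_imf(np.sin(2 * np.pi * np.arange(100) / 20) + 5)
        assert not ok
        assert not diag["envelope_ok"]

    def test_ramp_is_not_imf(self):
        assert not is_imf(np.linspace(0, 1, 50))[0]


class TestSiftImf:
    def test_imf_input_is_fixed_point(self, plain_cfg):
        x = np.sin(2 * np.pi * np.arange(128) / 16)
        imf, rem = sift_imf(x, plain_cfg)
        np.testing.assert_allclose(imf, x, atol=1e-6)
        np.testing.assert_allclose(rem, 0.0, atol=1e-6)

    def test_conservation_is_exact(self, plain_cfg):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=200))
        imf, rem = sift_imf(x, plain_cfg)
        # remainder is defined as input - imf, bit for bit
        np.testing.assert_array_equal(rem, x - imf)
        np.testing.assert_allclose(imf + rem, x, rtol=0, atol=1e-12)

    def test_first_imf_tracks_fast_tone(self, two_tone, plain_cfg):
        x, fast, _ = two_tone
        imf, _ = sift_imf(x, plain_cfg)
        assert np.corrcoef(imf, fast)[0, 1] > 0.95


class TestEmd:
    def test_reconstruction_within_1e8(self, two_tone, plain_cfg):
        x, _, _ = two_tone
        d = emd(x, plain_cfg)
        assert np.max(np.abs(x - d.reconstruct())) < 1e-8

    def test_single_tone_yields_one_dominant_imf(self, plain_cfg):
        x = np.sin(2 * np.pi * np.arange(512) / 16)
        d = emd(x, plain_cfg)
        assert d.n_imfs >= 1
        assert np.var(d.imfs[0]) / np.var(x) > 0.99

    def test_monotone_ramp_is_pure_residue(self, plain_cfg):
        x = np.linspace(0, 10, 64) ** 1.5
        d = emd(x, plain_cfg)
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residue, x)

    def test_frequency_ordering(self, synth_series, plain_cfg):
        d = emd(synth_series.values, plain_cfg)
        zc = [zero_crossings(c) for c in d.imfs]
        assert all(a >= b for a, b in zip(zc, zc[1:]))

    def test_too_short_rejected(self, plain_cfg):
        with pytest.raises(ValueError):
            emd(np.arange(5.0), plain_cfg)


class TestEemd:
    def test_degenerate_ensemble_equals_emd(self, two_tone):
        x, _, _ = two_tone
        cfg = SiftConfig(ensemble_size=1, noise_scale=0.0, seed=7)
        d1 = emd(x, cfg)
        d2 = eemd(x, cfg)
        assert d1.n_imfs == d2.n_imfs
        for a, b in zip(d1.components, d2.components):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_is_bit_identical(self, two_tone):
        x, _, _ = two_tone
        cfg = SiftConfig(ensemble_size=8, noise_scale=0.05, seed=11)
        d1, d2 = eemd(x, cfg), eemd(x, cfg)
        assert d1.n_imfs == d2.n_imfs
        for a, b in zip(d1.components, d2.components):
            np.testing.assert_array_equal(a, b)

    def test_noise_cancels_at_root_ne_rate(self, two_tone):
        # the reconstruction error is the member-mean of the added noise, so
        # its RMS should sit near noise*std/sqrt(NE)
        x, _, _ = two_tone
        ne = 16
        cfg = SiftConfig(ensemble_size=ne, noise_scale=0.05, seed=2)
        d = eemd(x, cfg)
        err = x - d.reconstruct()
        sigma = 0.05 * np.std(x) / np.sqrt(ne)
        assert np.sqrt(np.mean(err**2)) < 2 * sigma

    def test_absolute_noise_mode(self, two_tone):
        x, _, _ = two_tone
        cfg = SiftConfig(
            ensemble_size=4, noise_scale=0.01, noise_mode="absolute", seed=3
        )
        d = eemd(x, cfg)
        err = x - d.reconstruct()
        assert np.sqrt(np.mean(err**2)) < 2 * 0.01 / np.sqrt(4)


class TestMirrorVsClamp:
    def test_mirror_no_worse_at_boundaries_on_sines(self):
        rng = np.random.default_rng(1234)
        n = 256
        k = n // 10
        idx = np.r_[0:k, n - k : n]
        for _ in range(5):
            period = rng.uniform(12, 40)
            phase = rng.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * np.arange(n) / period + phase)
            rms = {}
            for ext in ("mirror", "clamp"):
                d = emd(x, SiftConfig(ensemble_size=1, noise_scale=0.0, extension=ext))
                imf1 = d.imfs[0] if d.n_imfs else d.residue
                rms[ext] = np.sqrt(np.mean((imf1[idx] - x[idx]) ** 2))
            assert rms["mirror"] <= rms["clamp"] + 1e-12
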