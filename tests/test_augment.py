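"""Unit and property tests for the Brownian-walk augmentation primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.random import SeedSequence, default_rng

from browaug.augment import (
    AugmentationConfig,
    BrownianAugmenter,
    TraceAugmenter,
    add_noise,
    augment_batch,
    brownian_augment,
    draw_indexes,
    equivalent_stretch_std,
    interpolate_trace,
    scale_magnitude,
    shift_baseline,
    uniform_stretch,
)


class TestDrawIndexes:
    def test_zero_sigma_is_identity_walk(self):
        iq = draw_indexes(5, 0.0, seed=7)
        np.testing.assert_array_equal(iq.values, [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_walk_starts_at_zero_and_is_clamped(self):
        iq = draw_indexes(700, 0.9, seed=0)
        assert iq.values[0] == 0.0
        assert iq.values.min() >= 0.0
        assert iq.values.max() <= 699.0
        assert len(iq) == 700

    def test_deterministic_under_seed(self):
        a = draw_indexes(300, 0.9, seed=42)
        b = draw_indexes(300, 0.9, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            draw_indexes(10, -0.1, seed=0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(sigma=st.floats(0.0, 3.0), seed=st.integers(0, 2**31 - 1))
    def test_clamping_property(self, sigma, seed):
        iq = draw_indexes(64, sigma, seed=seed)
        assert iq.values.min() >= 0.0
        assert iq.values.max() <= 63.0

    def test_preclamp_moments_follow_brownian_law(self):
        # E[i0[n]] = n and Var[i0[n]] = n * sigma^2 on the raw walk
        sigma, n, n_draws = 0.5, 100, 4000
        sample = np.array(
            [draw_indexes(n + 1, sigma, seed=s).raw_values[n] for s in range(n_draws)])
        se_mean = sigma * np.sqrt(n) / np.sqrt(n_draws)
        assert abs(sample.mean() - n) < 4 * se_mean
        target_var = n * sigma**2
        assert abs(sample.var(ddof=1) - target_var) / target_var < 4 * np.sqrt(2 / n_draws)


class TestInterpolate:
    def test_hand_computed_example(self):
        X = np.array([0.0, 10.0, 20.0, 30.0])
        out = interpolate_trace(X, np.array([0.0, 1.5, 2.25, 3.0]))
        np.testing.assert_allclose(out, [0.0, 15.0, 22.5, 30.0])

    def test_integer_indexes_identity(self):
        X = default_rng(0).normal(size=50)
        out = interpolate_trace(X, np.arange(50, dtype=float))
        np.testing.assert_array_equal(out, X)

    def test_out_of_range_rejected(self):
        X = np.zeros(10)
        with pytest.raises(ValueError):
            interpolate_trace(X, np.full(10, 9.5))
        with pytest.raises(ValueError):
            interpolate_trace(X, np.full(10, -0.1))

    def test_convexity_between_bracketing_samples(self):
        X = default_rng(1).normal(size=50)
        iq = draw_indexes(50, 0.3, seed=2)
        Y = interpolate_trace(X, iq)
        lo = np.floor(iq.values).astype(int)
        hi = np.ceil(iq.values).astype(int)
        assert np.all(Y >= np.minimum(X[lo], X[hi]) - 1e-12)
        assert np.all(Y <= np.maximum(X[lo], X[hi]) + 1e-12)


class TestBrownianAugment:
    def test_sigma_zero_identity_bit_exact(self):
        X = default_rng(3).normal(size=700)
        np.testing.assert_array_equal(brownian_augment(X, 0.0, seed=9), X)

    def test_deterministic_under_seed(self):
        X = default_rng(4).normal(size=200)
        np.testing.assert_array_equal(
            brownian_augment(X, 0.9, seed=11), brownian_augment(X, 0.9, seed=11))

    def test_warps_nonuniformly(self):
        # the same trace gets squeezed in some regions and stretched in others
        iq = draw_indexes(700, 0.9, seed=0)
        dev = iq.values - np.arange(700)
        assert dev.max() > 0.5 and dev.min() < -0.5


class TestUniformStretch:
    def test_factor_one_identity(self):
        X = default_rng(5).normal(size=100)
        np.testing.assert_array_equal(uniform_stretch(X, 1.0), X)

    def test_hand_example_factor_two(self):
        out = uniform_stretch(np.array([0.0, 1.0, 2.0, 3.0]), 2.0)
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0, 1.5])

    @pytest.mark.parametrize("factor", [0.5, 0.9, 1.0, 1.3])
    def test_equals_degenerate_walk_interpolation(self, factor):
        X = default_rng(6).normal(size=300)
        idx = np.minimum(np.arange(300, dtype=float) / factor, 299.0)
        np.testing.assert_array_equal(uniform_stretch(X, factor),
                                      interpolate_trace(X, idx))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            uniform_stretch(np.zeros(10), 0.0)


class TestElementwiseAugmentations:
    def test_identities(self):
        X = default_rng(7).normal(size=64)
        np.testing.assert_array_equal(add_noise(X, 0.0, seed=0), X)
        np.testing.assert_array_equal(scale_magnitude(X, 1.0), X)
        np.testing.assert_array_equal(shift_baseline(X, 0.0), X)

    def test_noise_variance_matches_moment_law(self):
        X = np.zeros(100_000)
        out = add_noise(X, 0.25, seed=8)
        assert abs(out.var(ddof=1) - 0.25**2) / 0.25**2 < 0.03

    def test_negative_noise_std_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(5), -1.0, seed=0)


class TestEquivalentStretch:
    def test_zero_sigma_gives_zero(self):
        assert equivalent_stretch_std(0.0, 700, n_draws=10) == 0.0

    def test_matches_closed_form(self):
        est = equivalent_stretch_std(0.5, 401, n_draws=40_000, seed=0)
        assert abs(est - 0.5 / np.sqrt(400)) / (0.5 / np.sqrt(400)) < 0.05

    def test_linear_in_sigma(self):
        a = equivalent_stretch_std(0.3, 201, n_draws=40_000, seed=1)
        b = equivalent_stretch_std(0.6, 201, n_draws=40_000, seed=2)
        assert abs(b / a - 2.0) < 0.05

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            equivalent_stretch_std(0.9, 700, n_draws=1)


class TestAugmentBatch:
    def test_all_disabled_is_identity(self):
        X = default_rng(9).normal(size=(8, 120))
        out = augment_batch(X, AugmentationConfig.none(), epoch_seed=3)
        np.testing.assert_array_equal(out, X)

    def test_epoch_seeds_differ(self):
        X = default_rng(10).normal(size=(4, 120))
        cfg = AugmentationConfig.brownian_only(0.9)
        a = augment_batch(X, cfg, epoch_seed=1)
        b = augment_batch(X, cfg, epoch_seed=2)
        assert not np.array_equal(a, b)

    def test_brownian_only_matches_componentwise(self):
        X = default_rng(11).normal(size=(5, 150))
        cfg = AugmentationConfig.brownian_only(0.9)
        out = augment_batch(X, cfg, epoch_seed=77)
        children = SeedSequence(77).spawn(5)
        for i in range(5):
            expected = brownian_augment(X[i], 0.9, seed=default_rng(children[i]))
            np.testing.assert_array_equal(out[i], expected)

    def test_config_roundtrip(self, tmp_path):
        cfg = AugmentationConfig(sigma=0.5, use_noise=False)
        for name in ("cfg.json", "cfg.yaml"):
            p = tmp_path / name
            cfg.to_file(p)
            assert AugmentationConfig.from_file(p) == cfg


class TestTransformers:
    def test_brownian_augmenter_deterministic_and_shaped(self):
        X = default_rng(12).normal(size=(6, 90))
        tf = BrownianAugmenter(sigma=0.9, random_state=5).fit(X)
        a, b = tf.transform(X), tf.transform(X)
        assert a.shape == X.shape
        np.testing.assert_array_equal(a, b)

    def test_sigma_zero_transformer_identity(self):
        X = default_rng(13).normal(size=(3, 90))
        out = BrownianAugmenter(sigma=0.0).fit_transform(X)
        np.testing.assert_array_equal(out, X)

    def test_trace_augmenter_params_clone(self):
        from sklearn.base import clone

        tf = TraceAugmenter(sigma=0.4, use_noise=False, random_state=1)
        tf2 = clone(tf)
        assert tf2.get_params()["sigma"] == 0.4
        assert tf2.get_params()["use_noise"] is False
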