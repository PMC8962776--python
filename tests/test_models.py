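"""Classifier/generator/discriminator contracts and the two losses."""

import numpy as np
import pytest

from _oracles import receptive_field_by_gradient_support
from fundusprog import nn
from fundusprog.models import (ClassifierConfig, DiscriminatorConfig,
                               GeneratorConfig, build_classifier,
                               build_discriminator, build_generator,
                               classifier_forward, discriminator_forward,
                               gan_losses, generator_forward, receptive_field,
                               weighted_ce)


class TestClassifier:
    def test_output_on_probability_simplex(self, rng):
        clf = build_classifier(ClassifierConfig(input_size=32, width_scale=0.25))
        p = classifier_forward(clf, rng.random((4, 3, 32, 32)))
        assert p.shape == (4, 3)
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0)

    def test_single_image_convenience(self, rng):
        clf = build_classifier(ClassifierConfig(input_size=32, width_scale=0.25))
        p = classifier_forward(clf, rng.random((3, 32, 32)))
        assert p.shape == (3,)

    def test_age_fusion_extends_pooled_features_by_one(self, rng):
        cfg = ClassifierConfig(input_size=32, width_scale=0.25, age_fusion=True)
        clf = build_classifier(cfg)
        clf.forward(rng.random((2, 3, 32, 32)), age=[60.0, 70.0])
        assert clf.fused_dim_ == clf.feature_dim + 1
        with pytest.raises(ValueError, match="age"):
            clf.forward(rng.random((2, 3, 32, 32)))

    def test_binary_head(self, rng):
        clf = build_classifier(ClassifierConfig(num_classes=2, input_size=32,
                                                width_scale=0.25))
        assert classifier_forward(clf, rng.random((2, 3, 32, 32))).shape == (2, 2)

    def test_pretrained_flag_rejected_without_weights(self):
        with pytest.raises(ValueError, match="pretrained"):
            build_classifier(ClassifierConfig(pretrained=True))


class TestWeightedCE:
    def test_perfect_predictions_give_zero(self):
        p = np.eye(3)[[0, 1, 2]]
        assert weighted_ce(p, p, np.full(3, 1 / 3)) == pytest.approx(0.0, abs=1e-6)

    def test_single_sample_closed_form(self):
        # uniform weights 1/3, p_true = e^-1 => loss = 1/3
        p = np.array([np.exp(-1.0), 1 - np.exp(-1.0), 0.0])
        y = np.array([1.0, 0.0, 0.0])
        assert weighted_ce(p, y, np.full(3, 1 / 3)) == pytest.approx(1 / 3)

    def test_two_sample_hand_arithmetic(self):
        # -0.2*ln(0.5) and -0.4*ln(0.25), averaged
        p = np.array([[0.5, 0.3, 0.2], [0.5, 0.25, 0.25]])
        y = np.eye(3)[[0, 2]]
        w = np.array([0.2, 0.4, 0.4])
        expected = (-0.2 * np.log(0.5) - 0.4 * np.log(0.25)) / 2
        assert weighted_ce(p, y, w) == pytest.approx(expected)

    def test_uniform_weights_equal_scaled_standard_ce(self, rng):
        from sklearn.metrics import log_loss

        p = rng.dirichlet(np.ones(3), size=20)
        labels = rng.integers(0, 3, size=20)
        y = np.eye(3)[labels]
        ours = weighted_ce(p, y, np.full(3, 1 / 3))
        sk = log_loss(labels, p, labels=[0, 1, 2])
        assert ours * 3 == pytest.approx(sk, rel=1e-6)

    def test_zero_probability_clamped(self):
        p = np.array([[0.0, 1.0, 0.0]])
        y = np.array([[1.0, 0.0, 0.0]])
        val = weighted_ce(p, y, np.full(3, 1 / 3))
        assert np.isfinite(val) and val > 0


@pytest.fixture(scope="module")
def gen():
    return build_generator(GeneratorConfig(input_size=32, depth=4,
                                           base_channels=4), seed=0)


class TestGenerator:
    def test_deterministic_without_dropout(self, gen, rng):
        x = rng.uniform(-1, 1, (1, 3, 32, 32))
        a = generator_forward(gen, x, stochastic=False)
        b = generator_forward(gen, x, stochastic=False)
        assert np.array_equal(a, b)

    def test_stochastic_outputs_differ(self, gen, rng):
        x = rng.uniform(-1, 1, (1, 3, 32, 32))
        a = generator_forward(gen, x, stochastic=True)
        b = generator_forward(gen, x, stochastic=True)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("size,depth", [(16, 4), (32, 5), (64, 6)])
    def test_output_shape_matches_input(self, size, depth, rng):
        g = build_generator(GeneratorConfig(input_size=size, depth=depth,
                                            base_channels=4), seed=1)
        x = rng.uniform(-1, 1, (2, 3, size, size))
        y = g.forward(x)
        assert y.shape == x.shape

    def test_output_bounded_and_finite_over_many_passes(self, gen, rng):
        for _ in range(100):
            y = generator_forward(gen, rng.uniform(-1, 1, (1, 3, 32, 32)),
                                  stochastic=True)
            assert np.all(np.isfinite(y))
            assert y.min() >= -1.0 and y.max() <= 1.0

    def test_size_mismatch_rejected(self, gen, rng):
        with pytest.raises(ValueError):
            gen.forward(rng.uniform(-1, 1, (1, 3, 16, 16)))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            GeneratorConfig(input_size=48, depth=5)


class TestDiscriminator:
    def test_patch_grid_not_global(self, rng):
        d = build_discriminator(DiscriminatorConfig(layer_channels=(8, 16, 32, 32)))
        s = discriminator_forward(d, rng.random((1, 3, 64, 64)),
                                  rng.random((1, 3, 64, 64)))
        assert s.ndim == 3 and s.shape[1] > 1 and s.shape[2] > 1
        assert np.all((s >= 0) & (s <= 1))

    def test_pair_order_matters(self, rng):
        d = build_discriminator(DiscriminatorConfig(layer_channels=(8, 16, 32, 32)))
        a, b = rng.random((1, 3, 64, 64)), rng.random((1, 3, 64, 64))
        assert not np.allclose(discriminator_forward(d, a, b),
                               discriminator_forward(d, b, a))

    def test_one_score_for_one_patch_sized_input(self, rng):
        d = build_discriminator(DiscriminatorConfig(layer_channels=(8, 16, 32, 32),
                                                    pad=0))
        s = d.forward(rng.random((1, 3, 70, 70)), rng.random((1, 3, 70, 70)))
        assert s.shape == (1, 1, 1)

    def test_size_mismatch_rejected(self, rng):
        d = build_discriminator(DiscriminatorConfig(layer_channels=(8, 16, 32, 32)))
        with pytest.raises(ValueError):
            d.forward(rng.random((1, 3, 64, 64)), rng.random((1, 3, 32, 32)))


class TestGanLosses:
    def test_identity_generation_zeroes_l1(self, rng):
        img = rng.random((1, 3, 8, 8))
        s = rng.random((1, 4, 4))
        terms = gan_losses(s, s, img, img, lambda_r=100.0)
        assert terms.g_l1 == 0.0
        assert terms.g_total == terms.g_adv

    def test_zero_lambda_degenerates_to_pure_adversarial(self, rng):
        terms = gan_losses(rng.random((1, 2, 2)), rng.random((1, 2, 2)),
                           rng.random((1, 3, 4, 4)), rng.random((1, 3, 4, 4)),
                           lambda_r=0.0)
        assert terms.g_total == terms.g_adv

    def test_half_probability_scores_give_two_log_two(self):
        s = np.full((1, 3, 3), 0.5)
        img = np.zeros((1, 3, 8, 8))
        terms = gan_losses(s, s, img, img, lambda_r=1.0)
        assert terms.d_real + terms.d_fake == pytest.approx(-2 * np.log(2))

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            gan_losses(rng.random((1, 2, 2)), rng.random((1, 2, 2)),
                       np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 4, 4)),
                       lambda_r=-1.0)


class TestReceptiveField:
    def test_default_patch_size_is_seventy(self):
        assert receptive_field(DiscriminatorConfig()) == 70

    def test_single_unit_kernel(self):
        cfg = DiscriminatorConfig(layer_channels=(), strides=(), kernel=1)
        assert receptive_field(cfg) == 1

    def test_three_strided_layers_match_gradient_support(self):
        measured, expected = receptive_field_by_gradient_support(4, (2, 2, 2))
        assert measured == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_random_configs_match_gradient_support(self, seed):
        r = np.random.default_rng(seed)
        kernel = int(r.integers(2, 6))
        strides = tuple(int(s) for s in r.integers(1, 4, size=r.integers(1, 4)))
        measured, expected = receptive_field_by_gradient_support(kernel, strides,
                                                                 seed=seed)
        assert measured == expected
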