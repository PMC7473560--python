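import numpy as np
import pytest

from petcycle import autodiff as ad
from petcycle.sgan_model import (
    Critic,
    CriticSpec,
    Generator,
    GeneratorSpec,
    LossWeights,
    adversarial_loss,
    build_critic,
    build_generator,
    cycle_loss,
    gradient_penalty,
    identity_loss,
    supervised_loss,
    total_loss,
)

TINY_GEN = GeneratorSpec(base_filters=4, n_residual_modules=2)
TINY_CRITIC = CriticSpec(filters=(4, 8, 8, 16), dense_units=16, input_size=16)


class _FnCritic:
    """Wrap a plain tensor function as a critic."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(ad.as_tensor(x))


def _identity_gen(x):
    return ad.as_tensor(x)


class _ShiftGen:
    def __init__(self, c):
        self.c = c

    def __call__(self, x):
        return ad.as_tensor(x) + self.c


class TestGenerator:
    def test_output_shape_and_nonnegativity(self, rng):
        g = build_generator(TINY_GEN, seed=0)
        for size in (16, 56):
            y = g(rng.normal(size=(2, 1, size, size)))
            assert y.shape == (2, 1, size, size)
            assert y.data.min() >= 0.0

    def test_arbitrary_rectangular_input(self, rng):
        g = build_generator(TINY_GEN, seed=0)
        y = g(rng.random((1, 1, 24, 40)))
        assert y.shape == (1, 1, 24, 40)

    def test_parameter_count_bookkeeping(self):
        # independent per-layer accounting of the architecture
        for spec in (TINY_GEN, GeneratorSpec(base_filters=8, n_residual_modules=3)):
            f, k, c = spec.base_filters, spec.kernel, spec.in_channels
            expected = (c * k * k * f + f) + (f * k * k * f + f)  # stem
            expected += (
                spec.n_residual_modules
                * spec.convs_per_module
                * (f * k * k * f + f + 2 * f)  # conv + bias + BN scale/shift
            )
            cc = spec.concat_channels()
            expected += (cc * k * k * f + f) + (f * k * k * f + f)  # fusion
            expected += f * k * k * c + c  # output conv
            assert build_generator(spec, 0).n_params() == expected

    def test_concat_fanin_default_and_alternative(self):
        spec = GeneratorSpec(base_filters=4, n_residual_modules=2)
        assert spec.concat_channels() == 12  # (modules + last output) * filters
        alt = GeneratorSpec(
            base_filters=4, n_residual_modules=2, include_raw_input_in_concat=True
        )
        assert alt.concat_channels() == 13
        g = build_generator(alt, 0)
        assert g(np.zeros((1, 1, 8, 8))).shape == (1, 1, 8, 8)

    def test_deterministic_given_seed(self, rng):
        x = rng.random((1, 1, 12, 12))
        a = build_generator(TINY_GEN, seed=5)(x)
        b = build_generator(TINY_GEN, seed=5)(x)
        np.testing.assert_array_equal(a.data, b.data)


class TestCritic:
    def test_scalar_score_per_sample(self, rng):
        d = build_critic(TINY_CRITIC, seed=0)
        s = d(rng.random((3, 1, 16, 16)))
        assert s.shape == (3,)
        assert np.all(np.isfinite(s.data))

    def test_zero_image_finite_and_deterministic(self):
        d = build_critic(TINY_CRITIC, seed=0)
        a = d(np.zeros((1, 1, 16, 16)))
        b = d(np.zeros((1, 1, 16, 16)))
        assert np.isfinite(a.data).all()
        np.testing.assert_array_equal(a.data, b.data)

    def test_head_linearity_negation(self, rng):
        # negating the final dense layer's weights negates the score shift
        d = build_critic(TINY_CRITIC, seed=1)
        x = rng.random((2, 1, 16, 16))
        s1 = d(x).data.copy()
        d.dense[1].W.data *= -1
        d.dense[1].b.data *= -1
        s2 = d(x).data
        np.testing.assert_allclose(s2, -s1, atol=1e-12)

    def test_56x56_default_stack(self, rng):
        d = build_critic(CriticSpec(filters=(4, 4, 4, 4), dense_units=8), seed=0)
        assert d(rng.random((1, 1, 56, 56))).shape == (1,)


class TestLosses:
    def test_supervised_zero_for_perfect_generators(self, rng):
        xa = rng.random((2, 1, 4, 4))
        xb = rng.random((2, 1, 4, 4))

        class Swap:
            def __init__(self, out):
                self.out = out

            def __call__(self, x):
                return ad.as_tensor(self.out)

        assert supervised_loss(Swap(xb), Swap(xa), xa, xb).item() == 0.0

    def test_supervised_analytic_ones(self):
        xa = np.zeros((1, 1, 2, 2))
        xb = np.ones((1, 1, 2, 2))
        assert supervised_loss(_identity_gen, _identity_gen, xa, xb).item() == 2.0

    def test_supervised_matches_brute_force(self, rng):
        xa, xb = rng.random((2, 1, 3, 3)), rng.random((2, 1, 3, 3))
        g1, g2 = _ShiftGen(0.1), _ShiftGen(-0.2)
        expected = np.abs((xa + 0.1) - xb).mean() + np.abs((xb - 0.2) - xa).mean()
        assert supervised_loss(g1, g2, xa, xb).item() == pytest.approx(expected)

    def test_cycle_zero_for_identity_and_inverse_pair(self, rng):
        xa, xb = rng.random((2, 1, 3, 3)), rng.random((2, 1, 3, 3))
        assert cycle_loss(_identity_gen, _identity_gen, xa, xb).item() == 0.0
        add, sub = _ShiftGen(0.3), _ShiftGen(-0.3)
        assert cycle_loss(add, sub, xa, xb).item() == pytest.approx(0.0, abs=1e-15)

    def test_cycle_matches_brute_force(self, rng):
        xa, xb = rng.random((2, 1, 3, 3)), rng.random((2, 1, 3, 3))
        g1, g2 = _ShiftGen(0.2), _ShiftGen(0.1)
        expected = (
            np.abs((xa + 0.2 + 0.1) - xa).mean() + np.abs((xb + 0.1 + 0.2) - xb).mean()
        )
        assert cycle_loss(g1, g2, xa, xb).item() == pytest.approx(expected)

    def test_identity_loss_analytic_half_shift(self, rng):
        xa, xb = rng.random((2, 1, 3, 3)), rng.random((2, 1, 3, 3))
        assert identity_loss(_identity_gen, _identity_gen, xa, xb).item() == 0.0
        # G_BA shifts by +0.5: first term contributes exactly 0.5
        val = identity_loss(_identity_gen, _ShiftGen(0.5), xa, xb).item()
        assert val == pytest.approx(0.5)

    def test_identity_matches_brute_force(self, rng):
        xa, xb = rng.random((1, 1, 4, 4)), rng.random((1, 1, 4, 4))
        g1, g2 = _ShiftGen(-0.1), _ShiftGen(0.25)
        expected = np.abs((xa + 0.25) - xa).mean() + np.abs((xb - 0.1) - xb).mean()
        assert identity_loss(g1, g2, xa, xb).item() == pytest.approx(expected)


class TestGradientPenalty:
    def test_sum_over_four_pixels(self, rng):
        critic = _FnCritic(lambda x: ad.tsum(x, axis=(1, 2, 3)))
        r, f = rng.random((3, 1, 2, 2)), rng.random((3, 1, 2, 2))
        assert gradient_penalty(critic, r, f, 10.0, 0).item() == pytest.approx(
            10.0, abs=1e-6
        )

    def test_mean_over_four_pixels(self, rng):
        critic = _FnCritic(lambda x: ad.tmean(x, axis=(1, 2, 3)))
        r, f = rng.random((3, 1, 2, 2)), rng.random((3, 1, 2, 2))
        assert gradient_penalty(critic, r, f, 10.0, 0).item() == pytest.approx(
            2.5, abs=1e-6
        )

    def test_unit_gradient_gives_zero(self, rng):
        critic = _FnCritic(lambda x: ad.tsum(x, axis=(1, 2, 3)))
        r, f = rng.random((3, 1, 1, 1)), rng.random((3, 1, 1, 1))
        assert gradient_penalty(critic, r, f, 10.0, 0).item() == pytest.approx(
            0.0, abs=1e-6
        )


class TestAdversarialLoss:
    def test_constant_critic_reduces_to_penalty(self, rng):
        critic = _FnCritic(lambda x: ad.tsum(x * 0.0, axis=(1, 2, 3)) + 3.0)
        r, f = rng.random((2, 1, 2, 2)), rng.random((2, 1, 2, 2))
        c_obj, g_obj = adversarial_loss(
            _identity_gen, _identity_gen, critic, critic, r, f, 10.0, 0
        )
        # Wasserstein gap cancels; constant critic has zero input gradient,
        # so each direction's penalty is lambda * (0 - 1)^2 = 10
        assert c_obj.item() == pytest.approx(10.0, abs=1e-4)
        assert g_obj.item() == pytest.approx(-3.0)

    def test_identical_batches_zero_wasserstein(self, rng):
        critic = _FnCritic(lambda x: ad.tsum(x, axis=(1, 2, 3)))
        r = rng.random((2, 1, 2, 2))
        c_obj, _ = adversarial_loss(
            _identity_gen, _identity_gen, critic, critic, r, r, 0.0, 0
        )
        assert c_obj.item() == pytest.approx(0.0, abs=1e-12)

    def test_linear_critic_closed_form(self, rng):
        # critic = sum of pixel values; generators shift by known constants
        critic = _FnCritic(lambda x: ad.tsum(x, axis=(1, 2, 3)))
        xa, xb = rng.random((2, 1, 2, 2)), rng.random((2, 1, 2, 2))
        g_ab, g_ba = _ShiftGen(0.5), _ShiftGen(-0.25)
        c_obj, g_obj = adversarial_loss(g_ab, g_ba, critic, critic, xa, xb, 0.0, 0)
        fake_b = xa + 0.5
        fake_a = xb - 0.25
        want_c = 0.5 * (
            (fake_b.sum(axis=(1, 2, 3)).mean() - xb.sum(axis=(1, 2, 3)).mean())
            + (fake_a.sum(axis=(1, 2, 3)).mean() - xa.sum(axis=(1, 2, 3)).mean())
        )
        want_g = 0.5 * (
            -fake_b.sum(axis=(1, 2, 3)).mean() - fake_a.sum(axis=(1, 2, 3)).mean()
        )
        assert c_obj.item() == pytest.approx(want_c, abs=1e-9)
        assert g_obj.item() == pytest.approx(want_g, abs=1e-9)


class TestTotalLoss:
    def test_unit_components_with_reference_weights(self):
        w = LossWeights()
        comps = {"adv": 1.0, "cyclic": 1.0, "identity": 1.0, "sup": 1.0}
        assert total_loss(comps, w) == 21.0

    def test_zero_components(self):
        assert total_loss({"adv": 0, "cyclic": 0, "identity": 0, "sup": 0},
                          LossWeights()) == 0.0

    def test_gamma_zero_recovers_unsupervised_objective(self):
        w = LossWeights(gamma=0.0)
        comps = {"adv": 2.0, "cyclic": 1.0, "identity": 1.0}  # no sup at all
        assert total_loss(comps, w) == 2.0 + 10.0 + 5.0

    def test_nan_component_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            total_loss({"adv": 0.0, "cyclic": float("nan")}, LossWeights())
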