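"""Ancestral sampling, marginal likelihood, masked completion, features, correlations."""

import numpy as np
import pytest

from mcpc.dynamics import InferenceSchedule, run_unclamped
from mcpc.generation import (
    ancestral_sample,
    mc_marginal_loglik,
    neuron_feature,
    pixel_correlation,
    reconstruct_masked,
)
from mcpc.linear_oracle import LinearModelParams, marginal
from mcpc.model import GenerativeModel


def scalar_model(W0=2.0, mu=0.5):
    return GenerativeModel(weights=[np.array([[W0]])], prior_mean=[mu])


class TestAncestralSample:
    def test_linear_model_moments(self):
        s = ancestral_sample(scalar_model(), 100000, np.random.default_rng(0)).ravel()
        ma = marginal(LinearModelParams(2.0, 0.5))
        n = s.size
        assert abs(s.mean() - ma.mean) < 4 * np.sqrt(ma.variance / n)
        assert abs(s.var(ddof=1) - ma.variance) < 4 * ma.variance * np.sqrt(2.0 / n)

    def test_seed_reproducibility(self):
        a = ancestral_sample(scalar_model(), 1, np.random.default_rng(5))
        b = ancestral_sample(scalar_model(), 1, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_zero_weights_pure_layer_noise(self, rng):
        m = GenerativeModel(weights=[np.zeros((3, 2))], prior_mean=np.zeros(2))
        s = ancestral_sample(m, 50000, rng)
        assert abs(s.mean()) < 0.02
        assert s.var() == pytest.approx(1.0, rel=0.05)

    def test_bernoulli_returns_means_or_binary(self, rng):
        m = GenerativeModel.random([5, 3], rng, input_kind="bernoulli", activation="tanh")
        p = ancestral_sample(m, 100, rng)
        assert ((p > 0) & (p < 1)).all()
        b = ancestral_sample(m, 100, rng, binarize=True)
        assert np.isin(b, (0.0, 1.0)).all()

    def test_invalid_n(self, rng):
        with pytest.raises(ValueError):
            ancestral_sample(scalar_model(), 0, rng)

    def test_agrees_with_unclamped_dynamics(self):
        """Ancestral draws and long-run free dynamics target the same marginal."""
        m = scalar_model()
        anc = ancestral_sample(m, 50000, np.random.default_rng(1)).ravel()
        dyn = run_unclamped(m, 10000, np.random.default_rng(2), batch_size=32,
                            burn_in=2000, h=0.02).layers["x0"]
        # the chain's slow mode is long-lived: bound by the across-chain SE
        chain_means = dyn.mean(axis=(0, 2))
        se = chain_means.std(ddof=1) / np.sqrt(chain_means.size)
        assert abs(anc.mean() - dyn.mean()) < 4 * se + 0.02
        chain_vars = dyn.var(axis=(0, 2), ddof=1)
        se_v = chain_vars.std(ddof=1) / np.sqrt(chain_vars.size)
        assert abs(anc.var() - dyn.var(ddof=1)) < 4 * se_v + 0.1


class TestMarginalLoglik:
    def test_linear_model_oracle_value(self):
        """Single datum y=1: estimate matches -ln N(1; 1, 5)."""
        rep = mc_marginal_loglik(scalar_model(), np.array([[1.0]]), 100000,
                                 np.random.default_rng(4))
        assert rep.value == pytest.approx(0.5 * np.log(2 * np.pi * 5.0), abs=0.05)
        assert rep.n == 100000

    def test_estimate_improves_with_samples(self):
        m = scalar_model()
        y = np.array([[4.0]])  # in the tail: small-n estimates overshoot
        exact = 0.5 * np.log(2 * np.pi * 5.0) + 0.5 * 9.0 / 5.0
        errs = []
        for n in (200, 2000, 50000):
            vals = [mc_marginal_loglik(m, y, n, np.random.default_rng(s)).value
                    for s in range(5)]
            errs.append(abs(np.mean(vals) - exact))
        assert errs[2] < errs[0]

    def test_order_invariance(self, rng):
        m = scalar_model()
        data = rng.normal(1, 2, size=(20, 1))
        a = mc_marginal_loglik(m, data, 2000, np.random.default_rng(9)).value
        b = mc_marginal_loglik(m, data[::-1], 2000, np.random.default_rng(9)).value
        assert a == pytest.approx(b, rel=1e-12)

    def test_two_seeds_agree(self):
        m = scalar_model()
        y = np.array([[1.0], [0.0], [2.5]])
        vals = [mc_marginal_loglik(m, y, 50000, np.random.default_rng(s)).value
                for s in (1, 2)]
        assert abs(vals[0] - vals[1]) < 0.1

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            mc_marginal_loglik(scalar_model(), np.array([[1.0]]), 50, rng)


class TestReconstructMasked:
    def test_empty_mask_is_identity(self, rng):
        m = scalar_model()
        y = np.array([[1.7]])
        out = reconstruct_masked(m, y, np.zeros_like(y, dtype=bool))
        np.testing.assert_array_equal(out, y)

    def test_fully_masked_linear_gives_marginal_mode(self):
        m = scalar_model()
        out = reconstruct_masked(m, np.array([[0.0]]), np.array([[True]]))
        assert out[0, 0] == pytest.approx(1.0, abs=1e-3)  # W0 * mu

    def test_observed_entries_untouched(self, rng):
        m = GenerativeModel.random([6, 4], rng, input_kind="bernoulli", activation="tanh")
        y = (rng.random((3, 6)) < 0.5).astype(float)
        mask = np.zeros_like(y, dtype=bool)
        mask[:, :2] = True
        out = reconstruct_masked(m, y, mask)
        np.testing.assert_array_equal(out[:, 2:], y[:, 2:])
        assert ((out[:, :2] > 0) & (out[:, :2] < 1)).all()

    def test_trained_model_reconstructs_better_than_untrained(self, glyph_run):
        """Paired comparison over glyph images with the right half masked."""
        from mcpc.config import build_model
        from mcpc.datasets import toy_glyphs

        trained = glyph_run["model"]
        untrained = glyph_run["log"].checkpoints[0]
        stim = toy_glyphs(50, size=12, rng=np.random.default_rng(31))
        y = stim.flat()
        mask = np.zeros_like(y, dtype=bool)
        mask[:, 72:] = True  # right half of the 12x12 grid flattened row-major
        errs = {}
        for name, m in (("trained", trained), ("untrained", untrained)):
            out = reconstruct_masked(m, y, mask)
            errs[name] = np.mean((out[mask] - y[mask]) ** 2)
        assert errs["trained"] < errs["untrained"]


class TestNeuronFeature:
    def test_linear_one_latent(self):
        f = neuron_feature(scalar_model(), 1, 0, drive=10.0)
        assert f == pytest.approx([20.0])

    def test_zero_drive_bernoulli_uniform_half(self, rng):
        m = GenerativeModel.random([4, 3], rng, input_kind="bernoulli")
        np.testing.assert_allclose(neuron_feature(m, 1, 1, drive=0.0), 0.5)

    def test_relu_positive_homogeneity(self, rng):
        m = GenerativeModel.random([4, 3, 2], rng, activation="relu")
        f10 = neuron_feature(m, 2, 0, drive=10.0)
        f20 = neuron_feature(m, 2, 0, drive=20.0)
        np.testing.assert_allclose(f20, 2.0 * f10, atol=1e-12)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            neuron_feature(scalar_model(), 2, 0)
        with pytest.raises(IndexError):
            neuron_feature(scalar_model(), 1, 5)


class TestPixelCorrelation:
    def test_duplicated_column_full_correlation(self, rng):
        base = (rng.random((200, 3)) < 0.5).astype(float)
        imgs = np.column_stack([base, base[:, 0]])
        C, _, _ = pixel_correlation(imgs, imgs)
        assert C[0, 3] == pytest.approx(1.0)

    def test_independent_pixels_near_zero(self, rng):
        imgs = (rng.random((5000, 16)) < 0.5).astype(float)
        C, _, _ = pixel_correlation(imgs, imgs)
        off = ~np.eye(16, dtype=bool)
        assert C[off].mean() < 0.05

    def test_constant_reference_pixel_excluded(self, rng):
        ref = (rng.random((100, 4)) < 0.5).astype(float)
        ref[:, 2] = 0.0  # constant in the reference set
        smp = (rng.random((100, 4)) < 0.5).astype(float)
        Cs, Cr, _ = pixel_correlation(smp, ref)
        assert Cs.shape == (3, 3) and Cr.shape == (3, 3)

    def test_too_few_images(self, rng):
        with pytest.raises(ValueError):
            pixel_correlation(np.zeros((1, 4)), np.zeros((5, 4)))
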