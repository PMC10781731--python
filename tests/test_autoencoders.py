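"""Autoencoder architectures, losses, gradients and training contracts."""

import numpy as np
import pytest

from xdec import (MLPAutoencoderSpec, TrainingConfig, XVAESpec,
                  build_mlp_autoencoder, build_xvae, encode_dataset,
                  gaussian_prior_kl, reparameterize, train, xvae_loss)
from xdec._nn import collect_params
from conftest import make_dataset, rows_as_new_samples


def tiny_mixed(n=32, seed=0):
    rng = np.random.default_rng(seed)
    return make_dataset(
        {f"v{i}": rng.normal(size=n) for i in range(5)},
        {f"b{i}": rng.integers(0, 2, size=n).astype(float) for i in range(3)})


class TestArchitecture:
    def test_mlp_default_layer_chain(self):
        m = build_mlp_autoencoder(80)
        assert [m.enc1.W.shape, m.enc2.W.shape, m.dec1.W.shape, m.dec2.W.shape] \
            == [(80, 64), (64, 8), (8, 64), (64, 80)]

    def test_mlp_custom_chain_and_reconstruction_dim(self):
        m = build_mlp_autoencoder(5, MLPAutoencoderSpec(hidden=3, latent=2))
        x = np.random.default_rng(0).normal(size=(7, 5))
        assert m.forward(x).shape == (7, 5)
        assert m.encode(x).shape == (7, 2)

    def test_zero_latent_rejected(self):
        with pytest.raises(ValueError):
            MLPAutoencoderSpec(latent=0)

    def test_xvae_two_output_heads(self):
        m = build_xvae(XVAESpec(p_num=20, p_cat=10, latent=8))
        rn, pc, mu, sd = m.forward(np.zeros((3, 20)), np.zeros((3, 10)),
                                   np.zeros((3, 8)))
        assert rn.shape == (3, 20) and pc.shape == (3, 10)
        assert mu.shape == (3, 8) and (sd > 0).all()
        assert ((pc > 0) & (pc < 1)).all()

    def test_xvae_mirrored_parameter_counts(self):
        spec = XVAESpec(p_num=6, p_cat=6, branch_hidden=4, fused_hidden=5, latent=3)
        m = build_xvae(spec)
        # mirror pairs: branch in/out layers and fuse/dec_fuse transpose shapes
        assert m.enc_num.W.shape == m.out_num.W.shape[::-1]
        assert m.enc_cat.W.shape == m.out_cat.W.shape[::-1]
        assert m.fuse.W.shape == (2 * 4, 5) and m.dec_fuse.W.shape == (3, 5)

    def test_xvae_requires_both_blocks(self):
        with pytest.raises(ValueError, match="binary"):
            XVAESpec(p_num=5, p_cat=0)


class TestLossPieces:
    def test_reparameterize_arithmetic(self):
        assert np.allclose(
            reparameterize(np.array([1.0, 1.0]), np.array([2.0, 3.0]),
                           np.array([1.0, -1.0])), [3.0, -2.0])

    def test_reparameterize_deterministic_limits(self):
        mu = np.array([0.3, -0.7])
        assert np.allclose(reparameterize(mu, np.ones(2), np.zeros(2)), mu)
        assert np.allclose(reparameterize(mu, np.zeros(2), np.array([5.0, -9.0])), mu)

    def test_kl_zero_at_prior(self):
        assert gaussian_prior_kl(np.zeros(4), np.ones(4)) == pytest.approx(0.0)

    def test_kl_closed_form_value(self):
        assert gaussian_prior_kl(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_kl_nonnegative_random(self, seed):
        rng = np.random.default_rng(seed)
        kl = gaussian_prior_kl(rng.normal(size=6), np.exp(rng.normal(size=6)))
        assert kl >= 0

    def test_xvae_loss_hand_value(self):
        # single sample, p_num = p_cat = 1, beta = 0
        loss = xvae_loss(np.array([[1.0]]), np.array([[1.0]]),
                         np.array([[0.0]]), np.array([[0.5]]),
                         np.zeros((1, 2)), np.ones((1, 2)), kl_weight=0.0)
        assert loss == pytest.approx(1.0 + np.log(2.0))

    def test_perfect_reconstruction_floor(self):
        x_cat = np.array([[1.0, 0.0]])
        loss = xvae_loss(np.array([[2.0]]), x_cat, np.array([[2.0]]), x_cat,
                         np.zeros((1, 2)), np.ones((1, 2)), kl_weight=1.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_variable_count_scaling_invariance(self):
        # doubling p_num with identical per-variable errors leaves the term unchanged
        rng = np.random.default_rng(3)
        x1, r1 = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        x2, r2 = np.hstack([x1, x1]), np.hstack([r1, r1])
        cat = np.ones((4, 2))
        probs = np.full((4, 2), 0.8)
        args = (np.zeros((4, 2)), np.ones((4, 2)))
        assert xvae_loss(x1, cat, r1, probs, *args, kl_weight=0.0) == pytest.approx(
            xvae_loss(x2, cat, r2, probs, *args, kl_weight=0.0))


class TestGradients:
    """Backprop against central finite differences (the independent oracle)."""

    @staticmethod
    def _check(model, loss_fn, rtol=1e-5):
        params, grads = collect_params(model.layers)
        # jitter away from ReLU kinks, where finite differences and the
        # subgradient legitimately disagree (zero biases + 0/1 inputs can
        # put pre-activations exactly at 0)
        jit = np.random.default_rng(42)
        for p in params:
            p += jit.normal(scale=1e-3, size=p.shape)
        base_loss = loss_fn()
        analytic = [g.copy() for g in grads]
        rng = np.random.default_rng(0)
        h = 1e-6
        for p, g in zip(params, analytic):
            for _ in range(3):  # a few random coordinates per array
                ix = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + h
                lp = loss_fn(no_grad=True)
                p[ix] = orig - h
                lm = loss_fn(no_grad=True)
                p[ix] = orig
                numeric = (lp - lm) / (2 * h)
                assert g[ix] == pytest.approx(numeric, rel=rtol, abs=1e-8), \
                    f"gradient mismatch at {ix}"

    def test_mlp_gradients_match_finite_differences(self):
        from xdec._nn import zero_grads
        m = build_mlp_autoencoder(4, MLPAutoencoderSpec(hidden=3, latent=2), seed=1)
        x = np.random.default_rng(2).normal(size=(6, 4))

        def loss_fn(no_grad=False):
            if no_grad:
                return float(np.mean((m.forward(x) - x) ** 2))
            zero_grads(m.layers)
            return m.loss_and_backward(x)

        self._check(m, loss_fn)

    def test_xvae_gradients_match_finite_differences(self):
        from xdec._nn import zero_grads
        spec = XVAESpec(p_num=4, p_cat=3, branch_hidden=3, fused_hidden=4,
                        latent=2, kl_weight=0.7)
        m = build_xvae(spec, seed=1)
        rng = np.random.default_rng(2)
        xn = rng.normal(size=(6, 4))
        xc = rng.integers(0, 2, size=(6, 3)).astype(float)
        eps = rng.normal(size=(6, 2))

        def loss_fn(no_grad=False):
            if no_grad:
                rn, pc, mu, sd = m.forward(xn, xc, eps)
                return xvae_loss(xn, xc, rn, pc, mu, sd, spec.kl_weight)
            zero_grads(m.layers)
            return m.loss_and_backward(xn, xc, eps)

        self._check(m, loss_fn)


class TestTraining:
    def test_same_seed_identical_weights(self):
        ds = tiny_mixed()
        runs = []
        for _ in range(2):
            m = build_xvae(XVAESpec(p_num=5, p_cat=3, branch_hidden=4,
                                    fused_hidden=6, latent=2), seed=3)
            train(m, ds, TrainingConfig(epochs=5, batch_size=8, seed=3))
            runs.append(m.get_weights())
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_loss_decreases_on_structured_data(self):
        ds = tiny_mixed(n=64)
        m = build_mlp_autoencoder(8, MLPAutoencoderSpec(hidden=6, latent=3), seed=0)
        hist = train(m, ds, TrainingConfig(epochs=100, batch_size=16, seed=0))
        assert hist[-1] <= hist[0]
        # beats the zero predictor on z-scale data (variance ~= 1)
        assert hist[-1] < float(np.var(ds.to_matrix()))

    def test_mostly_monotone_loss_trend_on_separable_data(self, small_cohort):
        # minibatch + reparameterisation noise jitters single epochs, so the
        # monotone-trend contract is asserted on decile-averaged epoch losses
        ds, *_ = small_cohort
        m = build_xvae(XVAESpec(p_num=ds.p_num, p_cat=ds.p_cat, latent=3), seed=0)
        hist = np.array(train(m, ds, TrainingConfig(epochs=100, batch_size=32,
                                                    seed=0)))
        deciles = hist.reshape(10, 10).mean(axis=1)
        assert np.mean(np.diff(deciles) > 0) <= 0.05
        assert hist[-1] < hist[0]

    def test_single_epoch_valid(self):
        ds = tiny_mixed()
        m = build_mlp_autoencoder(8, MLPAutoencoderSpec(hidden=4, latent=2))
        hist = train(m, ds, TrainingConfig(epochs=1, batch_size=8))
        assert len(hist) == 1 and np.isfinite(hist[0])

    def test_incomplete_data_rejected(self):
        ds = tiny_mixed()
        ds.numeric.iloc[0, 0] = np.nan
        m = build_mlp_autoencoder(8, MLPAutoencoderSpec(hidden=4, latent=2))
        with pytest.raises(ValueError, match="missing"):
            train(m, ds, TrainingConfig(epochs=1))


class TestEncoding:
    def test_deterministic_and_duplicate_rows(self):
        ds = tiny_mixed(n=16)
        m = build_xvae(XVAESpec(p_num=5, p_cat=3, latent=2), seed=0)
        train(m, ds, TrainingConfig(epochs=3, batch_size=8))
        z1 = encode_dataset(m, ds)
        z2 = encode_dataset(m, ds)
        assert np.array_equal(z1, z2)
        dup = rows_as_new_samples(ds, [0, 0, 1])
        zd = encode_dataset(m, dup)
        assert np.array_equal(zd[0], zd[1])

    def test_permutation_equivariance(self):
        ds = tiny_mixed(n=12)
        m = build_mlp_autoencoder(8, MLPAutoencoderSpec(hidden=4, latent=3), seed=0)
        perm = np.random.default_rng(1).permutation(12)
        z = m.encode(ds.to_matrix())
        zp = m.encode(ds.to_matrix()[perm])
        assert np.allclose(zp, z[perm])

    def test_latent_dimension(self):
        ds = tiny_mixed(n=10)
        m = build_xvae(XVAESpec(p_num=5, p_cat=3, latent=8))
        assert encode_dataset(m, ds).shape == (10, 8)
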