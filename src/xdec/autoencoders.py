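"""Autoencoders supplying the latent space for deep embedded clustering.

Two architectures are provided:

* :class:`MLPAutoencoder` — the plain multilayer-perceptron autoencoder of
  baseline DEC: one hidden layer of 64 neurons and an 8-neuron encoding
  layer by default, mirrored in the decoder, trained on mean squared error.

* :class:`XVAE` — an X-shaped variational autoencoder for mixed data types.
  The numeric block and the binary block each feed their own hidden layer;
  the two branches fuse into a shared hidden layer and a diagonal-Gaussian
  encoding (mean and SD heads).  The decoder mirrors the X: a shared hidden
  layer splits into two branch hidden layers with a linear numeric output
  and a logistic binary output.  The loss is per-variable-scaled MSE plus
  per-variable-scaled binary cross-entropy plus a KL penalty against the
  standard-normal prior.

Both expose ``encode`` (deterministic: the XVAE returns the posterior mean)
and ``encode_backward`` so the clustering engine can push gradients of its
own loss through the encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Linear, collect_params, minibatches, relu, relu_backward, sigmoid, zero_grads
from .datamodel import MixedDataset

_EPS = 1e-7  # probability clipping guard for cross-entropy


@dataclass
class TrainingConfig:
    """Pretraining settings: 500 epochs of minibatches of 64 samples by
    default, Adam with learning rate 1e-3."""
    epochs: int = 500
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class MLPAutoencoderSpec:
    hidden: int = 64
    latent: int = 8

    def __post_init__(self):
        if self.hidden < 1 or self.latent < 1:
            raise ValueError("layer sizes must be >= 1")


@dataclass
class XVAESpec:
    """X-shaped VAE architecture.

    ``kl_weight`` defaults to 1/(p_num + p_cat): because the reconstruction
    terms are normalised per variable, an unscaled KL penalty would dominate
    the objective by roughly the variable count and collapse the posterior
    onto the prior; weighting it down by the total variable count restores
    the balance of the reference formulation, in which reconstruction
    errors are summed over variables against a unit-weight KL term.
    """

    p_num: int
    p_cat: int
    branch_hidden: int = 32
    fused_hidden: int = 64
    latent: int = 8
    kl_weight: float | None = None

    def __post_init__(self):
        if self.p_num < 1 or self.p_cat < 1:
            raise ValueError(
                "XVAE requires both a numeric and a binary block "
                "(use MLPAutoencoder for single-type data)")
        if min(self.branch_hidden, self.fused_hidden, self.latent) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.kl_weight is None:
            self.kl_weight = 1.0 / (self.p_num + self.p_cat)
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


# ---------------------------------------------------------------------------
# functional pieces (also used standalone in tests)
# ---------------------------------------------------------------------------

def reparameterize(mu: np.ndarray, sd: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Draw z = mu + sd * eps (elementwise); eps ~ N(0, 1) during training."""
    sd = np.asarray(sd, float)
    if (sd < 0).any():
        raise ValueError("sd must be non-negative")
    return np.asarray(mu, float) + sd * np.asarray(eps, float)


def gaussian_prior_kl(mu: np.ndarray, sd: np.ndarray) -> float:
    """KL(N(mu, diag(sd^2)) || N(0, I)) = -1/2 sum(1 + log sd^2 - mu^2 - sd^2).

    Summed over latent dimensions; if given a batch, averaged over rows.
    """
    mu = np.atleast_2d(np.asarray(mu, float))
    sd = np.atleast_2d(np.asarray(sd, float))
    if (sd <= 0).any():
        raise ValueError("sd must be strictly positive")
    per_sample = -0.5 * np.sum(1.0 + 2.0 * np.log(sd) - mu ** 2 - sd ** 2, axis=1)
    return float(per_sample.mean())


def binary_cross_entropy(x: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Per-element BCE with probability clipping; inputs may be any shape."""
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return -(x * np.log(p) + (1.0 - x) * np.log(1.0 - p))


def xvae_loss(x_num, x_cat, recon_num, recon_cat_probs, mu, sd,
              kl_weight: float = 1.0) -> float:
    """XVAE objective, averaged over the batch.

    Per sample: (sum of squared numeric errors)/p_num
    + (sum of binary cross-entropies)/p_cat + kl_weight * KL to the prior.
    Scaling each reconstruction term by its own variable count keeps the
    two data types on comparable footing regardless of block widths.
    """
    x_num, recon_num = np.atleast_2d(x_num), np.atleast_2d(recon_num)
    x_cat, recon_cat_probs = np.atleast_2d(x_cat), np.atleast_2d(recon_cat_probs)
    p_num, p_cat = x_num.shape[1], x_cat.shape[1]
    mse = np.sum((x_num - recon_num) ** 2, axis=1) / p_num
    bce = np.sum(binary_cross_entropy(x_cat, recon_cat_probs), axis=1) / p_cat
    return float(np.mean(mse + bce)) + kl_weight * gaussian_prior_kl(mu, sd)


# ---------------------------------------------------------------------------
# MLP autoencoder (baseline DEC)
# ---------------------------------------------------------------------------

class MLPAutoencoder:
    """80 -> 64 -> 8 -> 64 -> 80 by default (ReLU hidden layers, linear
    elsewhere), trained on mean squared error."""

    family = "mlp"

    def __init__(self, p: int, spec: MLPAutoencoderSpec | None = None, *, seed: int = 0):
        self.spec = spec or MLPAutoencoderSpec()
        if not (self.spec.latent < self.spec.hidden < p):
            warnings.warn(
                f"recommended latent < hidden < p; got latent={self.spec.latent}, "
                f"hidden={self.spec.hidden}, p={p}", stacklevel=2)
        self.p = p
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, d = self.spec.hidden, self.spec.latent
        self.enc1 = Linear(p, h, rng)
        self.enc2 = Linear(h, d, rng)
        self.dec1 = Linear(d, h, rng)
        self.dec2 = Linear(h, p, rng)
        self.layers = [self.enc1, self.enc2, self.dec1, self.dec2]
        self.encoder_layers = [self.enc1, self.enc2]

    @property
    def latent_dim(self) -> int:
        return self.spec.latent

    def _matrix(self, ds: MixedDataset) -> np.ndarray:
        return ds.to_matrix()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._a1 = self.enc1.forward(x)
        z = self.enc2.forward(relu(self._a1))
        self._a3 = self.dec1.forward(z)
        return self.dec2.forward(relu(self._a3))

    def loss_and_backward(self, x: np.ndarray) -> float:
        y = self.forward(x)
        n = x.shape[0]
        loss = float(np.mean((y - x) ** 2))
        g = 2.0 * (y - x) / (n * self.p)
        g = self.dec2.backward(g)
        g = relu_backward(g, self._a3)
        g = self.dec1.backward(g)
        g = self.enc2.backward(g)
        g = relu_backward(g, self._a1)
        self.enc1.backward(g)
        return loss

    def encode(self, x: np.ndarray) -> np.ndarray:
        self._a1 = self.enc1.forward(x)
        return self.enc2.forward(relu(self._a1))

    def encode_backward(self, grad_z: np.ndarray) -> None:
        """Accumulate encoder gradients for an upstream dL/dz (clustering phase)."""
        g = self.enc2.backward(grad_z)
        g = relu_backward(g, self._a1)
        self.enc1.backward(g)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


# ---------------------------------------------------------------------------
# X-shaped variational autoencoder (X-DEC)
# ---------------------------------------------------------------------------

class XVAE:
    """Two-branch variational autoencoder over (numeric, binary) blocks."""

    family = "xvae"

    def __init__(self, spec: XVAESpec, *, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        b, f, d = spec.branch_hidden, spec.fused_hidden, spec.latent
        # encoder
        self.enc_num = Linear(spec.p_num, b, rng)
        self.enc_cat = Linear(spec.p_cat, b, rng)
        self.fuse = Linear(2 * b, f, rng)
        self.head_mu = Linear(f, d, rng)
        self.head_logsd = Linear(f, d, rng)
        # decoder (mirrored)
        self.dec_fuse = Linear(d, f, rng)
        self.dec_num = Linear(f, b, rng)
        self.dec_cat = Linear(f, b, rng)
        self.out_num = Linear(b, spec.p_num, rng)
        self.out_cat = Linear(b, spec.p_cat, rng)
        self.layers = [self.enc_num, self.enc_cat, self.fuse, self.head_mu,
                       self.head_logsd, self.dec_fuse, self.dec_num, self.dec_cat,
                       self.out_num, self.out_cat]
        self.encoder_layers = [self.enc_num, self.enc_cat, self.fuse, self.head_mu]

    @property
    def latent_dim(self) -> int:
        return self.spec.latent

    def _matrix(self, ds: MixedDataset) -> tuple[np.ndarray, np.ndarray]:
        return ds.blocks()

    # -- encoder trunk -------------------------------------------------------

    def _encode_trunk(self, x_num: np.ndarray, x_cat: np.ndarray) -> np.ndarray:
        self._an = self.enc_num.forward(x_num)
        self._ac = self.enc_cat.forward(x_cat)
        self._hcat = np.hstack([relu(self._an), relu(self._ac)])
        self._af = self.fuse.forward(self._hcat)
        return relu(self._af)

    def encode(self, x) -> np.ndarray:
        """Posterior mean (deterministic inference latent)."""
        x_num, x_cat = x
        hf = self._encode_trunk(x_num, x_cat)
        return self.head_mu.forward(hf)

    def encode_backward(self, grad_mu: np.ndarray) -> None:
        g = self.head_mu.backward(grad_mu)
        self._trunk_backward(g)

    def _trunk_backward(self, g_hf: np.ndarray) -> None:
        g = relu_backward(g_hf, self._af)
        g = self.fuse.backward(g)
        b = self.spec.branch_hidden
        gn = relu_backward(g[:, :b], self._an)
        gc = relu_backward(g[:, b:], self._ac)
        self.enc_num.backward(gn)
        self.enc_cat.backward(gc)

    # -- full VAE pass -------------------------------------------------------

    def forward(self, x_num: np.ndarray, x_cat: np.ndarray, eps: np.ndarray):
        hf = self._encode_trunk(x_num, x_cat)
        mu = self.head_mu.forward(hf)
        logsd = np.clip(self.head_logsd.forward(hf), -10.0, 10.0)
        sd = np.exp(logsd)
        z = reparameterize(mu, sd, eps)
        self._ad = self.dec_fuse.forward(z)
        hd = relu(self._ad)
        self._adn = self.dec_num.forward(hd)
        self._adc = self.dec_cat.forward(hd)
        recon_num = self.out_num.forward(relu(self._adn))
        logits_cat = self.out_cat.forward(relu(self._adc))
        probs_cat = sigmoid(logits_cat)
        self._cache = (mu, logsd, sd, eps)
        return recon_num, probs_cat, mu, sd

    def loss_and_backward(self, x_num: np.ndarray, x_cat: np.ndarray,
                          eps: np.ndarray) -> float:
        spec = self.spec
        n = x_num.shape[0]
        recon_num, probs_cat, mu, sd = self.forward(x_num, x_cat, eps)
        loss = xvae_loss(x_num, x_cat, recon_num, probs_cat, mu, sd, spec.kl_weight)
        mu, logsd, sd, eps = self._cache
        # reconstruction gradients
        g_yn = 2.0 * (recon_num - x_num) / (n * spec.p_num)
        g_logits = (np.clip(probs_cat, _EPS, 1 - _EPS) - x_cat) / (n * spec.p_cat)
        g = self.out_num.backward(g_yn)
        g_hd = relu_backward(g, self._adn)
        g_hd = self.dec_num.backward(g_hd)
        g = self.out_cat.backward(g_logits)
        g2 = relu_backward(g, self._adc)
        g_hd = g_hd + self.dec_cat.backward(g2)
        g_z = self.dec_fuse.backward(relu_backward(g_hd, self._ad))
        # KL gradients (mean over batch)
        beta = spec.kl_weight
        g_mu = g_z + beta * mu / n
        g_logsd = g_z * sd * eps + beta * (np.exp(2.0 * logsd) - 1.0) / n
        g_hf = self.head_mu.backward(g_mu) + self.head_logsd.backward(g_logsd)
        self._trunk_backward(g_hf)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


def build_mlp_autoencoder(p: int, spec: MLPAutoencoderSpec | None = None,
                          seed: int = 0) -> MLPAutoencoder:
    return MLPAutoencoder(p, spec, seed=seed)


def build_xvae(spec: XVAESpec, seed: int = 0) -> XVAE:
    return XVAE(spec, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model, ds: MixedDataset, cfg: TrainingConfig | None = None) -> list[float]:
    """Pretrain an autoencoder on a complete dataset; returns the per-epoch
    mean loss history.  The trained encoder lives inside *model*; the decoder
    is retained for diagnostics but unused by the clustering engine.
    """
    cfg = cfg or TrainingConfig()
    if not ds.is_complete():
        raise ValueError("training requires a complete dataset (no missing cells); "
                         "filter/impute first")
    rng = np.random.default_rng(cfg.seed)
    params, grads = collect_params(model.layers)
    opt = Adam(params, lr=cfg.learning_rate)
    is_xvae = isinstance(model, XVAE)
    if is_xvae:
        x_num, x_cat = ds.blocks()
    else:
        x_all = ds.to_matrix()
    n = ds.n_samples
    history = []
    for epoch in range(cfg.epochs):
        losses = []
        for idx in minibatches(n, cfg.batch_size, rng):
            zero_grads(model.layers)
            if is_xvae:
                eps = rng.standard_normal((len(idx), model.spec.latent))
                loss = model.loss_and_backward(x_num[idx], x_cat[idx], eps)
            else:
                loss = model.loss_and_backward(x_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


def encode_dataset(model, ds: MixedDataset) -> np.ndarray:
    """Deterministic n x d latent matrix for a dataset (posterior mean for
    the XVAE; no sampling at inference)."""
    return model.encode(model._matrix(ds))
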