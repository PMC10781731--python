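"""Deep embedded clustering engine.

The algorithm proceeds in six steps: (1) pretrain an autoencoder mapping
the inputs to latent features; (2) initialise k cluster centroids with
K-means on the latent features; (3) compute soft labels (Student-t kernel
on latent distance to each centroid) and a sharpened, frequency-deflated
target distribution; (4) jointly optimise encoder weights and centroids by
gradient descent on the KL divergence between soft labels and target;
(5) every ``update_interval`` iterations, recompute soft labels over all
samples — if fewer than ``label_change_tol`` of samples changed hard
cluster membership since the previous check, stop; otherwise refresh the
target and continue; (6) freeze the model and emit final labels.

The user-facing API is statsmodels-flavoured:
``DeepEmbeddedClustering(dataset, ...).fit()`` returns a
:class:`DECResults` carrying labels, centroids, diagnostics and a frozen
``predict`` for external cohorts.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from ._nn import Adam, collect_params, minibatches, zero_grads
from .autoencoders import (MLPAutoencoder, MLPAutoencoderSpec, TrainingConfig,
                           XVAE, XVAESpec, encode_dataset, train)
from .datamodel import MixedDataset, ScalerParams


@dataclass
class DECConfig:
    """Clustering-phase settings.

    k=6 clusters, a convergence check every 140 gradient iterations, and a
    stop when under 1% of samples change hard cluster membership between
    checks are the defaults of the replicated pipeline.
    """
    k: int = 6
    update_interval: int = 140
    label_change_tol: float = 0.01
    max_iterations: int | None = None  # defaults to 20 * update_interval
    kmeans_restarts: int = 10
    batch_size: int = 64
    learning_rate: float = 3e-4  # gentler than pretraining: self-training should
                                 # refine, not tear up, the pretrained embedding
    seed: int = 0
    centroid_update: str = "gradient"  # or "mean": recompute as cluster means at checks

    def __post_init__(self):
        if not (0 < self.label_change_tol <= 1):
            raise ValueError("label_change_tol must be in (0, 1]")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.centroid_update not in ("gradient", "mean"):
            raise ValueError("centroid_update must be 'gradient' or 'mean'")
        if self.max_iterations is None:
            self.max_iterations = 20 * self.update_interval


# ---------------------------------------------------------------------------
# core formulas
# ---------------------------------------------------------------------------

def init_centroids(latent: np.ndarray, cfg: DECConfig) -> np.ndarray:
    """K-means on the latent features; best of ``kmeans_restarts`` runs."""
    n = latent.shape[0]
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} samples, got {n}")
    km = KMeans(n_clusters=cfg.k, n_init=cfg.kmeans_restarts, random_state=cfg.seed)
    km.fit(latent)
    return km.cluster_centers_.astype(float)


def compute_soft_labels(latent: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Student-t (one degree of freedom) soft assignments.

    q_ij = (1 + ||z_i - mu_j||^2)^-1, row-normalised to sum to one.
    """
    d2 = cdist(latent, centroids, "sqeuclidean")
    s = 1.0 / (1.0 + d2)
    return s / s.sum(axis=1, keepdims=True)


def compute_target_distribution(q: np.ndarray) -> np.ndarray:
    """Sharpened, cluster-frequency-deflated target.

    p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j') with f_j = sum_i q_ij.
    Squaring pushes confident assignments further; dividing by the soft
    cluster frequency f_j prevents large clusters from distorting the
    latent space; the final row normalisation keeps rows summing to one.
    """
    f = q.sum(axis=0)
    w = q ** 2 / f
    return w / w.sum(axis=1, keepdims=True)


def kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) = sum_ij p_ij log(p_ij / q_ij), with 0 log 0 = 0."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _check_row_stochastic(m: np.ndarray, what: str, tol: float = 1e-9) -> None:
    rows = m.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=tol):
        raise AssertionError(f"{what} rows do not sum to 1 (max dev "
                             f"{np.abs(rows - 1).max():.2e})")


def _dec_gradients(z: np.ndarray, centroids: np.ndarray, p: np.ndarray,
                   scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of KL(p||q) w.r.t. latent points and centroids.

    For the t-kernel with one degree of freedom:
    dL/dz_i = 2 * sum_j s_ij (p_ij - q_ij) (z_i - mu_j), s_ij = (1+d^2)^-1,
    and dL/dmu_j is its negative column-sum.  *scale* divides the loss
    (e.g. by the batch size).
    """
    d2 = cdist(z, centroids, "sqeuclidean")
    s = 1.0 / (1.0 + d2)
    q = s / s.sum(axis=1, keepdims=True)
    w = 2.0 * s * (p - q) * scale           # n x k
    # dL/dz_i = sum_j w_ij (z_i - mu_j) = z_i * sum_j w_ij - w_i @ centroids
    gz = z * w.sum(axis=1, keepdims=True) - w @ centroids
    gmu = -(w.T @ z - w.sum(axis=0)[:, None] * centroids)
    return gz, gmu


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DeepEmbeddedClustering:
    """Deep embedded clustering model over a mixed-type cohort.

    Parameters
    ----------
    dataset : MixedDataset
        Complete, z-scaled input data.
    family : str
        "dec" (MLP autoencoder over the concatenated blocks) or
        "xdec" (X-shaped variational autoencoder over the two blocks).
    ae_spec : MLPAutoencoderSpec | XVAESpec, optional
        Architecture; defaults mirror the 80 -> 64 -> 8 scale.
    train_config, dec_config : training- and clustering-phase settings.
    scaler : ScalerParams, optional
        Development-cohort scaling statistics, carried for frozen
        application to external cohorts.
    """

    def __init__(self, dataset: MixedDataset, family: str = "xdec", *,
                 ae_spec=None, train_config: TrainingConfig | None = None,
                 dec_config: DECConfig | None = None,
                 scaler: ScalerParams | None = None):
        if family not in ("dec", "xdec"):
            raise ValueError("family must be 'dec' or 'xdec'")
        if not dataset.is_complete():
            raise ValueError("dataset contains missing values; filter/impute first")
        self.dataset = dataset
        self.family = family
        self.train_config = train_config or TrainingConfig()
        self.dec_config = dec_config or DECConfig()
        self.scaler = scaler
        if ae_spec is None:
            if family == "xdec":
                ae_spec = XVAESpec(p_num=dataset.p_num, p_cat=dataset.p_cat)
            else:
                ae_spec = MLPAutoencoderSpec()
        self.ae_spec = ae_spec

    def _build(self, seed: int):
        if self.family == "xdec":
            if (self.ae_spec.p_num, self.ae_spec.p_cat) != (self.dataset.p_num,
                                                            self.dataset.p_cat):
                raise ValueError("XVAESpec block sizes do not match the dataset")
            return XVAE(self.ae_spec, seed=seed)
        return MLPAutoencoder(self.dataset.p_num + self.dataset.p_cat,
                              self.ae_spec, seed=seed)

    def fit(self) -> "DECResults":
        ds, cfg = self.dataset, self.dec_config
        tc = self.train_config
        # step 1: pretrain the autoencoder
        model = self._build(seed=tc.seed)
        pretrain_history = train(model, ds, tc)
        # step 2: K-means initialisation on latent features
        z = encode_dataset(model, ds)
        centroids = init_centroids(z, cfg)
        # steps 3-6: KL self-training
        n = ds.n_samples
        x = model._matrix(ds)
        enc_params, enc_grads = collect_params(model.encoder_layers)
        params = enc_params + [centroids]
        opt = Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed)
        batch_iter = iter(())
        q = compute_soft_labels(encode_dataset(model, ds), centroids)
        _check_row_stochastic(q, "soft labels")
        labels_prev = q.argmax(axis=1)
        p_full = compute_target_distribution(q)
        _check_row_stochastic(p_full, "target distribution")
        kl_history = [kl_loss(p_full, q)]
        change_history: list[float] = []
        converged = False
        t = 0
        while t < cfg.max_iterations:
            t += 1
            try:
                idx = next(batch_iter)
            except StopIteration:
                batch_iter = minibatches(n, cfg.batch_size, rng)
                idx = next(batch_iter)
            xb = (x[0][idx], x[1][idx]) if self.family == "xdec" else x[idx]
            zb = model.encode(xb)
            gz, gmu = _dec_gradients(zb, centroids, p_full[idx], scale=1.0 / len(idx))
            zero_grads(model.encoder_layers)
            model.encode_backward(gz)
            opt.step(enc_grads + [gmu])
            if t % cfg.update_interval == 0:
                z = encode_dataset(model, ds)
                if cfg.centroid_update == "mean":
                    hard = compute_soft_labels(z, centroids).argmax(axis=1)
                    for j in range(cfg.k):
                        if (hard == j).any():
                            centroids[j] = z[hard == j].mean(axis=0)
                q = compute_soft_labels(z, centroids)
                _check_row_stochastic(q, "soft labels")
                labels = q.argmax(axis=1)
                kl = kl_loss(compute_target_distribution(q), q)
                if not np.isfinite(kl):
                    raise FloatingPointError(f"non-finite KL loss at iteration {t}")
                kl_history.append(kl)
                empty = [j for j in range(cfg.k) if not (labels == j).any()]
                if empty:
                    warnings.warn(f"empty cluster(s) at iteration {t}: {empty}",
                                  stacklevel=2)
                changed = float(np.mean(labels != labels_prev))
                change_history.append(changed)
                labels_prev = labels
                if changed < cfg.label_change_tol:
                    converged = True
                    break
                p_full = compute_target_distribution(q)
                _check_row_stochastic(p_full, "target distribution")
        z = encode_dataset(model, ds)
        q = compute_soft_labels(z, centroids)
        return DECResults(self, model, centroids, q, n_iter=t, converged=converged,
                          pretrain_history=pretrain_history, kl_history=kl_history,
                          change_history=change_history)


class DECResults:
    """Frozen fitted clustering model plus fit diagnostics.

    Attributes
    ----------
    labels_ : final hard cluster labels on the training cohort
    soft_labels_ : n x k soft assignment matrix
    centroids_ : k x d latent cluster centres
    converged_ : whether the label-change stopping rule fired
    """

    def __init__(self, model: DeepEmbeddedClustering, network, centroids, q, *,
                 n_iter: int, converged: bool, pretrain_history, kl_history,
                 change_history):
        self.model = model
        self.network = network
        self.centroids_ = centroids
        self.soft_labels_ = q
        self.labels_ = q.argmax(axis=1)
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.pretrain_history_ = pretrain_history
        self.kl_history_ = kl_history
        self.change_history_ = change_history
        self.manifest_fingerprint = model.dataset.manifest.fingerprint()

    @property
    def k(self) -> int:
        return self.model.dec_config.k

    @property
    def scaler(self) -> ScalerParams | None:
        return self.model.scaler

    def encode(self, ds: MixedDataset) -> np.ndarray:
        if ds.manifest.fingerprint() != self.manifest_fingerprint:
            raise ValueError("dataset variables do not match the fitted model's manifest")
        return encode_dataset(self.network, ds)

    def predict(self, ds: MixedDataset) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic frozen assignment of (possibly external) samples.

        The dataset must already be scaled with the development cohort's
        statistics.  Returns (hard labels, soft labels); argmax ties break
        to the lowest cluster index.  No parameters are updated.
        """
        q = compute_soft_labels(self.encode(ds), self.centroids_)
        return q.argmax(axis=1), q

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.model.dec_config
        sizes = np.bincount(self.labels_, minlength=cfg.k)
        buf.write("Deep Embedded Clustering Results\n")
        buf.write("=" * 40 + "\n")
        buf.write(f"family:           {self.model.family}\n")
        buf.write(f"n samples:        {self.model.dataset.n_samples}\n")
        buf.write(f"clusters (k):     {cfg.k}\n")
        buf.write(f"latent dim:       {self.network.latent_dim}\n")
        buf.write(f"iterations:       {self.n_iter_}\n")
        buf.write(f"converged:        {self.converged_}\n")
        buf.write(f"final KL loss:    {self.kl_history_[-1]:.6f}\n")
        if self.change_history_:
            buf.write(f"last label change: {100 * self.change_history_[-1]:.2f}%\n")
        buf.write("cluster sizes:    " + " ".join(
            f"{j}:{s}" for j, s in enumerate(sizes)) + "\n")
        return buf.getvalue()

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Single-file bundle: architecture, weights, centroids, scaler,
        manifest fingerprint, configs and seeds."""
        meta = {
            "family": self.model.family,
            "ae_spec": asdict(self.model.ae_spec),
            "train_config": asdict(self.model.train_config),
            "dec_config": asdict(self.model.dec_config),
            "manifest_fingerprint": self.manifest_fingerprint,
            "n_iter": self.n_iter_,
            "converged": self.converged_,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        arrays["centroids"] = self.centroids_
        if self.scaler is not None:
            arrays["scaler_mean"] = self.scaler.mean.to_numpy()
            arrays["scaler_sd"] = self.scaler.sd.to_numpy()
            meta["scaler_vars"] = list(self.scaler.mean.index)
        np.savez(path, meta=json.dumps(meta), **arrays)

    @staticmethod
    def load(path, dataset: MixedDataset) -> "DECResults":
        """Rebuild a frozen model against a dataset with a matching manifest."""
        import pandas as pd
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            arrays = {k: f[k] for k in f.files if k != "meta"}
        scaler = None
        if "scaler_vars" in meta:
            idx = pd.Index(meta["scaler_vars"])
            scaler = ScalerParams(pd.Series(arrays["scaler_mean"], index=idx),
                                  pd.Series(arrays["scaler_sd"], index=idx))
        spec_cls = XVAESpec if meta["family"] == "xdec" else MLPAutoencoderSpec
        model = DeepEmbeddedClustering(
            dataset, meta["family"], ae_spec=spec_cls(**meta["ae_spec"]),
            train_config=TrainingConfig(**meta["train_config"]),
            dec_config=DECConfig(**meta["dec_config"]), scaler=scaler)
        network = model._build(seed=model.train_config.seed)
        weights = [arrays[f"w{i}"] for i in range(sum(1 for k in arrays
                                                      if k.startswith("w")))]
        network.set_weights(weights)
        centroids = arrays["centroids"]
        q = compute_soft_labels(encode_dataset(network, dataset), centroids)
        res = DECResults(model, network, centroids, q, n_iter=meta["n_iter"],
                         converged=meta["converged"], pretrain_history=[],
                         kl_history=[kl_loss(compute_target_distribution(q), q)],
                         change_history=[])
        if res.manifest_fingerprint != meta["manifest_fingerprint"]:
            raise ValueError("dataset manifest does not match the saved model")
        return res
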