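"""Convenience constructors tying the autoencoder and clustering engine
into one retrainable pipeline, as the stability and grid-search procedures
require (they retrain the entire pipeline per subset)."""

from __future__ import annotations

from dataclasses import replace

from .autoencoders import MLPAutoencoderSpec, TrainingConfig, XVAESpec
from .datamodel import MixedDataset, ScalerParams
from .dec import DECConfig, DECResults, DeepEmbeddedClustering


def make_pipeline_factory(family: str = "xdec", *,
                          hidden: int = 64, latent: int = 8,
                          branch_hidden: int = 32,
                          train_config: TrainingConfig | None = None,
                          dec_config: DECConfig | None = None,
                          scaler: ScalerParams | None = None):
    """Return ``factory(ds, seed) -> DECResults`` training a fresh pipeline.

    The seed overrides both the pretraining and clustering seeds, so
    repeated calls with the same (dataset, seed) are bit-reproducible and
    different subsets train independently.
    """
    train_config = train_config or TrainingConfig()
    dec_config = dec_config or DECConfig()

    def factory(ds: MixedDataset, seed: int) -> DECResults:
        if family == "xdec":
            spec = XVAESpec(p_num=ds.p_num, p_cat=ds.p_cat,
                            branch_hidden=branch_hidden,
                            fused_hidden=hidden, latent=latent)
        else:
            spec = MLPAutoencoderSpec(hidden=hidden, latent=latent)
        model = DeepEmbeddedClustering(
            ds, family, ae_spec=spec,
            train_config=replace(train_config, seed=seed),
            dec_config=replace(dec_config, seed=seed),
            scaler=scaler)
        return model.fit()

    return factory
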