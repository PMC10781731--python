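# xdec — deep embedded clustering for mixed-type cohort data

Patient populations in intensive care are heterogeneous: dozens of
laboratory summaries, vital signs and binary clinical flags per admission,
with no labels saying which patients "belong together".  Deep Embedded
Clustering (DEC) finds such subgroups by pretraining an autoencoder,
initialising cluster centroids with K-means on the latent features, and
then jointly refining encoder and centroids against a self-training target.
Plain DEC, however, treats every column alike, which handles a mix of
continuous and binary variables poorly.  **X-DEC** replaces the autoencoder
with an X-shaped variational autoencoder (XVAE): the numeric block and the
binary block each get their own encoder branch, fused into a shared
Gaussian latent space, with a per-datatype reconstruction loss (MSE for
numerics, cross-entropy for binaries, each normalised by its block width).

This package implements, for methodologists and clinical data scientists:

* **Both model families** — baseline DEC (MLP autoencoder, 80→64→8 by
  default) and X-DEC — as `DeepEmbeddedClustering(dataset, family).fit()`
  returning a `DECResults` object (labels, soft labels, centroids,
  convergence diagnostics, `summary()`, `predict()` for frozen application,
  `save()`/`load()`).
* **Cluster stability**: retrain the entire pipeline on R random 90%
  subsets, map each run's clusters onto a complete model by iterative
  exclusive Jaccard matching, and report cluster-wise Jaccard coefficients
  and sample-wise stability fractions.
* **Cluster generalisability**: apply a frozen model to an external cohort
  (scaled with the development cohort's statistics) and map each external
  cluster to its most similar development cluster in input space (Gower
  distance), outcome space and latent space (Euclidean), non-exclusively.
* **Architecture grid search** optimising cluster-wise stability.
* **A synthetic cohort generator** with planted cluster structure,
  cluster-linked outcomes (length of stay, ICU mortality, admission
  diagnosis, vasoactive requirement) and paired development/external
  cohorts with nuisance shifts, so every procedure is testable without
  restricted patient data.

## The algorithm in brief

Soft assignments use a Student-t kernel on latent distance to centroids,

    q_ij = (1 + ||z_i − μ_j||²)⁻¹ / Σ_j' (1 + ||z_i − μ_j'||²)⁻¹,

sharpened into a frequency-deflated target

    p_ij = (q_ij² / f_j) / Σ_j' (q_ij'² / f_j'),   f_j = Σ_i q_ij,

and the encoder and centroids minimise KL(p ‖ q) by minibatch gradient
descent.  Every 140 iterations the soft labels are recomputed over all
samples; when fewer than 1% of samples change hard cluster membership the
clustering is final.  The XVAE loss per sample is
`‖x_num − x̂_num‖²/p_num + BCE(x_cat, x̂_cat)/p_cat + β·KL(N(μ,σ²) ‖ N(0,I))`.

## Worked example

```python
from xdec import (SyntheticSpec, generate_cohort, fit_scaler, apply_scaler,
                  DeepEmbeddedClustering, DECConfig)

cohort = generate_cohort(SyntheticSpec(n=600, k=4, p_num=20, p_cat=10,
                                       delta=5.0, seed=1))
scaler = fit_scaler(cohort.dataset)
ds = apply_scaler(cohort.dataset, scaler)

model = DeepEmbeddedClustering(ds, "xdec", dec_config=DECConfig(k=4),
                               scaler=scaler)
results = model.fit()
print(results.summary())
```

prints

```
Deep Embedded Clustering Results
========================================
family:           xdec
n samples:        600
clusters (k):     4
latent dim:       8
iterations:       140
converged:        True
final KL loss:    73.426913
last label change: 0.67%
cluster sizes:    0:146 1:142 2:164 3:148
```

i.e. the label-change stopping rule fired at the first convergence check
(iteration 140, with 0.67% of samples changing cluster since
initialisation — below the 1% tolerance), and the four clusters sit close
to the planted 150/150/150/150 mixture.  The adjusted Rand index of
`results.labels_` against `cohort.true_labels` here is 0.948.  (The KL
value is the total over all samples; it is a diagnostic, not a quality
score.)

The same pipeline is available from the shell:

```bash
xdec simulate --outdir sim --seed 5192
xdec preprocess --data sim/data.csv --manifest sim/manifest.csv --outdir prep
xdec fit --data prep/data_scaled.csv --manifest prep/manifest.csv \
         --scaler prep/scaler.csv --outdir fit
xdec stability --data prep/data_scaled.csv --manifest prep/manifest.csv \
         --outdir stab
```

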