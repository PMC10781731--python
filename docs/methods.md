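# Methods

## Scope and data model

The package clusters per-admission cohort tables with two datatype blocks:
a numeric block (continuous, discrete and ordinal variables — typically
per-stay means and standard deviations of repeated laboratory
measurements) and a binary block.  A variable manifest (name, datatype,
role) is the single source of truth for the schema; datasets, fitted
models and file formats all validate against it.  Outcomes (length of stay
in days, ICU mortality, admission diagnosis category, vasoactive-medication
requirement) are carried separately and used only for evaluation, never for
fitting.

Preprocessing follows the replicated pipeline: variables with more than
40% missing values are removed, then samples with more than 40% missing
values across all input variables; both thresholds are strict
inequalities.  Repeated measurements are summarised per sample as mean and
sample-SD (n−1 denominator; a singleton's SD is missing), doubling the
variable count.  Numeric variables are z-scaled; external cohorts are
always scaled with the development cohort's means and SDs, which is what
makes frozen cross-cohort application well defined.  Two clinical encoding
rules are built in: presence indicators (e.g. replacing a sparsely measured
central-venous-pressure variable by a measured/not-measured flag) and
conditional constant fills (e.g. PEEP set to 5 cmH2O for non-ventilated
patients).  Chained-equation multiple imputation is out of scope: model
entry points reject incomplete data, and a documented mean/mode single
imputation is available behind an explicit flag.  Scaling statistics are
computed on the data as given to `fit_scaler`.

## Networks and training

No deep-learning framework is used; the networks are small dense models
with hand-written backpropagation and Adam, and their gradients are
verified against central finite differences in the test suite.

* **MLP autoencoder (baseline DEC)**: input → 64 ReLU → 8 linear latent →
  64 ReLU → linear output, trained on mean squared error.
* **XVAE (X-DEC)**: each block feeds its own hidden layer (default 32
  units); the branches concatenate into a fused hidden layer (default 64)
  ending in mean and log-SD heads of the latent size (default 8).  The
  decoder mirrors the X: fused hidden → two branch hiddens → a linear
  numeric head and a logistic binary head.  The training loss per sample is

      ‖x_num − x̂_num‖²/p_num + BCE(x_cat, p̂_cat)/p_cat + β · KL(N(μ, σ²) ‖ N(0, I)),

  averaged over the batch.  Normalising each reconstruction term by its own
  block width keeps the two datatypes on equal footing regardless of how
  many variables each contributes.

* **KL weight β.** With per-variable-normalised reconstruction terms, a
  unit-weight KL penalty exceeds the reconstruction signal by roughly the
  total variable count and collapses the posterior onto the prior (K-means
  then sees near-identical latent points).  The reference formulation of
  this architecture sums reconstruction errors over variables against an
  unweighted KL term; the equivalent weight in the normalised form is of
  order 1/p.  The default is therefore β = 1/(p_num + p_cat), configurable.

* Pretraining: 500 epochs, shuffled minibatches of 64 (the final short
  batch is used, not dropped), Adam at 1e-3.  The log-SD head keeps SDs
  positive by construction (clipped to e^±10 for numerical safety);
  probabilities are clipped to [1e-7, 1−1e-7] inside the cross-entropy.
* Inference is deterministic: the XVAE's latent representation is the
  posterior mean, with no sampling.  This is what guarantees that two
  identical samples — whichever cohort they come from — receive identical
  latent features and hence identical cluster assignments.

## Clustering engine

Soft labels use the Student-t kernel with one degree of freedom on latent
distance to centroids; the target distribution squares the soft labels and
deflates by soft cluster frequency before row normalisation.  Encoder
weights and centroids are optimised jointly by Adam on KL(p ‖ q) with the
target held constant between refreshes (no gradient flows through p).  The
centroid update is by gradient, matching the original formulation; a
cluster-mean recompute variant is available via
`DECConfig(centroid_update="mean")`.

The loop contract: every `update_interval` (default 140) minibatch
iterations, soft labels are recomputed over *all* samples; if the fraction
of samples whose hard label changed since the previous check falls below
`label_change_tol` (default 1%), the model is frozen.  The change fraction
is measured against the immediately previous check.  Hard labels are the
argmax of the soft labels with ties broken to the lowest cluster index.
Empty clusters at a check are warned about and retained (k is preserved
nominally).  `max_iterations` defaults to 20 · update_interval, after which
a non-converged flag is set.  The DEC-phase learning rate defaults to
3e-4 — gentler than pretraining, since self-training should refine rather
than tear up the pretrained embedding.

## Stability

R subsets (default 1000) of ⌈0.9 n⌉ samples are drawn without replacement
from a seeded plan; the full pipeline retrains on each, with per-run seeds
derived as plan seed + 1 + run index (the complete model uses the plan
seed itself).  Subset clusters map onto complete-model clusters greedily
and exclusively by Jaccard coefficient — the globally best pair first,
both leaving contention — with comparisons restricted to the samples
present in the subset (the only well-defined choice).  Ties break to the
lowest cluster indices.  Reference labels are the per-sample modal mapped
label; for small R a sample may appear in no subset, in which case it
takes the complete model's label and contributes no sample-wise fraction.
Cluster-wise stability is the Jaccard coefficient per (reference cluster,
subset), with cells where no subset cluster mapped to the reference
cluster recorded as missing and excluded from means; the overall Jaccard
coefficient is the mean over all cells.  Sample-wise stability divides by
the number of subsets containing the sample (≈ 0.9 R), since a sample
cannot be assigned anywhere by a run that excluded it.

## Generalisability

A frozen model assigns external samples deterministically.  Per-cluster
profiles are compared in three spaces:

* **input**: within-cluster means of the standardised numeric variables
  and within-cluster proportions of the binary variables, compared by
  Gower distance with ranges pooled over both cohorts' profiles (numeric:
  |Δ|/range, zero-range variables contribute 0; binary proportions: |Δ|,
  staying in [0, 1]; a strict modal-category variant is a flag).  Profiles
  are computed on the standardised inputs the model consumes, since the
  external cohort only exists in that space after the mandated scaling.
* **outcome**: [min–max-scaled mean LOS, mortality rate, diagnosis-category
  proportions], Euclidean.  LOS is min–max scaled across cluster means
  within each cohort separately, so each cohort's component spans [0, 1].
  The diagnosis vocabulary is the union across cohorts (absent categories
  contribute 0).  Vasoactive requirement is excluded by default because a
  systematic cohort-level shift in it would drag every mapping toward one
  cluster; a flag includes it.
* **latent**: per-cluster means of the frozen encoder's latent features,
  Euclidean.

Each external cluster maps non-exclusively to its nearest development
cluster (ties to the lowest index); several external clusters may share a
target.  When the external cohort shares the development cohort's
cluster-defining process, the latent-space mapping is expected to be the
identity — the clusters are defined in that space.

## Grid search

Candidate layer sizes (branch hidden, fused hidden, latent for the XVAE;
hidden, latent for the MLP) are scored by mean cluster-wise Jaccard over a
reduced inner stability loop (R_inner = 50 by default; the winner's
stability should be re-estimated at full R).  Ties break to the fewest
total neurons.  Because the simplest clusters can also be the most stable,
the leaderboard carries a cluster-size-entropy diagnostic alongside the
score — reported, not optimised.

## Synthetic cohorts

The generator emulates the statistical shape of the motivating ICU
cohorts: defaults n = 800, k = 6 clusters, 60 numeric + 20 binary
variables, cluster-linked outcomes, and an optional larger external cohort
with nuisance shifts (numeric offsets, altered mixing proportions, LOS /
mortality / vasoactive offsets), echoing a prospective development cohort
versus a larger retrospective external cohort with systematically higher
LOS and vasoactive use.

Numeric variables are spherical unit-variance Gaussians around cluster
means placed at the vertices of a regular simplex with edge length Δ (the
separation parameter, in within-cluster SD units), randomly rotated into
the full numeric space.  The rotation spreads the between-cluster variance
over all coordinates, so per-variable z-scaling — which caps how much
separation any single standardised coordinate can carry — shrinks the
planted separation only mildly.  Binary variables are per-cluster
Bernoulli draws at 0.5 ± contrast (default 0.3) with random signs, or an
explicit k × p rate matrix.  Outcomes: log-normal LOS with per-cluster
log-means (defaults spanning ≈ 2–14 days), per-cluster mortality (5–50%)
and vasoactive (20–80%) probabilities, and a diagnosis distribution in
which each cluster favours one category.  Missingness injection is MCAR.

What passing tests on these cohorts do **not** show: real admissions have
correlated variables (a correlated-covariance stress option exists),
non-Gaussian marginals, informative missingness, and cluster structure far
from equally-separated spheres.  Synthetic results certify the machinery
(optimisation, mapping, bookkeeping, determinism), not clinical
performance.

## Problem sizes used in the checks

The automated checks run the full pipelines at n = 600 (k = 4, 20 numeric
+ 10 binary variables, Δ = 5) with R = 20 stability subsets and 3
generator seeds, and the mixed-signal comparison at n = 400 with R = 8 —
sizes at which the complete procedure (500-epoch pretraining plus KL
self-training, retrained per subset) remains comfortably reproducible on a
single CPU.  Stability estimates at R = 20 are coarser than at the
production default R = 1000; they are used comparatively (planted vs
structureless, X-DEC vs DEC), not as precise coefficients.

## Numerical and design choices

* SD convention: sample SD (n−1) everywhere (summaries and scaler).
* Argmax/mapping ties: lowest index, documented and tested.
* Soft-label and target rows are asserted row-stochastic (1e-9) at every
  convergence check; KL values at checks must be finite.
* Model bundles serialise architecture, weights, centroids, scaler,
  manifest fingerprint and seeds; load → predict is bit-reproducible on
  the saving platform.
* All randomness flows through seeded NumPy generators; every CLI command
  records its configuration, seed and package version in a run manifest.
  The package-level default seed is 5192.

## Known limitations

* The decoder is frozen during self-training (retraining it jointly is a
  known possible extension).
* k is fixed by configuration (default 6); no automatic selection.
* Subset stability runs execute serially; runs are independent given their
  seeds, so external parallelisation is safe but not provided.
* Gower distance is computed between cluster *profiles*, not between
  individual samples; with few clusters the pooled ranges are coarse.
* The simple imputation fallback understates uncertainty relative to
  chained-equation multiple imputation.
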