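# Methods

This note documents the models and procedures implemented in `latentsim`,
the defaults they use, and the choices made where the design was open.

## The generative model

The compendium model is a variational autoencoder over samples of a
gene-expression matrix scaled to [0, 1] per gene. The encoder maps the
gene vector through one ReLU layer of width `intermediate_dim` to a
latent mean µ and log-variance per latent feature; the decoder mirrors
the encoder and ends in a sigmoid, so decoded values always lie in (0, 1)
and match the input scale. Training minimises

    L = BCE(x, x̂)  +  κ · KL( N(µ, σ²) ‖ N(0, I) )

with the binary cross-entropy summed over genes, the KL summed over
latent dimensions, and both averaged over the batch. During training the
latent code is drawn by the reparameterisation z = µ + exp(½·logvar)·ε;
all downstream use of `encode()` returns the deterministic mean µ, the
standard choice when a single representative code per sample is needed.

κ implements KL warmup: it starts at 0 and grows by `kl_warmup_step` per
epoch, capped at 1, so the model first learns to reconstruct and is only
gradually regularised toward the prior — avoiding posterior collapse.
Validation loss is computed each epoch with the current κ (a config flag
switches to κ = 1) and with z = µ, making it deterministic.

Defaults target full-size compendia (thousands of genes): intermediate
width 2,500, 30 latent features, Adam at learning rate 0.001, batch size
100, warmup step 0.01, 100 epochs, and a 90/10 train/validation split
drawn uniformly over samples without stratification by experiment. The
package's own simulation studies run on a reduced but structurally
identical setting — 300 genes → 100 → 10 latent features, 30 epochs,
1,000 samples — chosen so the whole pipeline (training plus a full
partition sweep with 5 repeats) completes in seconds while preserving
every qualitative property under study. Everything is plain numpy:
forward pass, analytic gradients (checked against finite differences in
the test suite) and Adam updates, bit-reproducible under a seed on a
single thread.

Numerical guards: log-variances are clipped to ±15 before
exponentiation; BCE is computed from logits in softplus form; a NaN loss
aborts with a diagnostic rather than training on.

## Simulating compendia

**Sample-level.** Draw z ~ N(0, I) per sample and decode. Samples are
exchangeable and carry no experiment structure — the model of a
compendium as a bag of independent conditions.

**Experiment-level.** Choose a template experiment (uniformly with
replacement, unless pinned), encode its members, and add one shift
vector to every member latent code: shift = target − centroid, with the
centroid the arithmetic mean of member µ vectors. Adding a common vector
preserves all pairwise latent distances, hence the template's internal
design; the decoded experiment sits elsewhere in expression space,
i.e. it probes a different underlying perturbation with the same design.
Target locations are drawn from a per-dimension Gaussian fitted to the
encoded compendium rather than from the N(0, I) prior: the data's latent
distribution is where decodable samples actually live, and the prior can
place targets in empty regions (the prior remains available behind a
flag). Simulated sample ids are `{experiment_index}_{template_sample_id}`
so provenance stays navigable.

## Noise injection and correction

Experiment-specific technical variability is modelled as one additive
gene-length vector per partition, entries i.i.d. N(0, variance), shared
by every sample of the partition. The default variance 0.2 is large
relative to the 0–1 expression scale — a deliberately strong effect. A
partition is a proxy for a lab or batch; units are samples or whole
experiments (all samples of an experiment then share a partition).
Assignment is a shuffled round-robin, so partition sizes differ by at
most one. Noisy values are *not* clipped to [0, 1]: the correction model
is strictly linear and clipping would break the exactness that makes
this a best-case scenario for noise removal.

Correction fits, per gene, OLS of expression on an intercept plus
sum-to-zero (deviation) coded partition indicators and subtracts the
fitted partition terms — the `limma::removeBatchEffect` model. Deviation
coding keeps the per-gene overall mean rather than shifting genes toward
a reference partition. Consequences worth knowing:

- the injected noise lies exactly in the design span, so it is removed
  exactly — but only up to a per-gene constant (the mean of the injected
  vectors is indistinguishable from a baseline shift), and the fit also
  removes the *data's own* between-partition mean differences, which is
  precisely the signal-removal phenomenon under study;
- k = 1 is the identity; k = n samples is a saturated design that
  collapses every gene to a constant (a warning is emitted, not an
  error — this is the sweep's meaningful degenerate endpoint);
- the fit uses a least-squares solve rather than the closed-form
  group-mean subtraction, so the saturated endpoint leaves solver-level
  round-off rather than exact constants and remains scoreable by SVCCA,
  where it behaves as an unrelated random subspace — the same floor the
  permuted baseline measures. The closed form serves as the independent
  oracle in the tests.

## SVCCA similarity

Two matched compendia (same samples, same order) are each centered per
gene and reduced by SVD to their top `n_components` = 10 principal-
component score matrices; canonical correlation analysis between the two
reduced representations is computed by the deterministic whitened-QR
formulation (singular values of Q₁ᵀQ₂), and the score is the plain mean
of the canonical correlations. The score is invariant to per-gene mean
shifts (hence single-partition noise scores 1) and to right-orthogonal
rotations of gene space. The component count is exposed as a parameter;
changing it moves the crossover point of the partition sweep but not the
qualitative trends, because k partitions perturb the data by a matrix of
rank k − 1 and therefore corrupt at most k − 1 of the retained
components. One structural consequence: at k = 2 the score cannot fall
below about (n_components − 1)/n_components, so the uncorrected curve's
dip deepens over the first several k before recovering.

The similarity floor is the score against a permuted copy in which each
gene column is independently shuffled across samples — sample-level
structure is destroyed, per-gene marginals kept. (Shuffling within rows
instead is available behind a flag; the column reading is the one that
preserves each gene's distribution.) For visual checks, PCA projections
fit components on the noise-free reference and project every other
version onto them, optionally subsampling to 500 samples per compendium.

## The partition-sweep studies

Per repeat, a base compendium is simulated once and reused for every
partition count k; for each k, fresh partition assignment and noise
vectors are derived from (master seed, repeat, k), the noisy and
corrected versions are scored against the base, and the permuted
baseline is scored alongside. Defaults: 5 repeats, reported as mean ± sd
(single curves are too noisy to assert tolerances on); k values
exceeding the number of units are skipped with a warning and recorded in
provenance. The experiment-effect variant holds one experiment per
partition and sweeps the number of experiments instead, separating the
number of noise sources from the per-partition effect size.

## Differential expression and over-representation

Two-group comparison per gene: logFC is the difference of group means on
the input scale (compendium values are log-scale microarray intensities
or treated as such after 0–1 scaling). Residual variances are shrunk
toward a prior s₀² with prior degrees of freedom d₀ estimated by
matching moments of log s² to a scaled-F distribution, with the trigamma
inversion solved by Newton iteration; if the excess variance is
non-positive the prior is degenerate (d₀ = ∞, all genes share s₀²,
normal reference distribution). The moderated t uses the shrunken
variance and d + d₀ degrees of freedom. Forcing d₀ = 0 reproduces the
ordinary pooled t exactly.

Adjustment: BH step-up with monotonicity enforcement and stable
tie-handling, or Bonferroni min(1, m·p) with m defaulting to the number
of tests but overridable (the 0.05/n_genes convention). DEG calling
supports the practical rule BH < 0.05 AND |logFC| > 1, and the stricter
Bonferroni rule; note that on 0–1-scaled data group-mean differences
cannot exceed 1, so the fold-change gate is only meaningful on
unstandardised (e.g. log₂) scales — the package's simulation comparisons
therefore use the Bonferroni rule. Over-representation is the one-sided
Fisher exact (hypergeometric upper tail) of each gene set against the
DEG list within the declared background, BH-adjusted across sets,
enriched at q < 0.02.

## The synthetic-data generator

Samples arise from a linear factor model squashed through a sigmoid:
factor coordinates are an experiment centroid (sd `experiment_spread` =
2.0 across experiments), a reserved group factor carrying a ±
`group_effect`/2 offset for the two condition groups within each
experiment, and within-experiment scatter (sd 0.3); gene values are
sigmoid(t·Lᵀ + b) plus N(0, 0.05) observation noise, clipped to [0, 1].
Exactly `n_differential_genes` = 30 genes load on the group factor
(loadings of magnitude 0.5–1.5, random sign) — these are the ground-truth
differential genes. Defaults produce 20 experiments × 50 samples × 300
genes with clearly separated experiment clusters, mirroring the
structure of real multi-experiment compendia at desk scale.

What the generator does *not* emulate: realistic gene–gene covariance of
any particular organism, count-based noise (values are continuous),
library-size or platform covariates, more than two condition groups, or
unbalanced designs. Tests passing on this generator therefore certify
the pipeline's mechanics and the qualitative phenomena (crossover,
signal removal, DE signal retention), not quantitative thresholds on any
real compendium — on real data the crossover point depends on the noise
magnitude and the signal structure and must be located by running the
sweep on that data.

## Known limitations

- The noise model is additive and linear by construction; the correction
  is its exact counterpart. Real technical variability is neither, so
  real-data corrections are strictly worse than this best case.
- The VAE is trained on a single thread for exact reproducibility;
  multi-threaded BLAS may reorder reductions and break bit-identity
  (not correctness).
- `encode()` returns µ only; analyses that need posterior uncertainty in
  latent space are out of scope.
- The moderated-t implementation covers the two-group design used here,
  not arbitrary design matrices.
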