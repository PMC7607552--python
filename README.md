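# latentsim

Simulation of gene-expression compendia with a variational autoencoder,
and a study pipeline for the question it was built to answer: **when does
correcting experiment-specific (batch) variability help, and when does it
remove the biological signal?**

Expression compendia aggregate samples from hundreds of independent
experiments. Each experiment carries its own technical signature, and the
standard reflex is to remove it with a linear batch-correction model. But
correction fits one effect per batch: with many batches the model soaks up
real biological variation along with the technical noise. `latentsim`
makes this trade-off measurable. It learns a generative model of a
compendium, simulates noise-free compendia from it, injects controlled
per-partition noise, corrects it, and quantifies how similar each version
is to the noise-free original.

## What is in the box

- **`ExpressionVAE` / `VAEResults`** — a two-layer variational autoencoder
  (genes → intermediate ReLU layer → latent mean µ and log-variance σ²;
  mirrored sigmoid decoder). The loss is per-sample binary cross-entropy
  plus κ·KL(q(z|x) ‖ N(0, I)), with κ ramped from 0 by a fixed warmup step
  per epoch. `fit()` returns a results object carrying parameters,
  per-epoch history, `encode`/`decode`, `summary()`, and `save`/`load`.
- **Simulation** — *sample-level*: decode draws z ~ N(0, I) from the
  prior; *experiment-level*: encode a template experiment and translate
  all of its samples by one latent shift vector to a new location drawn
  from the compendium's fitted latent distribution. Translation preserves
  within-experiment geometry exactly, so the simulated experiment keeps
  the template's design but represents a different perturbation.
- **Noise & correction** — balanced random partition assignment (samples
  or whole experiments), one additive N(0, 0.2) gene-length noise vector
  per partition, and per-gene OLS correction on sum-to-zero-coded
  partition indicators (the `limma::removeBatchEffect` model; verified
  against it in the test suite).
- **SVCCA similarity** — each matrix centered per gene, reduced to its top
  10 principal-component scores, compared by canonical correlation
  analysis; the score is the mean canonical correlation. A gene-permuted
  copy of the data provides the "no shared structure" floor.
- **Differential expression** — empirical-Bayes moderated t (variance
  shrinkage with prior df estimated by trigamma-inversion moment
  matching; verified against `limma::eBayes`), BH and Bonferroni
  adjustment, DEG calling, and Fisher-exact over-representation of gene
  sets (enriched at q < 0.02).
- **Synthetic data** — a factor-model generator producing compendia with
  known experiment clusters, two condition groups per experiment, and a
  known set of differential genes, so every stage is testable end to end
  without any download.

Real compendia are read from TSV/CSV (samples × genes or transposed) with
a two-column sample → experiment metadata table, and scaled to [0, 1] per
gene.

## Worked example

```python
import latentsim as ls

comp, truth = ls.generate_compendium(ls.SyntheticSpec(seed=0))   # 1000 x 300
cfg = ls.VAEConfig(input_dim=comp.n_genes, intermediate_dim=100,
                   latent_dim=10, epochs=30, seed=0)
results = ls.ExpressionVAE(comp, cfg).fit()
print(results.summary())

study = ls.run_partition_study(
    results,
    ls.StudyConfig(mode="sample_level", n_samples=1000,
                   partition_counts=(1, 10, 100, 1000), n_repeats=3, seed=0))
print(study.summary()["mean"].round(3))
```

Output:

```
Expression VAE results
========================================================
architecture        300 -> 100 -> 10 (mu, logvar) -> mirrored decoder
epochs              30
batch size          100
learning rate       0.001
KL warmup step      0.01
seed                0
train loss          207.864 (epoch 0) -> 154.489 (epoch 29)
validation loss     205.561 -> 153.551
final KL weight     0.290

condition  corrected  permuted_baseline  uncorrected
count
1              1.000              0.081        1.000
10             0.996              0.089        0.195
100            0.950              0.080        0.500
1000           0.079              0.080        0.754
```

Read the table by column. *Uncorrected* (noisy vs noise-free): a single
shared noise vector (k = 1) is removed by centering, so similarity is 1;
a handful of noise sources (k = 10) corrupts most of the top principal
components and similarity collapses toward the permuted floor (~0.08);
with one noise source per sample (k = 1000) the noise averages out of the
top components and similarity *recovers* to 0.75. *Corrected*: the batch
model restores similarity almost perfectly while partitions are few, then
degrades monotonically — at k = 1000 it has removed all variability and
sits exactly at the permuted floor. The crossover between the two columns
is the point past which correcting does more harm than good.

A `latentsim` console script exposes the same pipeline
(`latentsim synth | train | simulate | study | de | ora`); see
`latentsim --help`.

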