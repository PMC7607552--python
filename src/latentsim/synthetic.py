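"""Synthetic expression compendia with known ground truth.

The generator emulates the structure of public multi-experiment compendia:
samples cluster by experiment, each experiment contrasts two condition
groups (A vs B), and a known subset of genes responds to the group
contrast.  Expression is produced by a linear factor model squashed through
a sigmoid so values live in [0, 1], matching what a sigmoid-output decoder
is trained on.

Generative model, for sample s in experiment e with group label g:

    t_s  = c_e + (+-group_effect / 2) * u_group + eta_s        (factor space)
    x_s  = clip( sigmoid(t_s @ L.T + b) + eps_s , 0, 1 )       (gene space)

where c_e ~ N(0, experiment_spread^2 I) are experiment centroids over the
non-group factors, u_group is the reserved group factor, eta_s is
within-experiment factor scatter, L is the gene x factor loading matrix
(differential genes are exactly those with nonzero loading on the group
factor), b a per-gene baseline, and eps_s iid observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_io import ExpressionCompendium

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_compendium",
    "generate_gene_sets",
    "write_gmt",
    "read_gmt",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic-compendium generator.

    Defaults produce a compendium of 20 experiments x 50 samples (1,000
    samples x 300 genes) with clearly separated experiment clusters and a
    moderate two-group effect inside each experiment — the study conditions
    used throughout the package's simulation experiments.
    """

    n_experiments: int = 20
    samples_per_experiment: int = 50
    n_genes: int = 300
    n_latent_factors: int = 10
    experiment_spread: float = 2.0   # sd of experiment centroids, factor units
    group_effect: float = 1.0        # A-vs-B separation along the group factor
    observation_noise_sd: float = 0.05
    factor_noise_sd: float = 0.3     # within-experiment scatter, factor units
    n_differential_genes: int = 30
    seed: int = 0

    def __post_init__(self):
        for name in ("n_experiments", "samples_per_experiment", "n_genes",
                     "n_latent_factors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("experiment_spread", "group_effect", "observation_noise_sd",
                     "factor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.n_differential_genes <= self.n_genes:
            raise ValueError("n_differential_genes must be in [1, n_genes]")
        if self.n_latent_factors < 2:
            raise ValueError("need >= 2 latent factors (one is reserved for the group contrast)")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated compendium."""

    loadings: np.ndarray            # genes x factors; column 0 = group factor
    baselines: np.ndarray           # per-gene intercepts
    experiment_centroids: np.ndarray  # experiments x factors
    group_of: dict                  # sample_id -> "A" | "B"
    differential_genes: list = field(default_factory=list)  # gene ids

    @property
    def group_factor(self) -> int:
        return 0


def generate_compendium(spec: SyntheticSpec):
    """Generate a compendium plus its ground truth, reproducibly under seed.

    Returns
    -------
    (ExpressionCompendium, SyntheticTruth)
        The compendium is flagged ``scaled`` (values in [0, 1]) and carries
        ``experiment_of`` for every sample.
    """
    rng = np.random.default_rng(spec.seed)
    G, F = spec.n_genes, spec.n_latent_factors

    loadings = rng.normal(0.0, 1.0 / np.sqrt(F), size=(G, F))
    loadings[:, 0] = 0.0
    diff_idx = rng.choice(G, size=spec.n_differential_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_differential_genes)
    loadings[diff_idx, 0] = signs * rng.uniform(0.5, 1.5, size=spec.n_differential_genes)
    baselines = rng.normal(0.0, 0.5, size=G)

    centroids = rng.normal(0.0, spec.experiment_spread,
                           size=(spec.n_experiments, F))
    centroids[:, 0] = 0.0  # group factor reserved for the condition contrast

    sample_ids, exp_of, group_of, latent_rows = [], {}, {}, []
    for e in range(spec.n_experiments):
        for j in range(spec.samples_per_experiment):
            sid = f"exp{e}_s{j}"
            group = "A" if j < spec.samples_per_experiment / 2 else "B"
            t = centroids[e] + rng.normal(0.0, spec.factor_noise_sd, size=F)
            t[0] += (-0.5 if group == "A" else 0.5) * spec.group_effect
            sample_ids.append(sid)
            exp_of[sid] = f"E{e}"
            group_of[sid] = group
            latent_rows.append(t)
    latent = np.asarray(latent_rows)

    clean = expit(latent @ loadings.T + baselines)
    noisy = clean + rng.normal(0.0, spec.observation_noise_sd, size=clean.shape)
    values = np.clip(noisy, 0.0, 1.0)

    gene_ids = [f"g{i}" for i in range(G)]
    comp = ExpressionCompendium(values, sample_ids, gene_ids, exp_of, scaled=True)
    truth = SyntheticTruth(
        loadings=loadings,
        baselines=baselines,
        experiment_centroids=centroids,
        group_of=group_of,
        differential_genes=[gene_ids[i] for i in sorted(diff_idx)],
    )
    return comp, truth


def generate_gene_sets(truth: SyntheticTruth, n_sets: int, set_size: int,
                       enrichment_fraction: float, seed: int,
                       gene_ids=None) -> dict:
    """Build a named gene-set collection with one deliberately enriched set.

    The set named ``"enriched_set"`` draws ``round(enrichment_fraction *
    set_size)`` members from the truly differential genes; all other sets
    (and the remaining members) are uniform draws from the gene universe.
    """
    if not 0 <= enrichment_fraction <= 1:
        raise ValueError("enrichment_fraction must be in [0, 1]")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(truth.loadings.shape[0])]
    if set_size > len(gene_ids):
        raise ValueError("set_size exceeds number of genes")
    rng = np.random.default_rng(seed)
    diff = list(truth.differential_genes)
    n_enriched = int(np.rint(enrichment_fraction * set_size))
    if n_enriched > len(diff):
        raise ValueError(
            f"requested {n_enriched} differential members but truth has {len(diff)}"
        )
    non_diff = [g for g in gene_ids if g not in set(diff)]

    sets = {}
    members = list(rng.choice(diff, size=n_enriched, replace=False)) + \
        list(rng.choice(non_diff, size=set_size - n_enriched, replace=False))
    sets["enriched_set"] = sorted(members)
    for i in range(1, n_sets):
        sets[f"random_set_{i}"] = sorted(
            rng.choice(gene_ids, size=set_size, replace=False)
        )
    return sets


def write_gmt(sets: dict, path, description: str = "synthetic") -> None:
    """Write gene sets in GMT format (name, description, tab-separated members)."""
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets
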