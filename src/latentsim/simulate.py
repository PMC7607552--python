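"""Simulate compendia from a trained VAE.

Two modes mirror how real compendia are assembled:

* **sample-level** — draw latent codes z ~ N(0, I) from the prior and
  decode them; samples are independent and carry no experiment structure.
* **experiment-level** — pick a *template experiment* from an annotated
  compendium, encode its member samples, and translate the whole set by a
  single shift vector to a new latent location drawn from the compendium's
  fitted latent distribution.  Translation preserves all within-experiment
  latent geometry (pairwise distances are unchanged), so the simulated
  experiment keeps the template's design while representing a different
  underlying perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionCompendium
from .vae import VAEResults

__all__ = [
    "SimulatedCompendium",
    "SimulatedExperiment",
    "LatentSamplingDistribution",
    "simulate_samples",
    "fit_latent_distribution",
    "simulate_experiments",
    "translate_experiment",
]


@dataclass
class LatentSamplingDistribution:
    """Per-latent-dimension Gaussian used to draw target locations."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have identical shapes")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0 in every dimension")

    def draw(self, rng) -> np.ndarray:
        return rng.normal(self.mean, self.sd)

    @classmethod
    def standard_normal(cls, latent_dim: int) -> "LatentSamplingDistribution":
        return cls(np.zeros(latent_dim), np.ones(latent_dim))


@dataclass
class SimulatedExperiment:
    """Provenance of one simulated experiment."""

    experiment_id: str
    template_experiment_id: str
    shift: np.ndarray              # latent units, length latent_dim
    member_sample_ids: list = field(default_factory=list)
    template_sample_ids: list = field(default_factory=list)


@dataclass
class SimulatedCompendium(ExpressionCompendium):
    """An :class:`ExpressionCompendium` plus simulation provenance."""

    mode: str = "sample_level"     # or "experiment_level"
    records: list = field(default_factory=list)  # SimulatedExperiment per experiment


def simulate_samples(results: VAEResults, n_samples: int, seed: int) -> SimulatedCompendium:
    """Sample-level simulation: decode n_samples draws from the N(0, I) prior."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    results._require_trained()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, results.config.latent_dim))
    decoded = results.decode(z, sample_ids=[f"sim{i}" for i in range(n_samples)])
    return SimulatedCompendium(
        decoded.values, decoded.sample_ids, decoded.gene_ids,
        experiment_of=None, scaled=True, mode="sample_level",
    )


def fit_latent_distribution(results: VAEResults,
                            comp: ExpressionCompendium) -> LatentSamplingDistribution:
    """Per-dimension Gaussian fit (mean, sd) to the encoded compendium."""
    if comp.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a latent distribution")
    z = results.encode(comp).values
    return LatentSamplingDistribution(z.mean(axis=0), z.std(axis=0, ddof=1))


def translate_experiment(results: VAEResults, comp: ExpressionCompendium,
                         experiment_id, target: np.ndarray):
    """Shift one encoded experiment so its centroid lands on ``target``.

    Returns ``(decoded_compendium, shift, member_sample_ids)``.  The shift
    is ``target - centroid`` where the centroid is the arithmetic mean of
    the member latent means; adding one vector to every member preserves
    all pairwise latent distances exactly.
    """
    members = comp.samples_of_experiment(experiment_id)
    if not members:
        raise ValueError(f"experiment {experiment_id!r} has no samples")
    z = results.encode(comp.subset_samples(members))
    centroid = z.values.mean(axis=0)
    shift = np.asarray(target, dtype=float) - centroid
    decoded = results.decode(z.values + shift, sample_ids=list(members))
    return decoded, shift, members


def simulate_experiments(results: VAEResults, comp: ExpressionCompendium,
                         n_experiments: int | None, seed: int,
                         template_ids=None,
                         target_distribution: str | LatentSamplingDistribution = "fitted",
                         ) -> SimulatedCompendium:
    """Experiment-level simulation by latent-space template translation.

    Parameters
    ----------
    comp : ExpressionCompendium
        Annotated compendium supplying template experiments.
    n_experiments : int or None
        Number of experiments to simulate; templates are drawn uniformly
        with replacement.  If ``template_ids`` is given it pins the
        templates in order (and implies ``n_experiments`` when None).
    target_distribution : "fitted" | "prior" | LatentSamplingDistribution
        Where target locations are drawn from: the per-dimension Gaussian
        fit to the encoded compendium (default, following the data's own
        latent distribution), the N(0, I) prior, or an explicit one.
    """
    if comp.experiment_of is None or not comp.experiments:
        raise ValueError("compendium has no experiment annotation")
    available = comp.experiments
    if template_ids is not None:
        unknown = [t for t in template_ids if t not in set(available)]
        if unknown:
            raise ValueError(f"unknown template experiments: {unknown}")
        if n_experiments is None:
            n_experiments = len(template_ids)
        elif n_experiments != len(template_ids):
            raise ValueError("n_experiments must match len(template_ids) when both given")
    if n_experiments is None or n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")

    if target_distribution == "fitted":
        dist = fit_latent_distribution(results, comp)
    elif target_distribution == "prior":
        dist = LatentSamplingDistribution.standard_normal(results.config.latent_dim)
    elif isinstance(target_distribution, LatentSamplingDistribution):
        dist = target_distribution
    else:
        raise ValueError("target_distribution must be 'fitted', 'prior' or a distribution")

    rng = np.random.default_rng(seed)
    blocks, sample_ids, exp_of, records = [], [], {}, []
    for i in range(n_experiments):
        if template_ids is not None:
            template = template_ids[i]
        else:
            template = available[rng.integers(len(available))]
        target = dist.draw(rng)
        decoded, shift, members = translate_experiment(results, comp, template, target)
        sim_exp = f"simexp{i}"
        new_ids = [f"{i}_{s}" for s in members]
        blocks.append(decoded.values)
        sample_ids.extend(new_ids)
        exp_of.update({s: sim_exp for s in new_ids})
        records.append(SimulatedExperiment(
            experiment_id=sim_exp, template_experiment_id=template,
            shift=shift, member_sample_ids=new_ids, template_sample_ids=members,
        ))
    return SimulatedCompendium(
        np.vstack(blocks), sample_ids, list(comp.gene_ids),
        experiment_of=exp_of, scaled=True,
        mode="experiment_level", records=records,
    )
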