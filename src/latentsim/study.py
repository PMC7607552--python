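"""End-to-end partition-noise simulation studies.

Each study follows the same loop: simulate a base compendium from a
trained VAE, and for every partition count k inject per-partition noise,
score the noisy compendium against the base with SVCCA, apply the linear
correction and score again, and score a gene-permuted copy of the base as
the floor.  Sweeping k traces out the similarity curves whose crossover —
the k beyond which uncorrected data resemble the noise-free compendium
more than corrected data do — is the phenomenon this package studies.

The base compendium (the "compendium without noise") is the unpartitioned
simulated compendium, reused across every k within a repeat; noise is
drawn freshly per (k, repeat) from seeds derived off the master seed so
curves are independent across k but exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import warnings

import numpy as np
import pandas as pd

from .data_io import ExpressionCompendium
from .noise import (assign_partitions, add_partition_noise,
                    correct_partition_noise, DEFAULT_NOISE_VARIANCE)
from .similarity import svcca_similarity, permuted_baseline
from .simulate import simulate_samples, simulate_experiments
from .vae import VAEResults

__all__ = ["StudyConfig", "StudyResult", "run_partition_study",
           "run_experiment_effect_study"]

CONDITIONS = ("uncorrected", "corrected", "permuted_baseline")


@dataclass
class StudyConfig:
    """Configuration of a partition-noise study.

    ``mode`` selects how the base compendium is simulated and how units
    are partitioned: ``sample_level`` (prior-sampled compendium, samples
    partitioned), ``experiment_level`` (template-translated experiments,
    whole experiments partitioned) or ``experiment_effect`` (one
    experiment per partition, sweeping the number of experiments).
    """

    mode: str = "sample_level"
    n_samples: int = 1000
    n_experiments: int = 50
    partition_counts: tuple = (1, 2, 5, 10, 50, 100, 500, 1000)
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    n_repeats: int = 5
    svcca_components: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("sample_level", "experiment_level", "experiment_effect"):
            raise ValueError(f"unknown study mode {self.mode!r}")
        counts = tuple(self.partition_counts)
        if list(counts) != sorted(counts) or any(k < 1 for k in counts):
            raise ValueError("partition_counts must be ascending and >= 1")
        self.partition_counts = counts
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class StudyResult:
    """Long-format score table plus provenance."""

    table: pd.DataFrame   # mode, count, repeat, condition, svcca_score
    config: StudyConfig
    skipped: list = field(default_factory=list)   # (count, repeat, reason)

    def summary(self) -> pd.DataFrame:
        """Mean and sd of the SVCCA score per (count, condition)."""
        g = self.table.groupby(["count", "condition"])["svcca_score"]
        out = g.agg(["mean", "std"]).reset_index()
        return out.pivot(index="count", columns="condition",
                         values=["mean", "std"])

    def mean_scores(self, condition: str) -> pd.Series:
        sub = self.table[self.table["condition"] == condition]
        return sub.groupby("count")["svcca_score"].mean()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def provenance(self) -> dict:
        return {"config": asdict(self.config), "skipped": list(self.skipped)}

    def plot(self, path) -> None:
        """Write the similarity curves (mean +/- sd per condition) as PNG."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        styles = {"uncorrected": dict(color="lightblue", marker="o"),
                  "corrected": dict(color="darkblue", marker="o"),
                  "permuted_baseline": dict(color="grey", linestyle="--")}
        for cond, style in styles.items():
            sub = self.table[self.table["condition"] == cond]
            g = sub.groupby("count")["svcca_score"]
            ax.errorbar(g.mean().index, g.mean(), yerr=g.std().fillna(0),
                        label=cond, **style)
        ax.set_xscale("log")
        ax.set_xlabel("number of partitions")
        ax.set_ylabel("SVCCA similarity to noise-free compendium")
        ax.set_ylim(-0.05, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _derive_seed(master: int, *fields) -> int:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=tuple(int(f) for f in fields))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _safe_svcca(a, b, n_components):
    """SVCCA score, treating a fully degenerate (rank-0) matrix as sharing
    no structure (score 0) instead of failing the sweep."""
    try:
        return svcca_similarity(a, b, n_components=n_components).score
    except ValueError as exc:
        if "rank" in str(exc):
            return 0.0
        raise


def _simulate_base(results: VAEResults, train_comp, cfg: StudyConfig,
                   seed: int, n_experiments=None):
    if cfg.mode == "sample_level":
        return simulate_samples(results, cfg.n_samples, seed=seed)
    if train_comp is None:
        raise ValueError("experiment-level studies need the annotated training compendium")
    n_exp = cfg.n_experiments if n_experiments is None else n_experiments
    return simulate_experiments(results, train_comp, n_exp, seed=seed)


def run_partition_study(results: VAEResults, cfg: StudyConfig,
                        train_comp: ExpressionCompendium | None = None) -> StudyResult:
    """Sweep partition counts; score uncorrected / corrected / permuted.

    For ``sample_level`` the units partitioned are samples; for
    ``experiment_level`` they are whole simulated experiments (all samples
    of an experiment share a partition).  Partition counts exceeding the
    number of units are skipped with a warning and recorded in provenance.
    """
    if cfg.mode == "experiment_effect":
        raise ValueError("use run_experiment_effect_study for experiment_effect mode")
    rows, skipped = [], []
    for rep in range(cfg.n_repeats):
        base = _simulate_base(results, train_comp, cfg, _derive_seed(cfg.seed, rep, 0, 0))
        if cfg.mode == "sample_level":
            unit, unit_ids = "sample", list(base.sample_ids)
        else:
            unit, unit_ids = "experiment", list(base.experiments)
        for k in cfg.partition_counts:
            if k > len(unit_ids):
                warnings.warn(f"k={k} exceeds {len(unit_ids)} units; skipped",
                              UserWarning, stacklevel=2)
                skipped.append((k, rep, f"k exceeds {len(unit_ids)} units"))
                continue
            s_assign = _derive_seed(cfg.seed, rep, k, 1)
            s_noise = _derive_seed(cfg.seed, rep, k, 2)
            s_perm = _derive_seed(cfg.seed, rep, k, 3)
            assignment = assign_partitions(unit_ids, k, seed=s_assign, unit=unit)
            noisy, _ = add_partition_noise(base, assignment,
                                           variance=cfg.noise_variance, seed=s_noise)
            corrected = correct_partition_noise(noisy, assignment)
            scores = {
                "uncorrected": _safe_svcca(noisy, base, cfg.svcca_components),
                "corrected": _safe_svcca(corrected, base, cfg.svcca_components),
                "permuted_baseline": permuted_baseline(
                    base, seed=s_perm, n_components=cfg.svcca_components).score,
            }
            for cond in CONDITIONS:
                rows.append({"mode": cfg.mode, "count": k, "repeat": rep,
                             "condition": cond, "svcca_score": scores[cond]})
    return StudyResult(table=pd.DataFrame(rows), config=cfg, skipped=skipped)


def run_experiment_effect_study(results: VAEResults, cfg: StudyConfig,
                                train_comp: ExpressionCompendium) -> StudyResult:
    """Fixed one-experiment-per-partition analysis.

    For each n in ``partition_counts`` (here: numbers of experiments),
    simulate a compendium of n experiments, partition it into exactly n
    partitions (one experiment each), inject noise, and score the noisy
    and corrected compendia against the unpartitioned compendium of the
    same n experiments.  This disentangles the number of noise sources
    from the per-partition effect size.
    """
    rows = []
    for rep in range(cfg.n_repeats):
        for n_exp in cfg.partition_counts:
            base = simulate_experiments(
                results, train_comp, n_exp,
                seed=_derive_seed(cfg.seed, rep, n_exp, 0))
            assignment = assign_partitions(
                list(base.experiments), n_exp,
                seed=_derive_seed(cfg.seed, rep, n_exp, 1), unit="experiment")
            noisy, _ = add_partition_noise(
                base, assignment, variance=cfg.noise_variance,
                seed=_derive_seed(cfg.seed, rep, n_exp, 2))
            corrected = correct_partition_noise(noisy, assignment)
            scores = {
                "uncorrected": _safe_svcca(noisy, base, cfg.svcca_components),
                "corrected": _safe_svcca(corrected, base, cfg.svcca_components),
                "permuted_baseline": permuted_baseline(
                    base, seed=_derive_seed(cfg.seed, rep, n_exp, 3),
                    n_components=cfg.svcca_components).score,
            }
            for cond in CONDITIONS:
                rows.append({"mode": "experiment_effect", "count": n_exp,
                             "repeat": rep, "condition": cond,
                             "svcca_score": scores[cond]})
    return StudyResult(table=pd.DataFrame(rows), config=cfg)
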