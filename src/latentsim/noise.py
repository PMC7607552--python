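"""Experiment-specific (batch) noise: partition, inject, correct.

The noise model is the simplest one a linear batch-correction method can
remove exactly: every partition (a proxy for a lab or batch) receives one
additive gene-length vector drawn from N(0, variance), shared by all of
its samples.  Correction fits, per gene, an ordinary least-squares model of
expression on partition indicators (sum-to-zero coding plus intercept) and
subtracts the fitted partition terms — the same linear model
limma::removeBatchEffect uses, so corrected data keep the per-gene overall
mean rather than being shifted toward a reference partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionCompendium

__all__ = [
    "PartitionAssignment",
    "PartitionNoise",
    "assign_partitions",
    "add_partition_noise",
    "correct_partition_noise",
    "estimate_partition_effects",
]

DEFAULT_NOISE_VARIANCE = 0.2


@dataclass
class PartitionAssignment:
    """Assignment of units (samples or whole experiments) to partitions."""

    unit: str                      # "sample" | "experiment"
    partition_of: dict             # unit_id -> partition index in [0, k)
    k: int

    def __post_init__(self):
        if self.unit not in ("sample", "experiment"):
            raise ValueError("unit must be 'sample' or 'experiment'")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        parts = set(self.partition_of.values())
        if parts and (min(parts) < 0 or max(parts) >= self.k):
            raise ValueError("partition indices must lie in [0, k)")

    def sample_partitions(self, comp: ExpressionCompendium) -> np.ndarray:
        """Partition index per sample, in compendium sample order."""
        if self.unit == "sample":
            try:
                return np.array([self.partition_of[s] for s in comp.sample_ids])
            except KeyError as exc:
                raise ValueError(f"sample {exc.args[0]!r} not covered by assignment")
        if comp.experiment_of is None:
            raise ValueError("experiment-level assignment needs an annotated compendium")
        try:
            return np.array(
                [self.partition_of[comp.experiment_of[s]] for s in comp.sample_ids]
            )
        except KeyError as exc:
            raise ValueError(f"unit {exc.args[0]!r} not covered by assignment")


@dataclass
class PartitionNoise:
    """Per-partition additive noise vectors (0-1 expression scale)."""

    variance: float
    vectors: np.ndarray            # k x n_genes
    seed: int | None = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("noise vectors must form a k x n_genes matrix")


def assign_partitions(unit_ids, k: int, seed: int, unit: str = "sample") -> PartitionAssignment:
    """Balanced random assignment (shuffled round-robin).

    Partition sizes differ by at most 1; remainder units land in the
    lowest-index partitions.  Reproducible under seed.
    """
    unit_ids = list(unit_ids)
    n = len(unit_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    mapping = {unit_ids[order[i]]: i % k for i in range(n)}
    return PartitionAssignment(unit=unit, partition_of=mapping, k=k)


def add_partition_noise(comp: ExpressionCompendium, assignment: PartitionAssignment,
                        variance: float = DEFAULT_NOISE_VARIANCE, seed: int = 0):
    """Add one shared N(0, variance) gene-length vector per partition.

    Values are *not* clipped to [0, 1]: the downstream correction model is
    strictly linear and clipping would break its exactness.  Returns the
    noisy compendium and the :class:`PartitionNoise` (so tests can compare
    estimated against true effects).
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    part = assignment.sample_partitions(comp)
    rng = np.random.default_rng(seed)
    vectors = rng.normal(0.0, np.sqrt(variance), size=(assignment.k, comp.n_genes))
    values = comp.values + vectors[part]
    noisy = ExpressionCompendium(
        values, list(comp.sample_ids), list(comp.gene_ids),
        dict(comp.experiment_of) if comp.experiment_of is not None else None,
        scaled=False,
    )
    return noisy, PartitionNoise(variance=variance, vectors=vectors, seed=seed)


def _deviation_design(part: np.ndarray, k: int) -> np.ndarray:
    """Intercept + sum-to-zero (deviation) coded partition indicators."""
    n = part.shape[0]
    D = np.zeros((n, k))
    D[:, 0] = 1.0
    for j in range(k - 1):
        D[part == j, j + 1] = 1.0
        D[part == k - 1, j + 1] = -1.0
    return D


def _fit_partition_model(values: np.ndarray, part: np.ndarray, k: int):
    """OLS fit per gene; returns (coef, design) with coef rows matching design."""
    counts = np.bincount(part, minlength=k)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"partition(s) {empty.tolist()} have no samples")
    D = _deviation_design(part, k)
    coef, *_ = np.linalg.lstsq(D, values, rcond=None)
    return coef, D


def correct_partition_noise(comp: ExpressionCompendium,
                            assignment: PartitionAssignment) -> ExpressionCompendium:
    """Remove fitted per-partition effects from every gene.

    With k = 1 the input is returned unchanged.  With k equal to the number
    of samples the design is saturated and every gene column collapses to a
    constant (all variability, wanted or not, is removed); a warning is
    emitted but the call succeeds.
    """
    part = assignment.sample_partitions(comp)
    k = assignment.k
    if k == 1:
        return comp.copy()
    if k == comp.n_samples:
        warnings.warn(
            "one sample per partition: correction removes all variability "
            "(every gene becomes constant)", UserWarning, stacklevel=2,
        )
    coef, D = _fit_partition_model(comp.values, part, k)
    corrected = comp.values - D[:, 1:] @ coef[1:]
    return ExpressionCompendium(
        corrected, list(comp.sample_ids), list(comp.gene_ids),
        dict(comp.experiment_of) if comp.experiment_of is not None else None,
        scaled=False,
    )


def estimate_partition_effects(comp: ExpressionCompendium,
                               assignment: PartitionAssignment) -> np.ndarray:
    """Fitted per-partition effect vectors (k x n_genes, deviations from
    the intercept; rows sum to zero).  Comparable to the injected noise
    vectors up to a common per-gene offset."""
    part = assignment.sample_partitions(comp)
    k = assignment.k
    if k == 1:
        return np.zeros((1, comp.n_genes))
    coef, _ = _fit_partition_model(comp.values, part, k)
    effects = np.vstack([coef[1:], -coef[1:].sum(axis=0)])
    return effects
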