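"""Reading, writing, validating and scaling expression compendia.

A *compendium* is a collection of gene-expression samples aggregated across
many independent experiments.  Internally it is always oriented samples x
genes, with values optionally scaled to [0, 1] per gene (the scaling the
generative model expects, since its decoder is sigmoid-bounded).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCompendium",
    "ScalerParams",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "write_metadata",
    "scale_zero_one",
    "inverse_scale",
    "split_train_validation",
]


class ParseError(ValueError):
    """Raised when a delimited input file violates the expected layout."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ParseError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionCompendium:
    """Samples x genes expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Expression values; after :func:`scale_zero_one` they are unitless
        in [0, 1].
    sample_ids, gene_ids : list of str
        Ordered, unique identifiers for rows and columns.
    experiment_of : dict or None
        Maps ``sample_id -> experiment_id``; ``None`` for compendia without
        experiment annotation.
    scaled : bool
        True once per-gene 0-1 scaling has been applied.
    """

    values: np.ndarray
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)
    experiment_of: dict | None = None
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} != number of sample_ids {len(self.sample_ids)}"
            )
        if p != len(self.gene_ids):
            raise ValueError(
                f"column count {p} != number of gene_ids {len(self.gene_ids)}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        if self.scaled:
            if self.values.size and (
                self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
            ):
                raise ValueError("compendium flagged scaled but values leave [0, 1]")
        if self.experiment_of is not None:
            missing = [s for s in self.experiment_of if s not in set(self.sample_ids)]
            if missing:
                raise ValueError(f"experiment_of refers to unknown samples: {missing[:5]}")

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def experiments(self) -> list:
        """Distinct experiment ids, in first-appearance (sample) order."""
        if self.experiment_of is None:
            return []
        seen, out = set(), []
        for s in self.sample_ids:
            e = self.experiment_of.get(s)
            if e is not None and e not in seen:
                seen.add(e)
                out.append(e)
        return out

    def samples_of_experiment(self, experiment_id) -> list:
        if self.experiment_of is None:
            raise ValueError("compendium has no experiment annotation")
        return [s for s in self.sample_ids if self.experiment_of.get(s) == experiment_id]

    def subset_samples(self, sample_ids) -> "ExpressionCompendium":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        exp = None
        if self.experiment_of is not None:
            exp = {s: self.experiment_of[s] for s in sample_ids if s in self.experiment_of}
        return ExpressionCompendium(
            self.values[rows], list(sample_ids), list(self.gene_ids), exp, self.scaled
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def copy(self) -> "ExpressionCompendium":
        exp = dict(self.experiment_of) if self.experiment_of is not None else None
        return replace(self, values=self.values.copy(), experiment_of=exp)


@dataclass
class ScalerParams:
    """Per-gene minimum and maximum used by the 0-1 scaling."""

    gene_min: np.ndarray
    gene_max: np.ndarray

    def __post_init__(self):
        self.gene_min = np.asarray(self.gene_min, dtype=float)
        self.gene_max = np.asarray(self.gene_max, dtype=float)
        if self.gene_min.shape != self.gene_max.shape:
            raise ValueError("gene_min and gene_max must have the same shape")
        if np.any(self.gene_max < self.gene_min):
            raise ValueError("gene_max < gene_min for at least one gene")


def _delimiter_for(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_matrix(path, samples_in: str = "rows", delimiter=None) -> ExpressionCompendium:
    """Read a delimited expression matrix.

    The file must have one header row and one leading identifier column.
    ``samples_in`` says whether file rows are samples ("rows", default) or
    genes ("columns"); the result is always oriented samples x genes.
    """
    if samples_in not in ("rows", "columns"):
        raise ValueError("samples_in must be 'rows' or 'columns'")
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "column")  # pandas silently mangles duplicate headers
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ParseError(f"malformed delimited file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate row identifier: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if samples_in == "columns":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionCompendium(values, row_ids, col_ids)


def write_expression_matrix(comp: ExpressionCompendium, path, samples_in: str = "rows",
                            delimiter=None) -> None:
    sep = _delimiter_for(path, delimiter)
    df = comp.to_frame()
    if samples_in == "columns":
        df = df.T
    df.to_csv(path, sep=sep)


def read_metadata(path, delimiter=None) -> dict:
    """Read a two-column sample -> experiment table (header row expected)."""
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] != 2:
        raise ParseError(f"metadata must have exactly 2 columns, got {df.shape[1]}")
    samples = df.iloc[:, 0].tolist()
    _check_unique(samples, "sample")
    return dict(zip(samples, df.iloc[:, 1].tolist()))


def write_metadata(experiment_of: dict, path, delimiter="\t") -> None:
    pd.DataFrame(
        {"sample_id": list(experiment_of), "experiment_id": list(experiment_of.values())}
    ).to_csv(path, sep=delimiter, index=False)


def scale_zero_one(comp: ExpressionCompendium):
    """Scale every gene to [0, 1] by (x - min) / (max - min).

    Genes that are constant across all samples map to 0 everywhere (keeping
    the matrix finite and decodable).  Returns the scaled compendium and the
    :class:`ScalerParams` needed to invert the transform.
    """
    if comp.values.size == 0:
        raise ValueError("cannot scale an empty matrix")
    if comp.n_samples < 2:
        raise ValueError("scaling requires at least 2 samples")
    gmin = comp.values.min(axis=0)
    gmax = comp.values.max(axis=0)
    span = gmax - gmin
    safe = np.where(span > 0, span, 1.0)
    scaled = (comp.values - gmin) / safe
    scaled[:, span == 0] = 0.0
    out = ExpressionCompendium(
        scaled, list(comp.sample_ids), list(comp.gene_ids),
        dict(comp.experiment_of) if comp.experiment_of is not None else None,
        scaled=True,
    )
    return out, ScalerParams(gmin, gmax)


def inverse_scale(comp: ExpressionCompendium, params: ScalerParams) -> ExpressionCompendium:
    """Undo :func:`scale_zero_one`. Constant genes are restored to their min."""
    span = params.gene_max - params.gene_min
    values = comp.values * span + params.gene_min
    return ExpressionCompendium(
        values, list(comp.sample_ids), list(comp.gene_ids),
        dict(comp.experiment_of) if comp.experiment_of is not None else None,
        scaled=False,
    )


def split_train_validation(comp: ExpressionCompendium, train_fraction: float, seed: int):
    """Random sample-level split into train / validation compendia.

    Sizes are round(n * f) and n - round(n * f); the split is uniform over
    samples (no stratification by experiment) and reproducible under seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = comp.n_samples
    n_train = int(np.rint(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty side for n={n}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_ids = [comp.sample_ids[i] for i in sorted(order[:n_train])]
    val_ids = [comp.sample_ids[i] for i in sorted(order[n_train:])]
    return comp.subset_samples(train_ids), comp.subset_samples(val_ids)
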