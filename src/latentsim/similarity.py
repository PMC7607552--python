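"""SVCCA similarity between matched compendia, plus PCA projections.

SVCCA (singular-vector canonical correlation analysis) compares two data
representations: each matrix is centered per gene and reduced by SVD to
its top principal-component scores, then canonical correlation analysis
finds basis vectors w, s maximizing corr(w' X1, s' X2).  The similarity
score is the plain mean of the canonical correlations, so it is invariant
to per-gene mean shifts and to rotations of gene space — two compendia
that differ only by such transformations score 1.

The permuted-gene baseline (each gene column independently shuffled across
samples) destroys sample-level structure while preserving gene marginals;
its score is the floor against which real similarity is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .data_io import ExpressionCompendium

__all__ = [
    "SimilarityResult",
    "PCAProjection",
    "svcca_similarity",
    "permute_genes",
    "permuted_baseline",
    "pca_project",
]


@dataclass
class SimilarityResult:
    score: float                       # mean canonical correlation, in [-1, 1]
    canonical_correlations: np.ndarray  # non-increasing, each in [0, 1]
    n_components: int
    weights_a: np.ndarray              # components x components
    weights_b: np.ndarray

    def __post_init__(self):
        self.canonical_correlations = np.asarray(self.canonical_correlations, dtype=float)
        if self.canonical_correlations.shape[0] != self.n_components:
            raise ValueError("need one canonical correlation per component")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "component": np.arange(1, self.n_components + 1),
            "canonical_correlation": self.canonical_correlations,
        })


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, ExpressionCompendium):
        return x.values
    return np.asarray(x, dtype=float)


def _svd_scores(X: np.ndarray, n_components: int) -> np.ndarray:
    """Top principal-component scores (U * S) of the column-centered matrix."""
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = S[0] * max(Xc.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank < n_components:
        raise ValueError(
            f"matrix rank {rank} is below the requested {n_components} components"
        )
    return U[:, :n_components] * S[:n_components]


def _cca(A: np.ndarray, B: np.ndarray):
    """Canonical correlations between two zero-mean score matrices.

    Deterministic whitened-QR formulation: with A = Qa Ra, B = Qb Rb, the
    singular values of Qa' Qb are the canonical correlations and the weight
    vectors are Ra^-1 Ua, Rb^-1 Ub.
    """
    Qa, Ra = np.linalg.qr(A)
    Qb, Rb = np.linalg.qr(B)
    Ua, sigma, Vbt = np.linalg.svd(Qa.T @ Qb)
    sigma = np.clip(sigma, 0.0, 1.0)
    wa = np.linalg.solve(Ra, Ua)
    wb = np.linalg.solve(Rb, Vbt.T)
    return sigma, wa, wb


def svcca_similarity(a, b, n_components: int = 10) -> SimilarityResult:
    """SVCCA score between two matched compendia.

    ``a`` and ``b`` must have the same number of samples in aligned order.
    Each is centered per gene and reduced to its top ``n_components``
    principal-component scores before CCA.
    """
    A, B = _as_matrix(a), _as_matrix(b)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"sample counts differ: {A.shape[0]} vs {B.shape[0]} (must be matched)"
        )
    if n_components > min(A.shape[0] - 1, A.shape[1]) or \
       n_components > min(B.shape[0] - 1, B.shape[1]):
        raise ValueError("n_components exceeds min(samples - 1, genes)")
    Sa = _svd_scores(A, n_components)
    Sb = _svd_scores(B, n_components)
    sigma, wa, wb = _cca(Sa, Sb)
    return SimilarityResult(
        score=float(sigma.mean()), canonical_correlations=sigma,
        n_components=n_components, weights_a=wa, weights_b=wb,
    )


def permute_genes(a, seed: int, mode: str = "within_gene") -> np.ndarray:
    """Structure-destroying permutation of a copy of the matrix.

    ``within_gene`` (default) shuffles each gene column independently
    across samples, destroying sample-level structure while keeping each
    gene's marginal distribution; ``within_sample`` shuffles each row
    across genes instead.
    """
    X = _as_matrix(a).copy()
    rng = np.random.default_rng(seed)
    if mode == "within_gene":
        for j in range(X.shape[1]):
            X[:, j] = X[rng.permutation(X.shape[0]), j]
    elif mode == "within_sample":
        for i in range(X.shape[0]):
            X[i] = X[i, rng.permutation(X.shape[1])]
    else:
        raise ValueError("mode must be 'within_gene' or 'within_sample'")
    return X


def permuted_baseline(a, seed: int, n_components: int = 10,
                      mode: str = "within_gene") -> SimilarityResult:
    """SVCCA of a compendium against its gene-permuted copy (the floor)."""
    return svcca_similarity(a, permute_genes(a, seed, mode), n_components)


@dataclass
class PCAProjection:
    """Scores of one compendium on PCs fitted to a reference compendium."""

    scores: np.ndarray                 # samples x n
    explained_variance_ratio: np.ndarray
    sample_ids: list

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            self.scores, index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )


def pca_project(reference: ExpressionCompendium, others, n: int = 2,
                subsample: int | None = None, seed: int = 0):
    """Fit PCs on the reference and project every compendium onto them.

    ``subsample`` caps the number of samples per projected compendium
    (uniform draw, seeded), as used for plotting large compendia.
    Returns one :class:`PCAProjection` per entry of ``others``.
    """
    ref_genes = list(reference.gene_ids)
    pca = PCA(n_components=n, svd_solver="full")
    pca.fit(reference.values)
    rng = np.random.default_rng(seed)
    out = []
    for comp in others:
        if list(comp.gene_ids) != ref_genes:
            raise ValueError("gene identifiers do not match the reference compendium")
        ids = list(comp.sample_ids)
        values = comp.values
        if subsample is not None and len(ids) > subsample:
            keep = np.sort(rng.choice(len(ids), size=subsample, replace=False))
            values = values[keep]
            ids = [ids[i] for i in keep]
        out.append(PCAProjection(
            scores=pca.transform(values),
            explained_variance_ratio=pca.explained_variance_ratio_.copy(),
            sample_ids=ids,
        ))
    return out
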