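"""Two-group differential expression with empirical-Bayes moderation, and
Fisher over-representation analysis.

The moderated t-statistic shrinks each gene's residual variance s_g^2
toward a pooled prior s0^2 with prior degrees of freedom d0, both
estimated by matching moments of log s_g^2 to a scaled-F distribution
(closed form via trigamma inversion).  The moderated statistic

    t_g = logFC_g / sqrt(s~_g^2 * (1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

is referred to a t distribution with d + d0 degrees of freedom, gaining
power at small group sizes while damping genes whose sample variance is
spuriously small.  "logFC" is the difference of group means on the input
scale (compendium values are log-scale or treated as such after 0-1
scaling).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEResult",
    "ORAResult",
    "moderated_ttest",
    "adjust_pvalues",
    "call_degs",
    "ora_fisher",
]


@dataclass
class DEResult:
    """Per-gene differential-expression table plus moderation hyperparameters."""

    table: pd.DataFrame     # gene, logFC, t_ordinary, t_moderated, p_value, adjusted_p, deg
    d0: float               # prior degrees of freedom
    s0_squared: float       # prior variance
    groups: tuple           # (reference level, comparison level)
    adjust_method: str = "BH"

    @property
    def genes(self):
        return self.table["gene"].tolist()


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_prior(s2: np.ndarray, d: float):
    """Estimate (d0, s0^2) from residual variances with d df each.

    Moment matching on z = log(s^2): under the scaled-F model,
    Var(z) = trigamma(d/2) + trigamma(d0/2), and
    E(z) = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2).
    If the excess variance is non-positive the prior is degenerate
    (d0 = infinity) and every gene shares s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        warnings.warn("too few positive residual variances; using d0 = inf",
                      UserWarning, stacklevel=2)
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, d / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    half_d0 = _trigamma_inverse(excess)
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * half_d0
    s0sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0sq


def moderated_ttest(comp, group_labels, d0: float | None = None,
                    adjust_method: str = "BH") -> DEResult:
    """Empirical-Bayes moderated two-group t-test, per gene.

    Parameters
    ----------
    comp : ExpressionCompendium or (n_samples x n_genes) array
    group_labels : sequence
        One label per sample; exactly two levels, each with >= 2 samples.
    d0 : float, optional
        Force the prior degrees of freedom instead of estimating them
        (0 reproduces the ordinary pooled t; ``inf`` shares one variance).
    """
    from .data_io import ExpressionCompendium

    if isinstance(comp, ExpressionCompendium):
        X = comp.values
        gene_ids = list(comp.gene_ids)
    else:
        X = np.asarray(comp, dtype=float)
        gene_ids = [f"g{i}" for i in range(X.shape[1])]
    labels = np.asarray(group_labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("group_labels must cover every sample")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    m1 = labels == levels[0]
    m2 = labels == levels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1} and {n2})")

    mean1 = X[m1].mean(axis=0)
    mean2 = X[m2].mean(axis=0)
    logfc = mean2 - mean1
    ss = ((X[m1] - mean1) ** 2).sum(axis=0) + ((X[m2] - mean2) ** 2).sum(axis=0)
    d = n1 + n2 - 2
    s2 = ss / d
    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = logfc / (np.sqrt(s2) * se_factor)
        t_ord = np.where(s2 > 0, t_ord,
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))

    if d0 is None:
        d0_est, s0sq = _fit_prior(s2, d)
    else:
        d0_est = float(d0)
        _, s0sq = _fit_prior(s2, d) if d0_est != 0 else (None, float(np.mean(s2)))
    if np.isinf(d0_est):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    elif d0_est == 0:
        s2_post = s2
        df_total = float(d)
    else:
        s2_post = (d0_est * s0sq + d * s2) / (d0_est + d)
        df_total = d + d0_est

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / (np.sqrt(s2_post) * se_factor)
        t_mod = np.where(s2_post > 0, t_mod,
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    adj = adjust_pvalues(p, method=adjust_method)
    table = pd.DataFrame({
        "gene": gene_ids, "logFC": logfc, "t_ordinary": t_ord,
        "t_moderated": t_mod, "p_value": p, "adjusted_p": adj,
        "deg": False,
    })
    return DEResult(table=table, d0=d0_est, s0_squared=float(s0sq),
                    groups=(levels[0], levels[1]), adjust_method=adjust_method)


def adjust_pvalues(p, method: str = "BH", m: int | None = None) -> np.ndarray:
    """Multiple-testing adjustment.

    BH: step-up adjusted values min_{j >= i} (m * p_(j) / j), capped at 1,
    with a stable sort so ties keep input order on output.  Bonferroni:
    min(1, m * p).  ``m`` defaults to len(p); it can be larger when the
    tested genes are a subset of a declared universe.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if method.lower() in ("bonferroni",):
        return np.minimum(1.0, m * p)
    if method.upper() in ("BH", "FDR_BH"):
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        adj = m * ranked / np.arange(1, p.size + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty_like(adj)
        out[order] = adj
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def call_degs(de: DEResult, scheme: str = "fdr_fc", alpha: float = 0.05,
              lfc_threshold: float = 1.0) -> set:
    """Call differentially expressed genes.

    ``fdr_fc``: BH-adjusted p < alpha AND |logFC| > lfc_threshold (the
    common practical rule).  ``bonferroni``: Bonferroni-adjusted p < alpha
    with m = number of genes.  Updates the ``deg`` flag in the table and
    returns the gene-id set.
    """
    t = de.table
    if scheme == "fdr_fc":
        adj = adjust_pvalues(t["p_value"].to_numpy(), method="BH")
        mask = (adj < alpha) & (t["logFC"].abs().to_numpy() > lfc_threshold)
    elif scheme == "bonferroni":
        adj = adjust_pvalues(t["p_value"].to_numpy(), method="bonferroni",
                             m=len(t))
        mask = adj < alpha
    else:
        raise ValueError(f"unknown DEG scheme {scheme!r}")
    de.table = t.assign(adjusted_p=adj, deg=mask)
    de.adjust_method = "BH" if scheme == "fdr_fc" else "bonferroni"
    return set(t.loc[mask, "gene"])


@dataclass
class ORAResult:
    """Per-gene-set over-representation table (sorted by q-value)."""

    table: pd.DataFrame   # set, overlap, set_size, deg_count, background, p, q, enriched
    q_threshold: float = 0.02


def ora_fisher(degs, gene_sets: dict, background, q_threshold: float = 0.02) -> ORAResult:
    """One-sided Fisher exact over-representation of gene sets among DEGs.

    For each set the 2x2 table partitions the background universe by
    set membership and DEG status; the p-value is the hypergeometric upper
    tail P(X >= overlap).  q-values are BH across sets; a set is flagged
    enriched when q < ``q_threshold``.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    degs = set(degs)
    if not degs <= background:
        raise ValueError("DEGs must be a subset of the background universe")
    N, n_deg = len(background), len(degs)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        K = len(members)
        x = len(members & degs)
        # hypergeometric upper tail: P(X >= x)
        p = float(stats.hypergeom.sf(x - 1, N, K, n_deg)) if K else 1.0
        rows.append({"set": name, "overlap": x, "set_size": K,
                     "deg_count": n_deg, "background": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = adjust_pvalues(table["p"].to_numpy(), method="BH")
    table["enriched"] = table["q"] < q_threshold
    table = table.sort_values("q", kind="stable").reset_index(drop=True)
    return ORAResult(table=table, q_threshold=q_threshold)
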