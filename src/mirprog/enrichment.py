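"""Permutation gene-set enrichment and the LS category test.

Genes are ranked by a two-class t statistic (descending).  The
enrichment score of a gene set is the maximum of the classic
(unweighted) Kolmogorov-Smirnov running sum over the ranked list:
+sqrt((N-G)/G) at each set member and -sqrt(G/(N-G)) elsewhere, where N
is the list length and G the overlap size; the walk ends at 0 by
construction.  The null distribution comes from permuting the class
labels and re-ranking the genes each time; the permutation p-value uses
the add-one convention p = (1 + #{ES_perm >= ES_obs}) / (1 + n_perm).

The LS test scores a gene category by the mean of -ln(p) over its
member genes and compares it against random same-size categories drawn
from the tested gene universe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .diffexpr import two_class_ttest
from .normalization import ExpressionMatrix


@dataclass
class EnrichmentResult:
    gene_set_name: str
    observed_es: float
    perm_mean: float
    perm_sd: float
    n_ge_observed: int
    p_value: float
    n_perm: int
    seed: int
    exhaustive: bool = False


def _t_stats(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled-variance t per row; zero-variance rows fall back to the mean difference."""
    g0 = values[:, labels == 0]
    g1 = values[:, labels == 1]
    n0, n1 = g0.shape[1], g1.shape[1]
    m0, m1 = g0.mean(axis=1), g1.mean(axis=1)
    sp2 = ((n0 - 1) * g0.var(axis=1, ddof=1) + (n1 - 1) * g1.var(axis=1, ddof=1)) / (n0 + n1 - 2)
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / se
    bad = ~np.isfinite(t)
    t[bad] = m1[bad] - m0[bad]
    return t


def rank_genes(matrix: ExpressionMatrix, labels: np.ndarray) -> list[str]:
    """Full gene list ordered by the two-class t statistic, descending."""
    labels = np.asarray(labels).astype(int)
    tt = two_class_ttest(matrix.to_log2(), labels)
    if tt["degenerate"].any():
        warnings.warn("degenerate-variance genes ranked by mean difference",
                      RuntimeWarning, stacklevel=2)
    t = _t_stats(matrix.to_log2().values, labels)
    order = np.argsort(-t, kind="stable")
    return [matrix.feature_ids[i] for i in order]


def enrichment_score(ranked_list: list[str], gene_set: set[str]) -> float:
    """Maximum KS running sum of the gene set over the ranked list."""
    member = np.fromiter((g in gene_set for g in ranked_list), dtype=bool,
                         count=len(ranked_list))
    n = member.size
    g = int(member.sum())
    if g == 0:
        missing = sorted(gene_set)[:10]
        raise ValueError(f"gene set has no overlap with the ranked list (members: {missing} ...)")
    if g == n:
        raise ValueError("gene set covers the whole ranked list; ES undefined")
    steps = np.where(member, math.sqrt((n - g) / g), -math.sqrt(g / (n - g)))
    return float(np.max(np.cumsum(steps)))


def _es_from_t(t: np.ndarray, member_mask: np.ndarray) -> float:
    n = t.size
    g = int(member_mask.sum())
    order = np.argsort(-t, kind="stable")
    steps = np.where(member_mask[order], math.sqrt((n - g) / g), -math.sqrt(g / (n - g)))
    return float(np.max(np.cumsum(steps)))


def permutation_test(matrix: ExpressionMatrix, labels: np.ndarray, gene_set: set[str],
                     gene_set_name: str = "gene_set", n_perm: int = 1000,
                     seed: int = 0) -> EnrichmentResult:
    """Label-permutation null for the enrichment score.

    Each permutation re-computes the ranking statistic under shuffled
    class labels.  If the number of distinct label assignments is at most
    ``n_perm``, all of them are enumerated and the p-value is the exact
    fraction of assignments with ES at least the observed (the observed
    assignment is part of the enumeration); otherwise random permutations
    are drawn and the add-one convention is used.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels).astype(int)
    log2 = matrix.to_log2()
    values = log2.values
    member_mask = np.fromiter((f in gene_set for f in log2.feature_ids), dtype=bool,
                              count=len(log2.feature_ids))
    if not member_mask.any():
        raise ValueError("gene set has no overlap with the matrix features")

    observed = _es_from_t(_t_stats(values, labels), member_mask)

    n = labels.size
    n1 = int(labels.sum())
    n_distinct = math.comb(n, n1)
    exhaustive = n_distinct <= n_perm
    null_es = []
    if exhaustive:
        warnings.warn(f"n_perm={n_perm} exceeds the {n_distinct} distinct label "
                      "assignments; using exhaustive enumeration", RuntimeWarning,
                      stacklevel=2)
        for pos in combinations(range(n), n1):
            lab = np.zeros(n, dtype=int)
            lab[list(pos)] = 1
            null_es.append(_es_from_t(_t_stats(values, lab), member_mask))
        null_es = np.asarray(null_es)
        n_ge = int(np.sum(null_es >= observed))
        p = n_ge / n_distinct
        n_used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            lab = rng.permutation(labels)
            null_es.append(_es_from_t(_t_stats(values, lab), member_mask))
        null_es = np.asarray(null_es)
        n_ge = int(np.sum(null_es >= observed))
        p = (1 + n_ge) / (1 + n_perm)
        n_used = n_perm

    return EnrichmentResult(gene_set_name, observed, float(null_es.mean()),
                            float(null_es.std(ddof=1)) if null_es.size > 1 else 0.0,
                            n_ge, float(p), n_used, seed, exhaustive)


def ls_permutation_test(per_gene_p: np.ndarray, category_members: np.ndarray,
                        n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """LS category statistic and its random-set permutation p-value.

    LS = mean of -ln(p) over the category's genes; the null draws random
    gene sets of the same size from all tested genes.  p-value uses the
    add-one convention.
    """
    p = np.asarray(per_gene_p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("per-gene p-values must lie in (0, 1]")
    members = np.asarray(category_members, dtype=int)
    if members.size < 2:
        raise ValueError("category needs at least 2 genes")
    if members.size > p.size:
        raise ValueError("category larger than the tested gene universe")
    neglog = -np.log(p)
    observed = float(neglog[members].mean())
    rng = np.random.default_rng(seed)
    null = np.array([neglog[rng.choice(p.size, size=members.size, replace=False)].mean()
                     for _ in range(n_perm)])
    p_value = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return observed, float(p_value)
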