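"""Sign-weighted gene-signature scores and risk-group cutoffs.

A signature is a set of genes with weights w_i in {+1, -1}.  The score
of a sample is the sign-weighted mean of the expression of the signature
genes present on the platform,

    S = (1/n) * sum_i w_i * x_i ,

followed by robust scaling so that within a dataset the scores have
median 0 and interquartile range 1 (making different signatures
comparable).  The genomic-grade cutoff is the midpoint between the mean
scores of histological grade 1 and grade 3 tumors; samples above it are
genomic-grade High, which reclassifies the ambiguous grade-2 tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneSignature:
    """Gene identifiers with signed weights; only the sign of a weight is used."""

    name: str
    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"signature {self.name}: no entries")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name}: duplicate gene ids")
        self.entries = [(g, 1 if w >= 0 else -1) for g, w in self.entries]
        if any(w == 0 for _, w in self.entries):
            raise ValueError(f"signature {self.name}: zero weight")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def flipped(self) -> "GeneSignature":
        return GeneSignature(self.name, [(g, -w) for g, w in self.entries])


@dataclass
class ScoreSet:
    sample_ids: list[str]
    raw_scores: np.ndarray
    scaled_scores: np.ndarray
    n_genes_used: int


def signature_score(expr: dict[str, float], sig: GeneSignature,
                    normalize: bool = True) -> tuple[float, int]:
    """Score one sample: sign-weighted mean (or sum) over platform-present genes.

    Returns ``(score, n_genes_used)``; genes absent from ``expr`` are skipped.
    """
    terms = [w * expr[g] for g, w in sig.entries if g in expr]
    n = len(terms)
    if n == 0:
        raise ValueError(f"signature {sig.name}: no overlap with the expression data")
    s = float(np.sum(terms))
    return (s / n if normalize else s), n


def score_matrix(expr: pd.DataFrame, sig: GeneSignature, normalize: bool = True,
                 scale: bool = True) -> ScoreSet:
    """Score every sample of a genes x samples log2 expression frame."""
    present = [(g, w) for g, w in sig.entries if g in expr.index]
    if not present:
        raise ValueError(f"signature {sig.name}: no overlap with the expression data")
    w = np.array([w for _, w in present], dtype=float)
    x = expr.loc[[g for g, _ in present]].to_numpy(float)
    raw = w @ x
    if normalize:
        raw = raw / len(present)
    scaled = robust_scale(raw) if scale else raw.copy()
    return ScoreSet(list(expr.columns), raw, scaled, len(present))


def robust_scale(scores: np.ndarray) -> np.ndarray:
    """(s - median) / IQR, quartiles by linear interpolation of order statistics."""
    s = np.asarray(scores, dtype=float)
    if np.unique(s).size < 2:
        raise ValueError("robust scaling needs at least 2 distinct values")
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("IQR is zero; robust scaling undefined")
    return (s - med) / iqr


def ggi_cutoff(scores: np.ndarray, histological_grade: np.ndarray
               ) -> tuple[float, np.ndarray]:
    """Genomic-grade cutoff and High/Low labels from histological grades.

    cutoff = (mean score of grade-1 tumors + mean score of grade-3 tumors) / 2;
    scores above the cutoff are labelled High (True).  Grade-2 tumors are
    thereby reclassified into the two genomic-grade groups.
    """
    scores = np.asarray(scores, dtype=float)
    grade = np.asarray(histological_grade)
    for g in (1, 3):
        if not (grade == g).any():
            raise ValueError(f"no samples with histological grade {g}")
    cutoff = float((scores[grade == 1].mean() + scores[grade == 3].mean()) / 2.0)
    return cutoff, scores > cutoff


def median_split(marker: np.ndarray, training_cutoff: float | None = None
                 ) -> tuple[np.ndarray, float]:
    """High/Low risk labels from a median split (or an imported cutoff).

    Values strictly above the cutoff are high-risk; ties at the cutoff go
    to the low-risk group.  The cutoff used is returned so a validation
    cohort can reuse the training value unchanged.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.size == 0:
        raise ValueError("empty marker vector")
    cutoff = float(np.median(marker)) if training_cutoff is None else float(training_cutoff)
    labels = marker > cutoff
    if labels.all() or not labels.any():
        warnings.warn("median split produced a single group", RuntimeWarning, stacklevel=2)
    return labels, cutoff
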