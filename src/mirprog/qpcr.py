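"""Relative qPCR quantification by the 2^-dCt method.

A target miRNA is quantified relative to reference small RNAs (RNU44 and
RNU48 by default): dCt = mean target Ct minus the average of the
reference mean Cts, and relative expression is 2^-dCt.  Reactions are
run in triplicate; triplicates are averaged before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_REFERENCES = ("RNU44", "RNU48")


@dataclass
class QpcrMeasurement:
    sample_id: str
    target_cts: np.ndarray
    ref_cts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.target_cts = np.asarray(self.target_cts, dtype=float)
        self.ref_cts = {k: np.asarray(v, dtype=float) for k, v in self.ref_cts.items()}
        if self.target_cts.size == 0:
            raise ValueError(f"{self.sample_id}: no target Ct values")
        if not self.ref_cts:
            raise ValueError(f"{self.sample_id}: no reference assays")
        for name, cts in [("target", self.target_cts)] + list(self.ref_cts.items()):
            if cts.size == 0 or not np.all(np.isfinite(cts)) or np.any(cts <= 0):
                raise ValueError(f"{self.sample_id}: invalid Ct values for {name}")


def relative_expression(m: QpcrMeasurement) -> float:
    """2^-dCt with dCt = mean(target Ct) - mean over references of mean(ref Ct)."""
    ref_mean = float(np.mean([np.mean(cts) for cts in m.ref_cts.values()]))
    delta_ct = float(np.mean(m.target_cts)) - ref_mean
    return float(2.0 ** (-delta_ct))


def group_fold_change(expr: np.ndarray, groups: np.ndarray, summary: str = "mean") -> float:
    """Ratio of group summaries, high (group 1) over low (group 0).

    ``summary`` selects mean or median of the per-sample relative
    expressions within each group.
    """
    expr = np.asarray(expr, dtype=float)
    groups = np.asarray(groups).astype(int)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    if not ((groups == 0).any() and (groups == 1).any()):
        raise ValueError("both groups must be non-empty")
    agg = {"mean": np.mean, "median": np.median}[summary]
    lo, hi = agg(expr[groups == 0]), agg(expr[groups == 1])
    if lo == 0:
        raise ValueError("zero denominator group summary")
    return float(hi / lo)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)
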