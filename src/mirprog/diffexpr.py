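"""Two-class and three-group differential expression with BH FDR.

Comparisons are run on log2 normalized intensities with pooled-variance
Student t tests (two-tailed); fold changes are reported as ratios of
group medians on the linear scale, which is the convention behind the
printed median columns of the result tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalization import ExpressionMatrix


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1} or not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("labels must be binary 0/1 with both classes present")
    return labels


def two_class_ttest(matrix: ExpressionMatrix, labels: np.ndarray,
                    equal_var: bool = True) -> pd.DataFrame:
    """Per-feature two-sample t statistic and two-tailed p on log2 values.

    Pooled-variance (Student) by default; set ``equal_var=False`` for
    Welch.  Zero pooled variance yields t=0, p=1 with ``degenerate=True``.
    """
    if matrix.scale != "log2":
        raise ValueError("t tests run on the log2 matrix")
    labels = _check_binary(labels)
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    x0 = matrix.values[:, labels == 0]
    x1 = matrix.values[:, labels == 1]
    res = stats.ttest_ind(x1, x0, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame({"t_statistic": t, "p_value": p, "degenerate": degenerate},
                        index=matrix.feature_ids)


def median_fold_change(matrix: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Per-group medians of linear normalized intensities and their ratio.

    The ratio is median(group 1) / median(group 0); a log2 input matrix
    is inverted to the linear scale first.
    """
    labels = _check_binary(labels)
    lin = matrix.to_linear()
    med0 = np.median(lin.values[:, labels == 0], axis=1)
    med1 = np.median(lin.values[:, labels == 1], axis=1)
    if (med0 == 0).any():
        bad = [f for f, m in zip(matrix.feature_ids, med0) if m == 0]
        raise ValueError(f"zero median in denominator group for {bad[:5]}")
    return pd.DataFrame({"median_group0": med0, "median_group1": med1,
                         "fold_change": med1 / med0}, index=matrix.feature_ids)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(matrix: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Combined result table: medians, fold change, t, p and BH FDR."""
    tt = two_class_ttest(matrix.to_log2(), labels)
    fc = median_fold_change(matrix, labels)
    out = fc.join(tt[["t_statistic", "p_value"]])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values("p_value")


def fc_gene_calls(matrix: ExpressionMatrix, labels: np.ndarray,
                  threshold: float = 2.0) -> dict[str, list[str]]:
    """Genes whose between-class linear fold change strictly exceeds ``threshold``.

    Returns ``{"up": [...], "down": [...]}`` relative to class 1, using the
    mean of linear intensities per class (the usual microarray FC call).
    """
    labels = _check_binary(labels)
    lin = matrix.to_linear()
    m0 = lin.values[:, labels == 0].mean(axis=1)
    m1 = lin.values[:, labels == 1].mean(axis=1)
    if (m0 <= 0).any() or (m1 <= 0).any():
        raise ValueError("non-positive class means; fold change undefined")
    ratio = m1 / m0
    up = [f for f, r in zip(matrix.feature_ids, ratio) if r > threshold]
    down = [f for f, r in zip(matrix.feature_ids, ratio) if 1.0 / r > threshold]
    return {"up": up, "down": down}


def oneway_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p over >= 2 groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    chunks = [values[groups == g] for g in levels]
    if any(len(c) < 2 for c in chunks):
        raise ValueError("each group needs at least 2 samples")
    f, p = stats.f_oneway(*chunks)
    return float(f), float(p)
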