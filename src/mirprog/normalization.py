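"""Global-scaling normalization of spotted miRNA arrays.

The platform prints each miRNA probe on several replicate spots plus a set
of empty (negative-control) spots.  Per hybridization the pipeline is:

1. spot signal = mean signal minus local background (clamped at 0),
   averaged over replicate spots per probe;
2. thresholding: intensities below twice the mean empty-spot signal are
   set to a floor of 1;
3. scaling: every intensity is divided by the sample's 30th-largest
   post-threshold intensity;
4. log2 transformation.

Detection is recorded *before* flooring, so downstream "expressed in at
least X% of samples" filters use the biological detection call rather
than the floored sentinel value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EMPTY = "EMPTY"


@dataclass
class NormalizationParams:
    """Tunables of the three-step global scaling.

    threshold_multiplier
        Detection threshold as a multiple of the mean empty-spot signal.
    scaling_rank
        The per-sample intensity rank (1 = brightest) used as scaling
        divisor; the probe at this rank maps to log2 value 0.
    floor_value
        Replacement for sub-threshold intensities before scaling.
    rank_from_top
        If False, ``scaling_rank`` counts from the dimmest spot instead.
    """

    threshold_multiplier: float = 2.0
    scaling_rank: int = 30
    floor_value: float = 1.0
    rank_from_top: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.threshold_multiplier) and self.threshold_multiplier > 0):
            raise ValueError("threshold_multiplier must be finite and > 0")
        if self.scaling_rank < 1:
            raise ValueError("scaling_rank must be >= 1")
        if not (np.isfinite(self.floor_value) and self.floor_value > 0):
            raise ValueError("floor_value must be finite and > 0")


@dataclass
class RawArraySample:
    """Per-spot measurements for one hybridization.

    ``spots`` is a DataFrame with columns spot_id, feature_id (the token
    ``EMPTY`` marks empty spots), mean_signal, local_background,
    replicate_group.
    """

    sample_id: str
    spots: pd.DataFrame

    REQUIRED_COLUMNS = ("spot_id", "feature_id", "mean_signal", "local_background", "replicate_group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.spots.columns]
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing spot columns {missing}")
        if (self.spots["mean_signal"] < 0).any() or (self.spots["local_background"] < 0).any():
            raise ValueError(f"sample {self.sample_id}: negative signal or background")
        if not (self.spots["feature_id"] == EMPTY).any():
            raise ValueError(f"sample {self.sample_id}: no empty spots")
        nonempty = self.spots[self.spots["feature_id"] != EMPTY]
        per_group = nonempty.groupby("replicate_group")["feature_id"].nunique()
        if (per_group > 1).any():
            bad = per_group[per_group > 1].index.tolist()
            raise ValueError(f"sample {self.sample_id}: replicate groups map to several features: {bad}")


@dataclass
class SampleSummary:
    """Background-subtracted, replicate-averaged intensities for one sample."""

    sample_id: str
    feature_ids: list[str]
    intensities: np.ndarray  # linear scale, >= 0
    empty_mean: float


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with an explicit scale tag.

    ``detected`` flags values that were at or above the per-sample
    detection threshold before flooring.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str  # "linear" | "log2"
    detected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with feature/sample ids")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.detected is not None:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.values.shape:
                raise ValueError("detection mask shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(self.feature_ids, self.sample_ids,
                                np.power(2.0, self.values), "linear", self.detected)

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        if (self.values <= 0).any():
            raise ValueError("non-positive linear values cannot be log2-transformed")
        return ExpressionMatrix(self.feature_ids, self.sample_ids,
                                np.log2(self.values), "log2", self.detected)

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        idx = [self.feature_ids.index(f) for f in keep]
        det = self.detected[idx] if self.detected is not None else None
        return ExpressionMatrix(keep, self.sample_ids, self.values[idx], self.scale, det)


def summarize_spots(sample: RawArraySample) -> SampleSummary:
    """Background-subtract, clamp at zero and average replicate spots.

    Empty spots are summarized separately into the empty-spot mean used
    by :func:`detection_threshold`.
    """
    spots = sample.spots
    net = np.maximum(spots["mean_signal"].to_numpy(float) - spots["local_background"].to_numpy(float), 0.0)
    is_empty = (spots["feature_id"] == EMPTY).to_numpy()
    empty_mean = float(net[is_empty].mean())

    nonempty = spots.loc[~is_empty].assign(_net=net[~is_empty])
    # replicate spots of one probe share a replicate_group; average within it
    per_group = nonempty.groupby("replicate_group", sort=False).agg(
        feature_id=("feature_id", "first"), _net=("_net", "mean"))
    per_feature = per_group.groupby("feature_id", sort=False)["_net"].mean()
    return SampleSummary(sample.sample_id, per_feature.index.tolist(),
                         per_feature.to_numpy(float), empty_mean)


def detection_threshold(summary: SampleSummary, params: NormalizationParams | None = None) -> float:
    """Per-sample detection threshold: multiplier x mean empty-spot signal."""
    params = params or NormalizationParams()
    if not np.isfinite(summary.empty_mean):
        raise ValueError(f"sample {summary.sample_id}: empty-spot mean unavailable")
    return params.threshold_multiplier * summary.empty_mean


def threshold_and_scale(summary: SampleSummary,
                        params: NormalizationParams | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Apply thresholding, rank scaling and log2 to one sample.

    Returns ``(log2_values, detected)`` aligned with ``summary.feature_ids``.
    Values below the detection threshold are floored to ``params.floor_value``
    before ranking; the divisor is the ``scaling_rank``-th largest (or
    smallest, if ``rank_from_top`` is False) post-threshold intensity.
    """
    params = params or NormalizationParams()
    x = np.asarray(summary.intensities, dtype=float)
    if x.size < params.scaling_rank:
        raise ValueError(
            f"sample {summary.sample_id}: {x.size} features < scaling_rank {params.scaling_rank}")
    tau = detection_threshold(summary, params)
    detected = x >= tau
    floored = np.where(detected, x, params.floor_value)
    order = np.sort(floored)
    divisor = order[-params.scaling_rank] if params.rank_from_top else order[params.scaling_rank - 1]
    if divisor <= 0:
        raise ValueError(f"sample {summary.sample_id}: non-positive scaling divisor")
    if divisor == params.floor_value:
        warnings.warn(f"sample {summary.sample_id}: scaling divisor equals the floor value",
                      RuntimeWarning, stacklevel=2)
    return np.log2(floored / divisor), detected


def normalize_samples(samples: list[RawArraySample],
                      params: NormalizationParams | None = None) -> ExpressionMatrix:
    """Normalize a list of raw samples into one log2 ExpressionMatrix.

    All samples must carry the same probe set (order may differ).
    """
    params = params or NormalizationParams()
    if not samples:
        raise ValueError("no samples to normalize")
    summaries = [summarize_spots(s) for s in samples]
    features = summaries[0].feature_ids
    fset = set(features)
    cols, dets = [], []
    for summ in summaries:
        if set(summ.feature_ids) != fset:
            raise ValueError(f"sample {summ.sample_id}: probe set differs from first sample")
        reindex = pd.Series(summ.intensities, index=summ.feature_ids).reindex(features)
        summ = SampleSummary(summ.sample_id, features, reindex.to_numpy(float), summ.empty_mean)
        vals, det = threshold_and_scale(summ, params)
        cols.append(vals)
        dets.append(det)
    return ExpressionMatrix(
        feature_ids=list(features),
        sample_ids=[s.sample_id for s in samples],
        values=np.column_stack(cols),
        scale="log2",
        detected=np.column_stack(dets),
    )


def detection_filter(matrix: ExpressionMatrix, min_fraction: float) -> list[str]:
    """Features detected in at least ``min_fraction`` of samples (order kept)."""
    if matrix.values.size == 0:
        raise ValueError("empty expression matrix")
    if matrix.detected is None:
        raise ValueError("matrix has no detection mask")
    frac = matrix.detected.mean(axis=1)
    return [f for f, ok in zip(matrix.feature_ids, frac >= min_fraction) if ok]
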