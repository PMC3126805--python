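"""End-to-end orchestration of the discovery and validation analyses.

Discovery: normalize raw arrays, apply the detection filters, run the
clinical-contrast differential tables, evaluate each filtered miRNA as
a median-split survival marker, compare the designated marker against
gene signatures by Cox/tdROC, and (optionally) run target-set
enrichment.  Validation re-applies the exported training cutoff to an
independent cohort without refitting.

Every run writes a manifest recording parameters, the seed and sha256
digests of all outputs, so a rerun with the same config is verifiable
byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .diffexpr import differential_table
from .enrichment import permutation_test
from .normalization import NormalizationParams, detection_filter, normalize_samples
from .signatures import ggi_cutoff, median_split, robust_scale, score_matrix
from .survival import censor_at, compare_markers, cox_fit, kaplan_meier, td_roc


@dataclass
class PipelineConfig:
    raw_spots: str
    clinical: str
    outcomes: str
    output_dir: str
    mrna_expression: str | None = None   # pre-normalized log2 mRNA matrix (TSV)
    signature_files: list[str] = field(default_factory=list)
    gene_sets: str | None = None         # GMT of miRNA target sets
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    detection_fraction: float = 0.9
    expression_fraction: float = 0.2
    marker_feature: str = "hsa_miR_210"
    survival_horizon: float = 10.0
    n_perm: int = 1000
    n_boot: int = 200
    seed: int = 0


def run_discovery(config: PipelineConfig) -> dict:
    """Run the full discovery analysis; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.raw_spots, config.clinical, config.outcomes):
        if not Path(path).exists():
            raise FileNotFoundError(path)

    stage = "normalization"
    try:
        raw = io.read_spot_table(config.raw_spots)
        matrix = normalize_samples(raw, config.normalization)
        io.write_expression_tsv(matrix, out / "normalized_log2.tsv")

        detected_90 = detection_filter(matrix, config.detection_fraction)
        expressed_20 = detection_filter(matrix, config.expression_fraction)
        pd.DataFrame({"feature_id": detected_90}).to_csv(
            out / "detected_features.tsv", sep="\t", index=False)
        analysis = matrix.subset_features(expressed_20)

        stage = "differential_expression"
        clinical = io.read_clinical(config.clinical).set_index("sample_id").loc[matrix.sample_ids]
        tables = {}
        labels_er = (clinical["er_status"] == "positive").astype(int).to_numpy()
        tables["er_status"] = differential_table(analysis, labels_er)
        grade = clinical["histological_grade"].to_numpy()
        keep = np.isin(grade, [1, 3])
        if keep.sum() >= 4:
            sub = _subset_samples(analysis, keep)
            tables["grade_1v3"] = differential_table(sub, (grade[keep] == 3).astype(int))
        for name, tbl in tables.items():
            tbl.rename_axis("feature_id").to_csv(out / f"de_{name}.tsv", sep="\t")

        stage = "survival_screen"
        outcomes = censor_at(io.read_outcomes(config.outcomes), config.survival_horizon)
        if [o.sample_id for o in outcomes] != matrix.sample_ids:
            raise ValueError("outcome sample ids do not match the expression matrix")
        lin = analysis.to_linear()
        screen_rows = []
        for i, fid in enumerate(lin.feature_ids):
            marker = lin.values[i]
            labels, cutoff = median_split(marker)
            if labels.all() or not labels.any():
                continue
            cov = pd.DataFrame({"high": labels.astype(float)},
                               index=[o.sample_id for o in outcomes])
            try:
                fit = cox_fit(cov, outcomes)
            except (RuntimeError, ValueError):
                continue
            screen_rows.append({"feature_id": fid, "cutoff": cutoff,
                                "hr": float(fit.hazard_ratios.iloc[0]),
                                "p": float(fit.wald_p.iloc[0])})
        screen = pd.DataFrame(screen_rows).sort_values("p")
        screen["significant"] = screen["p"] < 0.05
        screen.to_csv(out / "survival_screen.tsv", sep="\t", index=False)

        stage = "marker_analysis"
        marker_results = {}
        if config.marker_feature in lin.feature_ids:
            marker = lin.values[lin.feature_ids.index(config.marker_feature)]
            labels, cutoff = median_split(marker)
            io.cutoff_sidecar(cutoff, config.marker_feature, out / "training_cutoff.json")
            cov = pd.DataFrame({"high": labels.astype(float)},
                               index=[o.sample_id for o in outcomes])
            fit = cox_fit(cov, outcomes)
            roc = td_roc(marker, outcomes, config.survival_horizon)
            km = kaplan_meier(outcomes, np.where(labels, "high", "low"))
            for gname, curve in km.items():
                curve.to_csv(out / f"km_{gname}.tsv", sep="\t", index=False)
            marker_results = {
                "feature": config.marker_feature, "cutoff": cutoff,
                "hr": float(fit.hazard_ratios.iloc[0]),
                "ci": [float(fit.ci_95["lower"].iloc[0]), float(fit.ci_95["upper"].iloc[0])],
                "p": float(fit.wald_p.iloc[0]), "auc": roc.auc,
            }
            io.write_json(marker_results, out / "marker_fit.json")

        stage = "signature_comparison"
        if config.mrna_expression and config.signature_files:
            mrna = io.read_expression_tsv(config.mrna_expression).to_frame()
            markers = {}
            if config.marker_feature in lin.feature_ids:
                markers[config.marker_feature] = lin.values[
                    lin.feature_ids.index(config.marker_feature)]
            for sig_path in config.signature_files:
                sig = io.read_signature(sig_path)
                scores = score_matrix(mrna[matrix.sample_ids], sig)
                markers[sig.name] = scores.scaled_scores
                grades = clinical["histological_grade"].to_numpy()
                if np.isin(grades, [1]).any() and np.isin(grades, [3]).any():
                    cut, gg_high = ggi_cutoff(scores.scaled_scores, grades)
                    pd.DataFrame({"sample_id": matrix.sample_ids,
                                  "score": scores.scaled_scores,
                                  "gg_high": gg_high.astype(int)}).to_csv(
                        out / f"scores_{sig.name}.tsv", sep="\t", index=False)
            if len(markers) >= 2:
                comp = compare_markers(markers, outcomes, config.survival_horizon,
                                       n_boot=config.n_boot, seed=config.seed)
                comp.to_csv(out / "marker_comparison.tsv", sep="\t", index=False)

        stage = "enrichment"
        if config.mrna_expression and config.gene_sets:
            mrna_mat = io.read_expression_tsv(config.mrna_expression)
            gsets = io.read_gmt(config.gene_sets)
            rows = []
            for k, (name, members) in enumerate(gsets.items()):
                res = permutation_test(mrna_mat, labels_er, members, gene_set_name=name,
                                       n_perm=config.n_perm, seed=config.seed + k)
                rows.append({"gene_set": name, "es": res.observed_es,
                             "p": res.p_value, "n_perm": res.n_perm, "seed": res.seed})
            pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(
            f"discovery pipeline failed at stage {stage!r} "
            f"(inputs: {io.file_sha256(config.raw_spots)[:12]}): {err}") from err

    manifest = _manifest(config, out, extra={"marker": marker_results})
    io.write_json(manifest, out / "manifest.json")
    return manifest


def run_validation(config: PipelineConfig, training_cutoff_path: str) -> dict:
    """Apply an exported training cutoff to an independent cohort.

    The validation cohort is normalized with the same parameters, the
    marker is dichotomized at the *training* cutoff (no refitting), and
    KM/Cox plus the grade-2 subgroup analysis are reported.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sidecar = io.read_cutoff_sidecar(training_cutoff_path)

    raw = io.read_spot_table(config.raw_spots)
    matrix = normalize_samples(raw, config.normalization)
    lin = matrix.to_linear()
    if sidecar["marker"] not in lin.feature_ids:
        raise ValueError(f"marker {sidecar['marker']} absent from validation data")
    marker = lin.values[lin.feature_ids.index(sidecar["marker"])]
    labels, cutoff = median_split(marker, training_cutoff=sidecar["cutoff"])

    outcomes = censor_at(io.read_outcomes(config.outcomes), config.survival_horizon)
    cov = pd.DataFrame({"high": labels.astype(float)},
                       index=[o.sample_id for o in outcomes])
    fit = cox_fit(cov, outcomes)
    km = kaplan_meier(outcomes, np.where(labels, "high", "low"))
    for gname, curve in km.items():
        curve.to_csv(out / f"km_validation_{gname}.tsv", sep="\t", index=False)

    results = {
        "marker": sidecar["marker"], "cutoff_used": cutoff,
        "n_low": int((~labels).sum()), "n_high": int(labels.sum()),
        "hr": float(fit.hazard_ratios.iloc[0]),
        "ci": [float(fit.ci_95["lower"].iloc[0]), float(fit.ci_95["upper"].iloc[0])],
        "p": float(fit.wald_p.iloc[0]),
    }

    clinical = io.read_clinical(config.clinical).set_index("sample_id").loc[matrix.sample_ids]
    grade2 = clinical["histological_grade"].to_numpy() == 2
    if grade2.sum() >= 4 and labels[grade2].any() and (~labels[grade2]).any():
        sub_out = [o for o, g in zip(outcomes, grade2) if g]
        events = [o for o in sub_out if o.event]
        if events:
            cov2 = pd.DataFrame({"high": labels[grade2].astype(float)},
                                index=[o.sample_id for o in sub_out])
            try:
                fit2 = cox_fit(cov2, sub_out)
                results["grade2_hr"] = float(fit2.hazard_ratios.iloc[0])
                results["grade2_p"] = float(fit2.wald_p.iloc[0])
            except (RuntimeError, ValueError):
                warnings.warn("grade-2 subgroup Cox fit failed", RuntimeWarning, stacklevel=2)
    io.write_json(results, out / "validation_fit.json")

    manifest = _manifest(config, out, extra={"validation": results,
                                             "training_cutoff": sidecar})
    io.write_json(manifest, out / "manifest_validation.json")
    return manifest


def _subset_samples(matrix, keep: np.ndarray):
    from .normalization import ExpressionMatrix
    det = matrix.detected[:, keep] if matrix.detected is not None else None
    return ExpressionMatrix(matrix.feature_ids,
                            [s for s, k in zip(matrix.sample_ids, keep) if k],
                            matrix.values[:, keep], matrix.scale, det)


def _manifest(config: PipelineConfig, out: Path, extra: dict | None = None) -> dict:
    outputs = {p.name: io.file_sha256(p)
               for p in sorted(out.iterdir())
               if p.suffix in (".tsv", ".json") and not p.name.startswith("manifest")}
    manifest = {
        "parameters": {**asdict(config)},
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    return manifest
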