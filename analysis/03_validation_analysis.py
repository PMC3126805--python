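#!/usr/bin/env python
"""Validation analysis: the training cutoff applied to the second cohort.

The marker cutoff exported by the discovery run is applied unchanged to
the independent validation cohort (no refitting), reproducing the
median-split risk groups, the Cox hazard ratio and the grade-2 subgroup
analysis.
"""

import shutil
from pathlib import Path

from mirprog.pipeline import PipelineConfig, run_validation

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohorts" / "validation"
OUT = ROOT / "scratch" / "validation_out"
RESULTS = ROOT / "results"


def main() -> None:
    cfg = PipelineConfig(raw_spots=str(COHORT / "spots.tsv"),
                         clinical=str(COHORT / "clinical.tsv"),
                         outcomes=str(COHORT / "outcomes.tsv"),
                         output_dir=str(OUT), seed=202)
    manifest = run_validation(cfg, str(ROOT / "scratch" / "discovery_out"
                                       / "training_cutoff.json"))
    val = manifest["validation"]
    shutil.copy(OUT / "validation_fit.json", RESULTS / "validation_fit.json")
    frac_low = val["n_low"] / (val["n_low"] + val["n_high"])
    print(f"training cutoff {val['cutoff_used']:.3f} assigns "
          f"{val['n_low']}/{val['n_low'] + val['n_high']} "
          f"({100 * frac_low:.0f}%) of validation patients to the low-risk group")
    print(f"validation HR = {val['hr']:.2f} "
          f"(95% CI {val['ci'][0]:.2f}-{val['ci'][1]:.2f}), p = {val['p']:.2g}")
    if "grade2_hr" in val:
        print(f"grade-2 subgroup: HR = {val['grade2_hr']:.2f}, p = {val['grade2_p']:.2g}")


if __name__ == "__main__":
    main()
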