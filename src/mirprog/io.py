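"""Readers and writers for the pipeline's plain-text formats.

Raw spot tables, clinical annotation, survival outcomes and signature
weights travel as TSV; expression matrices as TSV (features in rows)
or GCT 1.2; gene sets as GMT; fitted models and cutoff sidecars as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .normalization import EMPTY, ExpressionMatrix, RawArraySample
from .signatures import GeneSignature
from .survival import SurvivalOutcome

SPOT_COLUMNS = ["sample_id", "spot_id", "feature_id", "mean_signal",
                "local_background", "replicate_group"]


def write_spot_table(samples: list[RawArraySample], path: str | Path) -> None:
    frames = []
    for s in samples:
        df = s.spots.copy()
        df.insert(0, "sample_id", s.sample_id)
        frames.append(df[SPOT_COLUMNS])
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path) -> list[RawArraySample]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [RawArraySample(str(sid), sub.drop(columns="sample_id").reset_index(drop=True))
            for sid, sub in df.groupby("sample_id", sort=False)]


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("feature_id").to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
                            df.to_numpy(float), scale)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """GCT 1.2: version line, dims line, then NAME/Description + samples."""
    df = matrix.to_frame()
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(df.columns) + "\n")
        for fid, row in df.iterrows():
            fh.write(fid + "\tna\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: unsupported GCT version {version!r}")
        fh.readline()
        df = pd.read_csv(fh, sep="\t", index_col=0).drop(columns="Description")
    return ExpressionMatrix(df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
                            df.to_numpy(float), scale)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_outcomes(outcomes: list[SurvivalOutcome], path: str | Path) -> None:
    pd.DataFrame({"sample_id": [o.sample_id for o in outcomes],
                  "time_years": [o.time for o in outcomes],
                  "event": [int(o.event) for o in outcomes]}).to_csv(path, sep="\t", index=False)


def read_outcomes(path: str | Path) -> list[SurvivalOutcome]:
    df = pd.read_csv(path, sep="\t")
    return [SurvivalOutcome(str(r.sample_id), float(r.time_years), bool(r.event))
            for r in df.itertuples()]


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    pd.DataFrame(sig.entries, columns=["gene_id", "weight"]).to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t")
    # any real weight is accepted; only its sign is used
    entries = [(str(g), 1 if w >= 0 else -1) for g, w in zip(df["gene_id"], df["weight"])]
    return GeneSignature(name or Path(path).stem, entries)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str] | set[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def cutoff_sidecar(cutoff: float, marker_name: str, path: str | Path) -> None:
    """Write a training cutoff with an integrity checksum for exact reuse."""
    payload = {"marker": marker_name, "cutoff": float(cutoff)}
    payload["checksum"] = _cutoff_checksum(payload)
    write_json(payload, path)


def read_cutoff_sidecar(path: str | Path) -> dict:
    payload = read_json(path)
    expected = _cutoff_checksum({k: payload[k] for k in ("marker", "cutoff")})
    if payload.get("checksum") != expected:
        raise ValueError(f"{path}: cutoff sidecar checksum mismatch")
    return payload


def _cutoff_checksum(payload: dict) -> str:
    blob = json.dumps({k: payload[k] for k in ("marker", "cutoff")}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
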