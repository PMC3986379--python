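"""Readers and writers for the tab-separated interchange formats.

All matrices travel as UTF-8 TSV with a header row and the feature or
sample id in the first column; numbers use '.' as the decimal separator
and are written with six significant digits by default.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BasisMatrix,
    COMPARTMENTS,
    CompositionMatrix,
    Differential,
    ExpressionMatrix,
    GroupDesign,
)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_composition_tsv",
    "write_composition_tsv",
    "read_basis_tsv",
    "write_basis_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_differential_tsv",
    "write_differential_tsv",
    "read_platform_map",
    "write_signature_tsv",
    "read_signature_tsv",
    "write_provenance",
]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.size == 0:
        raise ValueError(f"{path}: no data columns")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: ragged rows or missing cells in columns {bad[:5]}")
    df.index.name = None
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value at row {bad[0]!r}, column {col!r}"
                ) from None
        raise


def read_expression_tsv(path, scale: str = "linear", normalized: bool = False) -> ExpressionMatrix:
    df = _to_numeric(_read_table(path), path)
    return ExpressionMatrix(df, scale=scale, normalized=normalized)


def write_expression_tsv(X: ExpressionMatrix, path, digits: int = 6) -> None:
    X.values.to_csv(path, sep="\t", float_format=f"%.{digits}g", index_label="feature_id")


def read_composition_tsv(path) -> CompositionMatrix:
    return CompositionMatrix(_to_numeric(_read_table(path), path))


def write_composition_tsv(W: CompositionMatrix, path, digits: int = 10) -> None:
    # 10 digits: at 6 the per-entry rounding can push a 7-type row sum
    # outside the 1e-6 simplex tolerance on re-read
    W.weights.to_csv(path, sep="\t", float_format=f"%.{digits}g", index_label="sample_id")


def read_basis_tsv(path, scale: str = "log2") -> BasisMatrix:
    return BasisMatrix(_to_numeric(_read_table(path), path), scale=scale)


def write_basis_tsv(H: BasisMatrix, path, digits: int = 6, sidecar: dict | None = None) -> None:
    H.values.to_csv(path, sep="\t", float_format=f"%.{digits}g", index_label="feature_id")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_design_tsv(path, case: str | None = None) -> GroupDesign:
    df = _read_table(path)
    return GroupDesign(df.iloc[:, 0].rename("group"), case=case)


def write_design_tsv(design: GroupDesign, path) -> None:
    design.labels.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_differential_tsv(path) -> Differential:
    df = _to_numeric(_read_table(path), path)
    missing = [c for c in COMPARTMENTS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing differential columns {missing}")
    return Differential(df)


def write_differential_tsv(diff: Differential, path, digits: int = 6) -> None:
    diff.fractions.to_csv(path, sep="\t", float_format=f"%.{digits}g", index_label="sample_id")


def read_platform_map(path) -> dict:
    df = _read_table(path)
    return df.iloc[:, 0].to_dict()


def write_signature_tsv(sig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tdirection\n")
        for g in sig.up_ids:
            fh.write(f"{g}\tup\n")
        for g in sig.down_ids:
            fh.write(f"{g}\tdown\n")


def read_signature_tsv(path):
    from .ratio import RatioSignature

    df = _read_table(path)
    direction = df.iloc[:, 0]
    up = tuple(direction.index[direction == "up"])
    down = tuple(direction.index[direction == "down"])
    return RatioSignature(up_ids=up, down_ids=down)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir, command: str, params: dict, inputs: list | None = None) -> None:
    """Record what produced an output directory: command, params, checksums."""
    from . import __version__

    record = {
        "tool": "bloodmix",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()},
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(record, indent=2, default=str))
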