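"""Readers and writers for quantification tables, metadata and matrices.

All tables are plain TSV/CSV.  Intensities are stored internally on the log2
scale; raw-scale inputs are transformed once at parse time.  Export dialects
("multiquant", "skyline") are column maps over the same long format.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    METADATA_COLUMNS,
    QUANT_COLUMNS,
    ValidationError,
    validate_metadata_frame,
    validate_quant_frame,
)

logger = logging.getLogger(__name__)

#: column maps per export dialect; ``raw`` marks intensities on the raw
#: (pre-log) scale by default
DIALECTS: dict[str, dict] = {
    "native": {
        "columns": {c: c for c in QUANT_COLUMNS},
        "raw": False,
    },
    "multiquant": {
        "columns": {
            "Sample Name": "run_id",
            "Sample Group": "cohort_id",
            "Sample ID": "subject_id",
            "Protein Name": "protein_id",
            "Component Name": "peptide_id",
            "Component Group": "channel",
            "IS": "is_standard",
            "Batch": "batch_id",
            "Area": "log2_intensity",
        },
        "raw": True,
    },
    "skyline": {
        "columns": {
            "FileName": "run_id",
            "Condition": "cohort_id",
            "BioReplicate": "subject_id",
            "ProteinName": "protein_id",
            "PeptideSequence": "peptide_id",
            "IsotopeLabelType": "channel",
            "StandardType": "is_standard",
            "Batch": "batch_id",
            "Area": "log2_intensity",
        },
        "raw": True,
    },
}

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", ""}


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_bool(column: pd.Series) -> pd.Series:
    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY or s == "nan":
            return False
        raise ValidationError(f"cannot interpret {v!r} as a boolean flag")

    return column.map(one)


def read_quant_table(
    path,
    dialect: str = "native",
    raw: bool | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a long-format quantification table.

    Parameters
    ----------
    path
        TSV or CSV file; lines starting with ``#`` are comments.
    dialect
        One of ``native``, ``multiquant``, ``skyline`` — selects the column
        map and the default intensity scale.
    raw
        Override the dialect's intensity scale: ``True`` means raw peak
        areas, log2-transformed on read (non-positive areas parse as
        missing).
    column_map
        Explicit source-column -> schema-column map overriding the dialect.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}")
    spec = DIALECTS[dialect]
    cmap = dict(column_map) if column_map is not None else spec["columns"]
    if raw is None:
        raw = spec["raw"]

    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    missing = [src for src in cmap if src not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.rename(columns=cmap).loc[:, list(cmap.values())]

    intensity = pd.to_numeric(df["log2_intensity"], errors="coerce")
    raw_text = df["log2_intensity"].astype(str).str.strip()
    bad = intensity.isna() & ~raw_text.isin({"", "nan", "NA", "NaN", "None"})
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: non-numeric intensity {df['log2_intensity'].iloc[row]!r} "
            f"at data row {row}"
        )
    if raw:
        with np.errstate(divide="ignore", invalid="ignore"):
            intensity = pd.Series(
                np.where(intensity > 0, np.log2(intensity), np.nan),
                index=df.index,
            )
    df["log2_intensity"] = intensity.astype(float)
    df["is_standard"] = _parse_bool(df["is_standard"])
    df["channel"] = df["channel"].str.strip().str.lower()
    return validate_quant_frame(df.reset_index(drop=True))


def write_quant_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Write a quantification table as native-dialect TSV/CSV."""
    df = validate_quant_frame(df)
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a subject metadata table."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for col in ("tumor_diameter_cm", "cea_ng_ml", "age_years"):
        text = df[col].astype(str).str.strip()
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~text.isin({"", "nan", "NA", "NaN", "None"})
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: non-numeric {col} at data row {row}"
            )
        df[col] = vals
    df["stage"] = df["stage"].replace({"": None, "NA": None, "nan": None})
    df["stage"] = df["stage"].where(df["stage"].notna(), None)
    return validate_metadata_frame(df.reset_index(drop=True))


def write_metadata(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    df = validate_metadata_frame(df)
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def write_matrix(matrix, path) -> None:
    """Write an :class:`~srmsig.types.AbundanceMatrix` as TSV."""
    matrix.to_frame().to_csv(path, sep="\t")


def read_matrix(path):
    from .types import AbundanceMatrix

    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return AbundanceMatrix.from_frame(df)
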