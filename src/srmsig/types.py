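"""Core data containers shared across the pipeline stages.

Quantification data travel as long-format :class:`pandas.DataFrame` objects
with the column schema in :data:`QUANT_COLUMNS`; subject metadata use
:data:`METADATA_COLUMNS`.  Summarized protein abundances are held in
:class:`AbundanceMatrix` (subjects x proteins, ``NaN`` == missing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Long-format quantification table schema (one transition-group measurement
#: per row).  ``log2_intensity`` may be NaN for censored measurements.
QUANT_COLUMNS = [
    "run_id",
    "cohort_id",
    "subject_id",
    "protein_id",
    "peptide_id",
    "channel",
    "is_standard",
    "batch_id",
    "log2_intensity",
]

CHANNELS = ("light", "heavy")

#: Subject metadata table schema.
METADATA_COLUMNS = [
    "subject_id",
    "cohort",
    "group",
    "stage",
    "tumor_diameter_cm",
    "cea_ng_ml",
    "age_years",
    "run_id",
]

GROUPS = ("CRC", "benign", "healthy")
STAGES = ("I", "II", "III", "IV")
CONTROL_GROUPS = ("benign", "healthy")


class ValidationError(ValueError):
    """Raised when an input table violates the schema contracts."""


class ConfigurationError(ValueError):
    """Raised for inconsistent pipeline or simulation configuration."""


def validate_quant_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format quantification frame against the schema.

    Checks required columns, channel values, finite intensities and
    uniqueness of ``(run_id, peptide_id, channel)``.  Returns the frame with
    canonical column order.
    """
    missing = [c for c in QUANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"quant table missing columns: {missing}")
    bad_channel = set(df["channel"].unique()) - set(CHANNELS)
    if bad_channel:
        raise ValidationError(f"unknown channel values: {sorted(bad_channel)}")
    vals = df["log2_intensity"].to_numpy(dtype=float)
    if np.isinf(vals).any():
        raise ValidationError("log2_intensity contains non-finite values")
    dup = df.duplicated(subset=["run_id", "peptide_id", "channel"], keep=False)
    if dup.any():
        key = df.loc[dup, ["run_id", "peptide_id", "channel"]].iloc[0].tolist()
        raise ValidationError(
            f"duplicate (run_id, peptide_id, channel) key: {tuple(key)}"
        )
    return df.loc[:, QUANT_COLUMNS]


def validate_metadata_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a subject metadata frame.

    Stage must be absent (NA) for non-CRC subjects; group labels must be
    known; numeric fields must be non-negative where present.
    """
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata table missing columns: {missing}")
    bad_group = set(df["group"].unique()) - set(GROUPS)
    if bad_group:
        raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
    stage = df["stage"]
    staged_controls = df[(df["group"] != "CRC") & stage.notna()]
    if len(staged_controls):
        sid = staged_controls["subject_id"].iloc[0]
        raise ValidationError(
            f"subject {sid!r} is not CRC but carries a stage annotation"
        )
    known = stage.dropna()
    bad_stage = set(known.unique()) - set(STAGES)
    if bad_stage:
        raise ValidationError(f"unknown stage labels: {sorted(bad_stage)}")
    for col in ("tumor_diameter_cm", "cea_ng_ml"):
        v = pd.to_numeric(df[col], errors="coerce")
        if (v.dropna() < 0).any():
            raise ValidationError(f"{col} must be >= 0")
    if df["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_id in metadata")
    return df.loc[:, METADATA_COLUMNS]


@dataclass
class AbundanceMatrix:
    """Subjects x proteins log2 relative abundance with explicit missingness.

    ``values`` is indexed by subject_id with protein_id columns; NaN cells
    are missing.  ``cohort`` labels each subject.
    """

    values: pd.DataFrame
    cohort: pd.Series

    def __post_init__(self) -> None:
        self.cohort = self.cohort.reindex(self.values.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is missing."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.cohort.copy())

    def select_proteins(self, protein_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[:, list(protein_ids)], self.cohort)

    def select_subjects(self, subject_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.loc[list(subject_ids)], self.cohort.loc[list(subject_ids)]
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "cohort", self.cohort)
        out.index.name = "subject_id"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        cohort = df["cohort"]
        return cls(df.drop(columns=["cohort"]).astype(float), cohort)


@dataclass
class SignatureModel:
    """A fitted biomarker signature: proteins, logistic coefficients,
    classification threshold and the cross-validation selection counts."""

    protein_ids: list[str]
    coefficients: list[float]
    intercept: float
    threshold: float
    covariates: dict[str, float] = field(default_factory=dict)
    fold_selection_counts: dict[str, int] = field(default_factory=dict)
    converged: bool = True
    separated: bool = False

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.protein_ids):
            raise ValidationError("coefficient count must match protein count")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValidationError("threshold must lie in [0, 1]")

    def to_json(self, **kwargs) -> str:
        payload = {"schema_version": 1, **asdict(self)}
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        payload.pop("schema_version", None)
        return cls(**payload)


@dataclass
class GroundTruth:
    """Planted generative parameters of a synthetic cohort."""

    marker_ids: list[str]
    true_log2fc: list[float]
    size_responsive_ids: list[str]
    generative_coefficients: dict[str, float]
    generative_intercept: float = 0.0

    def __post_init__(self) -> None:
        if len(self.true_log2fc) != len(self.marker_ids):
            raise ValidationError("true_log2fc must align with marker_ids")
        if any(fc == 0 for fc in self.true_log2fc):
            raise ValidationError("planted markers must have non-zero effects")


def dump_json(payload: Mapping, path) -> None:
    """Serialize a report mapping deterministically (sorted keys)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
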