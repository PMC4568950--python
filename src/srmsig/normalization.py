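"""Two-stage plasma normalization plus the tissue-phase feature filter.

Stage 1 (:func:`normalize_by_reference`) equalizes each protein's per-run
heavy-reference median across runs, shifting light and heavy records of that
protein in a run by the same constant — this removes acquisition drift.

Stage 2 (:func:`normalize_by_standard`) summarizes a spiked standard protein
per run, screens its stability against the per-run sample medians by Pearson
correlation (stable iff r > 0.6), and shifts every light intensity in a run
so the standard summaries are equal across runs — this removes
sample-preparation bias.

Cross-cohort median equalization and the tissue feature filter / scale
normalization live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linmodel import additive_summaries
from .types import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

STABILITY_CUTOFF = 0.6


@dataclass
class NormalizationReport:
    """Diagnostics of both normalization stages."""

    reference_targets: dict[str, float] = field(default_factory=dict)
    stage1_shifts: pd.DataFrame | None = None  # run x protein
    stage2_shifts: pd.Series | None = None  # per run
    standard_correlations: dict[str, float] = field(default_factory=dict)
    chosen_standard: str | None = None
    unstable_standards: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "reference_targets": self.reference_targets,
            "stage1_shifts": (
                None if self.stage1_shifts is None
                else self.stage1_shifts.round(12).to_dict()
            ),
            "stage2_shifts": (
                None if self.stage2_shifts is None
                else self.stage2_shifts.round(12).to_dict()
            ),
            "standard_correlations": self.standard_correlations,
            "chosen_standard": self.chosen_standard,
            "unstable_standards": self.unstable_standards,
        }


def normalize_by_reference(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Equalize each protein's per-run heavy median across runs.

    For every protein, the per-run shift is ``global median of the protein's
    heavy intensities − the run's median heavy intensity for the protein``;
    both light and heavy records of that protein in that run move by it.
    Proteins lacking heavy records in a run are left unshifted there (with a
    warning).
    """
    df = records.copy()
    heavy = df[(df["channel"] == "heavy") & df["log2_intensity"].notna()]
    report = NormalizationReport()
    if heavy.empty:
        logger.warning("no heavy reference records: stage-1 normalization skipped")
        report.stage1_shifts = pd.DataFrame()
        return df, report

    targets = heavy.groupby("protein_id")["log2_intensity"].median()
    run_medians = heavy.groupby(["protein_id", "run_id"])["log2_intensity"].median()
    shifts = (targets.reindex(
        run_medians.index.get_level_values("protein_id")
    ).to_numpy() - run_medians.to_numpy())
    shift_table = pd.Series(shifts, index=run_medians.index, name="shift")

    covered = df.set_index(["protein_id", "run_id"]).index
    shift_per_row = shift_table.reindex(covered).to_numpy()
    no_ref = np.isnan(shift_per_row)
    if no_ref.any():
        pairs = df.loc[no_ref, ["protein_id", "run_id"]].drop_duplicates()
        for pid in pairs["protein_id"].unique():
            logger.warning(
                "protein %s has runs without heavy references; left unshifted "
                "in those runs", pid,
            )
    df["log2_intensity"] = df["log2_intensity"] + np.nan_to_num(shift_per_row)

    report.reference_targets = {k: float(v) for k, v in targets.items()}
    report.stage1_shifts = shift_table.unstack("protein_id")
    return df, report


def per_run_sample_medians(records: pd.DataFrame, basis: str = "median") -> pd.Series:
    """Per-run summary of the endogenous light intensities.

    ``basis='median'`` (default) is the per-run median of observed endogenous
    light log2 intensities; ``basis='sum'`` is their sum.
    """
    endog = records[
        (records["channel"] == "light")
        & (~records["is_standard"])
        & records["log2_intensity"].notna()
    ]
    grouped = endog.groupby("run_id")["log2_intensity"]
    if basis == "median":
        return grouped.median()
    if basis == "sum":
        return grouped.sum()
    raise ValidationError(f"unknown sample-median basis {basis!r}")


def summarize_standard_protein(records: pd.DataFrame, standard_id: str) -> pd.Series:
    """One summary value per run for a spiked standard protein.

    Fits an additive peptide + run fixed-effects model by least squares on
    the observed light intensities of the standard; the summary for a run is
    the fitted run level.  Runs where every peptide is missing get NaN.
    """
    sub = records[
        (records["protein_id"] == standard_id) & (records["channel"] == "light")
    ]
    if sub.empty:
        raise ValidationError(f"standard protein {standard_id!r} not present")
    runs = sub["run_id"].unique()
    if len(runs) < 2:
        raise ValidationError(
            f"standard protein {standard_id!r} observed in fewer than 2 runs"
        )
    return additive_summaries(
        sub["log2_intensity"].to_numpy(),
        sub["peptide_id"].to_numpy(),
        sub["run_id"].to_numpy(),
        col_levels=runs,
    )


def assess_standard_stability(
    standard_summaries: pd.Series,
    sample_medians: pd.Series,
    cutoff: float = STABILITY_CUTOFF,
) -> tuple[float, bool]:
    """Pearson correlation of per-run standard summaries with per-run sample
    medians; the standard is stable iff r > cutoff (strict)."""
    joined = pd.concat(
        [standard_summaries.rename("s"), sample_medians.rename("m")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValidationError("need >= 3 paired values to assess stability")
    s, m = joined["s"].to_numpy(), joined["m"].to_numpy()
    if np.std(s) == 0 or np.std(m) == 0:
        logger.warning("zero variance in stability inputs; standard flagged unstable")
        return float("nan"), False
    r = float(stats.pearsonr(s, m).statistic)
    return r, r > cutoff


def normalize_by_standard(
    records: pd.DataFrame,
    standard_id: str,
    check_stability: bool = True,
    sample_basis: str = "median",
    cutoff: float = STABILITY_CUTOFF,
) -> tuple[pd.DataFrame, pd.Series]:
    """Shift every light intensity in a run so the standard protein's per-run
    summaries become equal across runs.

    Refuses unstable standards (r <= cutoff against the per-run sample
    medians) unless ``check_stability`` is disabled.
    """
    summaries = summarize_standard_protein(records, standard_id)
    if check_stability:
        r, stable = assess_standard_stability(
            summaries, per_run_sample_medians(records, basis=sample_basis),
            cutoff=cutoff,
        )
        if not stable:
            raise ValidationError(
                f"standard {standard_id!r} is unstable (r={r:.3f} <= {cutoff}); "
                "pick another standard or skip stage-2 normalization"
            )
    target = summaries.median()
    shifts = (target - summaries).fillna(0.0)
    df = records.copy()
    is_light = df["channel"] == "light"
    df.loc[is_light, "log2_intensity"] = (
        df.loc[is_light, "log2_intensity"]
        + shifts.reindex(df.loc[is_light, "run_id"]).to_numpy()
    )
    return df, shifts


def choose_standard(
    records: pd.DataFrame,
    standard_ids: list[str] | None = None,
    sample_basis: str = "median",
    cutoff: float = STABILITY_CUTOFF,
) -> tuple[str | None, dict[str, float], list[str]]:
    """Screen the spiked standards and pick the stable one with the highest
    correlation.  Returns (chosen id or None, per-standard r, unstable ids)."""
    if standard_ids is None:
        standard_ids = sorted(
            records.loc[records["is_standard"], "protein_id"].unique()
        )
    medians = per_run_sample_medians(records, basis=sample_basis)
    correlations: dict[str, float] = {}
    unstable: list[str] = []
    best, best_r = None, -np.inf
    for sid in standard_ids:
        summaries = summarize_standard_protein(records, sid)
        r, stable = assess_standard_stability(summaries, medians, cutoff=cutoff)
        correlations[sid] = r
        if stable:
            if r > best_r:
                best, best_r = sid, r
        else:
            unstable.append(sid)
    return best, correlations, unstable


def equalize_cohort_medians(
    matrix_a: AbundanceMatrix, matrix_b: AbundanceMatrix
) -> AbundanceMatrix:
    """Shift matrix_b by one constant so its grand median over observed cells
    equals matrix_a's."""
    shared = set(matrix_a.protein_ids) & set(matrix_b.protein_ids)
    if not shared:
        raise ValidationError("cohort matrices share no proteins")
    med_a = np.nanmedian(matrix_a.values.to_numpy())
    med_b = np.nanmedian(matrix_b.values.to_numpy())
    out = matrix_b.copy()
    out.values = out.values + (med_a - med_b)
    return out


def filter_sparse_features(
    feature_table: pd.DataFrame, run_groups: pd.Series
) -> pd.DataFrame:
    """Remove features (rows) missing in more than five-sixths of the runs or
    missing in every run of at least one group."""
    missing = feature_table.isna()
    frac = missing.mean(axis=1)
    remove = frac > 5.0 / 6.0
    for g in run_groups.unique():
        runs = run_groups.index[run_groups == g]
        remove |= missing.loc[:, runs].all(axis=1)
    return feature_table.loc[~remove]


def scale_normalize(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Equalize each run's median absolute deviation about its own median to
    the geometric mean of the per-run MADs (multiplicative on centered
    values).  Runs with fewer than two observed values are skipped."""
    out = feature_table.copy()
    mads: dict[str, tuple[float, float]] = {}
    for run in out.columns:
        col = out[run].dropna()
        if len(col) < 2:
            logger.warning("run %s has < 2 observed values; scale skipped", run)
            continue
        med = float(col.median())
        mad = float((col - med).abs().median())
        if mad == 0:
            logger.warning("run %s has zero MAD; scale skipped", run)
            continue
        mads[run] = (med, mad)
    if not mads:
        return out
    target = float(np.exp(np.mean([np.log(m) for _, m in mads.values()])))
    for run, (med, mad) in mads.items():
        out[run] = med + (out[run] - med) * (target / mad)
    return out
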