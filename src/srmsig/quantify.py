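"""Protein-level summarization and differential abundance testing.

Summarization fits, per protein, an additive peptide + subject fixed-effects
model to the normalized light intensities and reports one log2 relative
abundance per subject.  Group comparisons use a pooled-variance two-sample
t-test on those summaries with Benjamini–Hochberg adjustment across tested
proteins, and Delta-method fold-change transforms to the original scale.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._linmodel import additive_summaries
from .types import AbundanceMatrix, ValidationError

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: significance presets: (alpha on the adjusted/raw p, cutoff, cutoff scale)
PRESETS = {
    # adj_p < 0.05 and original-scale FC outside [1/1.1, 1.1]
    "plasma": {"alpha": 0.05, "fc_cutoff": 1.1, "scale": "original"},
    # adj_p < 0.05 and |log2FC| >= 1.5
    "tissue": {"alpha": 0.05, "fc_cutoff": 1.5, "scale": "log2"},
}

RESULT_COLUMNS = [
    "protein_id", "log2fc", "se_log2", "dof", "p_value", "adj_p",
    "fc_original", "se_original", "n_case", "n_control", "significant",
]


def summarize_protein_abundance(
    records: pd.DataFrame, min_subjects: int = 1
) -> AbundanceMatrix:
    """Summarize endogenous light peptide intensities into one log2 relative
    abundance per (subject, protein).

    Cells where the subject has no observed peptide for the protein stay
    masked; proteins observed in fewer than ``min_subjects`` subjects are
    dropped with a warning.
    """
    endog = records[(records["channel"] == "light") & (~records["is_standard"])]
    subjects = list(pd.unique(endog["subject_id"]))
    cohort = endog.drop_duplicates("subject_id").set_index("subject_id")["cohort_id"]

    columns = {}
    for pid, sub in endog.groupby("protein_id", sort=True):
        observed = sub["log2_intensity"].notna()
        n_obs_subjects = sub.loc[observed, "subject_id"].nunique()
        if n_obs_subjects < min_subjects:
            logger.warning("protein %s observed in %d subjects; dropped",
                           pid, n_obs_subjects)
            continue
        columns[pid] = additive_summaries(
            sub["log2_intensity"].to_numpy(),
            sub["peptide_id"].to_numpy(),
            sub["subject_id"].to_numpy(),
            col_levels=subjects,
        )
    values = pd.DataFrame(columns, index=pd.Index(subjects, name="subject_id"))
    return AbundanceMatrix(values, cohort.reindex(subjects))


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def delta_transform(log2fc: float, se_log2: float) -> tuple[float, float]:
    """Delta-method transform to the original scale:
    ``fc = 2**log2fc`` and ``se = se_log2 * ln(2) * 2**log2fc``."""
    fc = float(2.0 ** log2fc)
    return fc, float(se_log2 * LN2 * fc)


def differential_abundance(
    matrix: AbundanceMatrix,
    group_labels: pd.Series,
    preset: str = "plasma",
    alpha: float | None = None,
    fc_cutoff: float | None = None,
    use_adjusted_p: bool = True,
    case_label: str = "CRC",
) -> pd.DataFrame:
    """Per-protein case-vs-control comparison of summarized abundances.

    Pooled-variance two-sample t-test on observed cells (log2 scale), BH
    adjustment across tested proteins, Delta-method original-scale FC/SE and
    a preset-dependent significance flag.  ``group_labels`` maps subject to a
    group; subjects labelled ``case_label`` are cases, everything else is
    control.  Proteins with fewer than 2 observed values in either group are
    skipped (and excluded from the BH family).
    """
    if preset not in PRESETS and preset != "custom":
        raise ValidationError(f"unknown preset {preset!r}")
    params = PRESETS.get(preset, PRESETS["plasma"]).copy()
    if alpha is not None:
        params["alpha"] = alpha
    if fc_cutoff is not None:
        params["fc_cutoff"] = fc_cutoff

    labels = group_labels.reindex(matrix.values.index)
    is_case = (labels == case_label).to_numpy()
    values = matrix.values.to_numpy(dtype=float)
    observed = np.isfinite(values)

    case_obs = observed & is_case[:, None]
    ctrl_obs = observed & ~is_case[:, None]
    n1 = case_obs.sum(axis=0)
    n2 = ctrl_obs.sum(axis=0)

    with np.errstate(invalid="ignore"):
        sum1 = np.where(case_obs, values, 0.0).sum(axis=0)
        sum2 = np.where(ctrl_obs, values, 0.0).sum(axis=0)
        mean1 = np.divide(sum1, n1, out=np.full_like(sum1, np.nan), where=n1 > 0)
        mean2 = np.divide(sum2, n2, out=np.full_like(sum2, np.nan), where=n2 > 0)
        ss1 = np.where(case_obs, (values - mean1[None, :]) ** 2, 0.0).sum(axis=0)
        ss2 = np.where(ctrl_obs, (values - mean2[None, :]) ** 2, 0.0).sum(axis=0)

    testable = (n1 >= 2) & (n2 >= 2)
    skipped = [matrix.protein_ids[j] for j in np.flatnonzero(~testable)]
    for pid in skipped:
        logger.info("protein %s skipped: < 2 observed values in a group", pid)

    rows = []
    for j in np.flatnonzero(testable):
        dof = n1[j] + n2[j] - 2
        pooled_var = (ss1[j] + ss2[j]) / dof
        se = float(np.sqrt(pooled_var * (1.0 / n1[j] + 1.0 / n2[j])))
        log2fc = float(mean1[j] - mean2[j])
        if se == 0:
            t = 0.0 if log2fc == 0 else np.sign(log2fc) * np.inf
        else:
            t = log2fc / se
        p = float(2.0 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
        fc, se_orig = delta_transform(log2fc, se)
        rows.append({
            "protein_id": matrix.protein_ids[j],
            "log2fc": log2fc, "se_log2": se, "dof": float(dof),
            "p_value": p, "fc_original": fc, "se_original": se_orig,
            "n_case": int(n1[j]), "n_control": int(n2[j]),
        })
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                         if c not in ("adj_p", "significant")])
    if result.empty:
        result["adj_p"] = []
        result["significant"] = []
        return result.loc[:, RESULT_COLUMNS]

    result["adj_p"] = adjust_bh(result["p_value"].to_numpy())
    p_used = result["adj_p"] if use_adjusted_p else result["p_value"]
    if params["scale"] == "original":
        cut = params["fc_cutoff"]
        passes_fc = (result["fc_original"] > cut) | (result["fc_original"] < 1.0 / cut)
    else:
        passes_fc = result["log2fc"].abs() >= params["fc_cutoff"]
    result["significant"] = (p_used < params["alpha"]) & passes_fc
    return result.loc[:, RESULT_COLUMNS]
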