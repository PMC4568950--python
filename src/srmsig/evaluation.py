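"""ROC/AUC machinery with bootstrap inference, confusion metrics, stratified
subgroup evaluation, CEA comparison, decile response curves, probability
surfaces, univariate tests and Ward clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .types import AbundanceMatrix, SignatureModel, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_B = 2000
CEA_CUTOFF = 5.0
TUMOR_SIZE_EDGES = (3.5, 6.0)  # cm: [0, 3.5), [3.5, 6), [6, inf)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = P(case score > control score) + 0.5 * P(tie), via the rank
    (Mann–Whitney) statistic.  Requires both classes."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes required to compute AUC")
    ranks = stats.rankdata(s)
    u = np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Operating points (threshold, sensitivity, specificity) of the
    empirical ROC curve at every distinct score (rule: score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    thresholds = np.unique(s)[::-1]
    rows = []
    for t in np.concatenate([[np.inf], thresholds]):
        pred = s >= t
        sens = float(np.mean(pred[y == 1])) if np.any(y == 1) else np.nan
        spec = float(np.mean(~pred[y == 0])) if np.any(y == 0) else np.nan
        rows.append({"threshold": float(t), "sensitivity": sens,
                     "specificity": spec})
    return pd.DataFrame(rows)


@dataclass
class ROCCurve:
    points: pd.DataFrame
    auc: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_bootstrap: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_bootstrap": self.n_bootstrap, "seed": self.seed,
            "points": self.points.to_dict(orient="list"),
        }


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    B: int = DEFAULT_B,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Stratified nonparametric bootstrap percentile CI for the AUC."""
    if B < 1:
        raise ValidationError("B must be >= 1")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    auc = roc_auc(s, y)
    case = np.flatnonzero(y == 1)
    ctrl = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for b in range(B):
        ci = rng.choice(case, size=len(case), replace=True)
        cj = rng.choice(ctrl, size=len(ctrl), replace=True)
        idx = np.concatenate([ci, cj])
        boots[b] = roc_auc(s[idx], y[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return auc, float(lo), float(hi)


def compare_auc_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired bootstrap comparison of two correlated ROC curves measured on
    the same subjects.

    Resamples subjects (stratified by class), computes the bootstrap
    distribution of delta AUC, and reports a two-sided p-value as twice the
    smaller tail fraction crossing zero, capped at 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValidationError("score vectors must align with labels")
    delta = roc_auc(a, y) - roc_auc(b, y)
    case = np.flatnonzero(y == 1)
    ctrl = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    for i in range(B):
        ci = rng.choice(case, size=len(case), replace=True)
        cj = rng.choice(ctrl, size=len(ctrl), replace=True)
        idx = np.concatenate([ci, cj])
        deltas[i] = roc_auc(a[idx], y[idx]) - roc_auc(b[idx], y[idx])
    p_low = float(np.mean(deltas <= 0.0))
    p_high = float(np.mean(deltas >= 0.0))
    p = min(1.0, 2.0 * min(p_low, p_high))
    return float(delta), p


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> dict[str, float]:
    """Sensitivity, specificity and accuracy with rule score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required")
    pred = s >= threshold
    tp = float(np.sum(pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    n1 = float(np.sum(y == 1))
    n0 = float(np.sum(y == 0))
    return {
        "sensitivity": tp / n1,
        "specificity": tn / n0,
        "accuracy": (tp + tn) / (n1 + n0),
    }


# ---------------------------------------------------------------------------
# stratified evaluation

@dataclass
class StratifiedReport:
    strata: dict[str, dict] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"strata": self.strata, "excluded": self.excluded}


def _stage_strata(meta: pd.DataFrame) -> dict[str, pd.Index]:
    crc = meta[meta["group"] == "CRC"]
    return {
        f"stage_{st}": crc.index[crc["stage"] == st]
        for st in ("I", "II", "III", "IV")
    }


def _size_strata(meta: pd.DataFrame, edges=TUMOR_SIZE_EDGES):
    crc = meta[meta["group"] == "CRC"]
    d = crc["tumor_diameter_cm"]
    known = d.notna()
    lo, hi = edges
    strata = {
        f"size_lt_{lo}": crc.index[known & (d < lo)],
        f"size_{lo}_to_{hi}": crc.index[known & (d >= lo) & (d < hi)],
        f"size_ge_{hi}": crc.index[known & (d >= hi)],
    }
    return strata, int((~known).sum())


def _cea_strata(meta: pd.DataFrame, cutoff=CEA_CUTOFF):
    crc = meta[meta["group"] == "CRC"]
    c = crc["cea_ng_ml"]
    known = c.notna()
    strata = {
        "cea_positive": crc.index[known & (c > cutoff)],
        "cea_negative": crc.index[known & (c <= cutoff)],
    }
    return strata, int((~known).sum())


def stratified_evaluate(
    model: SignatureModel,
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    strata_spec: list[str] | None = None,
    threshold: float | None = None,
    B: int = 0,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> StratifiedReport:
    """Evaluate the signature per CRC stratum against the shared full control
    group, at a fixed probability threshold.

    ``strata_spec`` subsets of {"stage", "size", "cea"}; default all three.
    Each stratum entry reports n, AUC (with optional bootstrap CI when
    ``B > 0``) and the fixed-threshold confusion metrics; empty strata are
    reported with n=0 and no curve.
    """
    if threshold is None:
        threshold = model.threshold
    if strata_spec is None:
        strata_spec = ["stage", "size", "cea"]
    from .discovery import predict_probability

    meta = metadata.set_index("subject_id").reindex(matrix.values.index)
    scores = predict_probability(model, matrix, covariates)
    controls = meta.index[meta["group"] != "CRC"]
    y_ctrl = np.zeros(len(controls))

    report = StratifiedReport()
    strata: dict[str, pd.Index] = {}
    if "stage" in strata_spec:
        strata.update(_stage_strata(meta))
    if "size" in strata_spec:
        size_strata, n_na = _size_strata(meta)
        strata.update(size_strata)
        report.excluded["size_na"] = n_na
    if "cea" in strata_spec:
        cea_strata, n_na = _cea_strata(meta)
        strata.update(cea_strata)
        report.excluded["cea_na"] = n_na
    if not strata:
        strata = {"all_CRC": meta.index[meta["group"] == "CRC"]}

    for name, case_ids in strata.items():
        n = len(case_ids)
        if n == 0:
            report.strata[name] = {"n": 0}
            continue
        ids = list(case_ids) + list(controls)
        s = scores.loc[ids].to_numpy()
        y = np.concatenate([np.ones(n), y_ctrl])
        entry: dict = {"n": n, "auc": roc_auc(s, y)}
        if B > 0:
            _, lo, hi = bootstrap_auc_ci(s, y, B=B, seed=seed)
            entry.update(ci_low=lo, ci_high=hi, n_bootstrap=B)
        entry.update(confusion_metrics(s, y, threshold))
        report.strata[name] = entry
    return report


def cea_classify(
    cea_values: pd.Series | np.ndarray, cutoff: float = CEA_CUTOFF
) -> tuple[pd.Series, int]:
    """CEA rule: positive iff value > cutoff (strict).  NA values are
    excluded and counted."""
    v = pd.Series(cea_values).astype(float)
    known = v.dropna()
    n_excluded = int(v.isna().sum())
    return (known > cutoff).astype(int), n_excluded


# ---------------------------------------------------------------------------
# descriptive characterization

def decile_response(
    abundance: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    smooth: bool = False,
) -> pd.DataFrame:
    """Partition subjects into ``n_bins`` near-equal rank groups of abundance
    and report the per-bin mean abundance and CRC proportion.

    Bin sizes differ by at most one (larger bins first).  With
    ``smooth=True`` a lowess-smoothed proportion is attached (presentation
    only).
    """
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(labels, dtype=float)
    n = len(x)
    if n < n_bins:
        raise ValidationError(f"need >= {n_bins} subjects for decile response")
    order = np.argsort(x, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    rows, start = [], 0
    for b, size in enumerate(sizes):
        idx = order[start:start + size]
        start += size
        rows.append({
            "bin": b + 1,
            "n": size,
            "mean_abundance": float(np.mean(x[idx])),
            "crc_proportion": float(np.mean(y[idx])),
        })
    out = pd.DataFrame(rows)
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        sm = lowess(out["crc_proportion"], out["mean_abundance"],
                    frac=0.75, return_sorted=False)
        out["smoothed_proportion"] = sm
    return out


def probability_surface(
    model: SignatureModel,
    varying_protein: str,
    training_matrix: AbundanceMatrix,
    fixed_spec: dict[str, list[float]] | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Predicted probability as a function of one protein's abundance with
    the other signature proteins fixed at quantiles of their training
    distributions (one curve per quantile combination)."""
    import itertools

    from scipy.special import expit

    if varying_protein not in model.protein_ids:
        raise ValidationError(f"{varying_protein!r} is not a model protein")
    if model.covariates:
        raise ValidationError("probability_surface does not support covariates")
    others = [p for p in model.protein_ids if p != varying_protein]
    if fixed_spec is None:
        fixed_spec = {p: [0.25, 0.75] for p in others}
    unknown = set(fixed_spec) - set(others)
    if unknown:
        raise ValidationError(f"unknown fixed proteins: {sorted(unknown)}")
    missing = set(others) - set(fixed_spec)
    if missing:
        raise ValidationError(f"fixed_spec missing proteins: {sorted(missing)}")

    coef = dict(zip(model.protein_ids, model.coefficients))
    col = training_matrix.values[varying_protein].dropna()
    grid = np.linspace(col.min(), col.max(), n_grid)
    combos = list(itertools.product(*[
        [(p, q) for q in fixed_spec[p]] for p in others
    ])) or [()]

    rows = []
    for combo in combos:
        offset = model.intercept
        label_parts = []
        for p, q in combo:
            xq = float(training_matrix.values[p].dropna().quantile(q))
            offset += coef[p] * xq
            label_parts.append(f"{p}@q{q:g}")
        eta = offset + coef[varying_protein] * grid
        probs = expit(eta)
        label = ",".join(label_parts) or "baseline"
        for xv, pv in zip(grid, probs):
            rows.append({"curve": label, "abundance": float(xv),
                         "probability": float(pv)})
    return pd.DataFrame(rows)


def group_mean_test(values_a, values_b) -> tuple[float, float]:
    """Two-sample pooled-variance t-test, two-sided.

    Degenerate case (zero pooled variance, equal means) reports t=0, p=1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    dof = len(a) + len(b) - 2
    pooled_var = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / dof
    se = np.sqrt(pooled_var * (1.0 / len(a) + 1.0 / len(b)))
    diff = a.mean() - b.mean()
    if se == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t = float(diff / se)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return t, p


def ward_clustering(matrix: AbundanceMatrix) -> dict:
    """Agglomerative clustering of subjects (Euclidean metric, Ward linkage)
    on a complete (imputed) matrix.  Returns the leaf order and the merge
    tree."""
    values = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("matrix contains missing cells; impute first")
    subjects = matrix.subject_ids
    if len(subjects) == 1:
        return {"leaf_order": subjects, "linkage": []}
    Z = linkage(values, method="ward", metric="euclidean")
    order = [subjects[i] for i in leaves_list(Z)]
    return {"leaf_order": order, "linkage": Z.tolist()}


def cut_tree_two(linkage_matrix: list, n_leaves: int) -> np.ndarray:
    """Cluster assignment when cutting the merge tree at two clusters."""
    from scipy.cluster.hierarchy import fcluster

    Z = np.asarray(linkage_matrix, dtype=float)
    return fcluster(Z, t=2, criterion="maxclust")
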