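"""Signature discovery: LOD imputation, missingness filtering, stepwise-AIC
logistic regression inside consensus cross-validation, threshold selection
and the exhaustive bootstrapped subset search.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import AbundanceMatrix, SignatureModel, ValidationError

logger = logging.getLogger(__name__)

MAX_IRLS_ITER = 30
SEPARATION_BOUND = 30.0
DEFAULT_FILTER_PARAMS = {"alpha": 0.05, "fc_cutoff": 1.1, "use_adjusted_p": True}


# ---------------------------------------------------------------------------
# missingness handling

def impute_lod(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Impute each protein's missing cells with the minimal observed value of
    that protein within the same cohort (its effective limit of detection).

    Raises if a protein is entirely missing within a cohort.
    """
    out = matrix.copy()
    for cohort in out.cohort.unique():
        rows = out.cohort == cohort
        block = out.values.loc[rows]
        minima = block.min(axis=0, skipna=True)
        dead = minima.index[minima.isna()]
        if len(dead):
            raise ValidationError(
                f"protein {dead[0]!r} has no observed value in cohort "
                f"{cohort!r}: cannot impute its limit of detection"
            )
        out.values.loc[rows] = block.fillna(minima)
    return out


def filter_missing_proteins(
    matrix: AbundanceMatrix, max_frac: float = 0.40
) -> AbundanceMatrix:
    """Drop proteins whose missing fraction exceeds ``max_frac`` (strict)."""
    frac = matrix.values.isna().mean(axis=0)
    keep = frac.index[frac <= max_frac]
    return matrix.select_proteins(list(keep))


# ---------------------------------------------------------------------------
# logistic regression by IRLS

@dataclass
class LogisticFit:
    feature_names: list[str]
    coefficients: np.ndarray  # intercept first
    log_likelihood: float
    aic: float
    converged: bool
    separated: bool
    n_iter: int

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coefficients[0] + X @ self.coefficients[1:]
        return expit(eta)


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = MAX_IRLS_ITER,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares.

    Returns coefficients (intercept first), log-likelihood and
    ``AIC = -2*ll + 2*n_params``.  Fits where any |linear predictor| exceeds
    the separation bound are flagged ``separated``; fits that fail to
    converge within ``max_iter`` iterations are flagged ``converged=False``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = design @ beta
        if np.max(np.abs(eta)) > SEPARATION_BOUND:
            separated = True
            break
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        new_beta, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        if step < tol:
            converged = True
            break

    eta = design @ beta
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    aic = -2.0 * ll + 2.0 * (p + 1)
    return LogisticFit(
        feature_names=feature_names,
        coefficients=beta,
        log_likelihood=ll,
        aic=aic,
        converged=converged,
        separated=separated,
        n_iter=it,
    )


def stepwise_select(
    values: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str] | None = None,
    forced: pd.DataFrame | None = None,
    start: str = "empty",
    max_steps: int = 100,
) -> tuple[list[str], list[float]]:
    """Bidirectional greedy stepwise selection minimizing AIC.

    At every step evaluates all single additions and single drops, applies
    the move with the lowest AIC if it improves the current AIC, and stops
    otherwise.  Fits flagged as separated are excluded from the move set.
    Returns the selected protein list and the AIC trace of accepted states.
    """
    if candidates is None:
        candidates = list(values.columns)
    if start == "empty":
        current: list[str] = []
    elif start == "full":
        current = list(candidates)
    else:
        raise ValidationError("start must be 'empty' or 'full'")

    def fit_for(subset: list[str]) -> LogisticFit:
        cols = values[subset]
        if forced is not None:
            cols = pd.concat([cols, forced], axis=1)
        if cols.shape[1] == 0:
            cols = pd.DataFrame(index=values.index)
        return fit_logistic(cols.to_numpy(dtype=float).reshape(len(values), -1),
                            y, feature_names=list(cols.columns))

    current_fit = fit_for(current)
    if current_fit.separated:
        logger.warning("start model is separated; returning start set")
        return current, [current_fit.aic]
    trace = [current_fit.aic]
    for _ in range(max_steps):
        moves: list[tuple[float, list[str]]] = []
        for pid in candidates:
            if pid in current:
                continue
            trial = current + [pid]
            f = fit_for(trial)
            if not f.separated:
                moves.append((f.aic, trial))
        for pid in current:
            trial = [q for q in current if q != pid]
            f = fit_for(trial)
            if not f.separated:
                moves.append((f.aic, trial))
        if not moves:
            break
        best_aic, best_set = min(moves, key=lambda m: (m[0], len(m[1])))
        if best_aic < trace[-1] - 1e-10:
            current = best_set
            trace.append(best_aic)
        else:
            break
    return current, trace


# ---------------------------------------------------------------------------
# prediction and threshold

def predict_probability(
    model: SignatureModel,
    matrix: AbundanceMatrix,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Inverse-logit of the signature's linear predictor per subject."""
    missing = [p for p in model.protein_ids if p not in matrix.values.columns]
    if missing:
        raise ValidationError(f"matrix lacks model proteins: {missing}")
    eta = np.full(len(matrix.values.index), model.intercept, dtype=float)
    for pid, beta in zip(model.protein_ids, model.coefficients):
        eta += beta * matrix.values[pid].to_numpy(dtype=float)
    for name, beta in model.covariates.items():
        if covariates is None or name not in covariates.columns:
            raise ValidationError(f"covariate {name!r} required for prediction")
        eta += beta * covariates[name].reindex(matrix.values.index).to_numpy()
    return pd.Series(expit(eta), index=matrix.values.index, name="probability")


def choose_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing accuracy on the training predictions.

    Candidates are midpoints between consecutive sorted unique probabilities
    plus the 0/1 sentinels; prediction rule is ``score >= threshold``; ties
    break toward the smallest threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    uniq = np.unique(p)
    candidates = np.concatenate([[0.0], (uniq[1:] + uniq[:-1]) / 2.0, [1.0]])
    best_t, best_acc = 0.0, -1.0
    for t in candidates:
        acc = float(np.mean((p >= t) == y))
        if acc > best_acc + 1e-12:
            best_t, best_acc = float(t), acc
    return best_t


# ---------------------------------------------------------------------------
# consensus cross-validation

@dataclass
class CVReport:
    """Per-fold record of the consensus cross-validation."""

    fold_assignments: dict[str, int]
    fold_selected: list[list[str]]
    fold_auc: list[float]
    selection_counts: dict[str, int]
    consensus: list[str]
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "fold_assignments": self.fold_assignments,
            "fold_selected": self.fold_selected,
            "fold_auc": self.fold_auc,
            "selection_counts": self.selection_counts,
            "consensus": self.consensus,
            "parameters": self.parameters,
        }


def assign_folds(
    labels: pd.Series, k: int, seed: int, case_label: str = "CRC"
) -> dict[str, int]:
    """Stratified, seeded fold assignment keyed by subject id.

    Subjects are sorted by id within each class, shuffled with the seed, and
    dealt round-robin — so the assignment depends on the subject ids and the
    seed, not on input row order.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for cls in (True, False):
        ids = sorted(labels.index[(labels == case_label) == cls])
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignment[ids[idx]] = pos % k
    return assignment


def consensus_cv(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    k: int = 10,
    min_count: int = 5,
    filter_params: dict | None = None,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
    case_label: str = "CRC",
    start: str = "empty",
) -> tuple[CVReport, SignatureModel]:
    """Consensus cross-validated signature selection.

    For each of ``k`` stratified folds: a differential-abundance filter on
    the training folds (plasma preset with ``filter_params``), stepwise-AIC
    logistic selection, a fit, and held-out AUC.  The consensus set is the
    proteins selected in at least ``min_count`` folds; the final model is
    refit on the full cohort with the threshold chosen by best training
    accuracy.  An empty consensus yields an explicit intercept-only model.

    The matrix must already be imputed (no missing cells).
    """
    from .evaluation import roc_auc
    from .quantify import differential_abundance

    if matrix.n_missing:
        raise ValidationError("consensus_cv requires an imputed matrix")
    fp = {**DEFAULT_FILTER_PARAMS, **(filter_params or {})}
    labels = labels.reindex(matrix.values.index)
    y_all = (labels == case_label).astype(float)

    folds = assign_folds(labels, k=k, seed=seed, case_label=case_label)
    order = list(matrix.values.index)
    fold_of = np.array([folds[s] for s in order])

    fold_selected: list[list[str]] = []
    fold_auc: list[float] = []
    counts: dict[str, int] = {p: 0 for p in matrix.protein_ids}
    for f in range(k):
        train_ids = [s for s, ff in zip(order, fold_of) if ff != f]
        test_ids = [s for s, ff in zip(order, fold_of) if ff == f]
        train = matrix.select_subjects(train_ids)
        diff = differential_abundance(
            train, labels, preset="plasma",
            alpha=fp["alpha"], fc_cutoff=fp["fc_cutoff"],
            use_adjusted_p=fp["use_adjusted_p"], case_label=case_label,
        )
        candidates = sorted(diff.loc[diff["significant"], "protein_id"])
        forced = None if covariates is None else covariates.reindex(train_ids)
        selected, _ = stepwise_select(
            train.values, y_all.loc[train_ids].to_numpy(),
            candidates=candidates, forced=forced, start=start,
        )
        fold_selected.append(sorted(selected))
        for pid in selected:
            counts[pid] += 1
        fit = _fit_signature(train, y_all.loc[train_ids].to_numpy(),
                             sorted(selected), forced)
        test = matrix.select_subjects(test_ids)
        model = _fit_to_model(fit, sorted(selected), covariates)
        probs = predict_probability(
            model, test,
            None if covariates is None else covariates.reindex(test_ids),
        )
        y_test = y_all.loc[test_ids].to_numpy()
        if len(np.unique(y_test)) < 2:
            fold_auc.append(float("nan"))
        else:
            fold_auc.append(roc_auc(probs.to_numpy(), y_test))

    consensus = sorted(p for p, c in counts.items() if c >= min_count)
    if not consensus:
        logger.info("no stable signature: consensus set is empty")

    forced_all = None if covariates is None else covariates.reindex(order)
    final_fit = _fit_signature(matrix, y_all.to_numpy(), consensus, forced_all)
    model = _fit_to_model(final_fit, consensus, covariates)
    probs = predict_probability(model, matrix, forced_all)
    if len(np.unique(probs.to_numpy())) > 1:
        threshold = choose_threshold(probs.to_numpy(), y_all.to_numpy())
    else:
        threshold = 0.5
    model.threshold = threshold
    model.fold_selection_counts = {p: c for p, c in sorted(counts.items()) if c > 0}

    report = CVReport(
        fold_assignments=folds,
        fold_selected=fold_selected,
        fold_auc=fold_auc,
        selection_counts=model.fold_selection_counts,
        consensus=consensus,
        parameters={
            "k": k, "min_count": min_count, "seed": seed, **fp,
            "start": start, "case_label": case_label,
            "covariates": [] if covariates is None else list(covariates.columns),
        },
    )
    return report, model


def _fit_signature(matrix, y, protein_ids, forced):
    cols = matrix.values[list(protein_ids)]
    if forced is not None:
        cols = pd.concat([cols, forced], axis=1)
    X = cols.to_numpy(dtype=float).reshape(len(matrix.values.index), -1)
    return fit_logistic(X, y, feature_names=list(cols.columns))


def _fit_to_model(fit: LogisticFit, protein_ids, covariates) -> SignatureModel:
    cov_names = [] if covariates is None else [
        n for n in fit.feature_names if n not in protein_ids
    ]
    coef_map = dict(zip(fit.feature_names, fit.coefficients[1:]))
    return SignatureModel(
        protein_ids=list(protein_ids),
        coefficients=[float(coef_map[p]) for p in protein_ids],
        intercept=fit.intercept,
        threshold=0.5,
        covariates={n: float(coef_map[n]) for n in cov_names},
        converged=fit.converged,
        separated=fit.separated,
    )


# ---------------------------------------------------------------------------
# exhaustive bootstrapped subset search

@dataclass
class ExhaustiveResult:
    models: pd.DataFrame  # columns: proteins (tuple), size, median_auc
    protein_frequency: pd.Series
    parameters: dict
    n_redraws: int = 0

    @property
    def n_models(self) -> int:
        return len(self.models)


def n_subset_models(p: int, max_size: int) -> int:
    """Number of candidate models: sum of C(p, k) for k = 1..max_size."""
    return int(sum(math.comb(p, k) for k in range(1, min(max_size, p) + 1)))


def bootstrap_plan(
    y: np.ndarray, B: int, seed: int
) -> tuple[list[tuple[np.ndarray, np.ndarray]], int]:
    """B stratified bootstrap rounds: (train indices resampled with
    replacement within class, out-of-bag indices).  Rounds whose out-of-bag
    set lacks a class are redrawn (counted)."""
    y = np.asarray(y, dtype=float)
    case = np.flatnonzero(y == 1)
    ctrl = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    plan = []
    redraws = 0
    while len(plan) < B:
        tr = np.concatenate([
            rng.choice(case, size=len(case), replace=True),
            rng.choice(ctrl, size=len(ctrl), replace=True),
        ])
        oob = np.setdiff1d(np.arange(len(y)), np.unique(tr))
        if len(oob) == 0 or len(np.unique(y[oob])) < 2:
            redraws += 1
            continue
        plan.append((tr, oob))
    return plan, redraws


def exhaustive_search(
    matrix: AbundanceMatrix | pd.DataFrame,
    labels: pd.Series | np.ndarray,
    max_size: int = 5,
    B: int = 100,
    seed: int = 0,
    max_proteins: int = 15,
    allow_large: bool = False,
    case_label: str = "CRC",
    tie_tol: float = 0.01,
) -> ExhaustiveResult:
    """Enumerate all protein subsets of size 1..max_size, score each by the
    median out-of-bag AUC over ``B`` stratified bootstrap rounds, and rank
    models by median AUC (descending).  Among the set of top models whose
    median AUC is within ``tie_tol`` of the best, proteins are ranked by
    their frequency of occurrence.
    """
    from .evaluation import roc_auc

    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    if isinstance(labels, pd.Series):
        y = (labels.reindex(values.index) == case_label).to_numpy(dtype=float)
    else:
        y = np.asarray(labels, dtype=float)
    proteins = list(values.columns)
    p = len(proteins)
    total = n_subset_models(p, max_size)
    if p > max_proteins and not allow_large:
        raise ValidationError(
            f"{p} proteins would require {total} models; restrict the "
            "candidate pool or pass allow_large=True"
        )

    plan, redraws = bootstrap_plan(y, B, seed)
    X_all = values.to_numpy(dtype=float)
    rows = []
    for size in range(1, min(max_size, p) + 1):
        for combo in itertools.combinations(range(p), size):
            aucs = []
            X = X_all[:, combo]
            for tr, oob in plan:
                fit = fit_logistic(X[tr], y[tr])
                probs = fit.predict(X[oob])
                aucs.append(roc_auc(probs, y[oob]))
            rows.append({
                "proteins": tuple(proteins[j] for j in combo),
                "size": size,
                "median_auc": float(np.median(aucs)),
            })
    models = pd.DataFrame(rows)
    models = models.sort_values(
        ["median_auc", "size", "proteins"], ascending=[False, True, True]
    ).reset_index(drop=True)

    best = models["median_auc"].iloc[0]
    top = models[models["median_auc"] >= best - tie_tol]
    freq: dict[str, int] = {}
    for combo in top["proteins"]:
        for pid in combo:
            freq[pid] = freq.get(pid, 0) + 1
    frequency = pd.Series(freq, dtype=int)
    frequency = frequency.sort_index().sort_values(
        ascending=False, kind="stable")

    return ExhaustiveResult(
        models=models,
        protein_frequency=frequency,
        parameters={"max_size": max_size, "B": B, "seed": seed,
                    "tie_tol": tie_tol},
        n_redraws=redraws,
    )
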