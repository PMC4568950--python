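"""Synthetic SRM cohort generator.

Emulates the data structure the analysis pipeline assumes: long-format
transition-group intensities for two channels (endogenous *light* plus a
paired stable-isotope *heavy* reference per endogenous peptide), two spiked
non-human standard proteins in every run, per-run acquisition drift, per-batch
sample-preparation shifts, planted case/control effects for a configurable
marker panel, tumor-size-dependent effects for two markers, and left
censoring at a limit of detection.

The generative model on the log2 scale is additive::

    light  = baseline + peptide_offset + subject_effect + group_effect
             + size_effect + batch_shift + run_drift + noise
    heavy  = baseline + peptide_offset + run_drift + noise

Heavy references are spiked into the final peptide sample, so they share the
acquisition drift of the run but not the sample-preparation batch shift nor
any biology; standard proteins are spiked before preparation, so their light
channel carries the batch shift but no subject or group term.  This is the
structure the two normalization stages are designed to invert.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AbundanceMatrix,
    ConfigurationError,
    GroundTruth,
    METADATA_COLUMNS,
    QUANT_COLUMNS,
    STAGES,
)

#: identifiers of the two spiked bovine-like standard proteins
STANDARD_PROTEINS = ("STD-BOV-A", "STD-BOV-B")
_STANDARD_BASELINES = (20.0, 22.0)
_STANDARD_N_PEPTIDES = (3, 2)

#: default stage proportions for synthetic CRC subjects
DEFAULT_STAGE_WEIGHTS = (43, 58, 49, 52)

#: default per-stage CEA log-normal parameters (natural-log ng/ml);
#: controls draw from the lowest-location entry
DEFAULT_CEA_PARAMS = {
    "control": (0.69, 0.80),
    "I": (0.90, 0.90),
    "II": (1.10, 1.00),
    "III": (1.40, 1.00),
    "IV": (2.00, 1.10),
}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort draw.

    All scales are log2 units unless noted.  ``seed`` fully determines the
    output; protein-level parameters (baselines, peptide layout, marker
    identity and effects) depend on ``seed`` only, so cohorts generated with
    different labels from the same config share the same planted truth.
    """

    n_crc: int = 100
    n_benign: int = 34
    n_healthy: int = 66
    n_proteins: int = 70
    peptides_per_protein: tuple[int, int] = (1, 3)
    n_signature: int = 5
    planted_log2fc: tuple[float, ...] | None = None
    subject_sd: float = 0.8
    peptide_sd: float = 1.0
    run_sd: float = 0.3
    batch_sd: float = 1.5
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (10.0, 26.0)
    lod: float = 12.0
    random_missing_rate: float = 0.02
    tumor_size_effect: float = 0.15
    cea_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CEA_PARAMS)
    )
    age_shift: float = 5.0
    n_batches: int = 8
    stage_weights: tuple[int, ...] = DEFAULT_STAGE_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_crc", "n_benign", "n_healthy", "n_proteins", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_signature < 0 or self.n_signature > self.n_proteins:
            raise ConfigurationError("n_signature must be in [0, n_proteins]")
        for name in ("subject_sd", "peptide_sd", "run_sd", "batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.random_missing_rate < 1.0):
            raise ConfigurationError("random_missing_rate must be in [0, 1)")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ConfigurationError("peptides_per_protein must be a valid range")
        b_lo, b_hi = self.baseline_range
        if b_hi < b_lo:
            raise ConfigurationError("baseline_range must be ordered")
        if self.lod > b_hi:
            raise ConfigurationError(
                "lod above the baseline range maximum would censor everything"
            )
        if self.planted_log2fc is None:
            self.planted_log2fc = default_planted_effects(self.n_signature)
        else:
            self.planted_log2fc = tuple(float(x) for x in self.planted_log2fc)
        if len(self.planted_log2fc) != self.n_signature:
            raise ConfigurationError(
                "planted_log2fc must have exactly n_signature entries"
            )
        if any(x == 0 for x in self.planted_log2fc):
            raise ConfigurationError("planted effects must be non-zero")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cea_params"] = {k: list(v) for k, v in self.cea_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "cea_params" in d and d["cea_params"] is not None:
            d["cea_params"] = {k: tuple(v) for k, v in d["cea_params"].items()}
        for key in ("peptides_per_protein", "baseline_range", "planted_log2fc",
                    "stage_weights"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_planted_effects(n_signature: int) -> tuple[float, ...]:
    """Default marker effects: magnitudes spread over [0.4, 1.0] log2 units,
    with the last marker planted in the negative direction whenever two or
    more markers are requested."""
    if n_signature == 0:
        return ()
    if n_signature == 1:
        return (1.0,)
    mags = np.linspace(1.0, 0.4, n_signature)
    effects = list(mags)
    effects[-1] = -float(np.median(mags))
    return tuple(float(x) for x in effects)


def _cohort_rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode("utf8"))])
    )


def _protein_layout(config: SimulationConfig):
    """Seed-only protein-level parameters: baselines, peptide offsets,
    marker assignment, size-responsive proteins."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    n = config.n_proteins
    protein_ids = [f"PROT{i + 1:03d}" for i in range(n)]
    baselines = rng.uniform(*config.baseline_range, size=n)
    lo, hi = config.peptides_per_protein
    n_peptides = rng.integers(lo, hi + 1, size=n)

    # plant markers on proteins comfortably above the LOD so the signature
    # is recoverable; fall back to the highest baselines if needed
    eligible = np.flatnonzero(baselines >= config.lod + 2.0)
    if len(eligible) < config.n_signature:
        eligible = np.argsort(baselines)[::-1][: max(config.n_signature, 1)]
    marker_idx = rng.choice(eligible, size=config.n_signature, replace=False)
    effects = np.asarray(config.planted_log2fc, dtype=float)

    peptide_offsets = {}
    for i, pid in enumerate(protein_ids):
        peptide_offsets[pid] = rng.normal(0.0, config.peptide_sd, size=n_peptides[i])
    std_offsets = {
        sid: rng.normal(0.0, config.peptide_sd, size=k)
        for sid, k in zip(STANDARD_PROTEINS, _STANDARD_N_PEPTIDES)
    }

    # size-responsive proteins: the strongest positive marker and the
    # negative marker (when present)
    size_ids: list[str] = []
    if config.n_signature >= 1 and config.tumor_size_effect != 0:
        pos = [i for i, e in enumerate(effects) if e > 0]
        neg = [i for i, e in enumerate(effects) if e < 0]
        if pos:
            best = pos[int(np.argmax(effects[pos]))]
            size_ids.append(protein_ids[marker_idx[best]])
        if neg:
            worst = neg[int(np.argmin(effects[neg]))]
            size_ids.append(protein_ids[marker_idx[worst]])

    return protein_ids, baselines, n_peptides, peptide_offsets, std_offsets, \
        marker_idx, effects, size_ids


def _draw_metadata(config: SimulationConfig, label: str,
                   rng: np.random.Generator) -> pd.DataFrame:
    groups = (["CRC"] * config.n_crc + ["benign"] * config.n_benign
              + ["healthy"] * config.n_healthy)
    n = len(groups)
    subject_ids = [f"{label}-S{i + 1:04d}" for i in range(n)]
    run_ids = [f"{label}-R{i + 1:04d}" for i in range(n)]

    w = np.asarray(config.stage_weights, dtype=float)
    stage_p = w / w.sum()
    stages: list[str | None] = []
    diam: list[float] = []
    cea: list[float] = []
    age: list[float] = []
    for g in groups:
        if g == "CRC":
            st = STAGES[rng.choice(len(STAGES), p=stage_p)]
            stages.append(st)
            diam.append(float(np.exp(rng.normal(np.log(4.0), 0.35))))
            mu, sig = config.cea_params.get(st, config.cea_params["control"])
            cea.append(float(np.exp(rng.normal(mu, sig))))
            age.append(float(rng.normal(62.0 + config.age_shift, 10.0)))
        else:
            stages.append(None)
            diam.append(np.nan)
            mu, sig = config.cea_params["control"]
            cea.append(float(np.exp(rng.normal(mu, sig))))
            age.append(float(rng.normal(62.0, 10.0)))

    return pd.DataFrame({
        "subject_id": subject_ids,
        "cohort": label,
        "group": groups,
        "stage": stages,
        "tumor_diameter_cm": diam,
        "cea_ng_ml": cea,
        "age_years": age,
        "run_id": run_ids,
    })[METADATA_COLUMNS]


def generate_cohort(
    config: SimulationConfig, cohort_label: str = "training"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort.

    Returns ``(quant, metadata, truth)``: a long-format quantification frame
    (one run per subject, paired heavy reference for every endogenous
    peptide, both standard proteins in every run), the subject metadata
    frame, and the planted :class:`GroundTruth`.
    """
    (protein_ids, baselines, n_peptides, pep_offsets, std_offsets,
     marker_idx, effects, size_ids) = _protein_layout(config)
    rng = _cohort_rng(config.seed, cohort_label)

    meta = _draw_metadata(config, cohort_label, rng)
    n_subj = len(meta)
    is_crc = (meta["group"] == "CRC").to_numpy()
    diam = meta["tumor_diameter_cm"].to_numpy()

    # run/batch structure: batches assigned block-randomized over subjects
    batch_of_run = rng.permutation(np.arange(n_subj) % config.n_batches)
    batch_shifts = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    run_drift = rng.normal(0.0, config.run_sd, size=n_subj)

    effect_of_protein = np.zeros(config.n_proteins)
    effect_of_protein[marker_idx] = effects
    size_slope = np.zeros(config.n_proteins)
    for pid in size_ids:
        i = protein_ids.index(pid)
        size_slope[i] = config.tumor_size_effect * np.sign(effect_of_protein[i])

    # per subject x protein biological effect
    subj_eff = rng.normal(0.0, config.subject_sd, size=(n_subj, config.n_proteins))

    frames = []
    run_ids = meta["run_id"].to_numpy()
    subject_ids = meta["subject_id"].to_numpy()
    centered_diam = np.where(is_crc, np.nan_to_num(diam - 4.0), 0.0)
    for i, pid in enumerate(protein_ids):
        m = int(n_peptides[i])
        offs = pep_offsets[pid]
        base = baselines[i]
        group_term = np.where(is_crc, effect_of_protein[i], 0.0)
        size_term = size_slope[i] * centered_diam * is_crc
        subject_term = subj_eff[:, i]
        for q in range(m):
            pep_id = f"{pid}_pep{q + 1}"
            mu = base + offs[q]
            light = (mu + subject_term + group_term + size_term
                     + batch_shifts[batch_of_run] + run_drift
                     + rng.normal(0.0, config.noise_sd, size=n_subj))
            heavy = (mu + run_drift
                     + rng.normal(0.0, config.noise_sd, size=n_subj))
            frames.append(_records(run_ids, subject_ids, cohort_label, pid,
                                   pep_id, batch_of_run, light, heavy,
                                   is_standard=False))

    for sid, base, k in zip(STANDARD_PROTEINS, _STANDARD_BASELINES,
                            _STANDARD_N_PEPTIDES):
        offs = std_offsets[sid]
        for q in range(k):
            pep_id = f"{sid}_pep{q + 1}"
            mu = base + offs[q]
            light = (mu + batch_shifts[batch_of_run] + run_drift
                     + rng.normal(0.0, config.noise_sd, size=n_subj))
            heavy = (mu + run_drift
                     + rng.normal(0.0, config.noise_sd, size=n_subj))
            frames.append(_records(run_ids, subject_ids, cohort_label, sid,
                                   pep_id, batch_of_run, light, heavy,
                                   is_standard=True))

    quant = pd.concat(frames, ignore_index=True)

    # left-censoring at the LOD plus an MCAR component, light endogenous only
    light_endog = (quant["channel"] == "light") & (~quant["is_standard"])
    censored = light_endog & (quant["log2_intensity"] < config.lod)
    quant.loc[censored, "log2_intensity"] = np.nan
    if config.random_missing_rate > 0:
        idx = quant.index[light_endog & quant["log2_intensity"].notna()]
        drop = idx[rng.random(len(idx)) < config.random_missing_rate]
        quant.loc[drop, "log2_intensity"] = np.nan

    truth = _ground_truth(config, protein_ids, n_peptides, marker_idx,
                          effects, size_ids)
    return quant, meta, truth


def _records(run_ids, subject_ids, cohort, protein_id, peptide_id,
             batch_of_run, light, heavy, is_standard):
    n = len(run_ids)
    batch = np.array([f"B{b + 1}" for b in batch_of_run])
    return pd.DataFrame({
        "run_id": np.tile(run_ids, 2),
        "cohort_id": cohort,
        "subject_id": np.tile(subject_ids, 2),
        "protein_id": protein_id,
        "peptide_id": peptide_id,
        "channel": np.repeat(["light", "heavy"], n),
        "is_standard": is_standard,
        "batch_id": np.tile(batch, 2),
        "log2_intensity": np.concatenate([light, heavy]),
    })[QUANT_COLUMNS]


def _ground_truth(config, protein_ids, n_peptides, marker_idx, effects,
                  size_ids) -> GroundTruth:
    marker_ids = [protein_ids[i] for i in marker_idx]
    # implied per-protein subject-level variance after peptide averaging
    coefs = {}
    for pid, i, delta in zip(marker_ids, marker_idx, effects):
        var = config.subject_sd ** 2 + config.noise_sd ** 2 / max(int(n_peptides[i]), 1)
        coefs[pid] = float(delta / var) if var > 0 else float("inf")
    n_control = config.n_benign + config.n_healthy
    intercept = float(np.log(config.n_crc / n_control))
    return GroundTruth(
        marker_ids=marker_ids,
        true_log2fc=[float(e) for e in effects],
        size_responsive_ids=list(size_ids),
        generative_coefficients=coefs,
        generative_intercept=intercept,
    )


def generate_null_cohort(
    config: SimulationConfig, cohort_label: str = "training"
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """As :func:`generate_cohort` with every planted effect removed."""
    d = config.to_dict()
    d["n_signature"] = 0
    d["planted_log2fc"] = ()
    d["tumor_size_effect"] = 0.0
    return generate_cohort(SimulationConfig.from_dict(d), cohort_label)


def bayes_scores(truth: GroundTruth, matrix: AbundanceMatrix) -> np.ndarray:
    """Linear score of the data-generating logistic model on an abundance
    matrix (reference upper bound for fitted classifiers)."""
    score = np.zeros(len(matrix.subject_ids))
    for pid, beta in truth.generative_coefficients.items():
        if pid in matrix.values.columns:
            score += beta * matrix.values[pid].fillna(
                matrix.values[pid].min()).to_numpy()
    return score


def generate_feature_fixture(
    n_features: int,
    n_runs: int,
    missing_pattern: Mapping[int, Iterable[int]] | None = None,
    seed: int = 0,
    group_labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Tissue-style feature table (features x runs) with controlled
    per-feature missingness.

    ``missing_pattern`` maps a feature index to the run indices whose cells
    are set missing.  Returns the table and a per-run group label series
    (default: first half ``tumor``, second half ``normal``).
    """
    if n_runs < 2:
        raise ConfigurationError("n_runs must be >= 2")
    if n_features < 1:
        raise ConfigurationError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    run_ids = [f"run{j + 1:02d}" for j in range(n_runs)]
    feature_ids = [f"feat{i + 1:03d}" for i in range(n_features)]
    values = rng.normal(20.0, 2.0, size=(n_features, n_runs))
    table = pd.DataFrame(values, index=feature_ids, columns=run_ids)
    if missing_pattern:
        for fi, runs in missing_pattern.items():
            for rj in runs:
                table.iloc[int(fi), int(rj)] = np.nan
    if group_labels is None:
        half = n_runs // 2
        group_labels = ["tumor"] * half + ["normal"] * (n_runs - half)
    groups = pd.Series(list(group_labels), index=run_ids, name="group")
    return table, groups
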