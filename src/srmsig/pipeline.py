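"""End-to-end pipeline: simulate or load cohorts, normalize, summarize,
test differential abundance, discover a signature and evaluate it, writing a
deterministic report bundle to disk.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discovery, evaluation, io, normalization, quantify
from .synthetic import SimulationConfig, generate_cohort
from .types import AbundanceMatrix, ConfigurationError, dump_json

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "normalization": {"sample_basis": "median", "stability_cutoff": 0.6},
    "differential": {"preset": "plasma"},
    "discovery": {
        "k": 10,
        "min_count": 5,
        "alpha": 0.05,
        "fc_cutoff": 1.1,
        "use_adjusted_p": True,
        "max_missing_frac": 0.40,
    },
    "evaluation": {"B": 200, "strata": ["stage", "size", "cea"]},
}


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _acquire_cohorts(config: dict, log: list[str]):
    """Simulate or read the training (and optional validation) cohorts."""
    if "simulation" in config:
        sim = dict(config["simulation"])
        val_override = sim.pop("validation", None)
        sim.setdefault("seed", config["seed"])
        train_cfg = SimulationConfig.from_dict(sim)
        quant_t, meta_t, truth = generate_cohort(train_cfg, "training")
        log.append(f"simulated training cohort: {len(meta_t)} subjects, "
                   f"seed={train_cfg.seed}")
        cohorts = {"training": (quant_t, meta_t)}
        if val_override is not None:
            val_sim = dict(sim)
            val_sim.update(val_override or {})
            val_cfg = SimulationConfig.from_dict(val_sim)
            quant_v, meta_v, _ = generate_cohort(val_cfg, "validation")
            log.append(f"simulated validation cohort: {len(meta_v)} subjects")
            cohorts["validation"] = (quant_v, meta_v)
        return cohorts, truth
    if "inputs" in config:
        cohorts = {}
        for name, spec in config["inputs"].items():
            quant = io.read_quant_table(
                spec["quant"], dialect=spec.get("dialect", "native"),
                raw=spec.get("raw"),
            )
            meta = io.read_metadata(spec["metadata"])
            cohorts[name] = (quant, meta)
            log.append(f"read cohort {name}: {len(meta)} subjects")
        if "training" not in cohorts:
            raise ConfigurationError("inputs must include a 'training' cohort")
        return cohorts, None
    raise ConfigurationError(
        "config must provide either a 'simulation' block or an 'inputs' block"
    )


def _normalize_cohort(quant, params, log, name):
    normalized, report = normalization.normalize_by_reference(quant)
    chosen, correlations, unstable = normalization.choose_standard(
        normalized, sample_basis=params["sample_basis"],
        cutoff=params["stability_cutoff"],
    )
    report.standard_correlations = {k: float(v) for k, v in correlations.items()}
    report.chosen_standard = chosen
    report.unstable_standards = unstable
    if chosen is None:
        log.append(f"[{name}] no stable standard protein; stage-2 skipped")
        return normalized, report
    normalized, shifts = normalization.normalize_by_standard(
        normalized, chosen, check_stability=False,
        sample_basis=params["sample_basis"],
    )
    report.stage2_shifts = shifts
    log.append(f"[{name}] stage-2 normalization with standard {chosen} "
               f"(r={correlations[chosen]:.3f})")
    return normalized, report


def run_pipeline(config: dict, output_dir) -> dict:
    """Run every stage and write the report bundle under ``output_dir``.

    Returns a summary dict with the signature, per-cohort matrices and the
    evaluation report.  Identical config (including seed) produces a
    byte-identical bundle.
    """
    config = _merged(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config['seed']}"]

    cohorts, truth = _acquire_cohorts(config, log)

    matrices: dict[str, AbundanceMatrix] = {}
    for name, (quant, meta) in cohorts.items():
        normalized, report = _normalize_cohort(
            quant, config["normalization"], log, name)
        dump_json(report.to_dict(), out / f"normalization_{name}.json")
        matrix = quantify.summarize_protein_abundance(normalized)
        matrices[name] = matrix
        log.append(f"[{name}] summarized {len(matrix.protein_ids)} proteins "
                   f"x {len(matrix.subject_ids)} subjects")

    if "validation" in matrices:
        matrices["validation"] = normalization.equalize_cohort_medians(
            matrices["training"], matrices["validation"])
        log.append("validation medians equalized to training")

    disc = config["discovery"]
    train = discovery.filter_missing_proteins(
        matrices["training"], max_frac=disc["max_missing_frac"])
    log.append(f"missingness filter kept {len(train.protein_ids)} proteins")
    train = discovery.impute_lod(train)
    matrices["training"] = train
    if "validation" in matrices:
        shared = [p for p in train.protein_ids
                  if p in matrices["validation"].protein_ids]
        val = matrices["validation"].select_proteins(shared)
        matrices["validation"] = discovery.impute_lod(val)

    for name, matrix in matrices.items():
        io.write_matrix(matrix, out / f"abundance_{name}.tsv")

    meta_t = cohorts["training"][1]
    labels = meta_t.set_index("subject_id")["group"]
    diff = quantify.differential_abundance(
        train, labels, preset=config["differential"]["preset"])
    diff.to_csv(out / "differential_training.tsv", sep="\t", index=False,
                float_format="%.10g")
    log.append(f"differential abundance: {int(diff['significant'].sum())} "
               "significant proteins (training)")

    cv_report, model = discovery.consensus_cv(
        train, labels, k=disc["k"], min_count=disc["min_count"],
        filter_params={"alpha": disc["alpha"], "fc_cutoff": disc["fc_cutoff"],
                       "use_adjusted_p": disc["use_adjusted_p"]},
        seed=config["seed"],
    )
    (out / "signature.json").write_text(model.to_json() + "\n")
    dump_json(cv_report.to_dict(), out / "cv_report.json")
    log.append(f"consensus signature: {cv_report.consensus or 'EMPTY'}; "
               f"threshold={model.threshold:.6g}")

    eval_cfg = config["evaluation"]
    eval_name = "validation" if "validation" in matrices else "training"
    eval_matrix = matrices[eval_name]
    eval_meta = cohorts[eval_name][1]
    report = _evaluate(model, eval_matrix, eval_meta, eval_cfg, config["seed"])
    report["cohort"] = eval_name
    dump_json(report, out / "evaluation.json")
    log.append(f"evaluation on {eval_name}: AUC={report['auc']:.4f}, "
               f"accuracy={report['accuracy']:.4f}")

    if truth is not None:
        dump_json({
            "marker_ids": truth.marker_ids,
            "true_log2fc": truth.true_log2fc,
            "size_responsive_ids": truth.size_responsive_ids,
        }, out / "ground_truth.json")

    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return {"model": model, "cv_report": cv_report, "matrices": matrices,
            "differential": diff, "evaluation": report}


def _evaluate(model, matrix, metadata, eval_cfg, seed) -> dict:
    labels = metadata.set_index("subject_id")["group"].reindex(
        matrix.values.index)
    y = (labels == "CRC").to_numpy(dtype=float)
    scores = discovery.predict_probability(model, matrix)
    s = scores.to_numpy()
    report: dict = {"threshold": model.threshold, "n": int(len(y)),
                    "n_case": int(y.sum()), "n_control": int((1 - y).sum())}
    B = int(eval_cfg.get("B", 200))
    if len(np.unique(s)) > 1:
        auc, lo, hi = evaluation.bootstrap_auc_ci(s, y, B=max(B, 1), seed=seed)
    else:
        auc, lo, hi = 0.5, float("nan"), float("nan")
    report.update(auc=auc, ci_low=lo, ci_high=hi, n_bootstrap=B)
    report.update(evaluation.confusion_metrics(s, y, model.threshold))

    strata = eval_cfg.get("strata") or []
    if strata:
        strat = evaluation.stratified_evaluate(
            model, matrix, metadata, strata_spec=list(strata),
            threshold=model.threshold)
        report["stratified"] = strat.to_dict()

    # CEA comparison where CEA values are available
    meta = metadata.set_index("subject_id").reindex(matrix.values.index)
    cea = meta["cea_ng_ml"]
    has_cea = cea.notna().to_numpy()
    if has_cea.sum() >= 4 and len(np.unique(y[has_cea])) == 2:
        cea_pred, n_excluded = evaluation.cea_classify(cea)
        cea_y = y[has_cea]
        cea_scores = cea[has_cea].to_numpy()
        sig_scores = s[has_cea]
        cm = {
            "accuracy": float(np.mean(
                (cea_pred.reindex(meta.index[has_cea]).to_numpy() == cea_y))),
            "n_excluded": n_excluded,
        }
        delta, p = evaluation.compare_auc_bootstrap(
            sig_scores, cea_scores, cea_y, B=max(B, 1), seed=seed)
        cm["auc_cea"] = evaluation.roc_auc(cea_scores, cea_y)
        cm["auc_signature"] = evaluation.roc_auc(sig_scores, cea_y)
        cm["delta_auc"] = delta
        cm["p_value"] = p
        report["cea_comparison"] = cm
    return report
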