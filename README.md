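# srmsig

A tested, reusable re-implementation of a plasma SRM (selected reaction
monitoring) biomarker-signature analysis pipeline:

1. **Synthetic cohorts** (`srmsig.synthetic`) — a seeded generator emulating
   targeted-MS cohort data: light/heavy channel peptide intensities, spiked
   standard proteins, batch and run drift, planted case/control effects,
   tumor-size-dependent markers, LOD censoring, and the ground truth needed
   to score every downstream stage.
2. **I/O** (`srmsig.io`) — long-format TSV/CSV quant tables (native,
   MultiQuant-like and Skyline-like column maps), subject metadata, and
   abundance matrices. Intensities are stored internally on the log2 scale.
3. **Normalization** (`srmsig.normalization`) — two-stage plasma
   normalization: per-protein heavy-reference median equalization, then a
   run shift from a spiked standard protein screened for stability (Pearson
   r > 0.6 against the per-run sample medians). Also cross-cohort median
   equalization and the tissue-phase sparse-feature filter (> 5/6 missing
   or an entire group missing) with MAD scale normalization.
4. **Protein quantification** (`srmsig.quantify`) — additive fixed-effects
   summarization to one log2 abundance per subject and protein; pooled
   two-sample t-tests with Benjamini–Hochberg adjustment; Delta-method
   original-scale fold changes; plasma (adj p < 0.05, FC outside
   [1/1.1, 1.1]) and tissue (adj p < 0.05, |log2FC| >= 1.5) significance
   presets.
5. **Signature discovery** (`srmsig.discovery`) — LOD imputation (per-cohort
   observed minimum), a strict > 40 % missingness filter, logistic
   regression by IRLS with separation detection, bidirectional stepwise-AIC
   selection inside stratified k-fold consensus cross-validation
   (default k = 10, consensus at >= 5 folds), accuracy-optimal threshold
   selection, and an exhaustive bootstrapped subset search ranked by median
   out-of-bag AUC.
6. **Evaluation** (`srmsig.evaluation`) — rank-based ROC/AUC, stratified
   bootstrap CIs (B = 2,000 default), paired bootstrap curve comparison,
   confusion metrics at a fixed threshold, stage/tumor-size/CEA-stratified
   evaluation against the shared control group, the CEA > 5 ng/ml rule,
   decile response curves, probability surfaces, pooled t-tests and Ward
   clustering.

## CLI

All stages chain through the `srmsig` entry point:

```bash
# generate a synthetic cohort (quant + metadata TSV, ground-truth JSON)
srmsig simulate --seed 7 --out-dir cohort/

# two-stage normalization with a stability-screened standard protein
srmsig normalize --quant cohort/quant_training.tsv \
    --out normed.tsv --report norm_report.json

# protein-level summarization
srmsig quantify --quant normed.tsv --out matrix.tsv

# consensus cross-validated signature discovery
srmsig discover --matrix matrix.tsv --metadata cohort/metadata_training.tsv \
    --k 10 --min-count 5 --seed 7 --out signature.json --report cv.json

# ROC evaluation with bootstrap inference and subgroup strata
srmsig evaluate --matrix matrix.tsv --metadata cohort/metadata_training.tsv \
    --signature signature.json -B 2000 --seed 7 --out eval.json

# exhaustive bootstrapped subset search
srmsig search --matrix matrix.tsv --metadata cohort/metadata_training.tsv \
    --max-size 5 -B 100 --seed 7 --out models.tsv

# everything at once from a config file
srmsig run-all --config config.yaml --out-dir bundle/
```

A minimal `config.yaml` for `run-all`:

```yaml
seed: 7
simulation:
  n_crc: 100
  n_benign: 34
  n_healthy: 66
  n_proteins: 70
  validation: {n_crc: 202, n_benign: 17, n_healthy: 50}
discovery: {k: 10, min_count: 5}
evaluation: {B: 2000, strata: [stage, size, cea]}
```

Instead of a `simulation` block, an `inputs` block can point at measured
tables:

```yaml
inputs:
  training: {quant: train_quant.tsv, metadata: train_meta.tsv, dialect: native}
  validation: {quant: val_quant.tsv, metadata: val_meta.tsv}
```

## File schemas

* **Quant table** (TSV/CSV, one transition-group measurement per row):
  `run_id, cohort_id, subject_id, protein_id, peptide_id,
  channel{light,heavy}, is_standard, batch_id, log2_intensity`.
  Empty intensity cells (or absent rows) mean missing. Vendor-style exports
  are supported through the `multiquant`/`skyline` column maps, which carry
  raw-scale peak areas (log2-transformed at parse time).
* **Metadata table**: `subject_id, cohort, group{CRC,benign,healthy},
  stage{I..IV, empty}, tumor_diameter_cm, cea_ng_ml, age_years, run_id`.
  Stage must be empty for non-CRC subjects.
* **Abundance matrix**: TSV, subjects x proteins, `cohort` column first,
  empty cells mean missing.
* **Signature / CV report / evaluation**: versioned JSON written by the
  pipeline (`signature.json`, `cv_report.json`, `evaluation.json`).

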