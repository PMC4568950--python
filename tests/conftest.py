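import numpy as np
import pandas as pd
import pytest

from srmsig import discovery, normalization as nz, quantify
from srmsig.synthetic import SimulationConfig, generate_cohort
from srmsig.types import QUANT_COLUMNS


def mk_quant(rows):
    """Build a quant frame from (run, subject, protein, peptide, channel,
    is_standard, batch, intensity) tuples; missing fields get defaults."""
    records = []
    for row in rows:
        run, subject, protein, peptide, channel, is_std, batch, y = row
        records.append({
            "run_id": run,
            "cohort_id": "training",
            "subject_id": subject,
            "protein_id": protein,
            "peptide_id": peptide,
            "channel": channel,
            "is_standard": is_std,
            "batch_id": batch,
            "log2_intensity": y,
        })
    return pd.DataFrame(records)[QUANT_COLUMNS]


def prepare_matrix(quant):
    """Normalization + summarization as the pipeline chains them."""
    qn, _ = nz.normalize_by_reference(quant)
    chosen, _, _ = nz.choose_standard(qn)
    if chosen is not None:
        qn, _ = nz.normalize_by_standard(qn, chosen, check_stability=False)
    return quantify.summarize_protein_abundance(qn)


def discover_signature(quant, meta, seed):
    matrix = prepare_matrix(quant)
    labels = meta.set_index("subject_id")["group"]
    matrix = discovery.impute_lod(discovery.filter_missing_proteins(matrix))
    return discovery.consensus_cv(matrix, labels, seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(
        n_crc=40, n_benign=10, n_healthy=30, n_proteins=25, seed=11
    )
    quant, meta, truth = generate_cohort(cfg)
    return cfg, quant, meta, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, quant, meta, _ = small_cohort
    matrix = prepare_matrix(quant)
    labels = meta.set_index("subject_id")["group"]
    return matrix, labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
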