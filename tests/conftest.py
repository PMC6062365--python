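"""Shared fixtures: a small fast cohort for unit tests and the benchmark-
shaped default cohort (built once per session) for integration checks."""

from __future__ import annotations

import pytest

from toxtriad.featurization import assemble_table, qhts_block
from toxtriad.synthetic_data import SyntheticConfig, generate_cohort
from toxtriad.target_scorer import records_from_table, score_matrix, train_target_model

#: small cohort: same latent structure, ~20x cheaper than the default
SMALL_CONFIG = SyntheticConfig(
    n_compounds=160,
    n_toxic=40,
    n_chem_descriptors=24,
    n_fingerprint_bits=256,
    n_targets=36,
    n_cell_lines=4,
    n_concentrations=7,
    n_bioactivity_compounds=200,
    seed=7,
)


def build_features(cohort, min_records=50):
    """Cohort -> (DescriptorTable, labels, exclusion report)."""
    records = records_from_table(cohort.bioactivity_table, cohort.bioactivity_fingerprints)
    model = train_target_model(records, min_records=min_records)
    scores = score_matrix(model, dict(zip(cohort.compound_ids, cohort.fingerprints)))
    cyto = qhts_block(cohort.qhts_raw)
    return assemble_table(cohort.chem_descriptors, scores, cyto, cohort.pld50)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return build_features(small_cohort)


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return build_features(default_cohort)
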