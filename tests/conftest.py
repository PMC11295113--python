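import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from codesel.hierarchy import build_icd_hierarchy
from codesel.records import aggregate_records, encode_one_hot
from codesel.synthgen import (
    SynthConfig,
    generate_hierarchy,
    generate_outcome,
    generate_records,
)

# Miniature ICD-like table: chapter -> block -> category -> expansion.
ICD_ROWS = [
    ("Chapter IX", None, "Diseases of the circulatory system"),
    ("I20-I25", "Chapter IX", "Ischaemic heart diseases"),
    ("I20", "I20-I25", "Angina pectoris"),
    ("I25", "I20-I25", "Chronic ischaemic heart disease"),
    ("I251", "I25", "Atherosclerotic heart disease"),
    ("I259", "I25", "Chronic ischaemic heart disease, unspecified"),
    ("Chapter X", None, "Diseases of the respiratory system"),
    ("J40-J47", "Chapter X", "Chronic lower respiratory diseases"),
    ("J44", "J40-J47", "Other COPD"),
]


@pytest.fixture(scope="session")
def icd_hierarchy():
    return build_icd_hierarchy(ICD_ROWS)


@pytest.fixture(scope="session")
def small_cohort():
    """A small encoded synthetic cohort with outcome, shared across tests."""
    cfg = SynthConfig(n_patients=120, seed=7)
    hierarchy = generate_hierarchy(cfg.hierarchy_shape, 7)
    raw, truth = generate_records(cfg, hierarchy)
    matrix = encode_one_hot(aggregate_records(raw, cfg.window_days), hierarchy)
    outcome = generate_outcome(matrix, truth, cfg, seed=8)
    return matrix.with_outcome(outcome), hierarchy, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rows):
    """Helper: long-format records frame from (pid, date, code) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "date", "code"]).assign(system="SYNTH")
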