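"""Shared loading step for the analysis drivers: read the simulated cohort
written by 01_simulate_cohort.py and run it through filtering, log2 and
down-shift imputation."""

import os

from endoprot.io_tables import read_protein_groups, read_sample_annotation
from endoprot.preprocess import (
    ImputationParams,
    filter_protein_groups,
    impute_downshift,
    to_log2,
)

HERE = os.path.dirname(__file__)
DATA = os.path.join(HERE, "..", "results", "data")
SEED = 1


def load_matrix():
    table = read_protein_groups(os.path.join(DATA, "protein_groups.tsv"))
    annotations = read_sample_annotation(
        os.path.join(DATA, "sample_annotation.tsv")
    )
    filtered = filter_protein_groups(table)
    matrix = impute_downshift(to_log2(filtered), ImputationParams(seed=SEED))
    return filtered, matrix, annotations
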