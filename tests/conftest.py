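import numpy as np
import pandas as pd
import pytest

from endoprot.io_tables import ProteinGroupTable, SampleAnnotation
from endoprot.preprocess import (
    ExpressionMatrix,
    ImputationParams,
    filter_protein_groups,
    impute_downshift,
    to_log2,
)
from endoprot.simulate import SimulationConfig, generate_dataset


def make_matrix(values, samples=None, proteins=None, genes=None,
                observed=None) -> ExpressionMatrix:
    """Small ExpressionMatrix from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=proteins, columns=samples)
    obs = pd.DataFrame(
        observed if observed is not None else ~np.isnan(values),
        index=proteins, columns=samples,
    )
    gene_names = pd.Series(genes or proteins, index=proteins)
    return ExpressionMatrix(values=vals, observed=obs, gene_names=gene_names)


def make_table(intensities, samples=None, unique_peptides=None,
               reverse=None, contaminant=None, genes=None) -> ProteinGroupTable:
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    samples = samples or [f"S{j}" for j in range(intensities.shape[1])]
    proteins = [f"P{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "protein_ids": proteins,
            "gene_name": genes or [f"G{i}" for i in range(n)],
            "unique_peptides": unique_peptides if unique_peptides is not None
            else [5] * n,
            "is_reverse": reverse if reverse is not None else [False] * n,
            "is_contaminant": contaminant if contaminant is not None
            else [False] * n,
        },
        index=proteins,
    )
    lfq = pd.DataFrame(intensities, index=proteins, columns=samples)
    return ProteinGroupTable(meta=meta, lfq=lfq)


@pytest.fixture(scope="session")
def cohort_dataset():
    """One paper-shaped synthetic cohort (4 cohorts, 6/7/3/5 samples)."""
    cfg = SimulationConfig(n_proteins=600, n_housekeeping=30, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def cohort_imputed(cohort_dataset):
    table, annotations, truth = cohort_dataset
    filtered = filter_protein_groups(table)
    matrix = impute_downshift(to_log2(filtered), ImputationParams(seed=11))
    return matrix, annotations, truth


@pytest.fixture
def annotations_21():
    sizes = {"CC": 6, "EC": 7, "EMT": 3, "END": 5}
    return [
        SampleAnnotation(f"{c}_{i + 1}", c)
        for c, n in sizes.items()
        for i in range(n)
    ]
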