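"""Synthetic LFQ cohort generator.

Emulates the statistical structure of a label-free tissue proteomics study of
endometriosis-associated ovarian carcinomas: 21 samples in four unbalanced
cohorts (clear cell carcinoma CC, endometrioid carcinoma EC, endometriosis
EMT, benign endometrium END), thousands of protein groups with log-normal
intensities, subsets of proteins following progressive disease patterns, a
housekeeping set with identical means everywhere, and intensity-dependent
(missing-not-at-random) dropout emitted as zero intensities — the MaxQuant
convention the real pipeline input uses.

Progressive patterns, relative to the benign-endometrium baseline ``b`` and
effect size ``e`` (log2 units):

* ``A`` — END ``b``, EMT ``b+e``, cancer ``b+2e`` (monotone increase);
* ``B`` — END ``b``, EMT ``b+e``, cancer ``b+e`` (plateau after EMT);
* ``C`` — END ``b``, EMT ``b``, cancer ``b+e`` (cancer-only shift);
* ``housekeeping`` / ``none`` — equal means in all cohorts.

Dropout acts on the realized (noisy) log2 value, mirroring a detection limit:
``P(missing | x) = logistic(mnar_alpha - mnar_beta * x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from .errors import ValidationError
from .io_tables import ProteinGroupTable, SampleAnnotation

CANCER_COHORTS = ("CC", "EC")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the tissue study the pipeline analyzes: 21 samples in
    cohorts 6/7/3/5, log2 intensities around 25 +- 2, a 2 log2-unit disease
    effect, 2% of proteins per progressive pattern, and dropout tuned so a
    protein one SD below the baseline mean is missing about 25% of the time.
    """

    n_proteins: int = 5000
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"CC": 6, "EC": 7, "EMT": 3, "END": 5}
    )
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    effect_size: float = 2.0
    pattern_fractions: tuple[float, float, float] = (0.02, 0.02, 0.02)
    n_housekeeping: int = 50
    mnar_alpha: float = 21.9
    mnar_beta: float = 1.0
    noise_sd: float = 0.7
    single_peptide_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.pattern_fractions) > 1:
            raise ValidationError("pattern fractions must sum to <= 1")
        if any(f < 0 for f in self.pattern_fractions):
            raise ValidationError("pattern fractions must be >= 0")
        if self.n_proteins < 0 or self.n_housekeeping < 0:
            raise ValidationError("counts must be >= 0")
        if any(n < 0 for n in self.cohort_sizes.values()):
            raise ValidationError("cohort sizes must be >= 0")
        if not self.noise_sd > 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    pattern: pd.Series  # per protein: A/B/C/none/housekeeping
    true_means: pd.DataFrame  # proteins x cohorts, log2
    missing_prob: pd.DataFrame  # proteins x samples

    @property
    def marker_ids(self) -> pd.Index:
        """Proteins carrying any progressive pattern (the true marker set)."""
        return self.pattern.index[self.pattern.isin(["A", "B", "C"])]


def missingness_probability(x, config: SimulationConfig):
    """Dropout probability for a realized log2 intensity ``x``.

    ``logistic(mnar_alpha - mnar_beta * x)``: monotone non-increasing in
    ``x`` for non-negative ``mnar_beta``.
    """
    return expit(config.mnar_alpha - config.mnar_beta * np.asarray(x, float))


def _assign_patterns(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_proteins
    fA, fB, fC = config.pattern_fractions
    counts = {
        "A": int(round(fA * n)),
        "B": int(round(fB * n)),
        "C": int(round(fC * n)),
        "housekeeping": min(config.n_housekeeping, n),
    }
    if sum(counts.values()) > n:
        raise ValidationError("pattern counts plus housekeeping exceed n_proteins")
    labels = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for label, k in counts.items():
        labels[order[pos:pos + k]] = label
        pos += k
    return labels


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ProteinGroupTable, list[SampleAnnotation], SyntheticTruth]:
    """Draw one synthetic cohort; fully reproducible from ``config.seed``."""
    rng = substream(config.seed, "simulate")
    n = config.n_proteins
    cohorts = list(config.cohort_sizes)

    pattern = _assign_patterns(config, rng)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    e = config.effect_size
    shift = {"A": {"EMT": e, "cancer": 2 * e},
             "B": {"EMT": e, "cancer": e},
             "C": {"EMT": 0.0, "cancer": e}}
    true_means = pd.DataFrame(
        {c: baseline.copy() for c in cohorts},
        index=[f"P{i:05d}" for i in range(n)],
    )
    for pat, shifts in shift.items():
        rows = pattern == pat
        for c in cohorts:
            if c == "EMT":
                true_means.loc[rows, c] += shifts["EMT"]
            elif c in CANCER_COHORTS:
                true_means.loc[rows, c] += shifts["cancer"]

    samples: list[str] = []
    annotations: list[SampleAnnotation] = []
    sample_cohort: list[str] = []
    for c in cohorts:
        for i in range(config.cohort_sizes[c]):
            name = f"{c}_{i + 1}"
            samples.append(name)
            sample_cohort.append(c)
            annotations.append(SampleAnnotation(name, c))

    mean_mat = true_means[sample_cohort].to_numpy()
    x = mean_mat + rng.normal(0.0, config.noise_sd, size=mean_mat.shape)
    p_miss = missingness_probability(x, config)
    missing = rng.random(x.shape) < p_miss
    intensities = np.where(missing, 0.0, np.exp2(x))

    unique_peptides = 2 + rng.poisson(8, size=n)
    single = rng.random(n) < config.single_peptide_fraction
    unique_peptides[single] = 1

    index = true_means.index
    meta = pd.DataFrame(
        {
            "protein_ids": index,
            "gene_name": [f"GENE{i:05d}" for i in range(n)],
            "unique_peptides": unique_peptides,
            "is_reverse": False,
            "is_contaminant": False,
        },
        index=index,
    )
    lfq = pd.DataFrame(intensities, index=index, columns=samples)
    truth = SyntheticTruth(
        pattern=pd.Series(pattern, index=index, name="pattern"),
        true_means=true_means,
        missing_prob=pd.DataFrame(p_miss, index=index, columns=samples),
    )
    return ProteinGroupTable(meta=meta, lfq=lfq), annotations, truth
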