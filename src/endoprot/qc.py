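"""Quality control: inter-patient correlation, outlier flags, housekeeping.

The study's QC logic: protein expression profiles of patients with the same
diagnosis should correlate strongly (Pearson r above roughly 0.8 within a
cohort); a sample whose best within-cohort correlation falls clearly below
that floor is flagged as a potential misdiagnosis/outlier (the analysis this
reproduces excluded one endometrioid sample with r <= 0.72 on this basis).
Housekeeping proteins should be flat across all samples.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_tables import SampleAnnotation, cohort_of
from .preprocess import ExpressionMatrix


def correlation_matrix(
    m: ExpressionMatrix, use: str = "imputed_complete"
) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    ``use='imputed_complete'`` correlates the full (post-imputation) columns;
    ``use='observed_pairwise'`` restricts each pair to cells observed in both
    samples (>=3 shared proteins required per pair).
    """
    if len(m.samples) < 2:
        raise ValidationError("need >=2 samples for a correlation matrix")
    if use == "imputed_complete":
        if not m.is_complete:
            raise ValidationError(
                "matrix has missing cells; impute first or use observed_pairwise"
            )
        corr = m.values.corr(method="pearson")
    elif use == "observed_pairwise":
        samples = m.samples
        corr = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
        obs = m.observed
        for a, b in combinations(samples, 2):
            both = obs[a] & obs[b]
            if int(both.sum()) < 3:
                raise ValidationError(
                    f"samples {a!r} and {b!r} share only {int(both.sum())} "
                    f"observed proteins (need >=3)"
                )
            r = np.corrcoef(m.values.loc[both, a], m.values.loc[both, b])[0, 1]
            corr.loc[a, b] = corr.loc[b, a] = r
    else:
        raise ValidationError(f"unknown mode {use!r}")
    return corr


def flag_outliers(
    corr: pd.DataFrame,
    annotations: Sequence[SampleAnnotation],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Flag samples whose best within-cohort correlation is below threshold.

    Singleton cohorts are never flagged (no within-cohort partner exists).
    The comparison is strict: a maximum exactly at the threshold passes.
    """
    cohorts = cohort_of(annotations)
    missing = [s for s in corr.index if s not in cohorts]
    if missing:
        raise ValidationError(f"samples without annotation: {missing}")
    rows = []
    for s in corr.index:
        peers = [t for t in corr.index if t != s and cohorts[t] == cohorts[s]]
        if not peers:
            continue
        best = corr.loc[s, peers].max()
        if best < threshold:
            rows.append(
                {
                    "sample": s,
                    "cohort": cohorts[s],
                    "max_within_cohort_r": best,
                    "reason": f"max within-cohort Pearson r {best:.3f} < "
                              f"{threshold}",
                }
            )
    return pd.DataFrame(rows, columns=["sample", "cohort",
                                       "max_within_cohort_r", "reason"])


def housekeeping_report(
    m: ExpressionMatrix, housekeeping_ids: Sequence[str]
) -> pd.DataFrame:
    """Stability of designated housekeeping proteins across all samples.

    Reports the coefficient of variation on the linear intensity scale and
    the SD of the log2 values (sample SD) per protein.
    """
    unknown = [p for p in housekeeping_ids if p not in m.values.index]
    if unknown:
        raise ValidationError(f"unknown housekeeping ids: {unknown}")
    sub = m.values.loc[list(housekeeping_ids)]
    linear = np.exp2(sub)
    cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
    return pd.DataFrame(
        {
            "cv_linear": cv,
            "sd_log2": sub.std(axis=1, ddof=1),
            "range_log2": sub.max(axis=1) - sub.min(axis=1),
        }
    )
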