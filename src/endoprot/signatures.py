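"""Cross-referencing the proteome against external gene signatures.

Covers four readouts: extraction of marker sub-matrices with
observed-vs-imputed detection flags (the IHC-style "expressed in 4/6
samples" convention), direction concordance of transcriptomic signatures
with protein-level fold changes, signature-based cohort discrimination via
2-cut hierarchical clustering, and hypergeometric over-representation
against user-supplied gene sets (GMT).

Gene-to-protein mapping is case-insensitive exact symbol matching; when
several protein groups share a symbol the one with the highest mean
abundance wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import (
    ModeratedVariancePrior,
    VolcanoParams,
    moderated_t,
    s0_significance,
)
from .errors import ValidationError
from .io_tables import SampleAnnotation, SignatureSet, cohort_of
from .multivariate import cut_clusters, hierarchical_cluster, label_agreement
from .preprocess import ExpressionMatrix, zscore_rows


@dataclass
class MarkerMatrix:
    values: pd.DataFrame  # requested symbols x samples (mapped rows only)
    detected: pd.DataFrame  # observed (non-imputed) per cell
    unmapped: list[str]


def _symbol_index(m: ExpressionMatrix) -> dict[str, str]:
    """Uppercased symbol -> protein row id; multi-mapping resolved to the
    protein group with the highest mean abundance."""
    means = m.values.mean(axis=1)
    mapping: dict[str, str] = {}
    for pid, sym in m.gene_names.items():
        if not sym:
            continue
        key = sym.upper()
        if key not in mapping or means[pid] > means[mapping[key]]:
            mapping[key] = pid
    return mapping


def extract_marker_matrix(
    m: ExpressionMatrix, markers: Sequence[str]
) -> MarkerMatrix:
    """Sub-matrix for the requested gene symbols with detection flags.

    Detection means observed before imputation.  Unmapped symbols are
    reported, not fatal.
    """
    mapping = _symbol_index(m)
    rows, labels, unmapped = [], [], []
    for sym in markers:
        pid = mapping.get(sym.upper())
        if pid is None:
            unmapped.append(sym)
        else:
            rows.append(pid)
            labels.append(sym)
    values = m.values.loc[rows].copy()
    detected = m.observed.loc[rows].copy()
    values.index = detected.index = pd.Index(labels, name="symbol")
    return MarkerMatrix(values=values, detected=detected, unmapped=unmapped)


def concordance(
    sig: SignatureSet,
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    cancer: str,
    comparator: str = "EMT",
    volcano: VolcanoParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Direction concordance of a transcriptomic signature with the proteome.

    Each signature gene is mapped to a protein group; the protein-level
    direction is the sign of the cancer-vs-comparator log2 fold change, and
    a gene is concordant when that sign matches its expected direction.
    Significance comes from the S0 volcano rule over all proteins.
    Returns the per-gene table and summary counts.
    """
    volcano = volcano or VolcanoParams()
    # plain (unshrunk) two-sample components: the S0 rule consumes the
    # ordinary fold change and standard error
    diff = moderated_t(
        m, annotations, (cancer, comparator),
        prior=ModeratedVariancePrior(d0=0.0, s0_sq=1.0),
    )
    # plain (unmoderated) SE components feed the S0 rule
    s0_table, _curve = s0_significance(
        diff["log2fc"].to_numpy(),
        np.sqrt(diff["s2_pooled"]).to_numpy()
        * np.sqrt(1.0 / _group_size(annotations, m, cancer)
                  + 1.0 / _group_size(annotations, m, comparator)),
        df=_group_size(annotations, m, cancer)
        + _group_size(annotations, m, comparator) - 2,
        params=volcano,
    )
    s0_table.index = diff.index
    mapping = _symbol_index(m)
    rows = []
    for sym, expected in sig.genes:
        pid = mapping.get(sym.upper())
        if pid is None:
            rows.append({"gene": sym, "expected": expected, "protein": "",
                         "log2fc": np.nan, "observed_direction": "",
                         "concordant": False, "significant": False})
            continue
        delta = diff.loc[pid, "log2fc"]
        obs_dir = "up" if delta > 0 else ("down" if delta < 0 else "flat")
        rows.append(
            {
                "gene": sym,
                "expected": expected,
                "protein": pid,
                "log2fc": delta,
                "observed_direction": obs_dir,
                "concordant": obs_dir == expected,
                "significant": bool(s0_table.loc[pid, "significant"]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "expected", "protein", "log2fc",
                 "observed_direction", "concordant", "significant"],
    )
    up = table[table["expected"] == "up"]
    down = table[table["expected"] == "down"]
    summary = {
        "concordant_up": int(up["concordant"].sum()),
        "total_up": len(up),
        "concordant_down": int(down["concordant"].sum()),
        "total_down": len(down),
        "significant_and_concordant": int(
            (table["concordant"] & table["significant"]).sum()
        ),
        "unmapped": int((table["protein"] == "").sum()),
    }
    return table, summary


def _group_size(annotations, m, cohort) -> int:
    names = {a.sample for a in annotations if a.cohort == cohort}
    return len([s for s in m.samples if s in names])


def signature_discrimination(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    sig: SignatureSet,
    partitions: Mapping[str, Mapping[str, str]],
) -> dict[str, float]:
    """Can the signature sub-matrix separate the requested cohort labels?

    For each named partition (cohort -> binary label; cohorts absent from
    the mapping are excluded), samples are clustered into 2 groups by
    average-linkage Euclidean clustering of the z-scored signature
    sub-matrix, and the adjusted Rand index against the labelling is
    reported.
    """
    mapping = _symbol_index(m)
    pids = [mapping[s.upper()] for s, _ in sig.genes if s.upper() in mapping]
    pids = list(dict.fromkeys(pids))
    if len(pids) < 2:
        raise ValidationError("signature maps to <2 proteins")
    cohorts = cohort_of(annotations)
    out: dict[str, float] = {}
    for name, label_map in partitions.items():
        keep = [s for s in m.samples if cohorts.get(s) in label_map]
        if len(keep) < 2:
            raise ValidationError(f"partition {name!r} covers <2 samples")
        sub = ExpressionMatrix(
            values=m.values.loc[pids, keep],
            observed=m.observed.loc[pids, keep],
            gene_names=m.gene_names.loc[pids],
        )
        sub = zscore_rows(sub)
        tree = hierarchical_cluster(sub, axis="samples", linkage="average")
        clusters = cut_clusters(tree, 2)
        labels = [label_map[cohorts[s]] for s in keep]
        out[name] = label_agreement(clusters.loc[keep].tolist(), labels)
    return out


def ora_hypergeometric(
    query: Sequence[str],
    gene_sets: Mapping[str, set[str]],
    background: Sequence[str],
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    Hypergeometric upper tail P(X >= overlap) with the background as the
    population, set-intersect-background as successes and the query size as
    the number of draws; BH across sets.
    """
    from .differential import bh_adjust

    background_set = set(background)
    query_set = set(query)
    outside = query_set - background_set
    if outside:
        raise ValidationError(
            f"query symbols outside the background: {sorted(outside)[:10]}"
        )
    M, n = len(background_set), len(query_set)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & background_set)
        k = len(members & query_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k > 0 else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "background_size": M, "query_size": n, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        q, _ = bh_adjust(table["p"].to_numpy())
        table["q"] = q
    else:
        table["q"] = []
    return table
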