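"""Readers and writers for the tabular artifacts the pipeline touches.

The central input dialect is the MaxQuant ``proteinGroups.txt`` table:
tab-separated, one row per protein group, with per-sample quantification in
columns named ``LFQ intensity <sample>``.  Zero intensity means "not
quantified in this sample"; the interpretation (missing value) is deferred to
the preprocessing stage.  Sample annotations map sample names to the four
study cohorts (CC, EC, EMT, END); signatures carry gene symbols with an
expected direction of regulation; gene sets come in as GMT files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

LFQ_PREFIX = "LFQ intensity "
COHORTS = ("CC", "EC", "EMT", "END")

#: Direction synonyms accepted in signature files.
_DIRECTION_SYNONYMS = {
    "up": "up",
    "+": "up",
    "over": "up",
    "overexpressed": "up",
    "increased": "up",
    "down": "down",
    "-": "down",
    "under": "down",
    "underexpressed": "down",
    "decreased": "down",
}


@dataclass
class ProteinGroupTable:
    """Parsed protein-group quantification table.

    ``meta`` holds one row per protein group with columns ``protein_ids``
    (semicolon-joined accessions), ``gene_name`` (first symbol, may be empty),
    ``unique_peptides``, ``is_reverse`` and ``is_contaminant``.  ``lfq`` holds
    the non-negative intensities with one column per sample, in file order.
    """

    meta: pd.DataFrame
    lfq: pd.DataFrame
    filter_report: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.lfq.index):
            raise ValidationError("meta and lfq must share the same row index")
        if self.lfq.columns.duplicated().any():
            dupes = self.lfq.columns[self.lfq.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample names: {dupes}")
        if (self.lfq.to_numpy() < 0).any():
            raise ValidationError("LFQ intensities must be non-negative")
        empty = self.meta["protein_ids"].astype(str).str.strip() == ""
        if empty.any():
            raise ValidationError(
                f"{int(empty.sum())} protein groups have no protein id"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def n_groups(self) -> int:
        return len(self.meta)

    def protein_id_lists(self) -> pd.Series:
        """Accession lists per group (MaxQuant joins members with ';')."""
        return self.meta["protein_ids"].str.split(";")


@dataclass(frozen=True)
class SampleAnnotation:
    sample: str
    cohort: str
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"unknown cohort {self.cohort!r}; allowed: {list(COHORTS)}"
            )


@dataclass
class SignatureSet:
    """A named set of gene symbols with expected regulation direction."""

    name: str
    genes: list[tuple[str, str]]  # (symbol, "up"|"down")

    def __post_init__(self) -> None:
        for sym, direction in self.genes:
            if not sym:
                raise ValidationError("signature gene symbols must be non-empty")
            if direction not in ("up", "down"):
                raise ValidationError(f"invalid direction {direction!r}")

    @property
    def up(self) -> list[str]:
        return [s for s, d in self.genes if d == "up"]

    @property
    def down(self) -> list[str]:
        return [s for s, d in self.genes if d == "down"]


def cohort_of(annotations: Sequence[SampleAnnotation]) -> dict[str, str]:
    """Sample name -> cohort label."""
    return {a.sample: a.cohort for a in annotations}


def cohort_samples(
    annotations: Sequence[SampleAnnotation], cohort: str
) -> list[str]:
    return [a.sample for a in annotations if a.cohort == cohort]


def _first_present(df: pd.DataFrame, names: Iterable[str]) -> str | None:
    for name in names:
        if name in df.columns:
            return name
    return None


def read_protein_groups(path: str | os.PathLike) -> ProteinGroupTable:
    """Parse a proteinGroups-dialect TSV.

    Accepts both the full MaxQuant header set and a minimal dialect; LFQ
    sample columns are recognized solely by the ``LFQ intensity `` prefix.
    ``+`` in the Reverse / Potential contaminant columns maps to True.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_samples = [c[len(LFQ_PREFIX):] for c in header
                   if c.startswith(LFQ_PREFIX)]
    if len(set(raw_samples)) != len(raw_samples):
        raise FormatError(
            f"duplicate sample names in LFQ columns: {raw_samples}"
        )
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lfq_cols = [c for c in raw.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(
            f"no quantification columns found; expected columns with the "
            f"prefix {LFQ_PREFIX!r}"
        )
    samples = [c[len(LFQ_PREFIX):] for c in lfq_cols]

    id_col = _first_present(raw, ["Majority protein IDs", "Protein IDs"])
    if id_col is None:
        raise FormatError(
            "missing protein id column ('Majority protein IDs' or 'Protein IDs')"
        )
    gene_col = _first_present(raw, ["Gene names", "Gene name"])
    pep_col = _first_present(raw, ["Unique peptides", "Peptide counts (unique)"])

    lfq = pd.DataFrame(index=raw.index)
    for col, sample in zip(lfq_cols, samples):
        try:
            lfq[sample] = pd.to_numeric(raw[col].replace("", "0"))
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(raw[col].replace("", "0"), errors="coerce")
            row = int(bad[bad.isna()].index[0])
            raise FormatError(
                f"non-numeric intensity in column {col!r}, row {row}"
            ) from exc

    def flag(colnames: list[str]) -> pd.Series:
        col = _first_present(raw, colnames)
        if col is None:
            return pd.Series(False, index=raw.index)
        return raw[col].str.strip() == "+"

    genes = raw[gene_col] if gene_col else pd.Series("", index=raw.index)
    meta = pd.DataFrame(
        {
            "protein_ids": raw[id_col].str.strip(),
            # MaxQuant concatenates group members' symbols with ';'
            "gene_name": genes.str.split(";").str[0].str.strip(),
            "unique_peptides": (
                pd.to_numeric(raw[pep_col].replace("", "0")).astype(int)
                if pep_col
                else pd.Series(0, index=raw.index)
            ),
            "is_reverse": flag(["Reverse"]),
            "is_contaminant": flag(["Potential contaminant", "Contaminant"]),
        }
    )
    # rows are keyed by the protein-group id string so downstream tables
    # stay aligned across write/read round trips
    if not meta["protein_ids"].duplicated().any():
        key = pd.Index(meta["protein_ids"], name="protein_group")
        meta.index = key
        lfq.index = key
    return ProteinGroupTable(meta=meta, lfq=lfq)


def write_protein_groups(table: ProteinGroupTable, path: str | os.PathLike) -> None:
    """Serialize back to the proteinGroups dialect (minimal header set)."""
    out = pd.DataFrame(
        {
            "Majority protein IDs": table.meta["protein_ids"],
            "Gene names": table.meta["gene_name"],
            "Unique peptides": table.meta["unique_peptides"],
            "Reverse": np.where(table.meta["is_reverse"], "+", ""),
            "Potential contaminant": np.where(table.meta["is_contaminant"], "+", ""),
        }
    )
    for s in table.samples:
        out[LFQ_PREFIX + s] = table.lfq[s]
    out.to_csv(path, sep="\t", index=False)


def read_sample_annotation(path: str | os.PathLike) -> list[SampleAnnotation]:
    """Read a sample -> cohort table (tab- or comma-separated, with header)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns or "cohort" not in df.columns:
        raise FormatError("annotation file needs 'sample' and 'cohort' columns")
    records = []
    for _, row in df.iterrows():
        cohort = row["cohort"].strip()
        if cohort not in COHORTS:
            raise ValidationError(
                f"unknown cohort label {cohort!r} for sample {row['sample']!r}; "
                f"allowed: {list(COHORTS)}"
            )
        batch = row.get("batch", "") or None
        records.append(SampleAnnotation(row["sample"].strip(), cohort, batch))
    return records


def write_sample_annotation(
    annotations: Sequence[SampleAnnotation], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        {
            "sample": [a.sample for a in annotations],
            "cohort": [a.cohort for a in annotations],
            "batch": [a.batch or "" for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)


def read_signature(path: str | os.PathLike, name: str | None = None) -> SignatureSet:
    """Read a two-column (symbol, direction) signature table."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("signature file needs symbol and direction columns")
    sym_col, dir_col = df.columns[:2]
    genes = []
    for _, row in df.iterrows():
        direction = row[dir_col].strip().lower()
        if direction not in _DIRECTION_SYNONYMS:
            raise ValidationError(
                f"direction {row[dir_col]!r} for gene {row[sym_col]!r} not "
                f"recognized; use up/down/+/-"
            )
        genes.append((row[sym_col].strip(), _DIRECTION_SYNONYMS[direction]))
    return SignatureSet(name=name or os.path.basename(os.fspath(path)), genes=genes)


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line {lineno} has fewer than 3 fields"
                )
            name, _desc, *members = parts
            sets[name] = {m for m in members if m}
    return sets


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, str]:
    """Write named result tables as TSV files with stable column order.

    Floats are serialized with 10 significant digits so tables round-trip
    through ``pd.read_csv`` within that precision.  Returns name -> path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(os.fspath(out_dir), f"{name}.tsv")
        df.to_csv(path, sep="\t", index=True, float_format="%.10g")
        paths[name] = path
    return paths
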