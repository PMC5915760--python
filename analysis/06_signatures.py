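"""Signature concordance, cohort discrimination and over-representation.

Builds a transcriptomic-style signature from the simulation's cancer-shift
proteins, measures its direction concordance with the protein-level CC vs
EMT fold changes (S0 volcano significance), asks whether it separates
cancer from control and EMT from END (the study found the former but not
the latter for genomic signatures), and runs hypergeometric
over-representation of the called CC markers against pattern-defined gene
sets.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _common import DATA, load_matrix  # noqa: E402

from endoprot.io_tables import SignatureSet, write_results  # noqa: E402
from endoprot.signatures import (  # noqa: E402
    concordance,
    ora_hypergeometric,
    signature_discrimination,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "signatures")


def main() -> None:
    _, matrix, annotations = load_matrix()
    truth = pd.read_csv(os.path.join(DATA, "truth.tsv"), sep="\t",
                        index_col=0)
    pattern = truth["pattern"].reindex(matrix.values.index)

    cancer_genes = sorted(matrix.gene_names[pattern == "C"])
    sig = SignatureSet("cancer_shift", [(g, "up") for g in cancer_genes])
    table, summary = concordance(sig, matrix, annotations, "CC", "EMT")
    print(f"concordance (CC vs EMT): {summary['concordant_up']}/"
          f"{summary['total_up']} up-genes upregulated, "
          f"{summary['significant_and_concordant']} significant (S0=1, "
          f"FDR 0.05)")

    aris = signature_discrimination(
        matrix, annotations, sig,
        {
            "cancer_vs_control": {"CC": "cancer", "EC": "cancer",
                                  "EMT": "control", "END": "control"},
            "emt_vs_end": {"EMT": "emt", "END": "end"},
        },
    )
    print(f"signature discrimination ARI: "
          f"cancer vs control {aris['cancer_vs_control']:.2f}, "
          f"EMT vs END {aris['emt_vs_end']:.2f}")

    # ORA of called CC markers against pattern-defined gene sets
    markers_path = os.path.join(os.path.dirname(__file__), "..", "results",
                                "markers", "markers_CC.tsv")
    background = sorted(g for g in matrix.gene_names if g)
    gene_sets = {
        f"pattern_{p}": set(matrix.gene_names[pattern == p])
        for p in ("A", "B", "C", "housekeeping")
    }
    if os.path.exists(markers_path):
        calls = pd.read_csv(markers_path, sep="\t", index_col=0)
        query = sorted(
            set(calls.loc[calls["is_marker"].astype(bool), "gene_name"])
            & set(background)
        )
        ora = ora_hypergeometric(query, gene_sets, background)
        print("over-representation of called CC markers:")
        print(ora.sort_values("p").to_string(index=False))
    else:
        ora = pd.DataFrame()
        print("run 05_disease_markers.py first for the ORA step")

    write_results(
        {"concordance": table,
         "discrimination": pd.DataFrame([aris]),
         "ora_cc_markers": ora},
        OUT,
    )
    print(f"written to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
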