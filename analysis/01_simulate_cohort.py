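"""Generate the synthetic tissue cohort the downstream analyses consume.

Emulates the study design: 21 samples (6 CC / 7 EC / 3 EMT / 5 END),
~5000 protein groups, 2 log2-unit progressive disease effects on 2% of
proteins per pattern, housekeeping proteins, and intensity-dependent
dropout written as zero LFQ intensities.  Writes the protein-group table,
sample annotation and ground truth under results/data/.
"""

import os

import pandas as pd

from endoprot.io_tables import write_protein_groups, write_sample_annotation
from endoprot.simulate import SimulationConfig, generate_dataset

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")
SEED = 1


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    config = SimulationConfig(n_proteins=5000, seed=SEED)
    table, annotations, truth = generate_dataset(config)

    write_protein_groups(table, os.path.join(OUT, "protein_groups.tsv"))
    write_sample_annotation(
        annotations, os.path.join(OUT, "sample_annotation.tsv")
    )
    truth_table = pd.DataFrame({"pattern": truth.pattern}).join(
        truth.true_means.add_prefix("true_mean_")
    )
    truth_table.to_csv(os.path.join(OUT, "truth.tsv"), sep="\t")

    missing = float((table.lfq.to_numpy() == 0).mean())
    print(f"cohort: {len(annotations)} samples, {table.n_groups} protein groups")
    print(f"missing (zero-intensity) cells: {missing:.1%}")
    print(truth.pattern.value_counts().to_string())
    print(f"written to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
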