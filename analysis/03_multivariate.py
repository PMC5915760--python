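"""Unsupervised structure: PCA and hierarchical clustering of the cohort.

Checks that cohorts separate in principal-component space and that
2-group sample clustering recovers the cancer-vs-control split, mirroring
the study's observation that tumours segregate from their benign
precursors on overall protein expression.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(__file__))
from _common import load_matrix  # noqa: E402

from endoprot.io_tables import write_results  # noqa: E402
from endoprot.multivariate import (  # noqa: E402
    cut_clusters,
    hierarchical_cluster,
    label_agreement,
    pca,
)
from endoprot.preprocess import zscore_rows  # noqa: E402

OUT = os.path.join(os.path.dirname(__file__), "..", "results",
                   "multivariate")


def main() -> None:
    _, matrix, annotations = load_matrix()
    cohorts = {a.sample: a.cohort for a in annotations}

    res = pca(matrix)
    evr = res.explained_variance_ratio
    print(f"PC1/PC2 explained variance: {evr[0]:.1%} / {evr[1]:.1%}")

    tree = hierarchical_cluster(zscore_rows(matrix), axis="samples")
    parts = cut_clusters(tree, 2)
    binary = ["cancer" if cohorts[s] in ("CC", "EC") else "control"
              for s in parts.index]
    ari = label_agreement(parts.to_numpy(), binary)
    print(f"2-cluster ARI vs cancer/control labels: {ari:.3f}")

    write_results(
        {
            "pca_scores": res.scores,
            "pca_explained_variance": pd.DataFrame(
                {"evr": evr}, index=res.scores.columns
            ),
            "sample_clusters_k2": parts.to_frame(),
        },
        OUT,
    )
    print(f"written to {os.path.abspath(OUT)}")


if __name__ == "__main__":
    main()
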