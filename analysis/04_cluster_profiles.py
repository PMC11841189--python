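#!/usr/bin/env python
"""Cluster the Ca2+-dependent genes' response profiles.

The feature space is the per-gene (log2FC under H2O2, log2FC under
H2O2 + LaCl3) pair.  The number of clusters is fixed by the gap statistic
(B = 100 uniform reference datasets, one-standard-error rule), then k-means
partitions the profiles and each cluster is summarized as mean +/- SE with
a pattern label from its dominant dependency class.
"""

from pathlib import Path

import pandas as pd

from cadep.classifier import DEPENDENT_CLASSES
from cadep.clustering import gap_select_k, kmeans_fit, summarize_clusters

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "clusters"
SEED = 123


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    classes = pd.read_csv(BASE / "classification" / "classes.tsv", sep="\t")
    dependent = classes[classes["dep_class"].isin(DEPENDENT_CLASSES)].reset_index(
        drop=True
    )
    X = dependent[["lfc_h2o2", "lfc_combined"]].to_numpy()
    print(f"clustering {len(dependent)} Ca2+-dependent genes")

    curve = gap_select_k(X, k_max=8, B=100, seed=SEED)
    curve.to_frame().to_csv(OUT / "gap_curve.tsv", sep="\t", index=False)
    print(f"gap statistic chose k = {curve.chosen_k} "
          f"(gap at k: {curve.gap[curve.chosen_k - 1]:.3f})")

    model = kmeans_fit(X, curve.chosen_k, seed=SEED,
                       gene_ids=list(dependent["gene_id"]))
    assigned = dependent.assign(cluster=model.labels)
    assigned.to_csv(OUT / "clusters.tsv", sep="\t", index=False)

    summary = summarize_clusters(
        model,
        dependent[["lfc_h2o2", "lfc_combined"]],
        dep_classes=dependent["dep_class"],
        directions=dependent["direction"],
    )
    summary.to_csv(OUT / "cluster_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
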