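#!/usr/bin/env python
"""Generate the synthetic study: counts, DE tables, knowledge network, Ct
tables — all with planted truth.

Emulates the four-condition design (water control, H2O2, LaCl3,
H2O2 + LaCl3; three biological replicates each) at 2,000 genes, plus a
ranked/typed interaction network with planted regulatory paths and a qPCR
panel.  Everything lands under results/synthetic/.
"""

from pathlib import Path

from cadep.io_formats import write_de_table, write_network
from cadep.synthetic import (
    SimParams,
    simulate_counts,
    simulate_ct_table,
    simulate_de_tables,
    simulate_network,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 123


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimParams(n_genes=2000, seed=SEED)

    counts, truth = simulate_counts(params)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")
    print("planted classes:")
    print(truth["true_class"].value_counts().to_string())

    tables, _ = simulate_de_tables(params)
    for contrast, df in tables.items():
        write_de_table(df, OUT / f"de_{contrast}.tsv")
    print(f"wrote {len(tables)} DE tables (Wald noise sd {params.lfc_se})")

    net, ann, net_truth = simulate_network(
        n_nodes=120, n_planted=10, decoy_density=0.8, seed=SEED
    )
    write_network(net, OUT / "network.tsv")
    ann.to_csv(OUT / "annotations.tsv", sep="\t", index=False)
    print(
        f"network: {len(net.nodes)} nodes, {len(net)} edges, "
        f"{len(net_truth.paths)} planted paths to "
        f"{len(net_truth.targets)} targets"
    )

    ct, refs = simulate_ct_table(truth, n_genes_qpcr=10, ct_noise_sd=0.2,
                                 seed=SEED)
    ct.to_csv(OUT / "ct.csv", index=False)
    print(f"qPCR panel: 10 genes + references {refs}, Ct noise sd 0.2")


if __name__ == "__main__":
    main()
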