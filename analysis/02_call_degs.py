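#!/usr/bin/env python
"""Call DEGs per contrast and apply the channel-blocker uniqueness filter.

Reads the simulated DE tables, gates each contrast at FDR < 0.01 and
|log2FC| >= 0.5, and removes combined-treatment DEGs shared with the LaCl3
treatment alone — those changes cannot be attributed to the blocked Ca2+
transient.  Writes status-annotated tables and the unique-DEG list.
"""

from pathlib import Path

from cadep.classifier import filter_lacl3_shared
from cadep.de_stats import UC, call_deg_table
from cadep.io_formats import CONTRASTS, CONTRAST_COMBINED, CONTRAST_LACL3, read_de_table

BASE = Path(__file__).resolve().parents[1] / "results"
IN = BASE / "synthetic"
OUT = BASE / "degs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    status = {}
    for contrast in CONTRASTS:
        de = read_de_table(IN / f"de_{contrast}.tsv", contrast)
        st = call_deg_table(de)
        st.to_csv(OUT / f"status_{contrast}.tsv", sep="\t", index=False)
        status[contrast] = st
        n_up = int((st["status"] == "UP").sum())
        n_down = int((st["status"] == "DOWN").sum())
        print(f"{contrast}: {n_up} up, {n_down} down, "
              f"{int((st['status'] == UC).sum())} unchanged")

    retained = filter_lacl3_shared(
        status[CONTRAST_COMBINED], status[CONTRAST_LACL3], mode="identity"
    )
    n_comb = int((status[CONTRAST_COMBINED]["status"] != UC).sum())
    (OUT / "unique_combined_degs.txt").write_text(
        "\n".join(sorted(retained)) + "\n"
    )
    print(
        f"combined-treatment DEGs: {n_comb}; unique after omitting LaCl3-"
        f"shared: {len(retained)} ({n_comb - len(retained)} removed)"
    )


if __name__ == "__main__":
    main()
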