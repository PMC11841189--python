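"""Ca2+-dependency classification of H2O2-responsive genes.

The experimental logic: H2O2 triggers a cytosolic Ca2+ transient; LaCl3
blocks it.  Comparing a gene's response to H2O2 alone against its response to
H2O2 + LaCl3 therefore reveals whether the Ca2+ signal is required for the
transcriptional change.  Genes already responsive to LaCl3 alone are removed
first, since their change under the combined treatment cannot be attributed
to the blocked Ca2+ transient.

Classes for an H2O2-DEG (delta = log2FC_H2O2 - log2FC_combined):

* STRICT           — UC under H2O2 + LaCl3: the response requires Ca2+.
* PARTIAL_ADDITIVE — still a DEG, same direction, reduced magnitude,
                     |delta| >= 1: Ca2+ contributes part of the response.
* ENHANCED         — still a DEG, same direction, larger magnitude without
                     the Ca2+ transient (|delta| >= 1).
* ANTAGONISTIC     — regulation direction flips (up <-> down), |delta| >= 1.
* INDEPENDENT      — none of the above: the response does not need Ca2+.

The first four are collectively "Ca2+-dependent".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de_stats import DOWN, UC, UP, call_deg_table
from .io_formats import RunConfig

logger = logging.getLogger(__name__)

STRICT = "STRICT"
PARTIAL_ADDITIVE = "PARTIAL_ADDITIVE"
ENHANCED = "ENHANCED"
ANTAGONISTIC = "ANTAGONISTIC"
INDEPENDENT = "INDEPENDENT"
DEP_CLASSES = (STRICT, PARTIAL_ADDITIVE, ENHANCED, ANTAGONISTIC, INDEPENDENT)
#: Classes whose members count as Ca2+-dependent.
DEPENDENT_CLASSES = (STRICT, PARTIAL_ADDITIVE, ENHANCED, ANTAGONISTIC)


def filter_lacl3_shared(
    combined_degs: pd.DataFrame,
    lacl3_degs: pd.DataFrame,
    mode: str = "identity",
) -> set[str]:
    """Gene ids of combined-treatment DEGs not attributable to LaCl3 alone.

    Both inputs are status-annotated DE tables (``gene_id``/``status``); only
    non-UC rows participate.  ``identity`` mode (default, matching a Venn
    overlap) removes any combined DEG that is also a LaCl3-alone DEG;
    ``same_direction`` removes only same-sign overlaps.
    """
    if mode not in ("identity", "same_direction"):
        raise ValueError(f"unknown filter mode {mode!r}")
    comb = combined_degs.loc[combined_degs["status"] != UC, ["gene_id", "status"]]
    lacl = lacl3_degs.loc[lacl3_degs["status"] != UC, ["gene_id", "status"]]
    if mode == "identity":
        removed = set(comb["gene_id"]) & set(lacl["gene_id"])
    else:
        lacl_status = dict(zip(lacl["gene_id"], lacl["status"]))
        removed = {
            g for g, s in zip(comb["gene_id"], comb["status"])
            if lacl_status.get(g) == s
        }
    return set(comb["gene_id"]) - removed


def classify_gene(
    status_h2o2: str,
    lfc_h2o2: float,
    status_combined: str,
    lfc_combined: float,
    delta_cutoff: float = 1.0,
) -> str:
    """Assign the dependency class for one H2O2-DEG.

    Precondition: the gene is differentially expressed under H2O2 alone.
    STRICT when the combined response is UC; otherwise the two responses are
    compared and |delta| >= delta_cutoff marks a Ca2+-modulated response,
    split by direction flip (ANTAGONISTIC) or magnitude change
    (PARTIAL_ADDITIVE if attenuated, ENHANCED if amplified).
    """
    if status_h2o2 == UC:
        raise ValueError("classification requires an H2O2-DEG (status != UC)")
    if status_combined == UC:
        return STRICT
    delta = lfc_h2o2 - lfc_combined
    if abs(delta) >= delta_cutoff:
        if np.sign(lfc_h2o2) != np.sign(lfc_combined):
            return ANTAGONISTIC
        if abs(lfc_combined) < abs(lfc_h2o2):
            return PARTIAL_ADDITIVE
        if abs(lfc_combined) > abs(lfc_h2o2):
            return ENHANCED
        raise AssertionError(
            "equal-magnitude same-sign responses cannot satisfy the delta gate"
        )
    return INDEPENDENT


@dataclass
class ClassificationResult:
    """Per-gene classification plus the genes outside the domain."""

    table: pd.DataFrame
    #: Combined-treatment DEGs that are UC under H2O2 alone; the classifier's
    #: domain is H2O2-responsive genes, so these are reported, not classed.
    combined_only: list[str]


def classify_table(
    h2o2: pd.DataFrame,
    combined: pd.DataFrame,
    lacl3: pd.DataFrame,
    config: RunConfig | None = None,
    h2o2_deg_ids: list[str] | None = None,
) -> ClassificationResult:
    """Classify every H2O2-DEG using the three per-contrast DE tables.

    DEG status is computed for all three contrasts with the same thresholds;
    combined DEGs shared with LaCl3 alone are excluded
    (``excluded_lacl3_shared``) and receive no class.  The H2O2-DEG reference
    set defaults to genes passing the gate in the H2O2 table, but an external
    gene-id list may be supplied (``h2o2_deg_ids``), mirroring the use of a
    previously published DEG catalogue.
    """
    cfg = config or RunConfig()
    h = call_deg_table(h2o2, cfg.fdr_cutoff, cfg.lfc_cutoff).set_index("gene_id")
    c = call_deg_table(combined, cfg.fdr_cutoff, cfg.lfc_cutoff).set_index("gene_id")
    l = call_deg_table(lacl3, cfg.fdr_cutoff, cfg.lfc_cutoff).set_index("gene_id")

    retained = filter_lacl3_shared(
        c.reset_index(), l.reset_index(), mode=cfg.filter_mode
    )

    if h2o2_deg_ids is not None:
        deg_ids = [g for g in h2o2_deg_ids if g in h.index]
        if len(deg_ids) < len(h2o2_deg_ids):
            logger.warning(
                "%d externally supplied H2O2-DEG ids absent from the H2O2 table",
                len(h2o2_deg_ids) - len(deg_ids),
            )
    else:
        deg_ids = list(h.index[h["status"] != UC])

    missing = [g for g in deg_ids if g not in c.index]
    if missing:
        logger.warning(
            "%d H2O2-DEGs absent from the combined table were skipped", len(missing)
        )
        deg_ids = [g for g in deg_ids if g in c.index]

    rows = []
    for g in deg_ids:
        sh, lh = h.at[g, "status"], float(h.at[g, "log2fc"])
        sc, lc = c.at[g, "status"], float(c.at[g, "log2fc"])
        sl = l.at[g, "status"] if g in l.index else UC
        excluded = sc != UC and g not in retained
        dep = None if excluded else classify_gene(sh, lh, sc, lc, cfg.delta_cutoff)
        rows.append(
            dict(
                gene_id=g,
                status_h2o2=sh,
                status_combined=sc,
                status_lacl3=sl,
                lfc_h2o2=lh,
                lfc_combined=lc,
                delta_log2fc=lh - lc,
                dep_class=dep,
                direction=UP if sh == UP else DOWN,
                excluded_lacl3_shared=excluded,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "status_h2o2", "status_combined", "status_lacl3",
            "lfc_h2o2", "lfc_combined", "delta_log2fc", "dep_class",
            "direction", "excluded_lacl3_shared",
        ],
    )
    h2o2_deg_set = set(h.index[h["status"] != UC])
    combined_only = sorted(
        ({g for g in c.index[c["status"] != UC]} & retained) - h2o2_deg_set
    )
    return ClassificationResult(table=table, combined_only=combined_only)


def tabulate_classes(classifications: pd.DataFrame) -> dict:
    """Summary counts over a classification table.

    ``total_dependent`` is the sum of the four dependent classes and always
    equals strict + partial_or_antagonistic; excluded genes and genes without
    a class are counted separately and do not enter the partition.
    """
    counts = {cls: 0 for cls in DEP_CLASSES}
    per_direction = {UP: 0, DOWN: 0}
    excluded = 0
    if len(classifications):
        classed = classifications[classifications["dep_class"].notna()]
        excluded = int(classifications["excluded_lacl3_shared"].sum())
        for cls, n in classed["dep_class"].value_counts().items():
            counts[cls] = int(n)
        for d, n in classed["direction"].value_counts().items():
            per_direction[d] = int(n)
    partial_or_antag = (
        counts[PARTIAL_ADDITIVE] + counts[ENHANCED] + counts[ANTAGONISTIC]
    )
    total_dependent = counts[STRICT] + partial_or_antag
    return {
        "per_class": counts,
        "per_direction": per_direction,
        "strict": counts[STRICT],
        "partial_or_antagonistic": partial_or_antag,
        "independent": counts[INDEPENDENT],
        "total_dependent": total_dependent,
        "excluded_lacl3_shared": excluded,
        "total_classified": int(sum(counts.values())),
    }


def dependent_fraction(n_dependent: int, n_h2o2_degs: int) -> float:
    """Percentage of H2O2-responsive genes that are Ca2+-dependent."""
    if n_h2o2_degs <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * n_dependent / n_h2o2_degs
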