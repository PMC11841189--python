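"""Benchmark and calibration procedures over the synthetic generators.

Each function runs a pipeline stage against planted ground truth and returns
summary numbers: published-count arithmetic, classifier precision/recall,
planted-path and hub recovery, gap-statistic calibration, clustering
recovery, null FDR control, and the noiseless end-to-end chain.  The
analysis drivers and the acceptance machinery both run these, so reported
numbers always come from the same code paths as the library itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import classifier as cls
from .classifier import classify_table, dependent_fraction, tabulate_classes
from .clustering import gap_select_k, kmeans_fit
from .de_stats import UP, surrogate_de
from .io_formats import CONTRAST_COMBINED, CONTRAST_H2O2, CONTRAST_LACL3
from .network_paths import extract_paths, merge_paths, select_by_terms
from .qpcr import concordance, delta_delta_ct
from .synthetic import (
    ANTAG_UP_TO_DOWN,
    CLASS_EFFECTS,
    EXPECTED_DEP_CLASS,
    LACL3_ARTIFACT,
    NULL,
    PARTIAL_DOWN,
    PARTIAL_UP,
    STRICT_DOWN,
    STRICT_UP,
    SimParams,
    simulate_counts,
    simulate_ct_table,
    simulate_de_tables,
    simulate_hub_network,
    simulate_network,
)

#: Published per-tissue marginals: (strict, partial-or-antagonistic,
#: H2O2-DEG denominator).  The tissue summaries lump the partial and
#: antagonistic classes into one count, so the split below is irrelevant to
#: every derived total.
STUDY_COUNTS = {
    "leaf": (295, 36, 1001),
    "root": (799, 522, 1883),
}


def _classification_frame(n_strict: int, n_partial_or_antag: int) -> pd.DataFrame:
    rows = [
        dict(gene_id=f"s{i}", dep_class=cls.STRICT, direction=UP,
             excluded_lacl3_shared=False)
        for i in range(n_strict)
    ] + [
        dict(gene_id=f"p{i}", dep_class=cls.PARTIAL_ADDITIVE, direction=UP,
             excluded_lacl3_shared=False)
        for i in range(n_partial_or_antag)
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "dep_class", "direction",
                       "excluded_lacl3_shared"]
    )


def study_count_summary() -> dict[str, float]:
    """Totals and dependent fractions implied by the published per-tissue
    component counts, recomputed through the tabulation code."""
    out: dict[str, float] = {}
    totals = []
    for tissue, (n_strict, n_other, n_degs) in STUDY_COUNTS.items():
        summary = tabulate_classes(_classification_frame(n_strict, n_other))
        out[f"{tissue}_dependent_total"] = summary["total_dependent"]
        out[f"{tissue}_dependent_pct"] = dependent_fraction(
            summary["total_dependent"], n_degs
        )
        totals.append(summary["total_dependent"])
    out["cross_tissue_dependent_total"] = int(sum(totals))
    return out


def classifier_recovery(
    n_genes: int = 2000,
    n_seeds: int = 10,
    lfc_se: float = 0.15,
    base_seed: int = 123,
) -> dict:
    """Per-class precision/recall of the dependency classifier on synthetic
    DE tables at the given Wald noise, confusion aggregated over seeds."""
    tp: dict[str, int] = {c: 0 for c in cls.DEP_CLASSES}
    fp: dict[str, int] = {c: 0 for c in cls.DEP_CLASSES}
    fn: dict[str, int] = {c: 0 for c in cls.DEP_CLASSES}
    for i in range(n_seeds):
        params = SimParams(n_genes=n_genes, lfc_se=lfc_se,
                           seed=base_seed + 1000 * i)
        tables, truth = simulate_de_tables(params)
        res = classify_table(
            tables[CONTRAST_H2O2], tables[CONTRAST_COMBINED],
            tables[CONTRAST_LACL3],
        )
        predicted = dict(
            zip(res.table["gene_id"],
                res.table["dep_class"].where(res.table["dep_class"].notna(), None))
        )
        for gene, true_class in zip(truth["gene_id"], truth["true_class"]):
            expected = EXPECTED_DEP_CLASS[true_class]
            got = predicted.get(gene)
            if expected is not None and got == expected:
                tp[expected] += 1
            else:
                if expected is not None:
                    fn[expected] += 1
                if got is not None:
                    fp[got] += 1
    rows = []
    for c in cls.DEP_CLASSES:
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else float("nan")
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else float("nan")
        rows.append(dict(dep_class=c, precision=prec, recall=rec,
                         tp=tp[c], fp=fp[c], fn=fn[c]))
    table = pd.DataFrame(rows)
    return {
        "per_class": table,
        "min_precision": float(table["precision"].min()),
        "min_recall": float(table["recall"].min()),
    }


def noiseless_recovery_pct(n_genes: int = 2000, seed: int = 123) -> float:
    """Percent of classifiable planted genes recovered exactly in the
    noiseless limit (Wald noise 1e-8)."""
    params = SimParams(n_genes=n_genes, lfc_se=1e-8, seed=seed)
    tables, truth = simulate_de_tables(params)
    res = classify_table(
        tables[CONTRAST_H2O2], tables[CONTRAST_COMBINED], tables[CONTRAST_LACL3]
    )
    predicted = dict(zip(res.table["gene_id"], res.table["dep_class"]))
    classifiable = truth[
        ~truth["true_class"].isin([NULL, LACL3_ARTIFACT])
    ]
    hits = sum(
        predicted.get(g) == EXPECTED_DEP_CLASS[c]
        for g, c in zip(classifiable["gene_id"], classifiable["true_class"])
    )
    return 100.0 * hits / len(classifiable)


def null_fdr_fraction(n_genes: int = 20000, seed: int = 123) -> float:
    """Fraction of genes called at FDR < 0.01 in a full-null simulation."""
    params = SimParams(n_genes=n_genes, class_proportions={NULL: 1.0}, seed=seed)
    tables, _ = simulate_de_tables(params)
    return float((tables[CONTRAST_H2O2]["fdr"] < 0.01).mean())


def planted_path_recovery(
    n_networks: int = 200,
    n_nodes: int = 40,
    n_planted: int = 4,
    decoy_density: float = 0.5,
    base_seed: int = 123,
) -> float:
    """Percent of random networks whose rank-filtered extraction returns
    exactly the planted constrained paths despite decoy near-paths."""
    hits = 0
    for i in range(n_networks):
        net, ann, truth = simulate_network(
            n_nodes, n_planted, decoy_density=decoy_density,
            seed=base_seed + 7 * i,
        )
        sources = select_by_terms(net, ann, ["30.3", "34.21", "34.22"])
        paths = extract_paths(net, sources, truth.targets, max_len=3, max_rank=2)
        got = {(p.nodes, p.edges) for ps in paths.values() for p in ps}
        want = {(p.nodes, p.edges) for p in truth.paths}
        hits += got == want
    return 100.0 * hits / n_networks


def hub_recovery(n_seeds: int = 20, base_seed: int = 123) -> float:
    """Percent of seeded hub networks whose planted hub ranks first by
    (n_distinct_targets, n_path_occurrences)."""
    hits = 0
    for i in range(n_seeds):
        net, _, truth = simulate_hub_network(seed=base_seed + 11 * i)
        paths = extract_paths(net, set(truth.sources), truth.targets)
        merged = merge_paths(paths)
        hits += merged.hub_ranking[0] == truth.hub
    return 100.0 * hits / n_seeds


def gap_calibration(
    kind: str,
    n_seeds: int = 20,
    B: int = 100,
    n_points: int = 60,
    base_seed: int = 123,
) -> float:
    """Percent of seeds where the gap statistic picks the expected k.

    ``kind='blobs'``: two spherical clusters 10 within-cluster SDs apart,
    expected k = 2.  ``kind='uniform'``: structureless uniform noise,
    expected k = 1.
    """
    if kind not in ("blobs", "uniform"):
        raise ValueError("kind must be 'blobs' or 'uniform'")
    expected = 2 if kind == "blobs" else 1
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + 13 * i)
        if kind == "blobs":
            half = n_points // 2
            X = np.vstack([
                rng.normal((0.0, 0.0), 1.0, size=(half, 2)),
                rng.normal((10.0, 0.0), 1.0, size=(n_points - half, 2)),
            ])
        else:
            X = rng.uniform(0.0, 1.0, size=(n_points, 2))
        curve = gap_select_k(X, k_max=5, B=B, seed=base_seed + 13 * i)
        hits += curve.chosen_k == expected
    return 100.0 * hits / n_seeds


#: The five response patterns seen in leaf clusters: strict up/down,
#: partial up/down, and antagonistic.
LEAF_PATTERN_CLASSES = (
    STRICT_UP, STRICT_DOWN, PARTIAL_UP, PARTIAL_DOWN, ANTAG_UP_TO_DOWN,
)


def clustering_recovery_ari(
    n_per_class: int = 40, lfc_se: float = 0.15, seed: int = 123
) -> float:
    """Adjusted Rand index between k-means clusters of noisy planted
    profiles and the planted five-pattern partition."""
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    for c in LEAF_PATTERN_CLASSES:
        lh, lc, _ = CLASS_EFFECTS[c]
        for _ in range(n_per_class):
            profiles.append((lh + rng.normal(0, lfc_se),
                             lc + rng.normal(0, lfc_se)))
            labels.append(c)
    X = np.asarray(profiles)
    model = kmeans_fit(X, k=len(LEAF_PATTERN_CLASSES), seed=seed, n_restarts=25)
    return float(adjusted_rand_score(labels, model.labels))


def noiseless_chain(n_genes: int = 600, n_genes_qpcr: int = 12,
                    seed: int = 123) -> dict[str, float]:
    """End-to-end run: counts -> surrogate DE -> classification -> k-means
    -> qPCR concordance with noise-free Ct tables.

    The returned Pearson r compares planted log2FC against 2^-ddCt log2
    ratios, which is exact when Ct noise is zero regardless of count noise.
    """
    params = SimParams(n_genes=n_genes, seed=seed)
    counts, truth = simulate_counts(params)
    reps = params.n_reps
    groups = {c: [f"{c}_{r}" for r in range(1, reps + 1)]
              for c in ("ctrl", "h2o2", "lacl3", "comb")}
    de = {
        CONTRAST_H2O2: surrogate_de(counts, groups["ctrl"], groups["h2o2"],
                                    CONTRAST_H2O2),
        CONTRAST_COMBINED: surrogate_de(counts, groups["ctrl"], groups["comb"],
                                        CONTRAST_COMBINED),
        CONTRAST_LACL3: surrogate_de(counts, groups["ctrl"], groups["lacl3"],
                                     CONTRAST_LACL3),
    }
    res = classify_table(de[CONTRAST_H2O2], de[CONTRAST_COMBINED],
                         de[CONTRAST_LACL3])
    dependent = res.table[res.table["dep_class"].isin(cls.DEPENDENT_CLASSES)]
    n_clustered = 0
    if len(dependent) >= 5:
        model = kmeans_fit(
            dependent[["lfc_h2o2", "lfc_combined"]].to_numpy(), k=5, seed=seed
        )
        n_clustered = len(model.labels)

    ct, refs = simulate_ct_table(truth, n_genes_qpcr, ct_noise_sd=0.0, seed=seed)
    lookup = truth.set_index("gene_id")
    genes = [g for g in ct["gene_id"].unique() if g not in refs]
    qpcr_log2 = [
        np.log2(delta_delta_ct(ct, g, "h2o2", "ctrl", tuple(refs)).ratio)
        for g in genes
    ]
    planted = [float(lookup.loc[g, "lfc_h2o2"]) for g in genes]
    out = concordance(qpcr_log2, planted)
    return {
        "pearson_r": out["pearson_r"],
        "slope": out["slope"],
        "n_dependent": int(len(dependent)),
        "n_clustered": n_clustered,
        "n_qpcr_genes": len(genes),
    }
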