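"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design it stands in for: four conditions
(water control, H2O2, LaCl3, H2O2 + LaCl3) with three biological replicates,
negative-binomial counts, per-contrast Wald-style DE tables, a ranked/typed
knowledge network with planted constrained paths, and qPCR Ct tables whose
noiseless 2^-ddCt recovers the planted fold changes.

Each gene carries a true dependency class; the planted log2 fold changes are
chosen so that, at zero noise, the downstream classifier recovers the class
exactly, and every effect sits well clear (>= 0.6 log2 units, i.e. about
2.8 Wald standard errors at the default lfc_se = 0.15) of every decision
boundary (DEG gate 0.5, delta gate 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import classifier as _cls
from .de_stats import bh_adjust
from .io_formats import CONTRAST_COMBINED, CONTRAST_H2O2, CONTRAST_LACL3
from .network_paths import (
    BINDING,
    PTM,
    TF_REGULATION,
    EdgeRecord,
    KnowledgeNetwork,
    RegulatoryPath,
)

CONDITIONS = ("ctrl", "h2o2", "lacl3", "comb")

# True classes and their canonical planted (lfc_h2o2, lfc_combined, lfc_lacl3).
NULL = "NULL"
INDEPENDENT = "INDEPENDENT"
STRICT_UP = "STRICT_UP"
STRICT_DOWN = "STRICT_DOWN"
PARTIAL_UP = "PARTIAL_UP"
PARTIAL_DOWN = "PARTIAL_DOWN"
ENHANCED_DOWN = "ENHANCED_DOWN"
ANTAG_UP_TO_DOWN = "ANTAG_UP_TO_DOWN"
ANTAG_DOWN_TO_UP = "ANTAG_DOWN_TO_UP"
LACL3_ARTIFACT = "LACL3_ARTIFACT"

CLASS_EFFECTS: dict[str, tuple[float, float, float]] = {
    NULL: (0.0, 0.0, 0.0),
    INDEPENDENT: (1.8, 1.8, 0.0),
    STRICT_UP: (2.0, 0.0, 0.0),
    STRICT_DOWN: (-2.0, 0.0, 0.0),
    PARTIAL_UP: (3.0, 1.2, 0.0),
    PARTIAL_DOWN: (-3.0, -1.2, 0.0),
    ENHANCED_DOWN: (-1.2, -3.0, 0.0),
    ANTAG_UP_TO_DOWN: (1.5, -1.2, 0.0),
    ANTAG_DOWN_TO_UP: (-1.5, 1.2, 0.0),
    # The combined-treatment response is caused by LaCl3 itself: planted
    # identically in the LaCl3-alone and combined contrasts, so the
    # unique-DEG filter removes the gene.
    LACL3_ARTIFACT: (1.5, 1.5, 1.5),
}
TRUE_CLASSES = tuple(CLASS_EFFECTS)

#: Mapping from planted class to the dependency class the classifier should
#: assign at zero noise (None: outside the classified set).
EXPECTED_DEP_CLASS: dict[str, str | None] = {
    NULL: None,
    INDEPENDENT: _cls.INDEPENDENT,
    STRICT_UP: _cls.STRICT,
    STRICT_DOWN: _cls.STRICT,
    PARTIAL_UP: _cls.PARTIAL_ADDITIVE,
    PARTIAL_DOWN: _cls.PARTIAL_ADDITIVE,
    ENHANCED_DOWN: _cls.ENHANCED,
    ANTAG_UP_TO_DOWN: _cls.ANTAGONISTIC,
    ANTAG_DOWN_TO_UP: _cls.ANTAGONISTIC,
    LACL3_ARTIFACT: None,
}

DEFAULT_PROPORTIONS: dict[str, float] = {
    NULL: 0.55,
    INDEPENDENT: 0.09,
    STRICT_UP: 0.08,
    STRICT_DOWN: 0.08,
    PARTIAL_UP: 0.04,
    PARTIAL_DOWN: 0.04,
    ENHANCED_DOWN: 0.03,
    ANTAG_UP_TO_DOWN: 0.03,
    ANTAG_DOWN_TO_UP: 0.03,
    LACL3_ARTIFACT: 0.03,
}


@dataclass
class SimParams:
    """Simulation settings.

    ``baseline_log_mean``/``baseline_log_sd`` parameterize the log-normal
    gene-wise baseline mean; ``nb_dispersion`` d gives var = mu + d*mu^2;
    ``lfc_se`` is the Wald standard error applied when DE tables are
    generated directly.  Three biological replicates per condition by
    default, matching the emulated design.
    """

    n_genes: int = 2000
    n_reps: int = 3
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    lfc_se: float = 0.15
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    seed: int = 123

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.lfc_se <= 0:
            raise ValueError("lfc_se must be > 0")
        unknown = set(self.class_proportions) - set(TRUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in proportions: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1 (got {total})")


def assign_truth(params: SimParams) -> pd.DataFrame:
    """Draw per-gene true classes and planted effects; deterministic in seed."""
    rng = np.random.default_rng([params.seed, 0])
    classes = [c for c in TRUE_CLASSES if params.class_proportions.get(c, 0) > 0]
    probs = np.array([params.class_proportions[c] for c in classes])
    probs = probs / probs.sum()
    drawn = rng.choice(len(classes), size=params.n_genes, p=probs)
    records = []
    for i, ci in enumerate(drawn):
        cls = classes[ci]
        lh, lc, ll = CLASS_EFFECTS[cls]
        records.append(
            dict(gene_id=f"G{i:05d}", true_class=cls,
                 lfc_h2o2=lh, lfc_combined=lc, lfc_lacl3=ll)
        )
    return pd.DataFrame(records)


def simulate_counts(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for 4 conditions x n_reps samples.

    The control mean is mu_g = exp(Normal(baseline_log_mean,
    baseline_log_sd)); treated means scale by 2^lfc of the matching planted
    contrast.  var = mu + d*mu^2 with a shared dispersion d.
    """
    truth = assign_truth(params)
    rng = np.random.default_rng([params.seed, 1])
    n = params.n_genes
    mu0 = np.exp(
        rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=n)
    )
    lfc_by_cond = {
        "ctrl": np.zeros(n),
        "h2o2": truth["lfc_h2o2"].to_numpy(),
        "lacl3": truth["lfc_lacl3"].to_numpy(),
        "comb": truth["lfc_combined"].to_numpy(),
    }
    size = 1.0 / params.nb_dispersion
    cols = {}
    for cond in CONDITIONS:
        mu = mu0 * 2.0 ** lfc_by_cond[cond]
        p = size / (size + mu)
        for rep in range(1, params.n_reps + 1):
            cols[f"{cond}_{rep}"] = rng.negative_binomial(size, p)
    counts = pd.DataFrame(cols, index=truth["gene_id"])
    counts.index.name = "gene_id"
    return counts, truth


def simulate_de_tables(
    params: SimParams,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-contrast DE tables with Wald-style noise around the planted effects.

    observed log2FC = planted + Normal(0, lfc_se); the p-value is the
    two-sided normal tail of observed/lfc_se and FDR is BH within contrast.
    """
    truth = assign_truth(params)
    rng = np.random.default_rng([params.seed, 2])
    tables: dict[str, pd.DataFrame] = {}
    planted = {
        CONTRAST_H2O2: truth["lfc_h2o2"],
        CONTRAST_COMBINED: truth["lfc_combined"],
        CONTRAST_LACL3: truth["lfc_lacl3"],
    }
    for contrast, true_lfc in planted.items():
        obs = true_lfc.to_numpy() + rng.normal(0, params.lfc_se, size=params.n_genes)
        z = obs / params.lfc_se
        p = 2.0 * stats.norm.sf(np.abs(z))
        df = pd.DataFrame(
            {
                "gene_id": truth["gene_id"],
                "log2fc": obs,
                "pvalue": p,
                "fdr": bh_adjust(p),
            }
        )
        df.attrs["contrast_id"] = contrast
        tables[contrast] = df
    return tables, truth


# ---------------------------------------------------------------------------
# Knowledge-network simulation


@dataclass
class NetworkTruth:
    """Planted structure of a simulated knowledge network."""

    paths: list[RegulatoryPath]
    sources: list[str]
    targets: list[str]
    hub: str | None = None


def _planted_path_edges(
    rng: np.random.Generator, nodes: list[str]
) -> list[EdgeRecord]:
    """Edges realizing one valid path along ``nodes`` (final edge TF)."""
    edges = []
    for u, v in zip(nodes[:-2], nodes[1:-1]):
        if rng.random() < 0.5:
            edges.append(EdgeRecord(u, v, BINDING, int(rng.integers(0, 3)), False))
        else:
            edges.append(EdgeRecord(u, v, PTM, int(rng.integers(0, 3)), True))
    edges.append(
        EdgeRecord(nodes[-2], nodes[-1], TF_REGULATION, int(rng.integers(0, 3)), True)
    )
    return edges


def simulate_network(
    n_nodes: int,
    n_planted: int,
    decoy_density: float = 0.0,
    seed: int = 123,
) -> tuple[KnowledgeNetwork, pd.DataFrame, NetworkTruth]:
    """Random knowledge network with ``n_planted`` valid constrained paths.

    Each planted path (length 1-3, exactly one terminal TF edge, ranks <= 2)
    gets its own source, target and intermediates, so with
    ``decoy_density = 0`` path extraction must return exactly the planted
    paths.  Decoys add constraint-violating near-paths — two TF edges, a
    non-terminal TF edge, a length-4 route, a rank-3 parallel edge — plus
    random clutter among bystander nodes; none of them creates a new valid
    route at rank <= 2.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if decoy_density < 0:
        raise ValueError("decoy_density must be >= 0")
    rng = np.random.default_rng([seed, 3])
    lengths = rng.integers(1, 4, size=n_planted)
    needed = int((lengths + 1).sum())
    if needed > n_nodes:
        raise ValueError(
            f"n_planted={n_planted} needs {needed} nodes but n_nodes={n_nodes}"
        )
    ids = [f"N{i:04d}" for i in range(n_nodes)]
    rng.shuffle(ids)
    pool = iter(ids)

    source_terms = ["30.3", "34.21", "34.22", "30.3.2"]
    edges: list[EdgeRecord] = []
    ann_rows: list[dict] = []
    paths: list[RegulatoryPath] = []
    sources: list[str] = []
    targets: list[str] = []
    for L in lengths:
        nodes = [next(pool) for _ in range(int(L) + 1)]
        p_edges = _planted_path_edges(rng, nodes)
        edges.extend(p_edges)
        paths.append(RegulatoryPath(nodes=tuple(nodes), edges=tuple(p_edges)))
        sources.append(nodes[0])
        targets.append(nodes[-1])
        ann_rows.append(
            dict(node_id=nodes[0],
                 term=source_terms[int(rng.integers(0, len(source_terms)))])
        )

    bystanders = list(pool)
    for b in bystanders:
        ann_rows.append(dict(node_id=b, term="27.1"))

    # Bystanders consumed by decoy constructions are never reused, so decoy
    # fragments cannot combine across decoys into a new valid rank<=2 route.
    fresh = list(bystanders)
    n_decoys = rng.poisson(decoy_density * n_nodes) if decoy_density > 0 else 0
    for _ in range(n_decoys):
        kind = int(rng.integers(0, 5))
        tgt = targets[int(rng.integers(0, len(targets)))]
        src = sources[int(rng.integers(0, len(sources)))]
        if kind == 0 and len(fresh) >= 1:
            # Two-TF near-path: source -TF-> X -TF-> target (invalid).
            x = fresh.pop()
            edges.append(EdgeRecord(src, x, TF_REGULATION, 1, True))
            edges.append(EdgeRecord(x, tgt, TF_REGULATION, 3, True))
        elif kind == 1 and len(fresh) >= 1:
            # Non-terminal TF edge: source -TF-> X -BINDING- target (invalid).
            x = fresh.pop()
            edges.append(EdgeRecord(src, x, TF_REGULATION, 0, True))
            edges.append(EdgeRecord(x, tgt, BINDING, 1, False))
        elif kind == 2 and len(fresh) >= 3:
            # Length-4 route (too long).
            xs = [fresh.pop() for _ in range(3)]
            chain = [src, *xs]
            for u, v in zip(chain[:-1], chain[1:]):
                edges.append(EdgeRecord(u, v, PTM, 1, True))
            edges.append(EdgeRecord(xs[-1], tgt, TF_REGULATION, 2, True))
        elif kind == 3:
            # Rank-3 parallel TF edge into a target from a bystander.
            if bystanders:
                x = bystanders[int(rng.integers(0, len(bystanders)))]
                if x != tgt:
                    edges.append(EdgeRecord(x, tgt, TF_REGULATION, 3, True))
        else:
            # Random clutter among bystanders; rank 3 so clutter can never
            # splice decoy fragments into a new valid route at rank <= 2.
            if len(bystanders) >= 2:
                i, j = rng.choice(len(bystanders), size=2, replace=False)
                u, v = bystanders[int(i)], bystanders[int(j)]
                edges.append(
                    EdgeRecord(u, v, BINDING if rng.random() < 0.7 else PTM,
                               3, bool(rng.random() < 0.5))
                )

    net = KnowledgeNetwork(edges, extra_nodes=tuple(bystanders))
    annotations = pd.DataFrame(ann_rows, columns=["node_id", "term"]).drop_duplicates()
    truth = NetworkTruth(paths=paths, sources=sorted(set(sources)),
                         targets=sorted(set(targets)))
    return net, annotations, truth


def simulate_hub_network(
    n_targets: int = 5,
    n_sources: int = 3,
    n_decoy_regulators: int = 3,
    seed: int = 123,
) -> tuple[KnowledgeNetwork, pd.DataFrame, NetworkTruth]:
    """Network with one dominant planted hub regulating ``n_targets`` genes.

    Sources bind the hub, which transcriptionally regulates every target;
    decoy regulators each reach a single target through an equally short
    route, so the hub must win the (n_distinct_targets, n_path_occurrences)
    ranking without winning by default.
    """
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    rng = np.random.default_rng([seed, 4])
    n_nodes = 1 + n_sources + n_targets + n_decoy_regulators
    ids = [f"H{i:03d}" for i in range(n_nodes)]
    rng.shuffle(ids)
    pool = iter(ids)
    hub = next(pool)
    sources = [next(pool) for _ in range(n_sources)]
    targets = [next(pool) for _ in range(n_targets)]
    decoys = [next(pool) for _ in range(n_decoy_regulators)]

    edges: list[EdgeRecord] = []
    paths: list[RegulatoryPath] = []
    for s in sources:
        edges.append(EdgeRecord(s, hub, BINDING, int(rng.integers(0, 3)), False))
    hub_tf = {t: EdgeRecord(hub, t, TF_REGULATION, int(rng.integers(0, 3)), True)
              for t in targets}
    edges.extend(hub_tf.values())
    for s in sources:
        bind = next(e for e in edges if e.etype == BINDING and e.src == s)
        for t in targets:
            paths.append(
                RegulatoryPath(nodes=(s, hub, t), edges=(bind, hub_tf[t]))
            )
    for i, d in enumerate(decoys):
        t = targets[i % n_targets]
        s = sources[i % n_sources]
        e1 = EdgeRecord(s, d, BINDING, int(rng.integers(0, 3)), False)
        e2 = EdgeRecord(d, t, TF_REGULATION, int(rng.integers(0, 3)), True)
        edges.extend([e1, e2])
        paths.append(RegulatoryPath(nodes=(s, d, t), edges=(e1, e2)))

    ann_rows = [dict(node_id=s, term="30.3") for s in sources]
    net = KnowledgeNetwork(edges)
    annotations = pd.DataFrame(ann_rows, columns=["node_id", "term"])
    truth = NetworkTruth(paths=paths, sources=sorted(sources),
                         targets=sorted(targets), hub=hub)
    return net, annotations, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables

REFERENCE_GENES = ("REF_ACTIN", "REF_GAPDH")
_REF_BASE_CT = {"REF_ACTIN": 17.0, "REF_GAPDH": 19.0}
_COND_LFC_COLUMN = {"h2o2": "lfc_h2o2", "lacl3": "lfc_lacl3", "comb": "lfc_combined"}


def simulate_ct_table(
    truth: pd.DataFrame,
    n_genes_qpcr: int = 10,
    ct_noise_sd: float = 0.0,
    seed: int = 123,
    n_reps: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Ct table whose noiseless 2^-ddCt equals 2^(planted lfc) per contrast.

    Target genes are drawn from the non-NULL planted genes; two reference
    genes have condition-invariant expected Ct.  One PCR cycle corresponds to
    a twofold template difference, so the treated Ct is the control Ct minus
    the planted log2FC.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng([seed, 5])
    candidates = truth[truth["true_class"] != NULL]
    if len(candidates) < n_genes_qpcr:
        raise ValueError("not enough non-NULL genes in truth for the qPCR panel")
    pick = rng.choice(len(candidates), size=n_genes_qpcr, replace=False)
    panel = candidates.iloc[np.sort(pick)]

    rows = []
    for _, g in panel.iterrows():
        base_ct = float(rng.uniform(22.0, 28.0))
        for cond in CONDITIONS:
            lfc = 0.0 if cond == "ctrl" else float(g[_COND_LFC_COLUMN[cond]])
            for rep in range(1, n_reps + 1):
                rows.append(
                    dict(
                        gene_id=g["gene_id"],
                        sample_id=f"{cond}_{rep}",
                        condition=cond,
                        replicate=rep,
                        ct=base_ct - lfc + rng.normal(0, ct_noise_sd),
                    )
                )
    for ref in REFERENCE_GENES:
        for cond in CONDITIONS:
            for rep in range(1, n_reps + 1):
                rows.append(
                    dict(
                        gene_id=ref,
                        sample_id=f"{cond}_{rep}",
                        condition=cond,
                        replicate=rep,
                        ct=_REF_BASE_CT[ref] + rng.normal(0, ct_noise_sd),
                    )
                )
    ct = pd.DataFrame(rows)
    return ct, list(REFERENCE_GENES)
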