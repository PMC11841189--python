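"""Readers/writers for the tables and graphs the pipeline touches.

All tabular inputs are tab-separated with a header (the one exception is the
qPCR Ct table, which is CSV).  Gene and node identifiers are opaque strings —
no accession-format validation is applied, so synthetic identifiers pass.
Every parse failure is logged with a count; silent drops are forbidden.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .network_paths import (
    BINDING,
    EDGE_TYPES,
    OTHER,
    PTM,
    TF_REGULATION,
    EdgeRecord,
    KnowledgeNetwork,
    MergedPathNetwork,
)

logger = logging.getLogger(__name__)

#: Contrast identifiers: each treatment versus the water control.
CONTRAST_H2O2 = "H2O2_vs_ctrl"
CONTRAST_COMBINED = "H2O2LaCl3_vs_ctrl"
CONTRAST_LACL3 = "LaCl3_vs_ctrl"
CONTRASTS = (CONTRAST_H2O2, CONTRAST_COMBINED, CONTRAST_LACL3)

DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and sizes.

    fdr_cutoff/lfc_cutoff gate DEG calling (FDR < 0.01, |log2FC| >= 0.5);
    delta_cutoff is the log2FC-difference threshold marking a Ca2+-modulated
    response (1.0, i.e. a twofold change in fold change); max_path_len and
    max_rank constrain knowledge-network path extraction; gap_B is the number
    of gap-statistic reference datasets.
    """

    fdr_cutoff: float = 0.01
    lfc_cutoff: float = 0.5
    delta_cutoff: float = 1.0
    max_path_len: int = 3
    max_rank: int = 2
    gap_B: int = 100
    seed: int = 123
    filter_mode: str = "identity"  # or "same_direction"
    h2o2_deg_source: str = "computed"  # or "external"

    def __post_init__(self) -> None:
        for name in ("fdr_cutoff", "lfc_cutoff", "delta_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("max_path_len", "gap_B"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.max_rank < 0:
            raise ValueError("max_rank must be >= 0")
        if self.filter_mode not in ("identity", "same_direction"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load config from a YAML mapping; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# DE tables


def read_de_table(path: str | Path, contrast_id: str) -> pd.DataFrame:
    """Read a per-contrast differential-expression table.

    Requires columns gene_id, log2fc, pvalue, fdr (extra columns ignored).
    Rows with unparseable numerics are dropped with a logged warning; a
    duplicated gene_id is an error.  The contrast id is stored in
    ``df.attrs["contrast_id"]``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in DE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"DE table {path} is missing required column: {col}")
    df = df.loc[:, list(DE_COLUMNS)].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    if df["gene_id"].isna().any() or (df["gene_id"] == "nan").any():
        raise ValueError(f"DE table {path} has missing gene_id values")
    for col in ("log2fc", "pvalue", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["log2fc", "pvalue", "fdr"]].isna().any(axis=1)
    if bad.any():
        logger.warning(
            "DE table %s: dropped %d rows with unparseable numerics (first: %s)",
            path,
            int(bad.sum()),
            df.loc[bad, "gene_id"].iloc[0],
        )
        df = df[~bad].reset_index(drop=True)
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"DE table {path} has duplicate gene_id: {df.loc[dup, 'gene_id'].iloc[0]}"
        )
    df.attrs["contrast_id"] = contrast_id
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(DE_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Knowledge network

#: Hook for adapting third-party edge-type vocabularies (e.g. a real CKN
#: export) onto the canonical tokens.  Matching is case-insensitive.
DEFAULT_ETYPE_MAP = {t.lower(): t for t in EDGE_TYPES}

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def read_network(
    edges_path: str | Path,
    annotations_path: str | Path | None = None,
    etype_map: dict[str, str] | None = None,
) -> tuple[KnowledgeNetwork, pd.DataFrame | None]:
    """Read an edge TSV (src, dst, etype, rank, directed) into a network.

    Unknown edge types collapse to OTHER with a warning; self-loop rows are
    rejected with a warning; an empty edge file is an error.  Undirected
    transcriptional-regulation rows are an input error.  Returns the network
    and, if given, the node-annotation table.
    """
    df = pd.read_csv(edges_path, sep="\t")
    for col in ("src", "dst", "etype", "rank", "directed"):
        if col not in df.columns:
            raise ValueError(f"edge table {edges_path} missing column: {col}")
    if df.empty:
        raise ValueError(f"edge table {edges_path} is empty")
    mapping = dict(DEFAULT_ETYPE_MAP)
    if etype_map:
        mapping.update({k.lower(): v for k, v in etype_map.items()})
    edges: list[EdgeRecord] = []
    n_self = n_unknown = 0
    for row in df.itertuples(index=False):
        src, dst = str(row.src), str(row.dst)
        if src == dst:
            n_self += 1
            continue
        etype = mapping.get(str(row.etype).lower())
        if etype is None:
            n_unknown += 1
            etype = OTHER
        token = str(row.directed).strip().lower()
        if token in _TRUTHY:
            directed = True
        elif token in _FALSY:
            directed = False
        else:
            raise ValueError(f"unparseable directed flag {row.directed!r}")
        edges.append(
            EdgeRecord(src=src, dst=dst, etype=etype, rank=int(row.rank),
                       directed=directed)
        )
    if n_self:
        logger.warning("edge table %s: rejected %d self-loop rows", edges_path, n_self)
    if n_unknown:
        logger.warning(
            "edge table %s: %d rows with unknown etype mapped to OTHER",
            edges_path,
            n_unknown,
        )
    net = KnowledgeNetwork(edges)
    ann = read_annotations(annotations_path) if annotations_path else None
    return net, ann


def write_network(net: KnowledgeNetwork, path: str | Path) -> None:
    rows = [
        dict(src=e.src, dst=e.dst, etype=e.etype, rank=e.rank,
             directed=str(e.directed).lower())
        for e in net.edges
    ]
    pd.DataFrame(rows, columns=["src", "dst", "etype", "rank", "directed"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Node-annotation TSV (node_id, term); duplicate pairs are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("node_id", "term"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} missing column: {col}")
    n0 = len(df)
    df = df.drop_duplicates(subset=["node_id", "term"]).reset_index(drop=True)
    if len(df) < n0:
        logger.warning("annotation table %s: removed %d duplicate pairs",
                       path, n0 - len(df))
    return df[["node_id", "term"]]


def read_orthologs(path: str | Path) -> pd.DataFrame:
    """Ortholog best-hit TSV (query, subject, evalue, bitscore)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("query", "subject", "evalue", "bitscore"):
        if col not in df.columns:
            raise ValueError(f"ortholog table {path} missing column: {col}")
    df = df[["query", "subject", "evalue", "bitscore"]].copy()
    df["evalue"] = pd.to_numeric(df["evalue"])
    df["bitscore"] = pd.to_numeric(df["bitscore"])
    if (df["evalue"] < 0).any():
        raise ValueError("evalue must be >= 0")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """qPCR Ct CSV (gene_id, sample_id, condition, replicate, ct)."""
    df = pd.read_csv(path)
    for col in ("gene_id", "sample_id", "condition", "replicate", "ct"):
        if col not in df.columns:
            raise ValueError(f"Ct table {path} missing column: {col}")
    df["ct"] = pd.to_numeric(df["ct"])
    if not df["ct"].notna().all():
        raise ValueError("Ct values must be finite")
    return df


# ---------------------------------------------------------------------------
# Merged-network exports


def write_network_exports(
    net: MergedPathNetwork,
    basepath: str | Path,
    cluster_labels: dict[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write SIF and GraphML exports of a merged path network.

    The SIF file has one ``src <tab> etype <tab> dst`` line per merged edge;
    the GraphML carries node attributes (role, cluster) and edge attributes
    (etype, rank).  Output is sorted, hence byte-stable across runs for
    identical input.  An empty network is an error and writes nothing.
    """
    if not net.edges:
        raise ValueError("refusing to export an empty merged network")
    basepath = Path(basepath)
    sif_path = basepath.with_suffix(".sif")
    graphml_path = basepath.with_suffix(".graphml")
    cluster_labels = cluster_labels or {}

    sif_lines = sorted(f"{e.src}\t{e.etype}\t{e.dst}" for e in net.edges)
    sif_path.write_text("\n".join(sif_lines) + "\n")

    g = nx.MultiDiGraph()
    for n in sorted(net.nodes):
        g.add_node(n, role=net.node_roles.get(n, "intermediate"),
                   cluster=str(cluster_labels.get(n, "")))
    for e in sorted(net.edges, key=lambda e: (e.src, e.dst, e.etype, e.rank)):
        g.add_edge(e.src, e.dst, etype=e.etype, rank=int(e.rank),
                   directed=str(e.directed).lower())
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    graphml_path.write_bytes(buf.getvalue())
    return sif_path, graphml_path


def write_paths_table(net: MergedPathNetwork, path: str | Path) -> None:
    """Flat TSV of retained paths: target, length, node route, edge types."""
    rows = []
    for tgt in sorted(net.paths_by_target):
        for p in net.paths_by_target[tgt]:
            rows.append(
                dict(
                    target=tgt,
                    source=p.source,
                    length=p.length,
                    nodes="->".join(p.nodes),
                    etypes=",".join(e.etype for e in p.edges),
                    ranks=",".join(str(e.rank) for e in p.edges),
                )
            )
    pd.DataFrame(
        rows, columns=["target", "source", "length", "nodes", "etypes", "ranks"]
    ).to_csv(path, sep="\t", index=False)


def write_hub_table(net: MergedPathNetwork, path: str | Path) -> None:
    rows = [
        dict(
            node=n,
            role=net.node_roles[n],
            n_path_occurrences=net.hub_scores[n][0],
            n_distinct_targets=net.hub_scores[n][1],
        )
        for n in net.hub_ranking
    ]
    pd.DataFrame(
        rows, columns=["node", "role", "n_path_occurrences", "n_distinct_targets"]
    ).to_csv(path, sep="\t", index=False)
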