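"""Constrained regulatory-path extraction from a molecular-interaction knowledge network.

The network is a CKN/SKM-style knowledge graph: typed edges (transcriptional
regulation, post-translational modification, binding, other), each carrying a
reliability rank (0 = best) and a directedness flag.  The biological question
is which annotated "source" genes (e.g. Ca2+-signaling components) can reach a
differentially regulated "target" gene through a short, mechanistically
plausible route.  A route is accepted when it

* has at most ``max_len`` edges and is a simple path ending at the target,
* contains exactly one transcriptional-regulation edge, which is the final
  edge (the target must be directly transcriptionally regulated),
* respects edge direction (binding edges are traversable both ways),
* uses only edges at or below the reliability rank cutoff.

Per target, only paths of the minimal realized length are kept (the
"closest source" reduction); paths for all targets are then merged into a
single network in which recurrent intermediate regulators are scored as hubs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical edge-type tokens.  Input files may use any case; unknown types
#: collapse to OTHER.  A mapping hook in :func:`cadep.io_formats.read_network`
#: adapts third-party vocabularies to these tokens.
TF_REGULATION = "TF_REGULATION"
PTM = "PTM"
BINDING = "BINDING"
OTHER = "OTHER"
EDGE_TYPES = (TF_REGULATION, PTM, BINDING, OTHER)


@dataclass(frozen=True)
class EdgeRecord:
    """One interaction: ``src`` acts on ``dst`` (or binds it, if undirected)."""

    src: str
    dst: str
    etype: str
    rank: int
    directed: bool

    def __post_init__(self) -> None:
        if self.src == self.dst:
            raise ValueError(f"self-loop edge not allowed: {self.src}")
        if self.etype not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.etype!r}")
        if self.rank < 0:
            raise ValueError("rank must be >= 0")
        if self.etype == TF_REGULATION and not self.directed:
            raise ValueError(
                f"TF_REGULATION edge {self.src}->{self.dst} must be directed"
            )


class KnowledgeNetwork:
    """Typed, ranked interaction graph.

    Undirected edges are stored once but traversable in both directions.
    Parallel edges between the same node pair with different types are kept
    as distinct edges (a pair may both bind and regulate).
    """

    def __init__(self, edges: list[EdgeRecord], extra_nodes: tuple[str, ...] = ()):
        self.edges: list[EdgeRecord] = list(edges)
        self.nodes: set[str] = set(extra_nodes)
        for e in self.edges:
            self.nodes.add(e.src)
            self.nodes.add(e.dst)

    def __len__(self) -> int:
        return len(self.edges)

    def arc_adjacency(self) -> dict[str, list[tuple[str, int]]]:
        """Adjacency over traversable arcs: node -> [(neighbour, edge index)].

        Directed edges yield one arc; undirected edges yield one arc each way
        pointing at the same stored :class:`EdgeRecord`.
        """
        adj: dict[str, list[tuple[str, int]]] = {n: [] for n in self.nodes}
        for i, e in enumerate(self.edges):
            adj[e.src].append((e.dst, i))
            if not e.directed:
                adj[e.dst].append((e.src, i))
        return adj

    def to_multidigraph(self) -> nx.MultiDiGraph:
        """Arc expansion as a :class:`networkx.MultiDiGraph` (undirected edges
        appear as two antiparallel arcs sharing attributes)."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for i, e in enumerate(self.edges):
            attrs = dict(etype=e.etype, rank=e.rank, directed=e.directed, index=i)
            g.add_edge(e.src, e.dst, **attrs)
            if not e.directed:
                g.add_edge(e.dst, e.src, **attrs)
        return g


@dataclass(frozen=True)
class RegulatoryPath:
    """A source-to-target route satisfying all path constraints."""

    nodes: tuple[str, ...]
    edges: tuple[EdgeRecord, ...]

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def length(self) -> int:
        return len(self.edges)

    def validate(self, max_len: int = 3, max_rank: int | None = None) -> None:
        """Structurally assert every path invariant; raises AssertionError."""
        assert 1 <= self.length <= max_len, "path length out of bounds"
        assert len(self.nodes) == self.length + 1
        assert len(set(self.nodes)) == len(self.nodes), "path is not simple"
        tf_positions = [
            i for i, e in enumerate(self.edges) if e.etype == TF_REGULATION
        ]
        assert tf_positions == [self.length - 1], (
            "exactly one TF edge required, in final position"
        )
        for i, e in enumerate(self.edges):
            u, v = self.nodes[i], self.nodes[i + 1]
            if e.directed:
                assert (e.src, e.dst) == (u, v), "directed edge traversed backwards"
            else:
                assert {e.src, e.dst} == {u, v}, "edge does not join path nodes"
            if max_rank is not None:
                assert e.rank <= max_rank, "edge rank above cutoff"


@dataclass
class MergedPathNetwork:
    """Union of retained paths across targets, with node roles and hub scores.

    ``hub_scores`` maps node -> (n_path_occurrences, n_distinct_targets);
    ``hub_ranking`` is sorted by (n_distinct_targets, n_path_occurrences,
    node id) descending, so the dominant regulator comes first.
    """

    paths_by_target: dict[str, list[RegulatoryPath]]
    nodes: list[str] = field(default_factory=list)
    edges: list[EdgeRecord] = field(default_factory=list)
    node_roles: dict[str, str] = field(default_factory=dict)
    hub_scores: dict[str, tuple[int, int]] = field(default_factory=dict)
    hub_ranking: list[str] = field(default_factory=list)

    def all_paths(self) -> list[RegulatoryPath]:
        out: list[RegulatoryPath] = []
        for t in sorted(self.paths_by_target):
            out.extend(self.paths_by_target[t])
        return out


# ---------------------------------------------------------------------------
# Filtering and selection


def filter_by_rank(net: KnowledgeNetwork, max_rank: int) -> KnowledgeNetwork:
    """Keep only edges with reliability rank <= ``max_rank``; drop isolated nodes."""
    if max_rank < 0:
        raise ValueError("max_rank must be >= 0")
    kept = [e for e in net.edges if e.rank <= max_rank]
    if not kept:
        logger.warning(
            "rank filter (<= %d) removed all %d edges", max_rank, len(net.edges)
        )
    return KnowledgeNetwork(kept)


def select_by_terms(
    net: KnowledgeNetwork, annotations: pd.DataFrame, terms: list[str]
) -> set[str]:
    """Nodes whose annotation term equals, or is a dot-extension of, a query term.

    Term matching uses dot-boundary prefix semantics mirroring hierarchical
    functional bins: query "30.3" matches "30.3" and "30.3.1" but not "30.31".
    """
    if not terms:
        raise ValueError("terms must be nonempty")
    selected: set[str] = set()
    for node_id, term in annotations[["node_id", "term"]].itertuples(index=False):
        t = str(term)
        for q in terms:
            if t == q or t.startswith(q + "."):
                if node_id in net.nodes:
                    selected.add(str(node_id))
                break
    if not selected:
        logger.warning("no network nodes matched annotation terms %s", terms)
    return selected


# ---------------------------------------------------------------------------
# Constrained path search


def constrained_paths(
    net: KnowledgeNetwork,
    sources: set[str],
    target: str,
    max_len: int = 3,
    max_rank: int | None = None,
) -> list[RegulatoryPath]:
    """All valid source->target paths, reduced to the closest source(s).

    Enumerates simple paths of length <= ``max_len`` from any source to the
    target in which a transcriptional-regulation edge occurs exactly once, as
    the final edge.  Because a valid path must end with a TF edge into the
    target, the search only ever traverses TF edges when they complete a path
    and never enters the target through a non-TF edge.  The returned list is
    restricted to the minimal realized length for this target and sorted
    deterministically (node tuple, then edge attributes).
    """
    if target not in net.nodes:
        raise ValueError(f"target {target!r} not in network")
    adj = net.arc_adjacency()
    edges = net.edges
    found: list[RegulatoryPath] = []

    def dfs(node: str, path_nodes: list[str], path_edges: list[int]) -> None:
        if len(path_edges) == max_len:
            return
        for nbr, ei in adj[node]:
            rec = edges[ei]
            if max_rank is not None and rec.rank > max_rank:
                continue
            if rec.etype == TF_REGULATION:
                # TF edges are only usable as the terminal hop into the target.
                if nbr == target:
                    found.append(
                        RegulatoryPath(
                            nodes=tuple(path_nodes + [nbr]),
                            edges=tuple(edges[j] for j in path_edges + [ei]),
                        )
                    )
                continue
            if nbr == target or nbr in path_nodes:
                continue
            path_nodes.append(nbr)
            path_edges.append(ei)
            dfs(nbr, path_nodes, path_edges)
            path_nodes.pop()
            path_edges.pop()

    for s in sorted(sources):
        if s == target or s not in net.nodes:
            continue
        dfs(s, [s], [])

    if not found:
        return []
    shortest = min(p.length for p in found)
    kept = [p for p in found if p.length == shortest]
    kept = sorted(
        set(kept),
        key=lambda p: (p.nodes, tuple((e.etype, e.rank, e.directed) for e in p.edges)),
    )
    for p in kept:
        p.validate(max_len=max_len, max_rank=max_rank)
    return kept


def extract_paths(
    net: KnowledgeNetwork,
    sources: set[str],
    targets: list[str],
    max_len: int = 3,
    max_rank: int | None = None,
) -> dict[str, list[RegulatoryPath]]:
    """Run :func:`constrained_paths` per target; targets without valid paths
    are reported with an empty list."""
    out: dict[str, list[RegulatoryPath]] = {}
    for t in sorted(set(targets)):
        if t not in net.nodes:
            logger.warning("target %s absent from network", t)
            out[t] = []
            continue
        out[t] = constrained_paths(net, sources, t, max_len=max_len, max_rank=max_rank)
    return out


# ---------------------------------------------------------------------------
# Merging, hubs, orthologs


def merge_paths(
    paths_by_target: dict[str, list[RegulatoryPath]]
) -> MergedPathNetwork:
    """Merge retained paths into one network and score hubs.

    A node's hub score is (number of retained paths containing it, number of
    distinct targets with at least one retained path containing it).  Roles:
    targets > TF-hub (regulator on the terminal TF edge of paths to >= 2
    targets) > source > intermediate.
    """
    merged = MergedPathNetwork(paths_by_target={
        t: list(ps) for t, ps in paths_by_target.items() if ps
    })
    occurrences: dict[str, int] = defaultdict(int)
    targets_by_node: dict[str, set[str]] = defaultdict(set)
    tf_targets: dict[str, set[str]] = defaultdict(set)
    node_set: set[str] = set()
    edge_set: dict[tuple, EdgeRecord] = {}
    source_nodes: set[str] = set()
    target_nodes: set[str] = set()

    for tgt, paths in merged.paths_by_target.items():
        target_nodes.add(tgt)
        for p in paths:
            source_nodes.add(p.source)
            tf_targets[p.nodes[-2]].add(tgt)
            for n in p.nodes:
                occurrences[n] += 1
                targets_by_node[n].add(tgt)
                node_set.add(n)
            for e in p.edges:
                edge_set[(e.src, e.dst, e.etype, e.rank, e.directed)] = e

    merged.nodes = sorted(node_set)
    merged.edges = [edge_set[k] for k in sorted(edge_set)]
    for n in merged.nodes:
        if n in target_nodes:
            role = "target"
        elif len(tf_targets.get(n, ())) >= 2:
            role = "TF-hub"
        elif n in source_nodes:
            role = "source"
        else:
            role = "intermediate"
        merged.node_roles[n] = role
    merged.hub_scores = {
        n: (occurrences[n], len(targets_by_node[n])) for n in merged.nodes
    }
    merged.hub_ranking = sorted(
        merged.nodes,
        key=lambda n: (len(targets_by_node[n]), occurrences[n], n),
        reverse=True,
    )
    return merged


def extract_hub_subnetwork(merged: MergedPathNetwork, hub: str) -> MergedPathNetwork:
    """Union of all retained paths passing through ``hub``."""
    if hub not in merged.hub_scores:
        raise ValueError(f"hub {hub!r} not in merged network")
    sub = {
        t: [p for p in ps if hub in p.nodes]
        for t, ps in merged.paths_by_target.items()
    }
    return merge_paths({t: ps for t, ps in sub.items() if ps})


UNMAPPED = "UNMAPPED"


def map_orthologs(
    genes: list[str], hits: pd.DataFrame, evalue_cutoff: float = 1e-30
) -> dict[str, str]:
    """Best-hit ortholog per query gene under an E-value cutoff.

    Hits with E-value <= cutoff compete; the best has minimal E-value, ties
    broken by maximal bitscore, then lexicographically smallest subject id.
    Queries with no passing hit map to ``UNMAPPED``; many-to-one mappings are
    allowed.
    """
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    passing = hits[hits["evalue"] <= evalue_cutoff]
    best: dict[str, tuple[float, float, str]] = {}
    for q, s, ev, bs in passing[["query", "subject", "evalue", "bitscore"]].itertuples(
        index=False
    ):
        key = (float(ev), -float(bs), str(s))
        if q not in best or key < best[q]:
            best[q] = key
    return {g: (best[g][2] if g in best else UNMAPPED) for g in genes}
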