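"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementations: BH by the
literal step-up formula, k-means by exhaustive partition enumeration, and
constrained path extraction by enumerating every simple node sequence and
every parallel-edge combination, then applying the path predicates.
"""

from __future__ import annotations

import itertools

import numpy as np

from cadep.network_paths import TF_REGULATION, KnowledgeNetwork


def naive_bh(pvalues: np.ndarray) -> np.ndarray:
    """Step-up BH: sort, p * m / rank, cumulative min from the largest rank."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, p[order[i]] * m / rank)
        adjusted[order[i]] = running
    return adjusted


def brute_force_kmeans_ss(X: np.ndarray, k: int) -> float:
    """Minimal within-cluster SS over all assignments of n points to k labels."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    labels = np.array(list(itertools.product(range(k), repeat=n)))
    x2 = (X**2).sum(axis=1)
    total = np.zeros(len(labels))
    for c in range(k):
        mask = labels == c
        cnt = mask.sum(axis=1)
        s1 = mask @ X
        s2 = mask @ x2
        with np.errstate(invalid="ignore", divide="ignore"):
            ss = s2 - (s1**2).sum(axis=1) / cnt
        total += np.where(cnt > 0, ss, 0.0)
    return float(total.min())


def _arcs(net: KnowledgeNetwork) -> dict[tuple[str, str], list[int]]:
    """Usable arcs (u, v) -> indices of edges traversable from u to v."""
    arcs: dict[tuple[str, str], list[int]] = {}
    for i, e in enumerate(net.edges):
        arcs.setdefault((e.src, e.dst), []).append(i)
        if not e.directed:
            arcs.setdefault((e.dst, e.src), []).append(i)
    return arcs


def enumerate_constrained_paths(
    net: KnowledgeNetwork,
    sources: set[str],
    target: str,
    max_len: int = 3,
    max_rank: int | None = None,
):
    """All valid paths as (node tuple, edge-record tuple), closest-source
    reduced, via exhaustive enumeration of node sequences."""
    arcs = _arcs(net)
    others = sorted(net.nodes - {target})
    results = []
    for length in range(1, max_len + 1):
        for src in sorted(sources & net.nodes - {target}):
            middles = [n for n in others if n != src]
            for mid in itertools.permutations(middles, length - 1):
                nodes = (src, *mid, target)
                hops = list(zip(nodes[:-1], nodes[1:]))
                if any(h not in arcs for h in hops):
                    continue
                for combo in itertools.product(*(arcs[h] for h in hops)):
                    edges = tuple(net.edges[i] for i in combo)
                    if max_rank is not None and any(
                        e.rank > max_rank for e in edges
                    ):
                        continue
                    tf_pos = [
                        j for j, e in enumerate(edges) if e.etype == TF_REGULATION
                    ]
                    if tf_pos != [length - 1]:
                        continue
                    results.append((nodes, edges))
    if not results:
        return []
    shortest = min(len(e) for _, e in results)
    return sorted(
        {r for r in results if len(r[1]) == shortest},
        key=lambda r: (r[0], tuple((e.etype, e.rank, e.directed) for e in r[1])),
    )


def random_small_network(rng: np.random.Generator) -> KnowledgeNetwork:
    """Random mixed-type/rank/direction multigraph with <= 12 nodes, <= 30 edges."""
    from cadep.network_paths import BINDING, OTHER, PTM, EdgeRecord

    n_nodes = int(rng.integers(4, 13))
    nodes = [f"n{i}" for i in range(n_nodes)]
    n_edges = int(rng.integers(4, 31))
    etypes = [TF_REGULATION, PTM, BINDING, OTHER]
    edges = []
    for _ in range(n_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        etype = etypes[int(rng.integers(0, 4))]
        directed = True if etype in (TF_REGULATION, PTM) else bool(rng.random() < 0.5)
        edges.append(
            EdgeRecord(nodes[int(u)], nodes[int(v)], etype,
                       int(rng.integers(0, 4)), directed)
        )
    return KnowledgeNetwork(edges, extra_nodes=tuple(nodes))
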