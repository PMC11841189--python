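import numpy as np
import pandas as pd
import pytest

from cadep.network_paths import (
    BINDING,
    PTM,
    TF_REGULATION,
    UNMAPPED,
    EdgeRecord,
    KnowledgeNetwork,
    RegulatoryPath as RegPath,
    constrained_paths,
    extract_hub_subnetwork,
    extract_paths,
    filter_by_rank,
    map_orthologs,
    merge_paths,
    select_by_terms,
)
from helpers_oracles import enumerate_constrained_paths, random_small_network


class TestEdgeRecord:
    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            EdgeRecord("A", "A", BINDING, 0, False)

    def test_undirected_tf_rejected(self):
        with pytest.raises(ValueError):
            EdgeRecord("A", "B", TF_REGULATION, 0, False)


class TestFilterByRank:
    def _net(self, ranks):
        return KnowledgeNetwork(
            [EdgeRecord(f"a{i}", f"b{i}", BINDING, r, False)
             for i, r in enumerate(ranks)]
        )

    def test_rank_two_cutoff(self):
        assert len(filter_by_rank(self._net([0, 1, 2, 3]), 2)) == 3

    def test_rank_zero_only(self):
        assert len(filter_by_rank(self._net([0, 1, 2, 3]), 0)) == 1

    def test_all_filtered_warns(self, caplog):
        with caplog.at_level("WARNING"):
            net = filter_by_rank(self._net([3, 3]), 2)
        assert len(net) == 0 and len(net.nodes) == 0


class TestSelectByTerms:
    def _setup(self, term):
        net = KnowledgeNetwork([EdgeRecord("A", "B", BINDING, 0, False)])
        ann = pd.DataFrame(dict(node_id=["A"], term=[term]))
        return net, ann

    @pytest.mark.parametrize(
        "term,query,selected",
        [
            ("30.3", ["30.3"], True),
            ("30.31", ["30.3"], False),  # dot-boundary rule
            ("34.21.2", ["34.21"], True),
            ("21.1", ["30.3", "34.21"], False),
        ],
    )
    def test_dot_boundary_matching(self, term, query, selected):
        net, ann = self._setup(term)
        got = select_by_terms(net, ann, query)
        assert ("A" in got) == selected

    def test_empty_terms_rejected(self):
        net, ann = self._setup("30.3")
        with pytest.raises(ValueError):
            select_by_terms(net, ann, [])


class TestConstrainedPaths:
    def test_direct_tf_regulation(self):
        net = KnowledgeNetwork([EdgeRecord("S", "T", TF_REGULATION, 0, True)])
        paths = constrained_paths(net, {"S"}, "T")
        assert len(paths) == 1 and paths[0].nodes == ("S", "T")

    def test_two_tf_route_eliminated(self, chain_network):
        paths = constrained_paths(chain_network, {"S"}, "T")
        assert [p.nodes for p in paths] == [("S", "X", "T")]

    def test_final_edge_must_be_tf(self):
        net = KnowledgeNetwork([
            EdgeRecord("S", "X", TF_REGULATION, 0, True),
            EdgeRecord("X", "T", BINDING, 0, False),
        ])
        assert constrained_paths(net, {"S"}, "T") == []

    def test_closest_source_reduction(self):
        net = KnowledgeNetwork([
            EdgeRecord("S1", "T", TF_REGULATION, 0, True),
            EdgeRecord("S2", "X", BINDING, 0, False),
            EdgeRecord("X", "T", TF_REGULATION, 0, True),
        ])
        paths = constrained_paths(net, {"S1", "S2"}, "T")
        assert [p.nodes for p in paths] == [("S1", "T")]

    def test_directed_edges_not_traversed_backwards(self):
        net = KnowledgeNetwork([
            EdgeRecord("X", "S", PTM, 0, True),  # points the wrong way
            EdgeRecord("X", "T", TF_REGULATION, 0, True),
        ])
        assert constrained_paths(net, {"S"}, "T") == []

    def test_undirected_edge_traversable_both_ways(self):
        net = KnowledgeNetwork([
            EdgeRecord("X", "S", BINDING, 0, False),
            EdgeRecord("X", "T", TF_REGULATION, 0, True),
        ])
        paths = constrained_paths(net, {"S"}, "T")
        assert [p.nodes for p in paths] == [("S", "X", "T")]

    def test_missing_target_rejected(self):
        net = KnowledgeNetwork([EdgeRecord("S", "T", TF_REGULATION, 0, True)])
        with pytest.raises(ValueError):
            constrained_paths(net, {"S"}, "Z")

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        """Implementation and brute-force enumeration agree on random
        mixed-direction multigraphs, including closest-source reduction."""
        for _ in range(40):
            net = random_small_network(rng)
            nodes = sorted(net.nodes)
            k = min(3, len(nodes) - 1)
            sources = set(
                np.asarray(nodes, dtype=object)[
                    rng.choice(len(nodes), size=k, replace=False)
                ]
            )
            target = next(n for n in nodes if n not in sources)
            max_rank = int(rng.integers(1, 4))
            got = constrained_paths(net, sources, target, 3, max_rank)
            want = enumerate_constrained_paths(net, sources, target, 3, max_rank)
            assert [(p.nodes, p.edges) for p in got] == want

    def test_rank_filter_commutes_with_extraction(self, rng):
        for _ in range(20):
            net = random_small_network(rng)
            nodes = sorted(net.nodes)
            sources = {nodes[0], nodes[1]}
            target = nodes[-1]
            inline = constrained_paths(net, sources, target, 3, max_rank=2)
            pre = constrained_paths(
                filter_by_rank(net, 2), sources, target, 3
            ) if target in filter_by_rank(net, 2).nodes else []
            assert [p.nodes for p in inline] == [p.nodes for p in pre]


class TestMergeAndHubs:
    def _paths(self):
        e = {}
        e["s1x"] = EdgeRecord("S1", "X", BINDING, 0, False)
        e["xt1"] = EdgeRecord("X", "T1", TF_REGULATION, 0, True)
        e["xt2"] = EdgeRecord("X", "T2", TF_REGULATION, 1, True)
        e["s2x"] = EdgeRecord("S2", "X", PTM, 1, True)
        return {
            "T1": [
                RegPath(("S1", "X", "T1"), (e["s1x"], e["xt1"])),
                RegPath(("S2", "X", "T1"), (e["s2x"], e["xt1"])),
            ],
            "T2": [RegPath(("S1", "X", "T2"), (e["s1x"], e["xt2"]))],
        }

    def test_hub_scores_count_paths_and_targets(self):
        merged = merge_paths(self._paths())
        assert merged.hub_scores["X"] == (3, 2)
        assert merged.hub_ranking[0] == "X"
        assert merged.node_roles["X"] == "TF-hub"
        assert merged.node_roles["T1"] == "target"
        assert merged.node_roles["S1"] == "source"

    def test_disjoint_paths_union(self):
        e1 = EdgeRecord("S1", "A", BINDING, 0, False)
        e2 = EdgeRecord("A", "T1", TF_REGULATION, 0, True)
        e3 = EdgeRecord("S2", "B", BINDING, 0, False)
        e4 = EdgeRecord("B", "T2", TF_REGULATION, 0, True)
        merged = merge_paths({
            "T1": [RegPath(("S1", "A", "T1"), (e1, e2))],
            "T2": [RegPath(("S2", "B", "T2"), (e3, e4))],
        })
        assert merged.hub_scores["A"] == (1, 1)
        assert len(merged.edges) == 4
        assert len(merged.nodes) == 6

    def test_extract_hub_subnetwork_is_paths_through_hub(self):
        merged = merge_paths(self._paths())
        sub = extract_hub_subnetwork(merged, "S2")
        assert sub.nodes == ["S2", "T1", "X"]
        assert all("S2" in p.nodes for p in sub.all_paths())

    def test_missing_hub_rejected(self):
        with pytest.raises(ValueError):
            extract_hub_subnetwork(merge_paths(self._paths()), "ZZ")

    def test_merge_extract_remerge_identity(self, rng):
        """Re-merging the hub subnetworks of every node reproduces the
        original merged network."""
        from cadep.synthetic import simulate_network

        net, ann, truth = simulate_network(40, 5, decoy_density=0.8,
                                           seed=int(rng.integers(0, 2**16)))
        paths = extract_paths(net, set(truth.sources), truth.targets,
                              max_len=3, max_rank=2)
        merged = merge_paths(paths)
        if not merged.nodes:
            pytest.skip("no retained paths for this seed")
        recovered = {}
        for hub in merged.nodes:
            sub = extract_hub_subnetwork(merged, hub)
            for t, ps in sub.paths_by_target.items():
                recovered.setdefault(t, set()).update(ps)
        remerged = merge_paths({t: sorted(ps, key=lambda p: p.nodes)
                                for t, ps in recovered.items()})
        assert remerged.nodes == merged.nodes
        assert set(remerged.edges) == set(merged.edges)
        assert remerged.hub_scores == merged.hub_scores


class TestMapOrthologs:
    hits = pd.DataFrame(
        dict(
            query=["g1", "g1", "g2", "g3", "g3"],
            subject=["AT1", "AT2", "AT3", "AT4", "AT5"],
            evalue=[1e-40, 1e-10, 1e-20, 1e-50, 1e-50],
            bitscore=[200.0, 90.0, 120.0, 290.0, 310.0],
        )
    )

    def test_best_hit_under_cutoff(self):
        got = map_orthologs(["g1"], self.hits)
        assert got == {"g1": "AT1"}

    def test_above_cutoff_unmapped(self):
        assert map_orthologs(["g2"], self.hits)["g2"] == UNMAPPED

    def test_evalue_tie_broken_by_bitscore(self):
        assert map_orthologs(["g3"], self.hits)["g3"] == "AT5"

    def test_unknown_query_unmapped(self):
        assert map_orthologs(["gX"], self.hits)["gX"] == UNMAPPED
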