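"""Minimal connected network construction, pruning minimality and the null."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from aplnet import (
    Interactome,
    build_mcn,
    mcn_significance,
    mcn_statistics,
    prioritize_candidates,
    sample_null,
)
from aplnet.enrichment import EnrichmentResult
from aplnet.network import null_pvalue, write_mcn_graphml, write_mcn_sif


def seed_partition_oracle(graph: nx.Graph, seeds: set, intermediates: set):
    """Independent recomputation of the seed-component partition: seeds
    plus chosen intermediates, keeping only seed-seed and
    intermediate-seed edges."""
    sub = nx.Graph()
    sub.add_nodes_from(seeds)
    for u, v in graph.edges:
        if u in seeds and v in seeds:
            sub.add_edge(u, v)
        elif u in intermediates and v in seeds:
            sub.add_edge(u, v)
        elif v in intermediates and u in seeds:
            sub.add_edge(u, v)
    return frozenset(
        frozenset(c & seeds) for c in nx.connected_components(sub) if c & seeds
    )


class TestBuildMcn:
    def test_two_seeds_bridged_by_intermediate(self):
        """Two seeds with no direct interaction connect through a shared
        neighbor, which is retained as an intermediate."""
        net = Interactome.from_edges([("PTPN11", "STAT1"), ("STAT1", "PML")])
        result = build_mcn({"PTPN11", "PML"}, net)
        assert result.intermediates == ["STAT1"]
        assert result.components == 1
        assert result.connected_seed_count == 2
        assert result.roles["STAT1"] == "intermediate"

    def test_seed_triangle_has_no_intermediates(self):
        net = Interactome.from_edges([("A", "B"), ("B", "C"), ("A", "C"), ("A", "X")])
        result = build_mcn({"A", "B", "C"}, net)
        assert result.intermediates == []
        assert sorted(result.edges) == [("A", "B"), ("A", "C"), ("B", "C")]
        assert result.components == 1

    def test_missing_seeds_reported_not_fatal(self):
        net = Interactome.from_edges([("A", "B")])
        result = build_mcn({"A", "B", "ZZ"}, net)
        assert result.missing == ["ZZ"]

    def test_all_seeds_missing_is_error(self):
        net = Interactome.from_edges([("A", "B")])
        with pytest.raises(ValueError, match="ZZ"):
            build_mcn({"ZZ"}, net)

    def test_isolated_seeds_counted_as_singleton_components(self):
        net = Interactome.from_edges([("A", "B"), ("C", "D")])
        result = build_mcn({"A", "C"}, net)
        assert result.components == 2
        assert result.connected_seed_count == 0

    def test_deterministic_and_input_order_invariant(self, rng):
        edges = [
            (f"N{int(i)}", f"N{int(j)}")
            for i, j in rng.integers(0, 20, size=(60, 2))
            if i != j
        ]
        net1 = Interactome.from_edges(edges)
        net2 = Interactome.from_edges(list(reversed(edges)))
        seeds = ["N1", "N3", "N5", "N7", "N11"]
        seeds = [s for s in seeds if s in net1.adjacency]
        r1 = build_mcn(seeds, net1)
        r2 = build_mcn(list(reversed(seeds)), net2)
        assert r1.intermediates == r2.intermediates
        assert r1.edges == r2.edges

    def test_every_intermediate_touches_two_seeds_and_every_edge_a_seed(self, rng):
        for trial in range(20):
            graph = nx.gnp_random_graph(15, 0.25, seed=int(rng.integers(2**31)))
            graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
            net = Interactome(graph)
            seeds = {f"N{i}" for i in rng.choice(15, size=5, replace=False)}
            result = build_mcn(seeds, net)
            seed_set = set(result.seeds)
            adj = {u: set() for u in seed_set | set(result.intermediates)}
            for u, v in result.edges:
                assert u in seed_set or v in seed_set
                adj[u].add(v)
                adj[v].add(u)
            for v in result.intermediates:
                assert len(adj[v] & seed_set) >= 2

    def test_pruned_intermediates_are_minimum_cardinality(self, rng):
        """Exhaustive oracle: over 200 random graphs on <= 12 nodes no
        smaller intermediate subset reproduces the seed-component
        partition, and removing any retained intermediate changes it."""
        checked = 0
        trial = 0
        while checked < 200:
            trial += 1
            n = int(rng.integers(6, 13))
            graph = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31)))
            graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
            net = Interactome(graph)
            k = int(rng.integers(2, 6))
            seeds = {f"N{int(i)}" for i in rng.choice(n, size=min(k, n), replace=False)}
            result = build_mcn(seeds, net)
            full = build_mcn(seeds, net, prune=False)
            target = seed_partition_oracle(graph, set(result.seeds),
                                           set(full.intermediates))
            got = seed_partition_oracle(graph, set(result.seeds),
                                        set(result.intermediates))
            assert got == target
            best = None
            universe = full.intermediates
            for size in range(len(universe) + 1):
                for subset in combinations(universe, size):
                    if seed_partition_oracle(graph, set(result.seeds),
                                             set(subset)) == target:
                        best = size
                        break
                if best is not None:
                    break
            assert len(result.intermediates) == best
            for v in result.intermediates:
                reduced = set(result.intermediates) - {v}
                assert seed_partition_oracle(graph, set(result.seeds), reduced) != target
            checked += 1

    def test_statistics_match_recount_from_edge_list(self, rng):
        graph = nx.gnp_random_graph(30, 0.15, seed=7)
        graph = nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes})
        net = Interactome(graph)
        seeds = {f"N{int(i)}" for i in rng.choice(30, size=8, replace=False)}
        result = build_mcn(seeds, net)
        stats = mcn_statistics(result)
        degree = {s: 0 for s in result.seeds}
        for u, v in result.edges:
            if u in degree:
                degree[u] += 1
            if v in degree:
                degree[v] += 1
        assert stats["mean_seed_degree"] == pytest.approx(
            sum(degree.values()) / len(result.seeds)
        )
        assert stats["components"] == len(
            seed_partition_oracle(graph, set(result.seeds), set(result.intermediates))
        )


@pytest.fixture(scope="module")
def net():
    graph = nx.gnp_random_graph(80, 0.05, seed=21)
    return Interactome(nx.relabel_nodes(graph, {i: f"N{i}" for i in graph.nodes}))


class TestNull:
    def test_addone_bound_when_observed_exceeds_all_draws(self):
        assert null_pvalue(10.0, [1.0] * 99, "connected_seed_count") == pytest.approx(0.01)

    def test_component_statistic_reverses_tail(self):
        assert null_pvalue(1.0, [5.0] * 99, "components") == pytest.approx(0.01)

    def test_same_seed_gives_bit_identical_null(self, net):
        a = sample_null(net, seed_size=8, M=20, rng_seed=77)
        b = sample_null(net, seed_size=8, M=20, rng_seed=77)
        assert a == b

    def test_different_seed_gives_different_null(self, net):
        a = sample_null(net, seed_size=8, M=20, rng_seed=1)
        b = sample_null(net, seed_size=8, M=20, rng_seed=2)
        assert a != b

    def test_degree_matched_mode_respects_bins(self, net):
        seeds = net.nodes[:6]
        draws = sample_null(net, seed_size=6, M=5, mode="degree_matched",
                            rng_seed=3, observed_seeds=seeds)
        assert len(draws) == 5

    def test_null_summary_p_in_addone_bounds(self, net):
        summary = mcn_significance(net.nodes[:8], net, M=49, rng_seed=5)
        assert 1 / 50 <= summary.p_value <= 1.0
        assert len(summary.null_values) == 49

    def test_exports(self, net, tmp_path):
        result = build_mcn(net.nodes[:8], net)
        write_mcn_sif(result, tmp_path / "mcn.sif")
        write_mcn_graphml(result, tmp_path / "mcn.graphml")
        assert (tmp_path / "mcn.sif").exists()
        back = nx.read_graphml(tmp_path / "mcn.graphml")
        assert set(nx.get_node_attributes(back, "role").values()) <= {
            "seed", "intermediate"
        }


class TestPrioritization:
    def _enrichment(self, gene, p):
        return EnrichmentResult(gene=gene, n=25, k=5, f0=0.01, f0_used=0.01,
                                p_value=p, alpha=0.05)

    def test_connected_and_enriched_genes_intersect(self):
        net = Interactome.from_edges([("A", "B"), ("B", "C"), ("X", "Y")])
        mcn = build_mcn({"A", "B", "C", "X"}, net)
        summary = mcn_significance({"A", "B", "C", "X"}, net, M=9, rng_seed=0)
        enrichment = [self._enrichment("A", 0.001), self._enrichment("X", 0.002),
                      self._enrichment("Q", 0.003), self._enrichment("C", 0.5)]
        out = prioritize_candidates(summary, mcn, enrichment, alpha=0.05)
        got = {c.gene for c in out.candidates}
        # X is an isolated seed, C is not enriched, Q is outside the network
        assert got <= {"A", "B"}
        assert "Q" in out.not_in_network

    def test_zero_alpha_empties_candidates(self):
        net = Interactome.from_edges([("A", "B")])
        mcn = build_mcn({"A", "B"}, net)
        summary = mcn_significance({"A", "B"}, net, M=9, rng_seed=0)
        out = prioritize_candidates(summary, mcn,
                                    [self._enrichment("A", 0.001)], alpha=0.0)
        assert out.candidates == []

    def test_candidates_sorted_by_enrichment_p(self):
        net = Interactome.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        mcn = build_mcn({"A", "B", "C"}, net)
        summary = mcn_significance({"A", "B", "C"}, net, M=9, rng_seed=0)
        enrichment = [self._enrichment("C", 0.01), self._enrichment("A", 0.001),
                      self._enrichment("B", 0.005)]
        out = prioritize_candidates(summary, mcn, enrichment, alpha=0.05)
        if out.candidates:  # significance of the tiny null not guaranteed
            assert [c.gene for c in out.candidates] == sorted(
                (c.gene for c in out.candidates),
                key=lambda g: {"A": 0.001, "B": 0.005, "C": 0.01}[g],
            )
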