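"""Communities, centrality, correlation signing, subcircuits and enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from grnpipe import analysis as na
from grnpipe import synth
from grnpipe.analysis import ModulePartition

from conftest import design_grid, matrix_from
from oracles import brute_betweenness, hypergeom_upper_tail, max_modularity, modularity


def flat_matrix(vals, genes):
    design = design_grid(conditions=("c",), timepoints=(6.0,), replicates=vals.shape[1])
    return matrix_from(vals, genes, design, scale="normalized")


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = flat_matrix(np.vstack([x, 5.0 - x]), ["a", "b"])
        corr = na.pearson_matrix(m)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert corr.loc["b", "a"] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # x=(1,2,3,4), y=(2,1,4,3) -> r = 0.6
        m = flat_matrix(np.array([[1.0, 2, 3, 4], [2.0, 1, 4, 3]]), ["x", "y"])
        assert na.pearson_matrix(m).loc["x", "y"] == pytest.approx(0.6)

    def test_zero_variance_gene_flagged_nan(self):
        m = flat_matrix(np.array([[1.0, 2, 3], [5.0, 5, 5]]), ["a", "flat"])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            corr = na.pearson_matrix(m)
        assert np.isnan(corr.loc["a", "flat"])

    def test_too_few_samples_rejected(self):
        m = flat_matrix(np.array([[1.0, 2], [2.0, 1]]), ["a", "b"])
        with pytest.raises(ValueError, match="3 samples"):
            na.pearson_matrix(m)


class TestSignEdges:
    def make_net(self):
        g = nx.DiGraph()
        g.add_edge("A", "B", im=0.5)
        g.add_edge("A", "C", im=0.4)
        return g

    def test_sign_rule(self):
        corr = pd.DataFrame(
            [[1.0, 0.8, -0.3], [0.8, 1.0, 0.1], [-0.3, 0.1, 1.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        signed = na.sign_edges(self.make_net(), corr)
        assert signed["A"]["B"]["sign"] == "activating"
        assert signed["A"]["B"]["r"] == 0.8
        assert signed["A"]["C"]["sign"] == "repressive"

    def test_zero_correlation_left_unsigned(self):
        corr = pd.DataFrame(np.eye(3), index=list("ABC"), columns=list("ABC"))
        with pytest.warns(RuntimeWarning, match="unsigned"):
            signed = na.sign_edges(self.make_net(), corr)
        assert signed["A"]["B"]["sign"] == "unsigned"

    def test_sign_partition_is_exhaustive(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        corr = pd.DataFrame(rng.uniform(-1, 1, (10, 10)), index=genes, columns=genes)
        g = nx.DiGraph()
        for u, v in itertools.permutations(genes, 2):
            if rng.random() < 0.2:
                g.add_edge(u, v, im=rng.uniform())
        signed = na.sign_edges(g, corr)
        counts = {"activating": 0, "repressive": 0, "unsigned": 0}
        for _, _, d in signed.edges(data=True):
            counts[d["sign"]] += 1
        assert sum(counts.values()) == signed.number_of_edges()

    def test_recovers_planted_signs_on_synthetic_screen(self):
        """Planted +/- edge weights map to activating/repressive signs via correlation."""
        grn = synth.make_grn(30, tf_fraction=0.5, density=0.08, p_negative=0.4,
                             seed=13, weight_range=(0.8, 1.2), allow_cycles=False)
        cfg = synth.SimulationConfig(replicates=10, noise_sd=0.1, biological_sd=0.2,
                                     library_size_sd=0.0, n_housekeeping=0, seed=13)
        m, truth = synth.simulate_expression(grn, cfg)
        net = nx.DiGraph()
        for r, t, w in truth:
            net.add_edge(r, t, im=abs(w))
        signed = na.sign_edges(net, na.pearson_matrix(m))
        correct = total = 0
        for r, t, w in truth:
            expected = "activating" if w > 0 else "repressive"
            total += 1
            correct += signed[r][t]["sign"] == expected
        assert total > 10
        assert correct / total >= 0.9


class TestCommunities:
    def two_cliques(self):
        g = nx.Graph()
        a = ["a1", "a2", "a3", "a4"]
        b = ["b1", "b2", "b3", "b4"]
        for grp in (a, b):
            g.add_edges_from(itertools.combinations(grp, 2))
        g.add_edge("a1", "b1")
        return g, a, b

    def test_two_cliques_split_exactly(self):
        g, a, b = self.two_cliques()
        part = na.community_cluster(g)
        assert part.n_modules == 2
        assert {frozenset(part.members(1)), frozenset(part.members(2))} == {
            frozenset(a),
            frozenset(b),
        }

    def test_two_clique_modularity_equals_exhaustive_maximum(self):
        g, _, _ = self.two_cliques()
        part = na.community_cluster(g)
        edges = [(u, v, 1.0) for u, v in g.edges]
        best_q, _ = max_modularity(list(g.nodes), edges)
        assert part.modularity_q == pytest.approx(best_q, abs=1e-12)

    def test_edgeless_graph_gives_singletons(self):
        g = nx.DiGraph()
        g.add_nodes_from("abcde")
        part = na.community_cluster(g)
        assert part.n_modules == 5
        assert part.modularity_q == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            na.community_cluster(nx.DiGraph())

    @pytest.mark.parametrize("algorithm", ["greedy_modularity", "edge_betweenness"])
    def test_modularity_at_least_singleton_partition(self, algorithm):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.25, seed=3, directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        for u, v in g.edges:
            g[u][v]["im"] = rng.uniform(0.1, 1.0)
        part = na.community_cluster(g, algorithm=algorithm)
        und = [(u, v, d["weight"]) for u, v, d in na._undirected_projection(g).edges(data=True)]
        singleton_q = modularity(list(g.nodes), und, [[n] for n in g.nodes])
        assert part.modularity_q >= singleton_q - 1e-12
        # every node assigned, ids contiguous from 1
        assert set(part.assignment) == set(g.nodes)
        assert sorted(set(part.assignment.values())) == list(range(1, part.n_modules + 1))

    def test_small_graph_modularity_close_to_exhaustive_max(self):
        """Greedy partitions on <= 7 node graphs: q never exceeds the true max."""
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = rng.integers(4, 8)
            g = nx.gnp_random_graph(int(n), 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            part = na.community_cluster(g)
            edges = [(u, v, 1.0) for u, v in g.edges]
            best_q, _ = max_modularity(list(g.nodes), edges)
            assert part.modularity_q <= best_q + 1e-12


class TestCentrality:
    def test_directed_path_center(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        recs = {r.node: r for r in na.centrality(g, directed=True)}
        assert recs["b"].betweenness == 1.0
        assert recs["a"].betweenness == 0.0
        assert recs["b"].in_degree == 1 and recs["b"].out_degree == 1

    def test_undirected_star_center(self):
        g = nx.DiGraph([("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")])
        recs = {r.node: r for r in na.centrality(g, directed=False)}
        # C(4,2) = 6 unordered leaf pairs all route through the center
        assert recs["c"].betweenness == 6.0
        assert all(recs[f"l{i}"].betweenness == 0.0 for i in range(1, 5))

    @pytest.mark.parametrize("directed", [True, False])
    def test_matches_bruteforce_oracle_on_random_graphs(self, directed):
        rng = np.random.default_rng(8)
        for trial in range(30):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)), directed=True)
            if g.number_of_nodes() < 2:
                continue
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            recs = {r.node: r for r in na.centrality(g, directed=directed)}
            oracle = brute_betweenness(list(g.nodes), list(g.edges), directed=directed)
            for node, expect in oracle.items():
                assert recs[node].betweenness == pytest.approx(expect, abs=1e-9)

    def test_degree_sums_equal_edge_count(self, study_screen):
        grn, cfg, m, truth = study_screen
        g = nx.DiGraph()
        g.add_nodes_from(grn.genes)
        g.add_edges_from((r, t) for r, t, _ in truth)
        recs = na.centrality(g)
        assert sum(r.out_degree for r in recs) == g.number_of_edges()
        assert sum(r.in_degree for r in recs) == g.number_of_edges()


class TestFirstNeighbors:
    def demo_net(self):
        g = nx.DiGraph()
        g.add_edge("hub", "x", im=0.5)
        g.add_edge("hub", "y", im=0.4)
        g.add_edge("hub", "z", im=0.3)
        g.add_edge("x", "y", im=0.2)  # cross-edge among neighbours
        g.add_edge("w", "hub", im=0.6)
        g.add_edge("w", "q", im=0.1)
        return g

    def test_isolated_node(self):
        g = nx.DiGraph()
        g.add_node("solo")
        g.add_edge("a", "b")
        sub = na.first_neighbors(g, "solo")
        assert set(sub.nodes) == {"solo"}
        assert sub.number_of_edges() == 0

    def test_out_direction_hub(self):
        sub = na.first_neighbors(self.demo_net(), "hub", "out")
        assert set(sub.nodes) == {"hub", "x", "y", "z"}
        assert sub.number_of_edges() >= 3

    def test_induced_edges_equal_filter_oracle(self):
        g = self.demo_net()
        for direction in ("in", "out", "both"):
            sub = na.first_neighbors(g, "hub", direction)
            nodes = set(sub.nodes)
            expected = {(u, v) for u, v in g.edges if u in nodes and v in nodes}
            assert set(sub.edges) == expected
            # attributes preserved
            for u, v in sub.edges:
                assert sub[u][v]["im"] == g[u][v]["im"]

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            na.first_neighbors(self.demo_net(), "nope")


class TestEnrichment:
    def partition(self, blocks):
        assignment = {}
        for i, block in enumerate(blocks, start=1):
            for g in block:
                assignment[g] = i
        return ModulePartition(assignment=assignment, modularity_q=0.0, algorithm="fixed")

    def test_no_hits_gives_p_one(self):
        part = self.partition([["a", "b"], ["c", "d"]])
        res = na.enrich_modules(part, {"T": {"c", "d"}}, universe=["a", "b", "c", "d"])
        by_mod = {r.module_id: r for r in res}
        assert by_mod[1].k == 0
        assert by_mod[1].p_value == 1.0

    def test_full_overlap_matches_combinatorial_oracle(self):
        # N=20, K=5, n=5, k=5 -> 1/C(20,5)
        universe = [f"g{i}" for i in range(20)]
        module = universe[:5]
        rest = universe[5:]
        part = self.partition([module, rest])
        res = na.enrich_modules(part, {"T": set(module)}, universe=universe)
        hit = [r for r in res if r.module_id == 1][0]
        assert hit.p_value == pytest.approx(6.449948400412796e-05, rel=1e-12)
        assert hit.enriched

    def test_module_equals_universe_saturation(self):
        universe = ["a", "b", "c"]
        part = self.partition([universe])
        res = na.enrich_modules(part, {"T": {"a", "b"}}, universe=universe)
        assert res[0].k == res[0].K
        assert res[0].p_value == 1.0

    def test_term_outside_universe_skipped(self):
        part = self.partition([["a"], ["b"]])
        with pytest.warns(RuntimeWarning, match="skipped"):
            res = na.enrich_modules(part, {"T": {"zz"}}, universe=["a", "b"])
        assert res == []

    def test_matches_direct_summation_over_parameter_grid(self):
        """Implementation p equals exact combinatorial summation (spot grid)."""
        from scipy import stats as sps

        for N in (5, 10, 17):
            for K in (1, 3, N // 2):
                for n in (1, 2, N // 2):
                    for k in range(0, min(K, n) + 1):
                        expect = hypergeom_upper_tail(k, N, K, n)
                        got = float(sps.hypergeom.sf(k - 1, N, K, n))
                        assert got == pytest.approx(expect, rel=1e-10)

    def test_bh_correction_flags_subset(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(40)]
        part = self.partition([universe[:10], universe[10:]])
        sets = {f"T{j}": set(rng.choice(universe, 8, replace=False)) for j in range(5)}
        raw = na.enrich_modules(part, sets, universe, alpha=0.05, bh_correct=False)
        adj = na.enrich_modules(part, sets, universe, alpha=0.05, bh_correct=True)
        assert sum(r.enriched for r in adj) <= sum(r.enriched for r in raw)
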