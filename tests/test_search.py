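import math

import networkx as nx
import numpy as np
import pytest

from sequoia import Config, SimilarityTable, conductance, extend, prune, run_query, seed_network
from sequoia.correspondence import SeedList
from sequoia.search import Subnetwork
from sequoia.synth import SynthConfig, generate_pair

from conftest import make_connected_er
from oracles import conductance_bruteforce, greedy_extension_oracle


def _seedlist(nodes, scores=None):
    scores = scores or [float(i) for i in range(len(nodes))]
    return SeedList(tuple(nodes), tuple(scores))


class TestConductance:
    def test_whole_graph_has_zero_conductance(self, path_graph):
        h = Subnetwork(path_graph, frozenset(path_graph.nodes))
        assert conductance(path_graph, h) == 0.0
        assert conductance(path_graph, h, mode="standard") == 0.0

    def test_path_prefix(self, path_graph):
        h = Subnetwork(path_graph, frozenset({"a", "b"}))
        assert conductance(path_graph, h, mode="sequoia") == 1.0  # cut 1 / internal 1
        assert conductance(path_graph, h, mode="standard") == pytest.approx(1 / 3)

    def test_single_node_hits_infinity_sentinel(self, path_graph):
        h = Subnetwork(path_graph, frozenset({"b"}))
        assert math.isinf(conductance(path_graph, h))

    def test_member_outside_parent_rejected(self, path_graph):
        with pytest.raises(ValueError):
            conductance(path_graph, frozenset({"zz"}))

    def test_against_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(4, 31))
            g = make_connected_er(rng, n, "n", p=min(1.0, 4 / (n - 1)))
            k = int(rng.integers(1, n))
            members = set(rng.choice(sorted(g.nodes), size=k, replace=False))
            for mode in ("sequoia", "standard"):
                got = conductance(g, frozenset(map(str, members)), mode=mode)
                want = conductance_bruteforce(g, set(map(str, members)), mode)
                assert got == pytest.approx(want) or (math.isinf(got) and math.isinf(want))

    def test_standard_mode_bounded_by_one(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = make_connected_er(rng, 12, "n", p=0.3)
            members = frozenset(map(str, rng.choice(sorted(g.nodes), size=5, replace=False)))
            phi = conductance(g, members, mode="standard")
            if math.isfinite(phi):
                assert 0.0 <= phi <= 1.0


class TestSeedNetwork:
    def test_largest_component(self, path_graph):
        h = seed_network(path_graph, _seedlist(["a", "b", "d"]))
        assert h.members == {"a", "b"}

    def test_all_isolated_falls_back_to_best_seed(self):
        g = nx.Graph()
        g.add_nodes_from(["t1", "t2", "t3"])
        h = seed_network(g, _seedlist(["t2", "t1", "t3"], [-3.0, -1.0, -2.0]))
        assert h.members == {"t2"}

    def test_equal_components_pick_top_ranked_seed(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        h = seed_network(g, _seedlist(["c", "d", "a", "b"], [-4.0, -3.0, -2.0, -1.0]))
        assert h.members == {"c", "d"}

    def test_empty_or_foreign_seeds_rejected(self, path_graph):
        with pytest.raises(ValueError):
            seed_network(path_graph, _seedlist([]))
        with pytest.raises(ValueError):
            seed_network(path_graph, _seedlist(["zz"]))


class TestExtend:
    def test_path_extension_step_and_rewards(self, path_graph):
        seed_h = Subnetwork(path_graph, frozenset({"a", "b"}))
        h, rewards, trace = extend(path_graph, seed_h, query_size=4)
        # adding c: cut 1 / internal 2 = 0.5 <= 0.95 * 1.0; then d: 0/3 = 0
        assert h.members == {"a", "b", "c", "d"}
        assert trace == (1.0, 0.5, 0.0)
        assert rewards == {"a": 0, "b": 1, "c": 1, "d": 0}

    def test_full_graph_has_no_candidates(self, path_graph):
        seed_h = Subnetwork(path_graph, frozenset(path_graph.nodes))
        h, rewards, trace = extend(path_graph, seed_h, query_size=4)
        assert h.members == seed_h.members and trace == (0.0,)

    def test_cap_prevents_any_extension(self, path_graph):
        seed_h = Subnetwork(path_graph, frozenset({"a", "b"}))
        h, _, trace = extend(path_graph, seed_h, query_size=1, cap_factor=2.0)
        assert h.members == {"a", "b"} and len(trace) == 1

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(8, 31))
            g = make_connected_er(rng, n, "n", p=min(1.0, 4 / (n - 1)))
            nodes = sorted(g.nodes)
            k = int(rng.integers(2, 6))
            seeds = set(map(str, rng.choice(nodes, size=k, replace=False)))
            scores = {u: float(rng.uniform(-5, 0)) for u in nodes}
            qsize = int(rng.integers(3, 9))
            comp = max(nx.connected_components(g.subgraph(seeds)), key=len)
            seed_h = Subnetwork(g, frozenset(comp))
            got = extend(g, seed_h, qsize, scores=scores)
            want = greedy_extension_oracle(g, set(comp), qsize, scores=scores)
            assert got[0].members == want[0]
            assert got[1] == want[1]
            assert list(got[2]) == pytest.approx(want[2])
            assert len(got[0].members) <= 2 * qsize

    def test_trace_satisfies_reduction_rule(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            g = make_connected_er(rng, 20, "n", p=0.2)
            seeds = set(map(str, rng.choice(sorted(g.nodes), size=3, replace=False)))
            comp = max(nx.connected_components(g.subgraph(seeds)), key=len)
            _, _, trace = extend(g, Subnetwork(g, frozenset(comp)), query_size=6)
            for prev, cur in zip(trace, trace[1:]):
                assert math.isinf(prev) or cur <= 0.95 * prev


class TestPrune:
    def test_zero_threshold_keeps_seeds_and_rewarded(self, path_graph):
        h = Subnetwork(path_graph, frozenset({"a", "b", "c"}))
        kept = prune(h, {"a": 0, "b": 0, "c": 1}, seeds={"a"}, threshold=0)
        assert kept.members == {"a", "c"}

    def test_all_seeds_is_identity(self, path_graph):
        h = Subnetwork(path_graph, frozenset({"a", "b"}))
        assert prune(h, {"a": 0, "b": 0}, seeds={"a", "b"}).members == h.members

    def test_threshold_is_strict(self, path_graph):
        h = Subnetwork(path_graph, frozenset({"a", "b"}))
        kept = prune(h, {"a": 1, "b": 2}, seeds=set(), threshold=1)
        assert kept.members == {"b"}


class TestRunQuery:
    def test_single_node_query_perfect_match(self):
        query = nx.Graph()
        query.add_node("q1")
        target = nx.Graph()
        target.add_edge("t1", "t2", weight=1.0, pseudo=False)
        sim = SimilarityTable()
        sim.set("q1", "t1", 10.0)
        result = run_query(query, target, sim)
        assert result.nodes == frozenset({"t1"})
        assert result.seeds == ("t1",)
        assert result.provenance == {"t1": "seed"}

    def test_embedded_copy_is_recovered(self):
        cfg = SynthConfig(
            query_size=7, background_size=60, p_node_delete=0, p_node_insert=0,
            p_edge_rewire=0, spurious_pair_rate=0, rng_seed=12,
        )
        query, target, sim, truth = generate_pair(cfg)
        result = run_query(query, target, sim)
        assert result.nodes == truth.implanted_nodes

    def test_bit_identical_reruns(self):
        cfg = SynthConfig(rng_seed=5)
        query, target, sim, _ = generate_pair(cfg)
        r1 = run_query(query, target, sim)
        r2 = run_query(query, target, sim)
        assert r1 == r2

    def test_result_invariants(self):
        cfg = SynthConfig(rng_seed=6)
        query, target, sim, _ = generate_pair(cfg)
        result = run_query(query, target, sim)
        assert set(result.seeds) <= set(result.nodes) | result.pruned
        finite = [x for x in result.trace if math.isfinite(x)]
        assert finite == sorted(finite, reverse=True)
        assert all(v >= 0 for v in result.rewards.values())

    def test_no_similarity_is_a_configuration_error(self):
        query = nx.Graph()
        query.add_edge("q1", "q2", weight=1.0)
        target = nx.Graph()
        target.add_edge("t1", "t2", weight=1.0)
        with pytest.raises(ValueError, match="reduced target"):
            run_query(query, target, SimilarityTable())
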