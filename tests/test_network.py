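import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcx.network import (
    betweenness,
    build_graph,
    ora_enrichment,
    rank_understudied,
    topological_attack,
)


# ---------------------------------------------------------------------------
# exhaustive shortest-path betweenness oracle
# ---------------------------------------------------------------------------

def brute_betweenness(g: nx.Graph) -> dict:
    """Enumerate every shortest path between every ordered pair."""
    score = {v: 0.0 for v in g}
    for s, t in itertools.permutations(g.nodes, 2):
        # BFS distances from s
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        if t not in dist:
            continue
        # enumerate all shortest s->t paths by DFS over the BFS dag
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in g.neighbors(u):
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    path.append(w)
                    extend(path)
                    path.pop()

        extend([s])
        for p in paths:
            for v in p[1:-1]:
                score[v] += 1.0 / len(paths)
    for v in score:
        score[v] /= 2.0  # undirected: each unordered pair counted twice
    return score


class TestBetweenness:
    def test_path_graph_center(self):
        g = build_graph([("a", "b"), ("b", "c")])
        bc = betweenness(g)
        assert bc["b"] == pytest.approx(1.0)
        assert bc["a"] == bc["c"] == 0.0

    def test_star_center(self):
        g = build_graph([("c", "l1"), ("c", "l2"), ("c", "l3")])
        bc = betweenness(g)
        assert bc["c"] == pytest.approx(3.0)
        assert bc[["l1", "l2", "l3"]].eq(0).all()

    def test_complete_graph_zero(self):
        g = build_graph(list(itertools.combinations("abcd", 2)))
        assert betweenness(g).eq(0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        p = rng.uniform(0.2, 0.9)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        bc = betweenness(g)
        oracle = brute_betweenness(g)
        for v in g:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_tree_conservation(self):
        # on a tree, total betweenness equals sum over pairs of (path len - 1)
        g = nx.random_labeled_tree(10, seed=3)
        bc = betweenness(g)
        total = sum(
            nx.shortest_path_length(g, s, t) - 1
            for s, t in itertools.combinations(g.nodes, 2)
        )
        assert bc.sum() == pytest.approx(total)

    def test_normalized_in_unit_interval(self):
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        bc = betweenness(g, normalized=True)
        assert ((bc >= 0) & (bc <= 1)).all()

    def test_degree_one_nodes_zero(self):
        g = build_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "leaf")])
        assert betweenness(g)["leaf"] == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            betweenness(nx.Graph())


class TestBuildGraph:
    def test_self_loops_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="self-loop"):
            g = build_graph([("a", "a"), ("a", "b")])
        assert set(g.edges) == {("a", "b")}

    def test_node_types(self):
        g = build_graph([("TF1", "g1")], {"TF1": "TF"})
        assert g.nodes["TF1"]["type"] == "TF"
        assert g.nodes["g1"]["type"] == "gene"

    def test_duplicate_edges_collapse(self):
        g = build_graph([("a", "b"), ("b", "a"), ("a", "b")])
        assert g.number_of_edges() == 1


class TestTopologicalAttack:
    def test_path_graph_first_removal(self):
        g = build_graph([("a", "b"), ("b", "c")])
        curve = topological_attack(g, strategy="betweenness")
        assert curve.removal_order[0] == "b"
        assert curve.initial_lcc == 3
        assert curve.lcc_sizes[0] == 1

    def test_edgeless_graph(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        curve = topological_attack(g, strategy="degree")
        assert curve.initial_lcc == 1
        assert all(s in (0, 1) for s in curve.lcc_sizes)

    def test_exhaustion_reaches_zero(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        curve = topological_attack(g, strategy="degree")
        assert curve.lcc_sizes[-1] == 0
        assert len(curve.removal_order) == 10

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("recompute", [True, False])
    def test_lcc_non_increasing(self, seed, recompute):
        g = nx.gnp_random_graph(15, 0.25, seed=seed)
        curve = topological_attack(g, strategy="betweenness", recompute=recompute)
        sizes = [curve.initial_lcc] + curve.lcc_sizes
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_given_order(self):
        g = build_graph([("a", "b"), ("b", "c")])
        curve = topological_attack(g, strategy="given-order", order=["c", "a", "b"])
        assert curve.removal_order == ["c", "a", "b"]

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="strategy"):
            topological_attack(build_graph([("a", "b")]), strategy="pagerank")

    def test_ties_broken_lexicographically(self):
        g = build_graph([("x", "y")])  # both degree 1
        curve = topological_attack(g, strategy="degree")
        assert curve.removal_order[0] == "x"


class TestRankUnderstudied:
    def test_extreme_node_ranks_first(self):
        bc = pd.Series({"hub": 10.0, "a": 1.0, "b": 0.5})
        counts = {"hub": 0, "a": 50, "b": 40}
        out = rank_understudied(bc, counts)
        assert out.index[0] == "hub"

    def test_all_ties_score_zero(self):
        bc = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        out = rank_understudied(bc, {"a": 5, "b": 5, "c": 5})
        assert (out.understudied_score == 0).all()

    def test_hand_ranked_percentiles(self):
        bc = pd.Series({"n1": 5.0, "n2": 4.0, "n3": 3.0, "n4": 2.0, "n5": 1.0})
        counts = {"n1": 1, "n2": 2, "n3": 3, "n4": 4, "n5": 5}
        out = rank_understudied(bc, counts)
        # centrality pct: n1=1.0 ... n5=0.2; literature pct: n1=0.2 ... n5=1.0
        assert out.loc["n1", "understudied_score"] == pytest.approx(0.8)
        assert out.loc["n5", "understudied_score"] == pytest.approx(-0.8)
        assert out.loc["n3", "understudied_score"] == pytest.approx(0.0)

    def test_missing_counts_flagged_as_zero(self):
        bc = pd.Series({"a": 1.0, "b": 2.0})
        out = rank_understudied(bc, {"a": 3})
        assert out.loc["b", "literature_count"] == 0
        assert out.loc["b", "count_missing"]


def exact_hypergeom_tail(universe, set_size, query, overlap):
    total = math.comb(universe, query)
    return sum(
        math.comb(set_size, k) * math.comb(universe - set_size, query - k)
        for k in range(overlap, min(set_size, query) + 1)
    ) / total


class TestOra:
    def test_worked_example(self):
        res = ora_enrichment(
            query={f"q{i}" for i in range(4)} | {"x"},
            collections={"s": {f"q{i}" for i in range(4)} | {"y"}},
            universe={f"q{i}" for i in range(4)} | {"x", "y"}
            | {f"u{i}" for i in range(14)},
        )[0]
        assert res.overlap == 4
        assert res.p_hyper == pytest.approx(0.004902, abs=1e-6)

    def test_zero_overlap_p_one(self):
        res = ora_enrichment({"a"}, {"s": {"b"}}, {"a", "b", "c"})[0]
        assert res.p_hyper == 1.0

    def test_query_equals_universe(self):
        uni = {f"g{i}" for i in range(10)}
        res = ora_enrichment(uni, {"s": {f"g{i}" for i in range(4)}}, uni)[0]
        assert res.overlap == res.set_size == 4
        assert res.p_hyper == 1.0

    def test_exact_tail_oracle_small_parameters(self, rng):
        for _ in range(50):
            universe_n = int(rng.integers(10, 50))
            uni = {f"g{i}" for i in range(universe_n)}
            set_n = int(rng.integers(1, universe_n))
            query_n = int(rng.integers(1, universe_n))
            members = set(rng.choice(sorted(uni), set_n, replace=False))
            query = set(rng.choice(sorted(uni), query_n, replace=False))
            res = ora_enrichment(query, {"s": members}, uni)[0]
            expected = exact_hypergeom_tail(universe_n, set_n, query_n, res.overlap)
            assert res.p_hyper == pytest.approx(expected, abs=1e-12)

    def test_invariants(self):
        uni = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(8)}
        lib = {"a": {f"g{i}" for i in range(4, 12)}, "b": {"g0", "zz"}}
        for r in ora_enrichment(query, lib, uni):
            assert r.overlap <= min(r.set_size, r.query_size)
            assert 0 < r.p_hyper <= 1
            assert r.p_adj >= r.p_hyper - 1e-15

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(set(), {"s": {"a"}}, {"a"})
        with pytest.raises(ValueError):
            ora_enrichment({"a"}, {"s": {"a"}}, set())
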