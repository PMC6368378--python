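import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from triomethyl import enrichment as enr


class TestGeneZ:
    @pytest.mark.parametrize(
        "p,z",
        [(0.5, 0.0), (0.05, 1.6449), (0.975, -1.9600)],
    )
    def test_normal_quantiles(self, p, z):
        assert enr.gene_z(p) == pytest.approx(z, abs=1e-4)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 2.0])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            enr.gene_z(p)


class TestAggregateZ:
    def test_identity_and_hand_value(self):
        assert enr.aggregate_z([2.0]) == 2.0
        assert enr.aggregate_z([1, 1, 1, 1]) == pytest.approx(2.0)

    def test_appending_zero_shrinks_by_sqrt_ratio(self):
        zs = [1.3, 0.2, 2.2]
        k = len(zs)
        assert enr.aggregate_z(zs + [0.0]) == pytest.approx(
            enr.aggregate_z(zs) * math.sqrt(k / (k + 1))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enr.aggregate_z([])


class TestOverlapFraction:
    def test_examples(self):
        assert enr.overlap_fraction({"a", "b"}, {"a", "b"}) == 1.0
        assert enr.overlap_fraction({"a"}, {"b"}) == 0.0
        assert enr.overlap_fraction(set("abcd"), set("cdefgh")) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enr.overlap_fraction(set(), {"a"})


class TestFindActiveSubnetworks:
    def test_star_graph_keeps_only_strong_hub(self):
        g = nx.star_graph(5)  # node 0 is the hub
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        scores = {"g0": 0.001, **{f"g{i}": 0.9 for i in range(1, 6)}}
        subs = enr.find_active_subnetworks(g, scores)
        assert subs[0].members == frozenset({"g0"})

    def test_path_graph_takes_both_strong_nodes(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        scores = {"A": 0.001, "B": 0.001, "C": 0.9}
        subs = enr.find_active_subnetworks(g, scores)
        assert subs[0].members == frozenset({"A", "B"})
        # exhaustive check: {A,B} beats every other connected subset
        z = {g_: enr.gene_z(p) for g_, p in scores.items()}
        best = max(
            [{"A"}, {"B"}, {"C"}, {"A", "B"}, {"B", "C"}, {"A", "B", "C"}],
            key=lambda s: enr.aggregate_z([z[m] for m in s]),
        )
        assert subs[0].members == frozenset(best)

    def test_empty_network(self):
        assert enr.find_active_subnetworks(nx.Graph(), {}) == []

    def test_invariants_on_random_graph(self):
        rng = np.random.default_rng(11)
        g = nx.fast_gnp_random_graph(40, 0.1, seed=4)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        scores = {n: float(rng.uniform(0.001, 1.0)) for n in list(g.nodes)[:25]}
        subs = enr.find_active_subnetworks(g, scores, max_size=8, n_subnetworks=4)
        z = {
            n: enr.gene_z(min(scores.get(n, enr.UNSCORED_P), enr.UNSCORED_P))
            for n in g.nodes
        }
        for i, sub in enumerate(subs):
            assert nx.is_connected(g.subgraph(sub.members))
            assert sub.z_a == pytest.approx(
                enr.aggregate_z([z[m] for m in sub.members])
            )
            assert sub.z_a >= max(z[m] for m in sub.members) - 1e-12  # sanity floor
            for other in subs[:i]:
                assert enr.overlap_fraction(sub.members, other.members) <= 0.5

    def test_greedy_close_to_exhaustive_on_tiny_graph(self):
        # not claimed optimal: log the ratio against the exhaustive best
        g = nx.fast_gnp_random_graph(10, 0.35, seed=2)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        rng = np.random.default_rng(2)
        scores = {n: float(rng.uniform(0.001, 0.9)) for n in g.nodes}
        subs = enr.find_active_subnetworks(g, scores, n_subnetworks=1)
        z = {n: enr.gene_z(scores[n]) for n in g.nodes}
        best = 0.0
        import itertools

        nodes = list(g.nodes)
        for r in range(1, len(nodes) + 1):
            for combo in itertools.combinations(nodes, r):
                sub = g.subgraph(combo)
                if nx.is_connected(sub):
                    best = max(best, enr.aggregate_z([z[n] for n in combo]))
        ratio = subs[0].z_a / best
        print(f"greedy/exhaustive z_A ratio: {ratio:.3f}")
        assert subs[0].z_a >= max(z.values()) - 1e-12
        assert ratio <= 1.0 + 1e-12

    def test_deterministic(self):
        g = nx.fast_gnp_random_graph(30, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        rng = np.random.default_rng(0)
        scores = {n: float(rng.uniform(0.001, 1.0)) for n in g.nodes}
        assert enr.find_active_subnetworks(g, scores) == enr.find_active_subnetworks(
            g, scores
        )


def _enumeration_oracle(k, n, K, N):
    """Exact minimum-likelihood two-sided p over the support, in rationals."""
    k_min, k_max = max(0, n + K - N), min(n, K)
    pmf = {
        j: Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
        for j in range(k_min, k_max + 1)
    }
    return float(sum(p for p in pmf.values() if p <= pmf[k]))


class TestHypergeomTwoSided:
    def test_single_outcome_support(self):
        p, direction = enr.hypergeom_two_sided(3, 3, 3, 3)
        assert p == 1.0 and direction == enr.ENRICHED

    def test_against_enumeration_example(self):
        p, _ = enr.hypergeom_two_sided(3, 5, 10, 100)
        assert p == pytest.approx(_enumeration_oracle(3, 5, 10, 100), abs=1e-12)

    def test_tie_at_expectation_is_enriched_with_maximal_p(self):
        p, direction = enr.hypergeom_two_sided(1, 2, 2, 4)
        assert direction == enr.ENRICHED
        assert p == 1.0  # symmetric configuration: every outcome qualifies

    @given(
        data=st.data(),
        N=st.integers(1, 30),
    )
    def test_matches_enumeration_oracle(self, data, N):
        n = data.draw(st.integers(0, N))
        K = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        p, direction = enr.hypergeom_two_sided(k, n, K, N)
        assert p == pytest.approx(_enumeration_oracle(k, n, K, N), abs=1e-10)
        expect = n * K / N
        assert direction == (enr.ENRICHED if k >= expect else enr.DEPLETED)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            enr.hypergeom_two_sided(6, 5, 10, 100)
        with pytest.raises(ValueError):
            enr.hypergeom_two_sided(1, 5, 10, 8)

    def test_doubling_variant_bounded_by_one(self):
        p, _ = enr.hypergeom_two_sided(2, 4, 10, 20, method="doubling")
        assert 0 < p <= 1.0


class TestBonferroni:
    def test_pointwise_formula(self):
        assert enr.bonferroni_adjust([0.01] * 5)[0] == pytest.approx(0.05)
        assert enr.bonferroni_adjust([0.5, 0.5, 0.5])[0] == 1.0
        assert enr.bonferroni_adjust([0.3]) == [pytest.approx(0.3)]

    def test_never_decreases_and_preserves_order(self):
        raw = [0.001, 0.04, 0.2, 0.9]
        adj = enr.bonferroni_adjust(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert sorted(adj) == adj


def _result(pathway, sub_id, bonf, raw=None):
    return enr.PathwayResult(pathway, sub_id, 1, 5, 10, raw or bonf / 2, bonf, enr.ENRICHED)


class TestCollectSignificant:
    def test_most_significant_occurrence_reported_once(self):
        results = [_result("P1", 0, 0.01), _result("P1", 1, 0.001)]
        final = enr.collect_significant_pathways(results)
        assert len(final) == 1 and final[0].bonferroni_p == 0.001

    def test_no_significant_results(self):
        assert enr.collect_significant_pathways([_result("P1", 0, 0.9)]) == []

    def test_tie_broken_by_lower_subnetwork_id(self):
        results = [_result("P1", 2, 0.01), _result("P1", 0, 0.01), _result("P1", 1, 0.01)]
        final = enr.collect_significant_pathways(results)
        assert final[0].subnetwork_id == 0

    def test_permutation_invariant(self):
        results = [_result(f"P{i}", i % 2, 0.001 * (i + 1)) for i in range(6)]
        shuffled = list(reversed(results))
        assert enr.collect_significant_pathways(results) == (
            enr.collect_significant_pathways(shuffled)
        )


class TestSummarize:
    def test_counts_and_top_list(self):
        per_trio = {
            "t1": [_result("P1", 0, 0.01)],
            "t2": [_result("P1", 0, 0.02), _result("P2", 0, 0.03)],
            "t3": [],
        }
        pool = [_result(f"P{i}", 0, 0.001 * (i + 1)) for i in range(4)]
        summary = enr.summarize_across_trios(per_trio, pool, top_n=10)
        assert summary.n_trios == 3
        assert summary.counts == {"P1": 2, "P2": 1}
        assert len(summary.pool_top) == 4  # not padded to 10
        assert all(c <= summary.n_trios for c in summary.counts.values())


class TestTextInterfaces:
    def test_edge_list_round_trip_drops_self_loops(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\nB\tA\nC\tC\nB\tD\n")
        g = enr.read_edge_list(path)
        assert set(g.edges) == {("A", "B"), ("B", "D")}
        out = tmp_path / "out.tsv"
        enr.write_edge_list(g, out)
        assert enr.read_edge_list(out).edges == g.edges

    def test_gmt_round_trip(self, tmp_path):
        sets = {"PATH1": frozenset({"A", "B"}), "PATH2": frozenset({"C"})}
        path = tmp_path / "sets.gmt"
        enr.write_gmt(sets, path)
        assert enr.read_gmt(path) == sets

    def test_pathway_collection_trims_to_background(self):
        coll = enr.PathwayCollection.create(
            {"P1": {"A", "B", "Z"}, "P2": {"Z"}}, {"A", "B", "C"}
        )
        assert coll.sets == {"P1": frozenset({"A", "B"})}
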