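import itertools
import math

import networkx as nx
import numpy as np
import pytest

from dupnet.errors import (InsufficientDataError, InsufficientPopulationError,
                           MissingGeneError, ParseError)
from dupnet.homology import HomologyHit, build_homology_network
from dupnet.ppi import (NO_PATH, avg_family_distance, binned_k_vs_distance,
                        compare_distributions, distance_distribution,
                        parse_ppi, sample_nonparalog_pairs,
                        shortest_path_length)


def floyd_warshall_node_counts(graph):
    """Independent all-pairs oracle: min-plus Floyd-Warshall on the
    adjacency matrix, then +1 to convert hop counts to node counts."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in graph.edges:
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return nodes, d + 1.0


class TestParsePpi:
    def test_dedup_and_self_loop_removal(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("a\tb\nb\ta\na\ta\n")
        g = parse_ppi(p)
        assert sorted(g.edges) == [("a", "b")]

    def test_psimitab_prefix_stripping(self, tmp_path):
        p = tmp_path / "ppi.mitab"
        p.write_text("uniprotkb:P1\tuniprotkb:P2\textra\tcolumns\n")
        g = parse_ppi(p, format="psimitab")
        assert sorted(g.edges) == [("P1", "P2")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("")
        assert parse_ppi(p).number_of_nodes() == 0

    def test_bad_line_reports_number(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("a\tb\njustone\n")
        with pytest.raises(ParseError, match=":2:"):
            parse_ppi(p)


class TestShortestPath:
    def test_node_count_convention(self, chain_ppi):
        assert shortest_path_length(chain_ppi, "a", "b") == 2  # direct
        assert shortest_path_length(chain_ppi, "a", "c") == 3  # one between
        assert shortest_path_length(chain_ppi, "a", "e") == 5

    def test_disconnected_pair(self, chain_ppi):
        chain_ppi.add_node("island")
        assert shortest_path_length(chain_ppi, "a", "island") == NO_PATH

    def test_same_node_rejected(self, chain_ppi):
        with pytest.raises(ValueError):
            shortest_path_length(chain_ppi, "a", "a")

    def test_missing_node_rejected(self, chain_ppi):
        with pytest.raises(MissingGeneError):
            shortest_path_length(chain_ppi, "a", "nope")

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 25))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
            nodes, oracle = floyd_warshall_node_counts(g)
            for i, j in itertools.combinations(range(len(nodes)), 2):
                got = shortest_path_length(g, nodes[i], nodes[j])
                expect = oracle[i, j]
                assert (math.isinf(got) and math.isinf(expect)) or got == expect

    def test_symmetry_and_triangle_inequality(self):
        g = nx.gnp_random_graph(20, 0.25, seed=7)
        nodes = sorted(g.nodes)
        for a, b, c in itertools.islice(itertools.combinations(nodes, 3), 200):
            dab = shortest_path_length(g, a, b)
            assert dab == shortest_path_length(g, b, a)
            dac = shortest_path_length(g, a, c)
            dbc = shortest_path_length(g, b, c)
            if all(not math.isinf(x) for x in (dab, dac, dbc)):
                assert dac - 1 <= (dab - 1) + (dbc - 1)


class TestSampleNonparalogPairs:
    def test_never_returns_paralog_pairs(self, chain_ppi):
        paralogs = {("a", "b"), ("c", "d")}
        sample = sample_nonparalog_pairs(chain_ppi, paralogs, 5, seed=1)
        assert len(sample) == 5
        assert not set(sample) & paralogs

    def test_deterministic_under_seed(self, chain_ppi):
        s1 = sample_nonparalog_pairs(chain_ppi, {("a", "b")}, 4, seed=9)
        s2 = sample_nonparalog_pairs(chain_ppi, {("a", "b")}, 4, seed=9)
        assert s1 == s2

    def test_exhaustive_request_returns_full_set(self, chain_ppi):
        paralogs = {("a", "b")}
        all_pairs = {tuple(sorted(p))
                     for p in itertools.combinations(chain_ppi.nodes, 2)}
        expected = all_pairs - paralogs
        sample = sample_nonparalog_pairs(chain_ppi, paralogs, len(expected), seed=0)
        assert set(sample) == expected

    def test_overdraw_rejected(self, chain_ppi):
        with pytest.raises(InsufficientPopulationError):
            sample_nonparalog_pairs(chain_ppi, set(), 100, seed=0)


class TestDistanceDistribution:
    def test_percentages(self, chain_ppi):
        pairs = [("a", "b"), ("b", "c"), ("a", "c"), ("a", "d")]
        dist = distance_distribution(chain_ppi, pairs)
        assert dist.counts == {2: 2, 3: 1, 4: 1}
        assert dist.percentages() == {2: 50.0, 3: 25.0, 4: 25.0}

    def test_unreachable_tallied_separately(self, chain_ppi):
        chain_ppi.add_edge("u", "v")
        dist = distance_distribution(chain_ppi, [("a", "u"), ("b", "v")])
        assert dist.counts == {}
        assert dist.unreachable == 2
        assert dist.percentages() == {}

    def test_conservation(self, chain_ppi):
        chain_ppi.add_edge("u", "v")
        pairs = [("a", "b"), ("a", "u"), ("c", "e")]
        dist = distance_distribution(chain_ppi, pairs)
        assert dist.n_reachable + dist.unreachable == len(pairs)


class TestCompareDistributions:
    def test_identical_distributions_give_zero(self, chain_ppi):
        pairs = [("a", "b"), ("a", "c"), ("a", "d")]
        d = distance_distribution(chain_ppi, pairs)
        res = compare_distributions(d, d)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_boundary_collapse_closed_form(self):
        from dupnet.ppi import DistanceDistribution
        d1 = DistanceDistribution(counts={2: 20, 3: 10, 4: 6, 5: 4})
        d2 = DistanceDistribution(counts={2: 5, 3: 5, 4: 20, 5: 10})
        res = compare_distributions(d1, d2, boundary=3.5)
        # collapses to [[30,10],[10,30]] -> chi2 = 20, df 1
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_empty_side_rejected(self, chain_ppi):
        from dupnet.ppi import DistanceDistribution
        d = distance_distribution(chain_ppi, [("a", "b")])
        with pytest.raises(InsufficientDataError):
            compare_distributions(d, DistanceDistribution())


class TestAvgFamilyDistance:
    def _net(self):
        hits = []
        for u, v in itertools.permutations("abc", 2):
            hits.append(HomologyHit(u, v, 1e-40))
        return build_homology_network(hits)

    def test_triangle_all_direct(self):
        net = self._net()
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert avg_family_distance("a", net, g) == pytest.approx(2.0)

    def test_chain(self):
        net = self._net()
        g = nx.Graph([("a", "b"), ("b", "c")])
        assert avg_family_distance("a", net, g) == pytest.approx((2 + 2 + 3) / 3)

    def test_members_absent_from_graph(self):
        net = self._net()
        g = nx.Graph([("p", "q")])
        assert avg_family_distance("a", net, g) is None


class TestBinnedKvsDistance:
    def test_two_point_bins(self):
        hits = [HomologyHit("a", "b", 1e-40), HomologyHit("c", "d", 1e-40),
                HomologyHit("c", "e", 1e-40), HomologyHit("d", "e", 1e-40)]
        net = build_homology_network(hits)
        g = nx.Graph([("a", "b"), ("c", "x"), ("x", "d"), ("d", "y"), ("y", "e"),
                      ("c", "z"), ("z", "w"), ("w", "e")])
        bins, r, p = binned_k_vs_distance(["a", "b", "c", "d", "e"], net, g,
                                          bin_size=1)
        assert [b[0] for b in bins] == [1, 2]
        assert bins[0][1] == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_single_bin_rejected(self, chain_ppi):
        net = build_homology_network([HomologyHit("a", "b", 1e-40)])
        with pytest.raises(InsufficientDataError):
            binned_k_vs_distance(["a", "b"], net, chain_ppi)
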