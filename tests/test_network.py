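"""Minimum spanning networks and median-joining construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from mthap.haplotypes import collapse_haplotypes
from mthap.network import (
    hamming,
    hamming_matrix,
    median_joining,
    minimum_spanning_network,
    network_cost,
)


def medians(g):
    return [n for n, d in g.nodes(data=True) if d["kind"] == "median"]


def mst_cost(seqs):
    labels = list(seqs)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hamming(seqs[labels[i]], seqs[labels[j]])
    return float(minimum_spanning_tree(mat).sum())


class TestHamming:
    def test_identical_and_single_difference(self):
        assert hamming("AAA", "AAA") == 0
        assert hamming("AAA", "ATA") == 1

    def test_matrix_matches_per_site_loop(self):
        rng = np.random.default_rng(3)
        seqs = [
            ("h%d" % i, "".join(rng.choice(list("ACGT"), size=15))) for i in range(10)
        ]
        dm = hamming_matrix(seqs)
        for (ia, sa), (ib, sb) in itertools.combinations(seqs, 2):
            expect = sum(x != y for x, y in zip(sa, sb))
            assert dm.loc[ia, ib] == expect


class TestMSN:
    def test_tied_triangle_is_union_of_all_msts(self):
        dm = pd.DataFrame(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], index=list("ABC"), columns=list("ABC")
        )
        g = minimum_spanning_network(dm)
        assert sorted(g.edges()) == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_chain_keeps_path_edges_only(self):
        dm = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC")
        )
        g = minimum_spanning_network(dm)
        assert sorted(g.edges()) == [("A", "B"), ("B", "C")]

    def test_single_node(self):
        dm = pd.DataFrame([[0]], index=["A"], columns=["A"])
        g = minimum_spanning_network(dm)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_epsilon_relaxation_admits_near_minimal_edges(self):
        dm = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC")
        )
        g = minimum_spanning_network(dm, epsilon=1)
        assert ("A", "C") in g.edges() or ("C", "A") in g.edges()


class TestMedianJoining:
    def test_triple_gains_one_median(self):
        # 000 / 110 / 011 over three variable sites: the consensus 010
        # is the unique Steiner point; cost drops from 4 to 3
        haps = [("h1", "AAA"), ("h2", "GGA"), ("h3", "AGG")]
        g = median_joining(haps)
        assert len(medians(g)) == 1
        mv = medians(g)[0]
        assert g.nodes[mv]["sequence"] == "AGA"
        assert network_cost(g) == 3.0
        assert all(g.degree(m) >= 3 for m in medians(g))

    def test_exhaustive_steiner_oracle_on_triple(self):
        # brute force over all 8 binary-coded candidates confirms 3 is optimal
        haps = {"h1": "AAA", "h2": "GGA", "h3": "AGG"}
        best = mst_cost(haps)
        for cand in ("".join(c) for c in itertools.product("AG", repeat=3)):
            if cand in haps.values():
                continue
            best = min(best, mst_cost({**haps, "x": cand}))
        g = median_joining(list(haps.items()))
        assert network_cost(g) == best == 3.0

    def test_two_haplotypes_single_edge(self):
        g = median_joining([("a", "AAAA"), ("b", "AAGG")])
        assert medians(g) == []
        assert list(g.edges(data="mutations")) == [("a", "b", 2)]

    def test_star_data_needs_no_medians(self, star):
        table = collapse_haplotypes(star.alignment)
        g = median_joining(table.haplotypes)
        assert medians(g) == []
        # the observed center is already the optimal hub
        assert network_cost(g) == 5.0

    def test_every_observed_haplotype_present_once(self, table4_like):
        table = collapse_haplotypes(table4_like.alignment)
        counts = {h: table.total_count(h) for h in table.ids}
        g = median_joining(table.haplotypes, counts=counts)
        observed = [n for n, d in g.nodes(data=True) if d["kind"] == "observed"]
        assert sorted(observed) == sorted(table.ids)
        assert all(g.nodes[n]["count"] == counts[n] for n in observed)

    def test_cost_never_exceeds_observed_mst(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            base = rng.choice(list("ACGT"), size=12)
            haps = {}
            for i in range(5):
                s = base.copy()
                for pos in rng.choice(12, size=rng.integers(1, 5), replace=False):
                    s[pos] = rng.choice([c for c in "ACGT" if c != s[pos]])
                haps[f"h{i}"] = "".join(s)
            haps = {k: v for k, v in haps.items()}
            if len(set(haps.values())) < len(haps):
                continue
            g = median_joining(list(haps.items()))
            assert network_cost(g) <= mst_cost(haps) + 1e-9
            assert len(g) >= len(haps)
            import networkx as nx

            assert nx.is_connected(g)

    def test_order_invariance_without_ties(self):
        haps = [("h1", "AAA"), ("h2", "GGA"), ("h3", "AGG")]
        g1 = median_joining(haps)
        g2 = median_joining(list(reversed(haps)))
        assert network_cost(g1) == network_cost(g2)
        assert {d["sequence"] for _, d in g1.nodes(data=True)} == {
            d["sequence"] for _, d in g2.nodes(data=True)
        }

    def test_bruteforce_minimal_steiner_on_small_instance(self):
        # <= 6 haplotypes over <= 8 variable sites: exhaustive search over
        # up to two added medians drawn from per-column observed states
        haps = {
            "h1": "AAAAAA",
            "h2": "GGAAAA",
            "h3": "AAGGAA",
            "h4": "AAAAGG",
            "h5": "GGGGAA",
        }
        cols = list(zip(*haps.values()))
        candidates = {
            "".join(choice)
            for choice in itertools.product(*[sorted(set(c)) for c in cols])
        } - set(haps.values())
        best = mst_cost(haps)
        for cand in candidates:
            best = min(best, mst_cost({**haps, "x": cand}))
        for pair in itertools.combinations(sorted(candidates), 2):
            best = min(best, mst_cost({**haps, "x": pair[0], "y": pair[1]}))
        g = median_joining(list(haps.items()))
        assert network_cost(g) == pytest.approx(best)
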