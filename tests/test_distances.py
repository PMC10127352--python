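"""K2P distances, group means and bootstrap standard errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthap.distances import (
    PairwiseComparison,
    UndefinedDistanceError,
    bootstrap_se,
    count_site_patterns,
    distance_matrix,
    k2p_distance,
    k2p_pair,
    mean_between,
    mean_within,
)


class TestSitePatterns:
    def test_identical(self):
        c = count_site_patterns("AAAA", "AAAA")
        assert (c.L, c.P, c.Q, c.raw_diffs) == (4, 0.0, 0.0, 0)

    def test_transition_classified(self):
        c = count_site_patterns("AAAA", "GAAA")  # A<->G is purine<->purine
        assert c.L == 4 and c.P == pytest.approx(0.25) and c.Q == 0.0

    def test_pairwise_deletion_of_n_sites(self):
        c = count_site_patterns("AANA", "ACAA")
        assert c.L == 3
        assert c.Q == pytest.approx(1 / 3)  # A<->C transversion
        assert c.P == 0.0

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            count_site_patterns("NNN", "ACG")


class TestK2P:
    def test_zero_divergence(self):
        assert k2p_distance(PairwiseComparison(4, 0.0, 0.0, 0)) == 0.0

    def test_closed_form(self):
        d = k2p_distance(PairwiseComparison(100, 0.10, 0.05, 15))
        assert d == pytest.approx(0.170181, abs=1e-6)

    def test_single_transition_549bp(self):
        d = k2p_pair("A" * 548 + "G", "A" * 549)
        assert d == pytest.approx(0.0018248, abs=1e-7)

    def test_saturation_flagged(self):
        with pytest.raises(UndefinedDistanceError):
            k2p_distance(PairwiseComparison(10, 0.5, 0.0, 5))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 0.35), st.floats(0, 0.35))
    def test_correction_never_shrinks_observed(self, p, q):
        # K2P >= P+Q wherever the logs are defined
        if 1 - 2 * p - q <= 1e-9 or 1 - 2 * q <= 1e-9:
            return
        d = k2p_distance(PairwiseComparison(1000, p, q, 0))
        assert d >= p + q - 1e-12

    def test_matches_per_site_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=200))
            b = list(a)
            for pos in rng.choice(200, size=12, replace=False):
                b[pos] = rng.choice([c for c in "ACGT" if c != b[pos]])
            b = "".join(b)
            # independent oracle: classify each site by purine/pyrimidine table
            ts = tv = 0
            for ca, cb in zip(a, b):
                if ca == cb:
                    continue
                if {ca, cb} <= {"A", "G"} or {ca, cb} <= {"C", "T"}:
                    ts += 1
                else:
                    tv += 1
            P, Q = ts / 200, tv / 200
            expect = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
            assert k2p_pair(a, b) == pytest.approx(expect)


class TestGroupMeans:
    SEQS = {
        "h1": "A" * 50,
        "h2": "A" * 45 + "G" * 5,
        "h3": "A" * 40 + "G" * 10,
        "h4": "C" * 50,
    }

    def test_identical_within(self):
        r = mean_within(["h1", "h1b"], {"h1": "AAAA", "h1b": "AAAA"})
        assert r.estimate == 0.0

    def test_single_pair_between_equals_pairwise(self):
        r = mean_between(["h1"], ["h2"], self.SEQS)
        assert r.estimate == pytest.approx(k2p_pair(self.SEQS["h1"], self.SEQS["h2"]))
        assert r.n_pairs == 1

    def test_between_symmetric(self):
        ab = mean_between(["h1", "h2"], ["h3", "h4"], self.SEQS)
        ba = mean_between(["h3", "h4"], ["h1", "h2"], self.SEQS)
        assert ab.estimate == pytest.approx(ba.estimate)

    def test_within_matches_pair_enumeration(self):
        r = mean_within(["h1", "h2", "h3"], self.SEQS)
        pairs = [("h1", "h2"), ("h1", "h3"), ("h2", "h3")]
        expect = np.mean([k2p_pair(self.SEQS[a], self.SEQS[b]) for a, b in pairs])
        assert r.estimate == pytest.approx(expect)
        assert r.n_pairs == 3

    def test_groups_must_be_disjoint(self):
        with pytest.raises(ValueError):
            mean_between(["h1"], ["h1"], self.SEQS)


class TestBootstrap:
    def test_zero_variation_zero_se(self):
        seqs = {"a": "ACGT" * 10, "b": "ACGT" * 10}
        ses = bootstrap_se({"g": ["a", "b"]}, seqs, replicates=50, seed=0)
        assert ses[("g", "g")] == 0.0

    def test_deterministic_under_seed(self):
        seqs = {"a": "A" * 50, "b": "A" * 45 + "G" * 5}
        kw = dict(replicates=100, seed=42)
        assert bootstrap_se({"g": ["a", "b"]}, seqs, **kw) == bootstrap_se(
            {"g": ["a", "b"]}, seqs, **kw
        )

    def test_matches_direct_resampling_oracle(self):
        # 2 haplotypes, 5 differing sites of 50: SE of the site-bootstrap mean
        # distance estimated by an independent simulation
        L, k = 50, 5
        a = "A" * L
        b = "G" * k + "A" * (L - k)
        ses = bootstrap_se({"g": ["a", "b"]}, {"a": a, "b": b}, replicates=400, seed=1)
        rng = np.random.default_rng(99)
        sims = []
        for _ in range(400):
            hits = rng.binomial(L, k / L)  # resampled count of differing columns
            P = hits / L
            sims.append(-0.5 * math.log(1 - 2 * P))
        oracle = np.std(sims, ddof=1)
        se_of_se = oracle / math.sqrt(2 * 399)
        assert abs(ses[("g", "g")] - oracle) < 5 * se_of_se


def test_distance_matrix_symmetry_and_diagonal():
    seqs = [("a", "A" * 30), ("b", "A" * 28 + "GG"), ("c", "CC" + "A" * 26 + "GG")]
    dm = distance_matrix(seqs)
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0.0)
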