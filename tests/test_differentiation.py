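"""One-level AMOVA Fst/Phi-st and permutation significance."""

import itertools

import numpy as np
import pytest

from mthap.alignment import alignment_from_strings
from mthap.differentiation import (
    _amova_from_delta,
    amova_phi,
    pairwise_differentiation,
    permutation_p,
)

A_SEQ = "A" * 20
B_SEQ = "G" * 5 + "A" * 15


class TestAmova:
    def test_complete_differentiation(self, two_pop_fixed):
        recs = two_pop_fixed.alignment.records
        a = [r.sequence for r in recs if r.population == "popA"]
        b = [r.sequence for r in recs if r.population == "popB"]
        res = amova_phi(a, b, metric="differences")
        assert res.phi == pytest.approx(1.0)
        assert res.sigma2_within == 0.0

    def test_hand_amova_unit_delta(self):
        # 2+2 specimens, delta=1 across, 0 within: SSD_total=1,
        # sigma2_among=0.5, phi=1
        a, b = [A_SEQ, A_SEQ], ["G" + A_SEQ[1:], "G" + A_SEQ[1:]]
        res = amova_phi(a, b, metric="equality")
        assert res.phi == pytest.approx(1.0)
        assert res.sigma2_among == pytest.approx(0.5)
        assert res.df_among == 1 and res.df_within == 2
        assert res.n_prime == pytest.approx(2.0)

    def test_identical_urn_gives_zero(self):
        res = amova_phi([A_SEQ] * 3, [A_SEQ] * 3, metric="differences")
        assert res.phi == 0.0
        assert res.sigma2_among == 0.0

    def test_bruteforce_ssd_oracle_3_plus_3(self):
        # hand-set delta matrix, checked against termwise sums of squares
        rng = np.random.default_rng(5)
        delta = np.zeros((6, 6))
        for i in range(6):
            for j in range(i + 1, 6):
                delta[i, j] = delta[j, i] = rng.integers(0, 8)
        res = _amova_from_delta(delta, [3, 3])

        N, K = 6, 2
        ssd_total = delta.sum() / (2 * N)
        ssd_within = delta[:3, :3].sum() / 6 + delta[3:, 3:].sum() / 6
        ms_among = (ssd_total - ssd_within) / (K - 1)
        ms_within = ssd_within / (N - K)
        n_prime = (N - (9 + 9) / N) / (K - 1)
        s2a = (ms_among - ms_within) / n_prime
        expect_phi = s2a / (s2a + ms_within)
        assert res.phi == pytest.approx(expect_phi)

    def test_negative_estimates_reported_as_is(self):
        # more variation within than between -> negative phi allowed
        a = [A_SEQ, B_SEQ]
        b = [A_SEQ, B_SEQ]
        res = amova_phi(a, b, metric="differences")
        assert res.phi < 0

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            amova_phi([A_SEQ], [B_SEQ, B_SEQ])

    def test_phi_invariant_under_delta_scaling(self):
        # equality metric and differences metric agree when all distinct
        # haplotypes are equidistant (delta differs by a global constant)
        a = [A_SEQ, A_SEQ, B_SEQ]
        b = [B_SEQ, B_SEQ, A_SEQ]
        eq = amova_phi(a, b, metric="equality").phi
        df = amova_phi(a, b, metric="differences").phi
        assert eq == pytest.approx(df)


class TestPermutation:
    def test_exhaustive_enumeration_2_plus_2(self, two_pop_fixed):
        recs = two_pop_fixed.alignment.records
        a = [r.sequence for r in recs if r.population == "popA"]
        b = [r.sequence for r in recs if r.population == "popB"]
        p = permutation_p(a, b, exhaustive=True)
        # both extreme assignments of the 6 splits reach the observed stat
        assert p == pytest.approx(2 / 6)

    def test_monte_carlo_tracks_exhaustive(self):
        a = [A_SEQ, A_SEQ, B_SEQ]
        b = [B_SEQ, "C" + A_SEQ[1:], "C" + B_SEQ[1:]]
        exact = permutation_p(a, b, exhaustive=True)
        n_perm = 2000
        mc = permutation_p(a, b, n_perm=n_perm, seed=3)
        sigma = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) < 3 * sigma + 2 / n_perm

    def test_identical_populations_p_near_one(self):
        p = permutation_p([A_SEQ] * 3, [A_SEQ] * 3, n_perm=200, seed=1)
        assert p == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        a, b = [A_SEQ, A_SEQ, B_SEQ], [B_SEQ, B_SEQ, A_SEQ]
        kw = dict(n_perm=500, seed=11)
        assert permutation_p(a, b, **kw) == permutation_p(a, b, **kw)


class TestPairwiseMatrix:
    def _aln(self, by_pop):
        pairs, pops = [], {}
        i = 0
        for pop, seqs in by_pop.items():
            for s in seqs:
                pairs.append((f"r{i}", s))
                pops[f"r{i}"] = pop
                i += 1
        return alignment_from_strings(pairs, populations=pops)

    def test_fixed_pops_stat_one(self):
        aln = self._aln({"X": [A_SEQ] * 2, "Y": [B_SEQ] * 2})
        res = pairwise_differentiation(aln, n_perm=100, seed=1)
        assert res.stat.loc["Y", "X"] == pytest.approx(1.0)
        mixed = res.mixed_frame()
        assert mixed.loc["Y", "X"] == "1.0000"  # statistic bottom-left
        assert 0 <= float(mixed.loc["X", "Y"]) <= 1  # p-value top-right

    def test_panmictic_populations_low_stat_high_p(self):
        rng = np.random.default_rng(21)
        urn = [A_SEQ, B_SEQ, "C" + A_SEQ[1:], "T" + B_SEQ[1:]]
        by_pop = {
            f"pop{k}": [urn[i] for i in rng.integers(0, 4, size=8)] for k in range(4)
        }
        aln = self._aln(by_pop)
        res = pairwise_differentiation(aln, n_perm=500, seed=2)
        stats = res.long_frame()["stat"]
        pvals = res.long_frame()["p_value"]
        assert (stats.abs() < 0.25).all()
        assert (pvals > 0.05).all()

    def test_statistics_follow_population_relabeling(self):
        by_pop = {"X": [A_SEQ] * 3, "Y": [B_SEQ] * 3, "Z": [A_SEQ, B_SEQ, A_SEQ]}
        aln = self._aln(by_pop)
        res = pairwise_differentiation(aln, n_perm=50, seed=7)
        relabeled = self._aln(
            {"Z": by_pop["X"], "Y": by_pop["Y"], "X": by_pop["Z"]}
        )
        res2 = pairwise_differentiation(relabeled, n_perm=50, seed=7)
        assert res.stat.loc["X", "Y"] == pytest.approx(res2.stat.loc["Z", "Y"])
        assert res.stat.loc["X", "Z"] == pytest.approx(res2.stat.loc["Z", "X"])
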