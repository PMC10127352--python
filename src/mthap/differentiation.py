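"""Pairwise population differentiation: Fst / Phi-st via one-level AMOVA.

The analysis of molecular variance partitions the sum of squared
deviations implied by a specimen-by-specimen distance matrix into among-
and within-population components:

    SSD_total  = 1/(2N)  * sum_ij  delta_ij
    SSD_within = sum_k 1/(2 n_k) * sum_{i,j in k} delta_ij
    sigma2_w   = MS_within
    sigma2_a   = (MS_among - MS_within) / n'
    n'         = (N - sum_k n_k^2 / N) / (K - 1)
    Phi        = sigma2_a / (sigma2_a + sigma2_w)

With delta the 0/1 indicator of carrying different haplotypes this is
the haplotype-frequency Fst; with delta the count of differing sites it
is the distance-based Phi-st; ``k2p`` uses the model-corrected distance.
Significance comes from permuting specimens between the two populations
(sample sizes preserved) with the add-one convention
p = (1 + #{permuted >= observed}) / (1 + n_perm).  Negative estimates
are reported as-is.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import Alignment
from .distances import count_site_patterns, k2p_pair

METRICS = ("equality", "differences", "k2p")


@dataclass(frozen=True)
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    phi: float
    df_among: int
    df_within: int
    n_prime: float


def _delta_matrix(seqs: Sequence[str], metric: str) -> np.ndarray:
    n = len(seqs)
    delta = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "equality":
                d = 0.0 if seqs[i] == seqs[j] else 1.0
            elif metric == "differences":
                d = float(count_site_patterns(seqs[i], seqs[j]).raw_diffs)
            elif metric == "k2p":
                d = k2p_pair(seqs[i], seqs[j])
            else:
                raise ValueError(f"unknown metric {metric!r}")
            delta[i, j] = delta[j, i] = d
    return delta


def _amova_from_delta(delta: np.ndarray, sizes: Sequence[int]) -> AmovaResult:
    sizes = list(sizes)
    N = int(delta.shape[0])
    K = len(sizes)
    if sum(sizes) != N:
        raise ValueError("population sizes do not sum to matrix dimension")
    ssd_total = float(delta.sum()) / (2.0 * N)
    ssd_within = 0.0
    start = 0
    for nk in sizes:
        block = delta[start : start + nk, start : start + nk]
        ssd_within += float(block.sum()) / (2.0 * nk)
        start += nk
    ssd_among = ssd_total - ssd_within

    df_among = K - 1
    df_within = N - K
    ms_among = ssd_among / df_among
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    n_prime = (N - sum(nk * nk for nk in sizes) / N) / (K - 1)
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n_prime
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom > 0 else 0.0
    return AmovaResult(
        sigma2_among=sigma2_among,
        sigma2_within=sigma2_within,
        phi=float(phi),
        df_among=df_among,
        df_within=df_within,
        n_prime=n_prime,
    )


def amova_phi(
    pop_a: Sequence[str], pop_b: Sequence[str], metric: str = "differences"
) -> AmovaResult:
    """One-level AMOVA between two populations of specimen sequences.

    ``metric='equality'`` gives the haplotype-frequency Fst,
    ``'differences'`` the Phi-st on raw site-difference counts, and
    ``'k2p'`` the Phi-st on model-corrected distances.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 specimens")
    seqs = list(pop_a) + list(pop_b)
    delta = _delta_matrix(seqs, metric)
    return _amova_from_delta(delta, [len(pop_a), len(pop_b)])


def permutation_p(
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    metric: str = "differences",
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for the two-population Phi statistic.

    Specimens are shuffled between the populations with sample sizes
    preserved.  Monte-Carlo mode uses the add-one convention
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``; ties count as >=.
    ``exhaustive=True`` enumerates every split (feasible only for small
    samples) and returns the exact tail fraction without the correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    seqs = list(pop_a) + list(pop_b)
    na = len(pop_a)
    n = len(seqs)
    delta = _delta_matrix(seqs, metric)
    observed = _amova_from_delta(delta, [na, n - na]).phi
    tol = 1e-12

    if exhaustive:
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            order = list(combo) + [i for i in range(n) if i not in combo]
            perm = delta[np.ix_(order, order)]
            stat = _amova_from_delta(perm, [na, n - na]).phi
            total += 1
            if stat >= observed - tol:
                hits += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        order = rng.permutation(idx)
        perm = delta[np.ix_(order, order)]
        stat = _amova_from_delta(perm, [na, n - na]).phi
        if stat >= observed - tol:
            hits += 1
    return (1 + hits) / (1 + n_perm)


@dataclass
class DifferentiationMatrix:
    """Pairwise statistics (lower triangle) and p-values (upper triangle)."""

    populations: List[str]
    stat: pd.DataFrame
    pvalue: pd.DataFrame
    metric: str
    n_permutations: int
    seed: int

    def mixed_frame(self, percent: bool = False) -> pd.DataFrame:
        """Single table with the statistic bottom-left and the permutation
        significance top-right, the layout of pairwise Fst tables."""
        pops = self.populations
        out = pd.DataFrame("-", index=pops, columns=pops, dtype=object)
        scale = 100.0 if percent else 1.0
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    out.iloc[i, j] = f"{self.stat.loc[a, b] * scale:.4f}"
                elif i < j:
                    out.iloc[i, j] = f"{self.pvalue.loc[a, b]:.4f}"
        return out

    def long_frame(self, percent: bool = False) -> pd.DataFrame:
        rows = []
        scale = 100.0 if percent else 1.0
        for i, a in enumerate(self.populations):
            for b in self.populations[i + 1 :]:
                rows.append(
                    {
                        "pop_a": a,
                        "pop_b": b,
                        "stat": self.stat.loc[a, b] * scale,
                        "p_value": self.pvalue.loc[a, b],
                        "metric": self.metric,
                        "n_permutations": self.n_permutations,
                    }
                )
        return pd.DataFrame(rows)


def pairwise_differentiation(
    alignment: Alignment,
    metric: str = "differences",
    n_perm: int = 10_000,
    seed: int = 0,
    populations: Optional[List[str]] = None,
) -> DifferentiationMatrix:
    """All pairwise population Fst/Phi-st with permutation p-values.

    Populations are taken from the alignment's specimen labels; each
    population in the comparison needs >= 2 specimens.
    """
    pops = populations or alignment.populations()
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    by_pop: Dict[str, List[str]] = {p: [] for p in pops}
    for rec in alignment.records:
        if rec.population in by_pop:
            by_pop[rec.population].append(rec.sequence)

    stat = pd.DataFrame(np.nan, index=pops, columns=pops)
    pval = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        stat.loc[a, a] = 0.0
        for b in pops[i + 1 :]:
            res = amova_phi(by_pop[a], by_pop[b], metric=metric)
            pair_seed = int(rng.integers(0, 2**31 - 1))
            p = permutation_p(
                by_pop[a], by_pop[b], metric=metric, n_perm=n_perm, seed=pair_seed
            )
            stat.loc[a, b] = stat.loc[b, a] = res.phi
            pval.loc[a, b] = pval.loc[b, a] = p
    return DifferentiationMatrix(
        populations=pops,
        stat=stat,
        pvalue=pval,
        metric=metric,
        n_permutations=n_perm,
        seed=seed,
    )
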