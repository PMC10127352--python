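"""Haplotype diversity (H) and nucleotide diversity (pi), Nei estimators.

H is the probability that two specimens drawn without replacement carry
different haplotypes, with the small-sample correction n/(n-1):

    H = n/(n-1) * (1 - sum_i p_i^2)

pi is the expected per-site difference between two random sequences,

    pi = n/(n-1) * sum_{i != j} p_i p_j d_ij

with d_ij the raw proportion of differing sites between haplotypes i and
j under pairwise deletion (a flag switches to K2P-corrected distances).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .distances import k2p_pair, p_distance_pair
from .haplotypes import HaplotypeTable, collapse_haplotypes


@dataclass(frozen=True)
class DiversityStats:
    """Per-sample diversity summary (one population x species cell)."""

    population: str
    species: str
    n: int
    k: int
    H: Optional[float]
    pi: Optional[float]  # per site; None when n < 2


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Nei's unbiased haplotype diversity from haplotype counts."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 specimens")
    p = np.asarray(counts, dtype=float) / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(
    table: HaplotypeTable, corrected: bool = False
) -> float:
    """Nei's unbiased nucleotide diversity from a haplotype table.

    ``corrected=True`` uses K2P-corrected inter-haplotype distances
    instead of the default raw proportion of differing sites.
    """
    n = table.n_specimens
    if n < 2:
        raise ValueError("nucleotide diversity needs n >= 2 specimens")
    dist = k2p_pair if corrected else p_distance_pair
    haps = table.haplotypes
    freqs = {h: table.total_count(h) / n for h, _ in haps}
    total = 0.0
    for i in range(len(haps)):
        hi, si = haps[i]
        for j in range(i + 1, len(haps)):
            hj, sj = haps[j]
            total += 2.0 * freqs[hi] * freqs[hj] * dist(si, sj)
    return float(n / (n - 1) * total)


def diversity_report(
    alignment: Alignment, corrected: bool = False
) -> List[DiversityStats]:
    """One :class:`DiversityStats` row per (species, population) sample.

    Samples of a single specimen are emitted with H and pi undefined
    (``None``) rather than dropped, mirroring how a table of per-locality
    diversity lists every sampled locality.
    """
    cells: Dict[tuple, list] = {}
    for rec in alignment.records:
        cells.setdefault((rec.species, rec.population), []).append(rec)

    rows = []
    for (species, population), recs in cells.items():
        sub = Alignment(tuple(recs))
        table = collapse_haplotypes(sub)
        counts = [table.total_count(h) for h in table.ids]
        n = sum(counts)
        if n >= 2:
            H: Optional[float] = haplotype_diversity(counts)
            pi: Optional[float] = nucleotide_diversity(table, corrected=corrected)
        else:
            H = None
            pi = None
        rows.append(
            DiversityStats(
                population=population,
                species=species,
                n=n,
                k=len(counts),
                H=H,
                pi=pi,
            )
        )
    return rows


def diversity_frame(stats: List[DiversityStats]) -> pd.DataFrame:
    """TSV-ready frame: locality, species, N, haplotype count, pi (%), H."""
    return pd.DataFrame(
        [
            {
                "locality": s.population,
                "species": s.species,
                "N": s.n,
                "n_haplotypes": s.k,
                "pi_percent": None if s.pi is None else 100.0 * s.pi,
                "H": s.H,
            }
            for s in stats
        ]
    )
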