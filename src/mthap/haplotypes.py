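"""Haplotype collapsing, frequency shares and base composition.

Specimens carrying byte-identical aligned sequences share a haplotype.
Collapsing is exact-match: an ``N`` does not wildcard-match a base, so
two sequences differing only in an ambiguity call are distinct
haplotypes.  Haplotype ids are assigned ``H1..Hk`` in order of first
appearance in the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .alignment import BASES, Alignment


@dataclass(frozen=True)
class CompositionSummary:
    """Pooled A/C/G/T fractions, gaps and ambiguity codes excluded."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "A": self.freq_A,
            "C": self.freq_C,
            "G": self.freq_G,
            "T": self.freq_T,
        }


@dataclass
class HaplotypeTable:
    """Unique sequences with per-population specimen membership.

    Attributes
    ----------
    haplotypes:
        Ordered ``(haplotype_id, sequence)`` pairs, ids ``H1..Hk``.
    membership:
        ``haplotype_id -> list of specimen ids`` (each specimen appears
        exactly once across all haplotypes).
    counts:
        ``(haplotype_id, population) -> specimen count``; the empty
        string is the population of unlabeled specimens.
    species:
        ``haplotype_id -> species label`` of its members (first seen).
    """

    haplotypes: List[Tuple[str, str]]
    membership: Dict[str, List[str]]
    counts: Dict[Tuple[str, str], int]
    species: Dict[str, str]

    @property
    def n_specimens(self) -> int:
        return sum(self.counts.values())

    @property
    def ids(self) -> List[str]:
        return [h for h, _ in self.haplotypes]

    def sequence(self, hap_id: str) -> str:
        for h, s in self.haplotypes:
            if h == hap_id:
                return s
        raise KeyError(hap_id)

    def total_count(self, hap_id: str) -> int:
        return sum(v for (h, _), v in self.counts.items() if h == hap_id)

    def population_counts(self, hap_id: str) -> Dict[str, int]:
        return {p: v for (h, p), v in self.counts.items() if h == hap_id and v > 0}


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Collapse an alignment into distinct haplotypes (exact string match)."""
    seq_to_hap: Dict[str, str] = {}
    haplotypes: List[Tuple[str, str]] = []
    membership: Dict[str, List[str]] = {}
    counts: Counter = Counter()
    species: Dict[str, str] = {}

    for rec in alignment.records:
        hap = seq_to_hap.get(rec.sequence)
        if hap is None:
            hap = f"H{len(haplotypes) + 1}"
            seq_to_hap[rec.sequence] = hap
            haplotypes.append((hap, rec.sequence))
            membership[hap] = []
            species[hap] = rec.species
        membership[hap].append(rec.id)
        counts[(hap, rec.population)] += 1

    return HaplotypeTable(
        haplotypes=haplotypes,
        membership=membership,
        counts=dict(counts),
        species=species,
    )


def haplotype_shares(
    table: HaplotypeTable,
    species: Optional[str] = None,
    population: Optional[str] = None,
) -> Dict[str, float]:
    """Fraction of specimens carrying each haplotype within a scope.

    ``species`` and/or ``population`` restrict the specimen pool; shares
    always sum to 1 over the scoped specimens.
    """
    scoped: Dict[str, int] = {}
    for (hap, pop), n in table.counts.items():
        if species is not None and table.species.get(hap, "") != species:
            continue
        if population is not None and pop != population:
            continue
        scoped[hap] = scoped.get(hap, 0) + n
    total = sum(scoped.values())
    if total == 0:
        raise ValueError("no specimens in the requested scope")
    return {hap: n / total for hap, n in scoped.items()}


def species_share(
    table: HaplotypeTable, species: str, population: Optional[str] = None
) -> float:
    """Fraction of specimens (optionally within one population) that belong
    to ``species`` — e.g. the share of *M. macedonicus* among all *Mus*
    trapped at one locality."""
    hit = 0
    total = 0
    for (hap, pop), n in table.counts.items():
        if population is not None and pop != population:
            continue
        total += n
        if table.species.get(hap, "") == species:
            hit += n
    if total == 0:
        raise ValueError("no specimens in the requested scope")
    return hit / total


def base_composition(alignment: Alignment) -> CompositionSummary:
    """Pooled base composition over all specimen sequences.

    Gaps, ``N`` and IUPAC ambiguity codes are excluded from the
    denominator, so the four fractions sum to one.
    """
    counts = Counter()
    for rec in alignment.records:
        counts.update(rec.sequence)
    total = sum(counts[b] for b in BASES)
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return CompositionSummary(
        freq_A=counts["A"] / total,
        freq_C=counts["C"] / total,
        freq_G=counts["G"] / total,
        freq_T=counts["T"] / total,
    )


def haplotype_table_frame(table: HaplotypeTable) -> pd.DataFrame:
    """Tabular view: one row per haplotype with total and per-population counts."""
    pops = sorted({p for (_, p) in table.counts})
    rows = []
    for hap, _seq in table.haplotypes:
        row = {
            "haplotype_id": hap,
            "species": table.species.get(hap, ""),
            "n_total": table.total_count(hap),
        }
        for p in pops:
            row[f"n_{p or 'unassigned'}"] = table.counts.get((hap, p), 0)
        row["members"] = ",".join(table.membership[hap])
        rows.append(row)
    return pd.DataFrame(rows)


def write_haplotype_table(table: HaplotypeTable, tsv_path: str | Path) -> None:
    haplotype_table_frame(table).to_csv(tsv_path, sep="\t", index=False)
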