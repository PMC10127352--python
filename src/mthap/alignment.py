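"""Aligned sequence I/O and specimen metadata.

The pipeline operates on a pre-aligned set of equal-length haploid DNA
sequences (mitochondrial fragments such as a ~549-bp cytochrome-b window)
plus a specimen table mapping sequence IDs to sampling locality
("population") and species.  De novo alignment is out of scope: inputs
must already be aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Characters accepted in an aligned DNA sequence: the four bases, gap,
#: N, and the IUPAC ambiguity codes.
VALID_CHARS = frozenset("ACGTN-RYSWKMBDHV")

#: Characters counted as unambiguous bases.
BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned specimen sequence with optional metadata labels."""

    id: str
    sequence: str
    population: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length collection of :class:`SequenceRecord`."""

    records: Tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            bad = self._ragged_ids()
            raise ValueError(
                "alignment is ragged; offending ids (minority lengths): "
                + ", ".join(bad)
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {', '.join(dupes)}")
        object.__setattr__(self, "length", len(self.records[0].sequence))

    def _ragged_ids(self) -> list[str]:
        from collections import Counter

        counts = Counter(len(r.sequence) for r in self.records)
        majority = counts.most_common(1)[0][0]
        return [r.id for r in self.records if len(r.sequence) != majority]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def window(self, start: int, end: int) -> "Alignment":
        """Restrict to a 1-based inclusive column interval.

        Coordinates refer to the columns of this alignment, not to any
        full-gene numbering the fragment may correspond to.
        """
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"window {start}-{end} outside alignment of length {self.length}"
            )
        return Alignment(
            tuple(
                replace(r, sequence=r.sequence[start - 1 : end]) for r in self.records
            )
        )

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.population and r.population not in seen:
                seen[r.population] = None
        return list(seen)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.species and r.species not in seen:
                seen[r.species] = None
        return list(seen)


def _clean_sequence(rec_id: str, raw: str) -> str:
    seq = raw.upper()
    if "U" in seq:
        logger.warning("sequence %s contains 'U'; mapped to 'T'", rec_id)
        seq = seq.replace("U", "T")
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in VALID_CHARS]
    if bad:
        pos, char = bad[0]
        raise ValueError(
            f"illegal character {char!r} in sequence {rec_id!r} at position {pos}"
        )
    return seq


def read_alignment(
    path: str | Path, window: Optional[Tuple[int, int]] = None
) -> Alignment:
    """Read an aligned FASTA file, optionally restricting to a column window.

    Sequences are uppercased; ``U`` is mapped to ``T`` with a warning.
    ``window`` is a 1-based inclusive ``(start, end)`` pair on the columns
    of the provided alignment.

    Raises
    ------
    ValueError
        On an empty file, ragged alignment (the error names the offending
        ids), or characters outside the DNA/IUPAC alphabet (the error
        names the first offending position).
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, sequence=_clean_sequence(rec.id, str(rec.seq))))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    aln = Alignment(tuple(records))
    if window is not None:
        aln = aln.window(*window)
    return aln


def read_popmap(path: str | Path, alignment: Alignment) -> Alignment:
    """Attach population/species labels from a specimen table.

    The table is a TSV with header columns ``id``, ``population``,
    ``species``.  Records absent from the table keep empty labels (with a
    warning); table rows whose id is not in the alignment are ignored with
    a warning; duplicate ids in the table are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "population", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"popmap missing columns: {', '.join(sorted(missing))}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate ids in popmap: {', '.join(dupes)}")

    table = df.set_index("id")
    known = set(alignment.ids)
    for unknown in sorted(set(table.index) - known):
        logger.warning("popmap id %s not present in alignment; ignored", unknown)

    new_records = []
    for rec in alignment.records:
        if rec.id in table.index:
            row = table.loc[rec.id]
            new_records.append(
                replace(rec, population=row["population"], species=row["species"])
            )
        else:
            logger.warning("no popmap entry for %s; labels left empty", rec.id)
            new_records.append(rec)
    return Alignment(tuple(new_records))


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def write_popmap(alignment: Alignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": alignment.ids,
            "population": [r.population for r in alignment.records],
            "species": [r.species for r in alignment.records],
        }
    ).to_csv(path, sep="\t", index=False)


def alignment_from_strings(
    seqs: Sequence[Tuple[str, str]],
    populations: Optional[dict] = None,
    species: Optional[dict] = None,
) -> Alignment:
    """Build an alignment from in-memory (id, sequence) pairs."""
    populations = populations or {}
    species = species or {}
    return Alignment(
        tuple(
            SequenceRecord(
                id=i,
                sequence=_clean_sequence(i, s),
                population=populations.get(i, ""),
                species=species.get(i, ""),
            )
            for i, s in seqs
        )
    )
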