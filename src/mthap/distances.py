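"""Kimura two-parameter (K2P) distances and group-mean summaries.

The K2P model corrects observed sequence divergence for multiple hits
while distinguishing transitions (A<->G, C<->T) from transversions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the per-site transition and transversion proportions after
pairwise deletion of gap/ambiguous sites.  Group means are taken over
haplotypes weighted equally (one sequence per haplotype), matching the
convention of distance tables built over unique haplotypes; standard
errors come from site bootstrap over alignment columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .alignment import BASES

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset(BASES)


class UndefinedDistanceError(ValueError):
    """Raised when a pairwise distance cannot be computed (no shared
    unambiguous sites, or K2P log argument non-positive)."""


@dataclass(frozen=True)
class PairwiseComparison:
    """Site-pattern counts for one sequence pair after pairwise deletion."""

    L: int
    P: float
    Q: float
    raw_diffs: int


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def count_site_patterns(a: str, b: str) -> PairwiseComparison:
    """Classify differing sites into transitions and transversions.

    Sites where either sequence has a gap, ``N`` or ambiguity code are
    excluded (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError("sequences have unequal length")
    L = 0
    ts = 0
    tv = 0
    for ca, cb in zip(a, b):
        if ca not in _UNAMBIGUOUS or cb not in _UNAMBIGUOUS:
            continue
        L += 1
        if ca != cb:
            if is_transition(ca, cb):
                ts += 1
            else:
                tv += 1
    if L == 0:
        raise UndefinedDistanceError("no comparable sites after pairwise deletion")
    return PairwiseComparison(L=L, P=ts / L, Q=tv / L, raw_diffs=ts + tv)


def k2p_distance(c: PairwiseComparison) -> float:
    """K2P distance in substitutions/site for one comparison.

    Raises :class:`UndefinedDistanceError` when divergence saturates the
    correction (1 - 2P - Q <= 0 or 1 - 2Q <= 0).
    """
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise UndefinedDistanceError(
            f"K2P undefined for P={c.P:.4f}, Q={c.Q:.4f} (saturated)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_pair(a: str, b: str) -> float:
    return k2p_distance(count_site_patterns(a, b))


def p_distance_pair(a: str, b: str) -> float:
    """Raw proportion of differing sites (pairwise deletion)."""
    c = count_site_patterns(a, b)
    return c.raw_diffs / c.L


def distance_matrix(
    seqs: Sequence[Tuple[str, str]], model: str = "k2p"
) -> pd.DataFrame:
    """Labeled symmetric distance matrix over (id, sequence) pairs.

    ``model`` is ``"k2p"`` or ``"p"`` (raw proportion).  Undefined pairs
    are set to NaN with a warning.
    """
    fn = {"k2p": k2p_pair, "p": p_distance_pair}[model]
    labels = [i for i, _ in seqs]
    n = len(labels)
    mat = np.zeros((n, n))
    undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = fn(seqs[i][1], seqs[j][1])
            except UndefinedDistanceError:
                d = np.nan
                undefined += 1
            mat[i, j] = mat[j, i] = d
    if undefined:
        logger.warning("%d undefined pairwise distances set to NaN", undefined)
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass(frozen=True)
class GroupMeanResult:
    """Mean distance over a set of pairs with its bootstrap/na SE."""

    estimate: float
    se: float
    n_pairs: int


def _pairs_within(group: Sequence[str]) -> List[Tuple[str, str]]:
    g = list(group)
    return [(g[i], g[j]) for i in range(len(g)) for j in range(i + 1, len(g))]


def _pairs_between(a: Sequence[str], b: Sequence[str]) -> List[Tuple[str, str]]:
    return [(x, y) for x in a for y in b]


def _mean_over_pairs(
    pairs: Iterable[Tuple[str, str]], seq_of: Dict[str, str]
) -> Tuple[float, int]:
    vals = []
    dropped = 0
    for x, y in pairs:
        try:
            vals.append(k2p_pair(seq_of[x], seq_of[y]))
        except UndefinedDistanceError:
            dropped += 1
    if dropped:
        logger.warning("%d saturated pairs dropped from group mean", dropped)
    if not vals:
        raise UndefinedDistanceError("all pairs undefined in group mean")
    return float(np.mean(vals)), len(vals)


def mean_within(
    group: Sequence[str], seqs: Dict[str, str], se: Optional[float] = None
) -> GroupMeanResult:
    """Mean K2P distance over unordered pairs within one group of
    haplotype ids.  ``seqs`` maps id -> sequence."""
    if len(group) < 2:
        raise ValueError("within-group mean needs at least 2 members")
    est, n = _mean_over_pairs(_pairs_within(group), seqs)
    return GroupMeanResult(estimate=est, se=float("nan") if se is None else se, n_pairs=n)


def mean_between(
    group_a: Sequence[str],
    group_b: Sequence[str],
    seqs: Dict[str, str],
    se: Optional[float] = None,
) -> GroupMeanResult:
    """Mean K2P distance over all cross pairs between two disjoint groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    est, n = _mean_over_pairs(_pairs_between(group_a, group_b), seqs)
    return GroupMeanResult(estimate=est, se=float("nan") if se is None else se, n_pairs=n)


def bootstrap_se(
    groups: Dict[str, Sequence[str]],
    seqs: Dict[str, str],
    replicates: int = 1000,
    seed: int = 0,
) -> Dict[Tuple[str, str], float]:
    """Site-bootstrap standard errors for within/between group means.

    Alignment columns are resampled with replacement ``replicates``
    times; the SE of a group mean is the standard deviation of that mean
    across pseudo-alignments.  Keys of the result are ``(label, label)``
    for within-group means (groups of size >= 2) and ordered
    ``(label_a, label_b)`` pairs for between-group means.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    labels = list(groups)
    length = len(next(iter(seqs.values())))
    rng = np.random.default_rng(seed)

    jobs: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for i, la in enumerate(labels):
        if len(groups[la]) >= 2:
            jobs[(la, la)] = _pairs_within(groups[la])
        for lb in labels[i + 1 :]:
            jobs[(la, lb)] = _pairs_between(groups[la], groups[lb])

    sums: Dict[Tuple[str, str], List[float]] = {k: [] for k in jobs}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            sid: "".join(s[c] for c in cols) for sid, s in seqs.items()
        }
        for key, pairs in jobs.items():
            est, _ = _mean_over_pairs(pairs, resampled)
            sums[key].append(est)
    return {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in sums.items()}


def group_distance_report(
    groups: Dict[str, Sequence[str]],
    seqs: Dict[str, str],
    replicates: int = 1000,
    seed: int = 0,
    percent: bool = False,
) -> pd.DataFrame:
    """Within- and between-group mean K2P distances with bootstrap SEs.

    One row per group pair; ``kind`` is ``within`` or ``between``.
    """
    ses = bootstrap_se(groups, seqs, replicates=replicates, seed=seed)
    scale = 100.0 if percent else 1.0
    rows = []
    labels = list(groups)
    for i, la in enumerate(labels):
        if len(groups[la]) >= 2:
            r = mean_within(groups[la], seqs, se=ses[(la, la)])
            rows.append(
                {
                    "group_a": la,
                    "group_b": la,
                    "kind": "within",
                    "d": r.estimate * scale,
                    "se": ses[(la, la)] * scale,
                    "n_pairs": r.n_pairs,
                }
            )
        for lb in labels[i + 1 :]:
            r = mean_between(groups[la], groups[lb], seqs, se=ses[(la, lb)])
            rows.append(
                {
                    "group_a": la,
                    "group_b": lb,
                    "kind": "between",
                    "d": r.estimate * scale,
                    "se": ses[(la, lb)] * scale,
                    "n_pairs": r.n_pairs,
                }
            )
    return pd.DataFrame(rows)


def write_distance_matrix(
    dm: pd.DataFrame, path: str | Path, fmt: str = "tsv", percent: bool = False
) -> None:
    """Write a labeled distance matrix as square TSV or PHYLIP-style
    lower triangle; values optionally scaled to percent."""
    out = dm * 100.0 if percent else dm
    if fmt == "tsv":
        out.to_csv(path, sep="\t")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(out)}\n")
            for i, label in enumerate(out.index):
                vals = " ".join(f"{out.iloc[i, j]:.6f}" for j in range(i))
                fh.write(f"{label}  {vals}\n" if vals else f"{label}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
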