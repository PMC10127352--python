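"""Strict-clock divergence dating from a UPGMA tree.

A strict molecular clock makes node height (substitutions/site from the
node down to any descendant tip) proportional to age.  Two routes from
heights to ages are provided:

* a grid of assumed divergence rates (e.g. 3, 5, 10, 20, 40 % per Myr):
  ``age = 2 * height / rate`` when the rate is a pairwise-divergence
  rate (the default), or ``age = height / rate`` per lineage;
* calibration points — externally dated nodes (e.g. a 1.7 Ma root) —
  fitted by least squares through the origin, giving a single scale
  factor applied to every node.

The tree itself is built by UPGMA (average linkage) from a distance
matrix, the deterministic clock-compatible choice; ties in the
agglomeration order are broken by the lexicographically smallest member
label so repeated runs agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd


@dataclass
class ClockTree:
    """Rooted ultrametric binary tree with per-node heights.

    ``tree`` is a dendropy tree whose internal nodes carry a ``height``
    attribute in substitutions/site; leaves have height 0.  Internal
    nodes are labeled ``node1..nodeK`` in agglomeration (join) order.
    """

    tree: dendropy.Tree
    heights: Dict[str, float] = field(default_factory=dict)

    @property
    def root_height(self) -> float:
        return self.tree.seed_node.height

    def internal_labels(self) -> List[str]:
        return [
            nd.label
            for nd in self.tree.preorder_node_iter()
            if not nd.is_leaf()
        ]

    def leaf_labels(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def mrca_height(self, labels: Sequence[str]) -> float:
        taxa = [self.tree.taxon_namespace.get_taxon(l) for l in labels]
        missing = [l for l, t in zip(labels, taxa) if t is None]
        if missing:
            raise ValueError(f"labels not in tree: {', '.join(missing)}")
        node = self.tree.mrca(taxa=taxa)
        return node.height

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def upgma(dist: pd.DataFrame) -> ClockTree:
    """Average-linkage agglomeration of a labeled distance matrix.

    Node height = join distance / 2, so the tree is ultrametric by
    construction.  When several pairs tie for the minimal distance, the
    pair whose sorted (smallest-member-label, smallest-member-label) key
    is lexicographically least is joined first.
    """
    labels = list(dist.index)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    # cluster state: id -> (member labels, node, size, height)
    clusters: Dict[int, dict] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.height = 0.0
        clusters[i] = {"members": [lab], "node": node, "size": 1}
    d: Dict[Tuple[int, int], float] = {
        (i, j): mat[i, j]
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    heights: Dict[str, float] = {}
    next_id = len(labels)
    join_counter = 0

    while len(clusters) > 1:
        # minimal distance with deterministic lexicographic tie-break
        best_key = None
        best_d = np.inf
        for (i, j), val in d.items():
            key = tuple(sorted((min(clusters[i]["members"]), min(clusters[j]["members"]))))
            if val < best_d - 1e-15 or (
                abs(val - best_d) <= 1e-15 and (best_key is None or key < best_key[1])
            ):
                best_d = val
                best_key = ((i, j), key)
        (i, j), _ = best_key

        join_counter += 1
        parent = dendropy.Node()
        parent.label = f"node{join_counter}"
        parent.height = best_d / 2.0
        heights[parent.label] = parent.height
        for cid in (i, j):
            child = clusters[cid]["node"]
            child.edge.length = parent.height - child.height
            parent.add_child(child)

        merged = {
            "members": clusters[i]["members"] + clusters[j]["members"],
            "node": parent,
            "size": clusters[i]["size"] + clusters[j]["size"],
        }
        ni, nj = clusters[i]["size"], clusters[j]["size"]
        new_d: Dict[Tuple[int, int], float] = {}
        for (a, b), val in d.items():
            if i in (a, b) or j in (a, b):
                continue
            new_d[(a, b)] = val
        for cid in clusters:
            if cid in (i, j):
                continue
            di = d.get((min(i, cid), max(i, cid)))
            dj = d.get((min(j, cid), max(j, cid)))
            new_d[(min(cid, next_id), max(cid, next_id))] = (
                ni * di + nj * dj
            ) / (ni + nj)
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        d = new_d
        next_id += 1

    root = next(iter(clusters.values()))["node"]
    tree.seed_node = root
    tree.is_rooted = True
    return ClockTree(tree=tree, heights=heights)


def ages_from_rates(
    tree: ClockTree, rates: Sequence[float], per_lineage: bool = False
) -> pd.DataFrame:
    """Node ages (Ma) over a grid of divergence rates.

    ``rates`` are in substitutions/site/Myr (0.03 for "3 % per Myr") and
    must be positive and strictly increasing.  By default a rate is
    interpreted as a pairwise-divergence rate, ``age = 2 * height / r``;
    ``per_lineage=True`` switches to ``age = height / r``.  Rows are
    internal nodes in join order, columns one per rate; ages under a
    smaller rate are always older (exact inverse scaling in r).
    """
    rates = list(rates)
    if any(r <= 0 for r in rates):
        raise ValueError("rates must be positive")
    if any(b <= a for a, b in zip(rates, rates[1:])):
        raise ValueError("rates must be strictly increasing")
    factor = 1.0 if per_lineage else 2.0
    rows = {}
    for label in tree.internal_labels():
        h = tree.heights[label]
        rows[label] = [factor * h / r for r in rates]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{100 * r:g}%" for r in rates]
    )


@dataclass(frozen=True)
class Calibration:
    """An externally dated node: the MRCA of ``labels`` is ``age_ma`` old."""

    labels: Tuple[str, ...]
    age_ma: float

    def __post_init__(self) -> None:
        if self.age_ma <= 0:
            raise ValueError("calibration age must be positive")


def calibrate(tree: ClockTree, calibrations: Sequence[Calibration]) -> pd.DataFrame:
    """Scale node heights to absolute ages using calibration points.

    The scale factor ``s`` minimizes ``sum_i (s * height_i - age_i)^2``
    over the calibration nodes (least squares through the origin);
    every node age is then ``s * height``.  Returns a frame with one row
    per internal node: height, age (Ma), plus the fit residual stored in
    ``frame.attrs['residual']`` and scale in ``frame.attrs['scale']``.
    """
    if not calibrations:
        raise ValueError("need at least one calibration point")
    hs = []
    ages = []
    for cal in calibrations:
        h = tree.mrca_height(cal.labels)
        if h <= 0:
            raise ValueError(
                f"calibration MRCA of {cal.labels} has zero height; cannot scale"
            )
        hs.append(h)
        ages.append(cal.age_ma)
    hs_arr = np.asarray(hs)
    ages_arr = np.asarray(ages)
    s = float(np.dot(hs_arr, ages_arr) / np.dot(hs_arr, hs_arr))
    residual = float(np.sum((s * hs_arr - ages_arr) ** 2))

    rows = {
        label: {"height": tree.heights[label], "age_ma": s * tree.heights[label]}
        for label in tree.internal_labels()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["scale"] = s
    out.attrs["residual"] = residual
    return out
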