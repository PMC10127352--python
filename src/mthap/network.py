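"""Median-joining haplotype networks.

A haplotype network displays the mutational relationships among unique
sequences: observed haplotypes are nodes sized by specimen count, edge
weights count differing sites, and "median vectors" (mv1, mv2, ...) are
inferred, unsampled intermediate haplotypes — Steiner points that shorten
the network.

Construction follows the classic median-joining scheme:

1. build the minimum spanning network (MSN): the union of all minimum
   spanning trees, relaxed by a tolerance ``epsilon`` (an edge (u, v) is
   admitted when d(u, v) <= minimax-path(u, v) + epsilon);
2. for every linked triple in the MSN compute the position-wise majority
   consensus (the median) and add candidates that strictly reduce the
   total network (spanning) cost, greedily and deterministically;
3. repeat until no median helps, then iteratively prune median vectors
   of degree <= 2 that do not lie on any shortest path between observed
   haplotypes.

Only variable alignment columns enter the computation; distances are
Hamming counts with pairwise deletion of gap/ambiguous sites.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .alignment import BASES

_UNAMBIGUOUS = frozenset(BASES)

#: cap on tie-expansion candidates per triple (all-distinct columns)
MAX_TIE_CANDIDATES = 32


def hamming(a: str, b: str) -> int:
    """Count of differing sites, skipping gap/ambiguous positions."""
    return sum(
        1
        for ca, cb in zip(a, b)
        if ca in _UNAMBIGUOUS and cb in _UNAMBIGUOUS and ca != cb
    )


def hamming_matrix(seqs: Sequence[Tuple[str, str]]) -> pd.DataFrame:
    """Labeled integer matrix of pairwise site differences."""
    labels = [i for i, _ in seqs]
    n = len(labels)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = hamming(seqs[i][1], seqs[j][1])
    return pd.DataFrame(mat, index=labels, columns=labels)


def variable_columns(seqs: Sequence[str]) -> List[int]:
    """0-based indices of columns with more than one unambiguous state."""
    cols = []
    for pos in range(len(seqs[0])):
        states = {s[pos] for s in seqs if s[pos] in _UNAMBIGUOUS}
        if len(states) > 1:
            cols.append(pos)
    return cols


def _mst_cost(dist: np.ndarray) -> float:
    if dist.shape[0] < 2:
        return 0.0
    return float(minimum_spanning_tree(dist).sum())


def _minimax(dist: np.ndarray) -> np.ndarray:
    """Minimax path weight between all node pairs (single-linkage join
    level): the smallest possible maximum edge over paths connecting the
    pair.  An edge belongs to some MST iff its weight equals this value."""
    n = dist.shape[0]
    mst = minimum_spanning_tree(dist).toarray()
    mst = np.maximum(mst, mst.T)
    g = nx.from_numpy_array(mst)
    minimax = np.zeros((n, n))
    # max edge along the unique MST path between each pair
    for src in range(n):
        stack = [(src, -np.inf)]
        seen = {src}
        while stack:
            node, high = stack.pop()
            for nb in g.neighbors(node):
                if nb in seen or mst[node, nb] == 0:
                    continue
                seen.add(nb)
                h = max(high, mst[node, nb])
                minimax[src, nb] = h
                stack.append((nb, h))
    return minimax


def minimum_spanning_network(
    dist: pd.DataFrame, epsilon: int = 0
) -> nx.Graph:
    """Union of all minimum spanning trees, relaxed by ``epsilon``.

    An edge (u, v) is included when d(u, v) <= join cost of u's and v's
    clusters + epsilon, i.e. d(u, v) <= minimax-path weight + epsilon.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    labels = list(dist.index)
    mat = dist.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if len(labels) < 2:
        return g
    mm = _minimax(mat)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] == 0:
                continue  # identical haplotypes should be pre-collapsed
            if mat[i, j] <= mm[i, j] + epsilon:
                g.add_edge(labels[i], labels[j], weight=float(mat[i, j]))
    return g


def _medians_of_triple(a: str, b: str, c: str) -> List[str]:
    """Position-wise majority consensus; 3-way ties expand into variants,
    capped at MAX_TIE_CANDIDATES, in lexicographic order."""
    options: List[Tuple[str, ...]] = []
    n_variants = 1
    for ca, cb, cc in zip(a, b, c):
        votes = (ca, cb, cc)
        best = max(set(votes), key=lambda ch: (votes.count(ch), ch))
        if votes.count(best) >= 2:
            options.append((best,))
        else:
            choices = tuple(sorted(set(votes)))
            options.append(choices)
            n_variants *= len(choices)
    if n_variants > MAX_TIE_CANDIDATES:
        # keep the lexicographically first completions only
        out = []
        for combo in itertools.islice(itertools.product(*options), MAX_TIE_CANDIDATES):
            out.append("".join(combo))
        return out
    return ["".join(combo) for combo in itertools.product(*options)]


def _linked_triples(g: nx.Graph) -> List[Tuple[str, str, str]]:
    """Node triples induced by >= 2 network edges (u-v and v-w linked)."""
    triples = set()
    for v in g.nodes:
        nbrs = sorted(g.neighbors(v))
        for u, w in itertools.combinations(nbrs, 2):
            triples.add(tuple(sorted((u, v, w))))
    return sorted(triples)


def median_joining(
    haplotypes: Sequence[Tuple[str, str]],
    epsilon: int = 0,
    counts: Optional[Dict[str, int]] = None,
) -> nx.Graph:
    """Median-joining network over observed haplotypes.

    Parameters
    ----------
    haplotypes:
        ``(haplotype_id, sequence)`` pairs; sequences equal length and
        pairwise distinct.
    epsilon:
        MSN relaxation tolerance (0 reproduces the strict union of MSTs).
    counts:
        Optional specimen counts stored as the ``count`` node attribute.

    Returns
    -------
    networkx.Graph
        Nodes carry ``kind`` (``observed``/``median``), ``sequence``
        (variable sites only), and ``count``; edges carry ``weight`` =
        number of differing sites.  Median vectors are named ``mv1`` ...
        in creation order.
    """
    counts = counts or {}
    ids = [h for h, _ in haplotypes]
    full = [s for _, s in haplotypes]
    if len(set(full)) != len(full):
        raise ValueError("haplotype sequences must be pairwise distinct")

    if len(ids) == 1:
        g = nx.Graph()
        g.add_node(ids[0], kind="observed", sequence="", count=counts.get(ids[0], 1))
        return g

    var_cols = variable_columns(full)
    seqs = {h: "".join(s[c] for c in var_cols) for h, s in haplotypes}
    observed = list(ids)

    def dist_frame(node_seqs: Dict[str, str]) -> pd.DataFrame:
        return hamming_matrix(list(node_seqs.items()))

    # -- median addition loop -------------------------------------------
    median_seqs: Dict[str, str] = {}
    mv_counter = 0
    while True:
        nodes = {**seqs, **median_seqs}
        dm = dist_frame(nodes)
        msn = minimum_spanning_network(dm, epsilon=epsilon)
        base_cost = _mst_cost(dm.to_numpy(dtype=float))

        existing = set(nodes.values())
        candidates: Dict[str, None] = {}
        for u, v, w in _linked_triples(msn):
            for med in _medians_of_triple(nodes[u], nodes[v], nodes[w]):
                if med not in existing:
                    candidates[med] = None

        best_seq = None
        best_reduction = 0.0
        for cand in sorted(candidates):
            trial = dict(nodes)
            trial["__cand__"] = cand
            cost = _mst_cost(dist_frame(trial).to_numpy(dtype=float))
            reduction = base_cost - cost
            if reduction > best_reduction + 1e-9:
                best_reduction = reduction
                best_seq = cand
        if best_seq is None:
            break
        mv_counter += 1
        median_seqs[f"_m{mv_counter}"] = best_seq

    # -- pruning ---------------------------------------------------------
    def build(nodes: Dict[str, str]) -> nx.Graph:
        return minimum_spanning_network(dist_frame(nodes), epsilon=epsilon)

    nodes = {**seqs, **median_seqs}
    while True:
        g = build(nodes)
        plen = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        removed = False
        for m in [n for n in nodes if n.startswith("_m")]:
            if g.degree(m) > 2:
                continue
            on_path = any(
                abs(plen[a].get(m, np.inf) + plen[m].get(b, np.inf) - plen[a][b]) < 1e-9
                for a, b in itertools.combinations(observed, 2)
                if b in plen.get(a, {})
            )
            if not on_path:
                del nodes[m]
                removed = True
                break
        if not removed:
            break

    # -- final graph with stable mv naming -------------------------------
    surviving = [m for m in median_seqs if m in nodes]
    rename = {m: f"mv{i + 1}" for i, m in enumerate(surviving)}
    final = nx.relabel_nodes(build(nodes), rename)
    for node in final.nodes:
        if node.startswith("mv"):
            final.nodes[node]["kind"] = "median"
            final.nodes[node]["count"] = 0
            seq = median_seqs[surviving[int(node[2:]) - 1]]
        else:
            final.nodes[node]["kind"] = "observed"
            final.nodes[node]["count"] = counts.get(node, 1)
            seq = seqs[node]
        final.nodes[node]["sequence"] = seq
    for _, _, data in final.edges(data=True):
        data["mutations"] = int(data["weight"])
    return final


def network_cost(g: nx.Graph) -> float:
    """Parsimony cost of the network: the weight of a minimum spanning
    tree within it.  (The network itself may carry additional tied edges
    — it is a union of spanning trees — so the plain edge-weight sum can
    exceed this.)"""
    if g.number_of_nodes() < 2:
        return 0.0
    return float(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_tree(g, weight="weight").edges(data=True))
    )


def write_network(g: nx.Graph, path: str, fmt: str = "graphml") -> None:
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gml":
        nx.write_gml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
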