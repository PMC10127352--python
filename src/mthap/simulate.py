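"""Synthetic haploid sequence datasets with known truth.

Genealogies come from the structured Kingman coalescent (island model,
via msprime): time is scaled so that a pair of lineages in the same deme
coalesces at rate 1 (E[T2] = 1), and each lineage migrates at rate M.
Sequences are then generated by a finite-sites, transition-biased
mutation process layered on the genealogy: each branch of length t
receives Poisson(theta/2 * t * L) mutations, each hitting a uniformly
chosen site; a mutation is a transition with probability kappa/(kappa+1)
and otherwise one of the two transversions, equiprobably.  Under this
scaling the expected pairwise difference per site equals theta.

Deterministic fixtures with planted haplotype structure (skewed
frequency spectra, fixed inter-population differences, star phylogenies)
are provided for exact-value tests of downstream stages.

All randomness flows from one integer seed through a splittable
generator: the seed is spawned into independent streams in a fixed
order (genealogy first, then mutation, then root-sequence draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import msprime
import numpy as np

from .alignment import Alignment, alignment_from_strings

PURINE_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    theta is the scaled mutation rate per site (expected pairwise
    diversity); migration is the island-model rate M per lineage;
    kappa the transition/transversion ratio of the mutation process.
    """

    sample_sizes: Tuple[int, ...] = (10,)
    theta: float = 0.01
    migration: float = 1.0
    seq_length: int = 549
    kappa: float = 4.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.sample_sizes or any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.theta < 0 or self.kappa <= 0 or self.seq_length < 1:
            raise ValueError("theta >= 0, kappa > 0, seq_length >= 1 required")
        if len(self.sample_sizes) > 1 and self.migration <= 0:
            raise ValueError("migration must be > 0 with multiple demes")

    @property
    def n_demes(self) -> int:
        return len(self.sample_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.sample_sizes)


@dataclass
class SimulatedDataset:
    alignment: Alignment
    popmap: Dict[str, str]
    genealogy: Optional[object]  # tskit.Tree-bearing TreeSequence, or None for planted fixtures
    true_params: dict


def _spawn_seeds(seed: int, n: int) -> List[int]:
    """Independent child seeds (< 2**31) in a fixed stream order."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in ss.spawn(n)]


def simulate_genealogy(config: SimulationConfig):
    """Structured-coalescent genealogy as a single-tree TreeSequence.

    Deme sizes are 1 in coalescent units (haploid ploidy), so branch
    lengths are in units where the within-deme pairwise coalescence rate
    is 1; migration is symmetric island-model at rate ``migration``.
    """
    anc_seed = _spawn_seeds(config.seed, 3)[0]
    if config.n_demes == 1:
        ts = msprime.sim_ancestry(
            samples=config.sample_sizes[0],
            population_size=1.0,
            ploidy=1,
            sequence_length=config.seq_length,
            random_seed=anc_seed,
        )
    else:
        demography = msprime.Demography.island_model(
            initial_size=[1.0] * config.n_demes,
            migration_rate=config.migration,
        )
        samples = [
            msprime.SampleSet(n, population=f"pop_{i}", ploidy=1)
            for i, n in enumerate(config.sample_sizes)
        ]
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            ploidy=1,
            sequence_length=config.seq_length,
            random_seed=anc_seed,
        )
    return ts


def mutate(
    genealogy,
    theta: float,
    kappa: float,
    seq_length: int,
    seed: int,
) -> Alignment:
    """Drop transition-biased finite-sites mutations on a genealogy.

    Each branch of length t gets Poisson(theta/2 * t * seq_length)
    mutations at uniform sites; a hit is a transition with probability
    kappa/(kappa+1).  Returns the tip alignment (ids ``s1..sn``).
    """
    rng = np.random.default_rng(seed)
    tree = genealogy.first()
    root_seq = rng.choice(np.array(list("ACGT")), size=seq_length)

    seqs: Dict[int, np.ndarray] = {}
    p_transition = kappa / (kappa + 1.0)

    order = list(tree.nodes(order="preorder"))
    for node in order:
        parent = tree.parent(node)
        if parent == -1:
            seqs[node] = root_seq.copy()
            continue
        seq = seqs[parent].copy()
        t = tree.branch_length(node)
        n_mut = rng.poisson(theta / 2.0 * t * seq_length)
        for _ in range(n_mut):
            site = int(rng.integers(0, seq_length))
            base = seq[site]
            if rng.random() < p_transition:
                seq[site] = PURINE_PARTNER[base]
            else:
                seq[site] = TRANSVERSIONS[base][int(rng.integers(0, 2))]
        seqs[node] = seq

    pairs = []
    pops = {}
    for i, sample in enumerate(genealogy.samples()):
        sid = f"s{i + 1}"
        pairs.append((sid, "".join(seqs[sample])))
        pops[sid] = f"pop_{genealogy.node(sample).population}"
    return alignment_from_strings(pairs, populations=pops)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genealogy + mutations end to end under one seed."""
    seeds = _spawn_seeds(config.seed, 3)
    ts = simulate_genealogy(config)
    aln = mutate(ts, config.theta, config.kappa, config.seq_length, seed=seeds[1])
    popmap = {r.id: r.population for r in aln.records}
    return SimulatedDataset(
        alignment=aln, popmap=popmap, genealogy=ts, true_params=asdict(config)
    )


# ---------------------------------------------------------------------------
# Deterministic planted fixtures
# ---------------------------------------------------------------------------

_FIXTURE_BASE_SEED = 2026_04


def _base_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=length)


def _with_substitutions(seq: np.ndarray, sites: Sequence[int]) -> np.ndarray:
    out = seq.copy()
    for s in sites:
        out[s] = PURINE_PARTNER[out[s]]  # transition keeps it simple
    return out


def make_fixture(profile: str, seq_length: int = 549) -> SimulatedDataset:
    """Named deterministic datasets with planted structure.

    ``table4_like``
        One locality ("Sarykum") with two species: 7 specimens of
        species "macedonicus" carrying 3 haplotypes with counts 5/1/1
        (pairwise differences 1, 1, 2 sites) and 3 specimens of species
        "musculus", all singleton haplotypes.
    ``two_pop_fixed``
        Two populations of 2 specimens, each fixed for its own haplotype
        (5 sites apart): complete differentiation (Phi-st = 1).
    ``star``
        One central haplotype (5 specimens) with five satellites one
        mutation away at distinct sites, all in one population.
    """
    rng = np.random.default_rng(_FIXTURE_BASE_SEED)
    base = _base_sequence(seq_length, rng)

    def s(arr: np.ndarray) -> str:
        return "".join(arr)

    if profile == "table4_like":
        # planted pairwise differences: mac1-mac2 = 1, mac1-mac3 = 1,
        # mac2-mac3 = 2 (distinct mutated sites)
        mac1 = base
        mac2 = _with_substitutions(base, [10])
        mac3 = _with_substitutions(base, [40])
        mus = [
            _with_substitutions(base, [100 + 7 * i, 200 + 7 * i, 300 + 7 * i, 400, 410, 420])
            for i in range(3)
        ]
        pairs = []
        pops = {}
        species = {}
        for i in range(5):
            pairs.append((f"mac_a{i + 1}", s(mac1)))
        pairs.append(("mac_b1", s(mac2)))
        pairs.append(("mac_c1", s(mac3)))
        for i, m in enumerate(mus):
            pairs.append((f"mus_{i + 1}", s(m)))
        for sid, _ in pairs:
            pops[sid] = "Sarykum"
            species[sid] = "macedonicus" if sid.startswith("mac") else "musculus"
        aln = alignment_from_strings(pairs, populations=pops, species=species)
    elif profile == "two_pop_fixed":
        hap_a = base
        hap_b = _with_substitutions(base, [5, 15, 25, 35, 45])
        pairs = [
            ("a1", s(hap_a)),
            ("a2", s(hap_a)),
            ("b1", s(hap_b)),
            ("b2", s(hap_b)),
        ]
        pops = {"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"}
        aln = alignment_from_strings(pairs, populations=pops)
    elif profile == "star":
        center = base
        pairs = [(f"c{i + 1}", s(center)) for i in range(5)]
        for i in range(5):
            sat = _with_substitutions(base, [50 + 11 * i])
            pairs.append((f"sat{i + 1}", s(sat)))
        pops = {sid: "popA" for sid, _ in pairs}
        aln = alignment_from_strings(pairs, populations=pops)
    else:
        raise ValueError(f"unknown fixture profile {profile!r}")

    popmap = {r.id: r.population for r in aln.records}
    return SimulatedDataset(
        alignment=aln,
        popmap=popmap,
        genealogy=None,
        true_params={"profile": profile, "seq_length": seq_length},
    )
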