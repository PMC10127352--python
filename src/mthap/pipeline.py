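"""End-to-end analysis driver.

One configured run takes an aligned FASTA plus specimen table and emits
every stage's output into a directory: haplotype table, K2P distance
matrices and group means, per-population diversity, pairwise
differentiation (both the frequency Fst and distance Phi-st), the
median-joining network, the UPGMA tree with rate-grid and calibrated
ages, a machine-readable JSON summary, and a manifest.  All randomness
(bootstrap, permutations) flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import __version__
from .alignment import Alignment, read_alignment, read_popmap, write_fasta
from .clock import Calibration, ClockTree, ages_from_rates, calibrate, upgma
from .differentiation import pairwise_differentiation
from .distances import distance_matrix, group_distance_report, write_distance_matrix
from .diversity import diversity_frame, diversity_report
from .haplotypes import collapse_haplotypes, base_composition, write_haplotype_table
from .network import median_joining, network_cost, write_network

logger = logging.getLogger(__name__)

DEFAULT_RATE_GRID = (0.03, 0.05, 0.10, 0.20, 0.40)


@dataclass
class RunConfig:
    fasta: str
    popmap: Optional[str] = None
    outdir: str = "mthap_out"
    window: Optional[Tuple[int, int]] = None
    n_perm: int = 10_000
    seed: int = 1
    bootstrap_replicates: int = 1000
    epsilon: int = 0
    rates: Tuple[float, ...] = DEFAULT_RATE_GRID
    calibrations: Tuple[Tuple[Tuple[str, ...], float], ...] = ()
    percent: bool = True

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise FileNotFoundError(self.fasta)
        if self.popmap is not None and not Path(self.popmap).exists():
            raise FileNotFoundError(self.popmap)
        if self.n_perm < 1 or self.bootstrap_replicates < 1:
            raise ValueError("n_perm and bootstrap_replicates must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_all(config: RunConfig) -> dict:
    """Run every pipeline stage; returns the JSON-ready summary dict.

    Outputs land in ``config.outdir``; any stage failure aborts with an
    error naming the stage, retaining the outputs written so far.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: List[str] = []
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            **asdict(config),
            "window": list(config.window) if config.window else None,
        },
    }

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    logging.getLogger("mthap").addHandler(handler)
    try:
        aln = _stage("read_alignment")(read_alignment)(config.fasta, window=config.window)
        if config.popmap:
            aln = _stage("read_popmap")(read_popmap)(config.popmap, aln)

        # --- haplotypes ------------------------------------------------
        table = _stage("haplotypes")(collapse_haplotypes)(aln)
        write_haplotype_table(table, outdir / "haplotypes.tsv")
        write_fasta(table.haplotypes, outdir / "haplotypes.fasta")
        manifest += ["haplotypes.tsv", "haplotypes.fasta"]
        comp = base_composition(aln)
        summary["n_specimens"] = len(aln)
        summary["alignment_length"] = aln.length
        summary["n_haplotypes"] = len(table.haplotypes)
        summary["base_composition"] = comp.as_dict()

        # --- distances -------------------------------------------------
        dm = _stage("distances")(distance_matrix)(table.haplotypes, model="k2p")
        write_distance_matrix(dm, outdir / "k2p_matrix.tsv", percent=config.percent)
        manifest.append("k2p_matrix.tsv")
        species_groups = {
            sp: [h for h in table.ids if table.species.get(h) == sp]
            for sp in sorted({s for s in table.species.values() if s})
        }
        species_groups = {k: v for k, v in species_groups.items() if v}
        seqs = dict(table.haplotypes)
        if len(species_groups) >= 1 and any(len(v) >= 2 for v in species_groups.values()):
            rep = _stage("group_distances")(group_distance_report)(
                species_groups,
                seqs,
                replicates=config.bootstrap_replicates,
                seed=config.seed,
                percent=config.percent,
            )
            rep.to_csv(outdir / "group_distances.tsv", sep="\t", index=False)
            manifest.append("group_distances.tsv")
            summary["group_distances"] = rep.to_dict(orient="records")

        # --- diversity -------------------------------------------------
        stats = _stage("diversity")(diversity_report)(aln)
        div = diversity_frame(stats)
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        manifest.append("diversity.tsv")
        summary["diversity"] = div.to_dict(orient="records")

        # --- differentiation ------------------------------------------
        pops_ok = [
            p
            for p in aln.populations()
            if sum(r.population == p for r in aln.records) >= 2
        ]
        if len(pops_ok) >= 2:
            rng = np.random.default_rng(config.seed)
            for metric, fname in (("equality", "fst"), ("differences", "phist")):
                res = _stage("differentiation")(pairwise_differentiation)(
                    aln,
                    metric=metric,
                    n_perm=config.n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    populations=pops_ok,
                )
                res.mixed_frame().to_csv(outdir / f"{fname}.tsv", sep="\t")
                res.long_frame().to_csv(outdir / f"{fname}_long.tsv", sep="\t", index=False)
                manifest += [f"{fname}.tsv", f"{fname}_long.tsv"]
                summary[fname] = res.long_frame().to_dict(orient="records")

        # --- network ---------------------------------------------------
        counts = {h: table.total_count(h) for h in table.ids}
        net = _stage("network")(median_joining)(
            table.haplotypes, epsilon=config.epsilon, counts=counts
        )
        write_network(net, str(outdir / "network.graphml"), fmt="graphml")
        write_network(net, str(outdir / "network.gml"), fmt="gml")
        manifest += ["network.graphml", "network.gml"]
        summary["network"] = {
            "n_median_vectors": sum(
                1 for _, d in net.nodes(data=True) if d["kind"] == "median"
            ),
            "n_edges": net.number_of_edges(),
            "total_cost": network_cost(net),
        }

        # --- clock dating ---------------------------------------------
        if len(table.haplotypes) >= 2:
            tree = _stage("upgma")(upgma)(dm)
            (outdir / "tree.nwk").write_text(tree.newick() + "\n")
            manifest.append("tree.nwk")
            ages = _stage("ages")(ages_from_rates)(tree, config.rates)
            ages.round(4).to_csv(outdir / "ages.tsv", sep="\t")
            manifest.append("ages.tsv")
            summary["root_height"] = tree.root_height
            if config.calibrations:
                cals = [Calibration(tuple(l), a) for l, a in config.calibrations]
                cal_ages = _stage("calibrate")(calibrate)(tree, cals)
                cal_ages.round(4).to_csv(outdir / "calibrated_ages.tsv", sep="\t")
                manifest.append("calibrated_ages.tsv")
                summary["calibration_scale"] = cal_ages.attrs["scale"]
                summary["calibration_residual"] = cal_ages.attrs["residual"]

        # --- summary / manifest ---------------------------------------
        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest.append("summary.json")
        (outdir / "manifest.json").write_text(
            json.dumps({"files": manifest}, indent=2) + "\n"
        )
        return summary
    finally:
        logging.getLogger("mthap").removeHandler(handler)
        handler.close()
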