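"""End-to-end pipeline: inputs (real or simulated) to tables, curves, zeta.

A run consumes either real inputs (alignment or occurrence matrix, island
table, consensus tree) or a simulation config, and produces in its output
directory:

* ``islands.csv``, ``occurrence.csv`` (and, for simulations,
  ``alignment.fasta`` + ``tree.nwk``);
* ``diversity.csv`` — per-island Sn, H, Hd, Pi, PD;
* ``distance_summary.csv`` — per-haplotype max/min p-distance;
* ``curves_<metric>.csv`` — LTS and STL accumulation curves;
* ``sloss.json`` — Psi, DeltaA, zeta per metric (both support modes);
* ``env_stats.csv`` / ``rda.json`` — driver statistics (optional);
* ``manifest.json`` — seed, parameters, package version, input checksums.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .env import (
    DEFAULT_TRANSFORMS,
    ENV_VARIABLES,
    fit_glm,
    mantel_suite,
    rda_hierpart,
    transform_env,
    vif_screen,
)
from .haplotypes import (
    HaplotypeSet,
    collapse_haplotypes,
    distance_matrix,
    distance_summary,
    diversity_table,
)
from .io import (
    read_alignment,
    read_islands,
    read_occurrence,
    read_tree,
    reconcile,
    sha256_of,
    write_alignment,
    write_diversity,
    write_json,
    write_occurrence,
)
from .phylo import PhyloTree, pd_by_island
from .simulate import SimulationConfig, simulate_island_system
from .sloss import accumulate_pd, accumulate_richness, zeta_statistic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of {real inputs, ``simulation``} must be active.  Real
    inputs are an island CSV plus either an alignment FASTA (collapsed
    into haplotypes in-run) or a haplotype-by-island occurrence CSV whose
    row labels match the tree tips.
    """

    out_dir: str | Path = "sloss_run"
    alignment: str | Path | None = None
    island_map: str | Path | None = None
    occurrence: str | Path | None = None
    islands: str | Path | None = None
    tree: str | Path | None = None
    simulation: SimulationConfig | None = None
    pd_convention: str = "root_inclusive"
    support: str = "common"
    n_perm: int = 999
    seed: int = 0
    env_stats: bool = True

    def __post_init__(self) -> None:
        real = self.alignment is not None or self.occurrence is not None
        if real == (self.simulation is not None):
            raise ValueError(
                "exactly one of real inputs (alignment/occurrence) or a "
                "simulation config must be given"
            )
        if real and self.islands is None:
            raise ValueError("real inputs require an island table")


@dataclass
class PipelineResult:
    out_dir: Path
    islands: pd.DataFrame
    haplotypes: HaplotypeSet
    tree: PhyloTree | None
    diversity: pd.DataFrame
    curves: dict[str, dict[str, object]]
    sloss: dict[str, dict]
    env: dict[str, object] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("slossgen")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    t0 = time.time()
    checksums: dict[str, str] = {}
    try:
        if config.simulation is not None:
            _stage("simulate")
            sim = config.simulation
            system = simulate_island_system(sim)
            islands = system.islands
            haps, tree = system.consensus_view()
            write_alignment(out / "alignment.fasta", system.alignment, system.island_map)
            (out / "tree.nwk").write_text(tree.to_newick() + "\n")
            islands.to_csv(out / "islands.csv")
            sequences, island_map = system.alignment, system.island_map
        else:
            _stage("load")
            islands = read_islands(config.islands)
            checksums[str(config.islands)] = sha256_of(config.islands)
            tree = None
            if config.tree is not None:
                tree = read_tree(config.tree)
                checksums[str(config.tree)] = sha256_of(config.tree)
            if config.alignment is not None:
                sequences, island_map = read_alignment(
                    config.alignment, config.island_map
                )
                checksums[str(config.alignment)] = sha256_of(config.alignment)
                _stage("collapse_haplotypes")
                haps = collapse_haplotypes(sequences, island_map)
            else:
                occ = read_occurrence(config.occurrence)
                checksums[str(config.occurrence)] = sha256_of(config.occurrence)
                reconcile(occ, islands)
                haps = HaplotypeSet(sequences={}, occurrence=occ)
                sequences, island_map = None, None

        reconcile(haps.occurrence, islands)

        _stage("diversity")
        pd_island = None
        if tree is not None:
            pd_island = pd_by_island(
                tree, haps.occurrence, convention=config.pd_convention
            )
        div = diversity_table(
            haps,
            sequences if haps.sequences else None,
            island_map if haps.sequences else None,
            pd_per_island=pd_island,
        )
        write_diversity(out / "diversity.csv", div)
        write_occurrence(out / "occurrence.csv", haps.occurrence)

        if haps.sequences and haps.n_haplotypes > 1:
            _stage("distance_summary")
            dmat = distance_matrix(haps)
            distance_summary(dmat).to_csv(out / "distance_summary.csv")

        _stage("accumulation_curves")
        curves: dict[str, dict[str, object]] = {"richness": {}}
        for order in ("STL", "LTS"):
            curves["richness"][order] = accumulate_richness(
                haps.occurrence, islands, order
            )
        if tree is not None:
            curves["pd"] = {
                order: accumulate_pd(
                    haps.occurrence, islands, tree, order, config.pd_convention
                )
                for order in ("STL", "LTS")
            }
        for metric, pair in curves.items():
            frame = pd.concat([c.to_frame() for c in pair.values()])
            frame.to_csv(out / f"curves_{metric}.csv", index=False)

        _stage("zeta")
        sloss: dict[str, dict] = {}
        for metric, pair in curves.items():
            sloss[metric] = {}
            for support in ("common", "full"):
                res = zeta_statistic(pair["STL"], pair["LTS"], support=support)
                sloss[metric][support] = res.as_dict()
        write_json(out / "sloss.json", sloss)

        env_results: dict[str, object] = {}
        if config.env_stats:
            _stage("env_stats")
            env_cols = [c for c in ENV_VARIABLES if c in islands.columns]
            if len(env_cols) >= 2 and len(islands) >= len(env_cols) + 2:
                env_raw = islands.loc[list(haps.occurrence.columns), env_cols]
                envt = transform_env(env_raw, DEFAULT_TRANSFORMS)
                screen = vif_screen(
                    envt, n_perm=config.n_perm, seed=config.seed
                )
                env_results["vif"] = screen
                screen.as_frame().to_csv(out / "vif.csv", index=False)
                retained = envt[screen.retained]
                hp = rda_hierpart(
                    haps.occurrence.T.loc[retained.index],
                    retained,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                env_results["rda"] = hp
                write_json(
                    out / "rda.json",
                    {
                        "r2_full": hp.r2_full,
                        "r2_adj": hp.r2_adj,
                        "F": hp.f_statistic,
                        "df": list(hp.df),
                        "p_model": hp.p_model,
                        "contributions": dict(
                            zip(hp.predictors, hp.contributions.tolist())
                        ),
                        "p_values": dict(zip(hp.predictors, hp.p_values.tolist())),
                        "n_perm": hp.n_perm,
                    },
                )
                mant = mantel_suite(
                    env_raw,
                    div,
                    n_perm=config.n_perm,
                    seed=config.seed,
                )
                env_results["mantel"] = mant
                mant.to_csv(out / "mantel.csv", index=False)
                glms = []
                for var, transform in (
                    ("AREA", "log10"),
                    ("COA", "identity"),
                    ("POP", "log10"),
                ):
                    if var not in env_raw.columns:
                        continue
                    fitres = fit_glm(
                        div["H"], env_raw.loc[div.index, var], transform
                    )
                    glms.append(
                        {
                            "response": "H",
                            "predictor": var,
                            "transform": transform,
                            "slope": fitres.slope,
                            "intercept": fitres.intercept,
                            "r_squared": fitres.r_squared,
                            "p_value": fitres.p_value,
                            "n": fitres.n,
                        }
                    )
                env_results["glm"] = pd.DataFrame(glms)
                env_results["glm"].to_csv(out / "glm.csv", index=False)
            else:
                logger.warning("island table too small for env statistics; skipped")

        _stage("manifest")
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "pd_convention": config.pd_convention,
            "support": config.support,
            "simulation": (
                config.simulation.as_dict() if config.simulation else None
            ),
            "input_checksums": checksums,
            "elapsed_s": round(time.time() - t0, 3),
        }
        write_json(out / "manifest.json", manifest)
        return PipelineResult(
            out_dir=out,
            islands=islands,
            haplotypes=haps,
            tree=tree,
            diversity=div,
            curves=curves,
            sloss=sloss,
            env=env_results,
            manifest=manifest,
        )
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
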