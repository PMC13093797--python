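"""Synthetic island systems with the structure the SLOSS analysis assumes.

The generator emulates a continental archipelago sampled for a single
moss species: ~28 islands with strongly log-skewed areas, sampling effort
increasing with log area (~350 specimens in total), a haplotype pool in
which most sampled haplotypes are island-endemic (~87% observed on one
island only), and a dominant widespread haplotype reaching ~75% frequency
on the largest island.

Default parameter values are calibrated to the per-island area and
specimen-count structure of the study system the package targets:
``ln(AREA)`` is approximately normal with mean 1.67 and SD 1.68 (areas
0.2-500 km^2), and expected specimen count per island follows
``max(1, round(5.16 + 10.19 * log10 AREA))``.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` in documented stage order: island table,
haplotype tree, sequence evolution, specimen assignment.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field, asdict
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .phylo import PhyloTree

__all__ = [
    "SimulationConfig",
    "IslandSystem",
    "simulate_island_table",
    "simulate_haplotype_tree",
    "evolve_sequences",
    "assign_specimens",
    "simulate_island_system",
]

logger = logging.getLogger(__name__)

ISLAND_COLUMNS = ["Island", "LON", "LAT", "AREA", "COA", "ISD", "ISW", "POP", "FRE"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic island-system generator.

    Attributes
    ----------
    n_islands
        Number of islands (>= 2).
    area_lognormal_mu, area_lognormal_sigma
        Mean and SD of ln(area in km^2).
    specimens_intercept, specimens_slope
        Expected specimen count per island is
        ``max(1, round(intercept + slope * log10 AREA))``.
    n_haplotype_pool
        Size of the archipelago-wide haplotype pool (tree tips).
    n_shared
        Leading pool haplotypes that may occur on any island; the first of
        them is the dominant haplotype.
    tree_model, birth_rate
        Haplotype genealogy model; only a Yule (pure-birth) process is
        implemented, with per-lineage ``birth_rate``.
    seq_length, mutation_rate
        Alignment length (bases) and substitutions/site per unit branch
        length under a Jukes-Cantor process.
    dominance
        Probability mass of the dominant haplotype: its frequency on the
        largest island, and the share of non-endemic draws it takes
        elsewhere.
    endemism_rate
        Probability that a non-dominant specimen draw comes from its
        island's private haplotype sub-pool.
    seed
        Global integer seed.
    """

    n_islands: int = 28
    area_lognormal_mu: float = 1.674
    area_lognormal_sigma: float = 1.677
    specimens_intercept: float = 5.16
    specimens_slope: float = 10.19
    n_haplotype_pool: int = 90
    n_shared: int = 10
    tree_model: str = "yule"
    birth_rate: float = 1.0
    seq_length: int = 450
    mutation_rate: float = 0.05
    dominance: float = 0.75
    endemism_rate: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islands < 2:
            raise ValueError("n_islands must be >= 2")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50")
        if self.n_haplotype_pool < 2:
            raise ValueError("n_haplotype_pool must be >= 2")
        if not 1 <= self.n_shared <= self.n_haplotype_pool:
            raise ValueError("n_shared must be in [1, n_haplotype_pool]")
        if self.tree_model != "yule":
            raise ValueError(f"unsupported tree model {self.tree_model!r}")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be nonnegative")
        for name in ("dominance", "endemism_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.area_lognormal_sigma < 0:
            raise ValueError("area_lognormal_sigma must be nonnegative")
        # smallest possible island must still expect at least one specimen
        if self.specimens_intercept + self.specimens_slope * (-3) < -1e9:
            raise ValueError("specimen coefficients out of range")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class IslandSystem:
    """One simulated archipelago: metadata, genealogy, alignment, counts."""

    islands: pd.DataFrame
    tree: PhyloTree
    alignment: dict[str, str]
    island_map: dict[str, str]
    occurrence: pd.DataFrame
    specimen_haplotype: dict[str, str] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        per_island = pd.Series(self.island_map).value_counts()
        occ_sums = self.occurrence.sum(axis=0)
        for island in self.occurrence.columns:
            if int(occ_sums[island]) != int(per_island.get(island, 0)):
                raise ValueError(
                    f"occurrence column sum mismatch for island {island!r}"
                )
        tips = set(self.tree.tip_labels)
        haps = set(self.occurrence.index)
        if tips != haps:
            raise ValueError(
                "tree tips and occurrence haplotypes disagree: "
                f"{sorted(tips ^ haps)[:5]}"
            )

    def consensus_view(self):
        """Collapse the alignment into haplotypes and match the tree to them.

        Returns a ``(HaplotypeSet, PhyloTree)`` pair in which haplotype ids
        (``H01`` ...) are assigned in first-occurrence order over the
        alignment and the tree is the pool genealogy pruned to one
        representative tip per collapsed haplotype, relabelled to the
        haplotype ids.  This mirrors the real workflow, where the consensus
        tree is built on the collapsed haplotypes rather than on the
        underlying pool.
        """
        from .haplotypes import collapse_haplotypes

        haps = collapse_haplotypes(self.alignment, self.island_map)
        rep_tip: dict[str, str] = {}
        for sid, hap_id in haps.specimen_map.items():
            rep_tip.setdefault(hap_id, self.specimen_haplotype[sid])
        pruned = self.tree._tree.extract_tree_with_taxa_labels(
            labels=sorted(set(rep_tip.values()))
        )
        # round-trip through newick: the extracted tree shares Taxon
        # objects with the source, and the relabelling below must not
        # touch the original system tree
        pruned = dendropy.Tree.get(
            data=pruned.as_string(schema="newick"), schema="newick"
        )
        tip_to_hap = {tip: hap for hap, tip in rep_tip.items()}
        for leaf in pruned.leaf_node_iter():
            leaf.taxon.label = tip_to_hap[leaf.taxon.label.replace(" ", "_")]
        return haps, PhyloTree(pruned)


def simulate_island_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw an island metadata table (area, coastline, isolation, people).

    AREA is log-normal; COA scales with sqrt(AREA) (perimeter-like), POP
    grows allometrically with AREA, FRE is an ordinal 1-5 accessibility
    level increasing with population, ISD and ISW describe isolation.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_islands
    area = np.exp(
        rng.normal(config.area_lognormal_mu, config.area_lognormal_sigma, n)
    )
    # coastline ~ perimeter of an irregular island: c * sqrt(area) * noise
    coa = 5.5 * np.sqrt(area) * np.exp(rng.normal(0.0, 0.25, n))
    isd = np.exp(rng.normal(3.1, 0.9, n))  # km to nearest island
    # remoter islands tend to sit in open water (higher land:water contrast)
    isw = np.clip(
        1 / (1 + np.exp(-(np.log(isd) - 3.1))) + rng.normal(0, 0.15, n), 0.0, 1.0
    )
    log10_pop = 2.9 + 1.05 * np.log10(area) + rng.normal(0.0, 0.5, n)
    pop = np.maximum(1, np.round(10**log10_pop)).astype(int)
    fre = np.clip(
        np.round(1 + 0.8 * np.log10(pop + 1) + rng.normal(0, 0.4, n)), 1, 5
    ).astype(int)
    lon = rng.uniform(121.5, 123.4, n)
    lat = rng.uniform(29.5, 31.1, n)
    ids = [f"I{k + 1:02d}" for k in range(n)]
    table = pd.DataFrame(
        {
            "Island": ids,
            "LON": np.round(lon, 2),
            "LAT": np.round(lat, 2),
            "AREA": area,
            "COA": np.round(coa, 2),
            "ISD": np.round(isd, 2),
            "ISW": np.round(isw, 2),
            "POP": pop,
            "FRE": fre,
        },
        index=pd.Index(ids, name="ID"),
    )
    return table


def simulate_haplotype_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> PhyloTree:
    """Yule (pure-birth) genealogy of the haplotype pool, time-unit branches."""
    if config.n_haplotype_pool < 2:
        raise ValueError("n_haplotype_pool must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    py_rng = random.Random(int(rng.integers(2**31)))
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(
        [f"P{k + 1:03d}" for k in range(config.n_haplotype_pool)]
    )
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_haplotype_pool,
        taxon_namespace=taxa,
        rng=py_rng,
    )
    # the simulator stops exactly at the n-th birth, leaving the newest
    # tips with zero-length edges; extend all tip edges by the residual
    # time to the next (unrealised) birth so terminal branches are positive
    residual = py_rng.expovariate(config.n_haplotype_pool * config.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + residual
    return PhyloTree(tree)


def evolve_sequences(
    tree: PhyloTree,
    seq_length: int,
    mutation_rate: float,
    rng: np.random.Generator | int,
) -> dict[str, str]:
    """Evolve one sequence per tip under Jukes-Cantor along the tree.

    Branch lengths are multiplied by ``mutation_rate`` to give the expected
    substitutions/site ``d`` on each edge; a site then differs from its
    parent with probability ``3/4 (1 - exp(-4 d / 3))``, the replacement
    base uniform over the other three.  Identical tip sequences can and do
    arise on short terminal branches.
    """
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be nonnegative")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    bases = np.array(list("ACGT"))
    seqs: dict[int, np.ndarray] = {}
    root = tree._tree.seed_node
    seqs[id(root)] = rng.integers(0, 4, size=seq_length)
    out: dict[str, str] = {}
    for node in tree._tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            d = (node.edge.length or 0.0) * mutation_rate
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            parent_seq = seqs[id(node.parent_node)].copy()
            hit = rng.random(seq_length) < p
            n_hit = int(hit.sum())
            if n_hit:
                parent_seq[hit] = (
                    parent_seq[hit] + rng.integers(1, 4, size=n_hit)
                ) % 4
            seqs[id(node)] = parent_seq
        if node.is_leaf():
            label = (node.taxon.label if node.taxon else node.label).replace(" ", "_")
            out[label] = "".join(bases[seqs[id(node)]])
    # free internal states
    return out


def _expected_specimens(config: SimulationConfig, area: np.ndarray) -> np.ndarray:
    n = np.round(config.specimens_intercept + config.specimens_slope * np.log10(area))
    return np.maximum(1, n).astype(int)


def _assign_counts(
    islands: pd.DataFrame,
    pool: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str]]:
    """Allocate specimens to haplotypes island by island.

    The first ``n_shared`` pool haplotypes are potentially widespread; the
    first of those is the dominant haplotype.  Each island receives a
    private sub-pool drawn without replacement from the remaining pool
    (target size ``max(1, round(sqrt(n_i)) - 1)``); endemic draws sample
    uniformly (with replacement) within it.  If the pool tail runs out,
    endemic draws fall back to shared draws and a warning is logged.
    """
    area = islands["AREA"].to_numpy(dtype=float)
    n_spec = _expected_specimens(config, area)
    largest = int(np.argmax(area))
    shared = pool[: config.n_shared]
    dominant = shared[0]
    tail = list(pool[config.n_shared :])
    occ = pd.DataFrame(0, index=pool, columns=islands.index, dtype=int)
    island_map: dict[str, str] = {}
    hap_of: dict[str, str] = {}
    exhausted_warned = False
    spec_no = 0

    def shared_draw() -> str:
        if len(shared) == 1 or rng.random() < config.dominance:
            return dominant
        return shared[1 + int(rng.integers(len(shared) - 1))]

    for i, island in enumerate(islands.index):
        m = max(1, int(round(np.sqrt(n_spec[i]))) - 1)
        take = min(m, len(tail))
        private = [tail.pop() for _ in range(take)]
        if take < m and not exhausted_warned:
            logger.warning(
                "haplotype pool exhausted; endemic draws fall back to shared"
            )
            exhausted_warned = True
        for _ in range(int(n_spec[i])):
            if i == largest and rng.random() < config.dominance:
                hap = dominant
            elif rng.random() < config.endemism_rate and private:
                hap = private[int(rng.integers(len(private)))]
            elif i == largest:
                # the non-dominant remainder on the largest island
                hap = (
                    shared[1 + int(rng.integers(len(shared) - 1))]
                    if len(shared) > 1
                    else dominant
                )
            else:
                hap = shared_draw()
            spec_no += 1
            sid = f"spec{spec_no:04d}"
            occ.loc[hap, island] += 1
            island_map[sid] = str(island)
            hap_of[sid] = hap
    occ = occ.loc[occ.sum(axis=1) > 0]
    return occ, island_map, hap_of


def assign_specimens(
    islands: pd.DataFrame,
    tree: PhyloTree,
    sequences: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> IslandSystem:
    """Place specimens on islands and build the full island system.

    Specimen counts per island grow with log10 area; on the largest island
    the dominant haplotype reaches frequency ~``dominance``; elsewhere a
    specimen is, with probability ``endemism_rate``, an endemic drawn from
    the island's private sub-pool.  The returned tree is pruned to sampled
    haplotypes and rescaled to substitutions/site (branch length x
    mutation_rate) so PD shares units with the sequence divergence.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pool = list(tree.tip_labels)
    occ, island_map, hap_of = _assign_counts(islands, pool, config, rng)
    sampled = list(occ.index)
    alignment = {sid: sequences[hap_of[sid]] for sid in island_map}

    pruned = tree._tree.extract_tree_with_taxa_labels(labels=sampled)
    for edge in pruned.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * config.mutation_rate
    system = IslandSystem(
        islands=islands,
        tree=PhyloTree(pruned),
        alignment=alignment,
        island_map=island_map,
        occurrence=occ,
        specimen_haplotype=hap_of,
        config=config,
    )
    return system


def simulate_island_system(config: SimulationConfig) -> IslandSystem:
    """End-to-end generation: table -> tree -> sequences -> assignment."""
    rng = np.random.default_rng(config.seed)
    islands = simulate_island_table(config, rng)
    tree = simulate_haplotype_tree(config, rng)
    sequences = evolve_sequences(tree, config.seq_length, config.mutation_rate, rng)
    return assign_specimens(islands, tree, sequences, config, rng)
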