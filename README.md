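# slossgen

Tools for testing the SLOSS question — *does a Single Large reserve or do
Several Small reserves of the same total area conserve more diversity?* —
at the **within-species** level, using haplotype data sampled across an
island system.

The package is written for population geneticists and conservation
planners who have, for one species: an aligned set of specimen sequences
(e.g. an ITS2 barcode) collected across islands or habitat patches, a
haplotype phylogeny, and per-island metadata (area, coastline, isolation,
human population, accessibility). It computes per-island diversity,
builds diversity accumulation curves under the two reserve-design
orderings, and quantifies their difference with a single discriminant.

## The statistic at the core

Islands are ranked by area and added cumulatively in both directions —
largest-to-smallest (LTS, the "single large first" strategy) and
smallest-to-largest (STL, "several small first"). At each accumulation
step the diversity of the accumulated haplotype union is recorded, either
as haplotype richness *H* or as Faith's phylogenetic diversity
PD (the summed branch lengths connecting the union's haplotypes in the
consensus tree). With Ψ the signed integral of the difference between the
STL and LTS curves over cumulative area *A*, and ΔA the width of the
integration support,

```
ζ = Ψ / ΔA
```

ζ > 0 means the several-small ordering accumulates more diversity per
unit of protected area; ζ < 0 favours the single large reserve.

Around this the package implements the full analysis chain:

* **haplotypes** — collapse of aligned specimens into haplotypes;
  p-distances with pairwise deletion; Nei's unbiased haplotype diversity
  Hd = n(1 − Σp̂ᵢ²)/(n − 1); nucleotide diversity π; per-island tables.
* **phylo** — Faith's PD for arbitrary tip subsets of a fixed tree,
  under `root_inclusive` (default) or `mrca_subtree` conventions.
* **sloss** — accumulation curves, ζ, Ψ, ΔA, with `common`/`full`
  integration supports and linear/step interpolation.
* **env** — permutation-assisted VIF screening (exclusion at VIF ≥ 10),
  RDA with Chevan–Sutherland hierarchical partitioning of explained
  variance, permutation Mantel tests, and OLS lines of diversity on
  island characteristics.
* **chromatogram** — secondary-peak base calling for bimodal Sanger
  traces (50% ratio threshold, 30% in repeat regions) and triplicate
  majority consensus.
* **simulate** — a calibrated synthetic island-system generator (Yule
  haplotype genealogy, Jukes–Cantor sequences, log-skewed island areas,
  tunable endemism and dominance) so the whole pipeline is testable
  without any field data.

## Worked example

```python
from slossgen import (SimulationConfig, simulate_island_system,
                      diversity_table, pd_by_island)
from slossgen.sloss import accumulate_richness, accumulate_pd, zeta_statistic

system = simulate_island_system(SimulationConfig(seed=42))
haps, tree = system.consensus_view()
print(len(system.alignment), haps.n_haplotypes, round(haps.endemism_fraction(), 2))
# 351 74 0.86   <- specimens, haplotypes, single-island haplotype fraction

div = diversity_table(haps, system.alignment, system.island_map,
                      pd_by_island(tree, haps.occurrence))
print(div.head(3).round(3))
#         Sn  H     Hd     Pi     PD
# Island
# I01     15  6  0.819  0.137  0.529
# I02      5  3  0.700  0.136  0.443
# I03     18  7  0.856  0.145  0.578

stl = accumulate_richness(haps.occurrence, system.islands, "STL")
lts = accumulate_richness(haps.occurrence, system.islands, "LTS")
print(zeta_statistic(stl, lts))
# SlossResult(metric='richness', psi=7199.12, delta_a=245.91, zeta=29.28, ...)
```

On this simulated archipelago the smallest-first strategy conserves ~29
extra haplotypes per km² of protected area (ζ_H = 29.28); the same
computation on PD curves gives ζ_PD = 0.95. Positive values of both —
the several-small advantage — are the expected outcome whenever
small-island endemism is strong, and arise for the same reason as in
real archipelago data: rare haplotypes confined to small islands are
picked up early by the STL ordering.

The same analyses run from the shell:

```
slossgen simulate --out sim --seed 42
slossgen run --seed 42 --out run42          # full pipeline on synthetic data
slossgen sloss --occurrence occ.csv --islands islands.csv --tree tree.nwk
slossgen diversity --alignment aln.fasta --islands islands.csv --tree tree.nwk
slossgen envstats --islands islands.csv --diversity diversity.csv --occurrence occ.csv
slossgen callbases --traces traces_dir/ --nonrepeat 0.5 --repeat 0.3
```

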