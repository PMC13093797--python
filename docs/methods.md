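# Methods

This note records the statistical conventions, parameter choices and
known limitations behind each stage of the package.

## Diversity estimators

**Haplotype collapsing.** Specimens join the earliest haplotype from
which they show zero differences over comparable positions (both
sequences unambiguous A/C/G/T). Sequences that differ only at gap or
ambiguity positions are therefore merged into the earlier haplotype,
matching the behaviour of standard haplotype software. This greedy
first-match rule is order-dependent in the (rare) case where a partially
ambiguous sequence is compatible with two earlier haplotypes; input
order — first occurrence in the alignment — decides, and ids (`H01`,
`H02`, …) record that order.

**Distances.** All distances between sequences are uncorrected
p-distances with pairwise deletion: positions carrying a gap or non-ACGT
symbol in either sequence are excluded from numerator and denominator.
No multiple-hit correction is applied; at the divergence scale of an
intraspecific barcode (p ≤ ~0.3) this is the conventional choice, and a
single substitution in a ~450-site alignment yields the granularity
(~0.002) seen in real tables.

**Haplotype diversity.** Nei's unbiased estimator
Hd = n(1 − Σp̂ᵢ²)/(n − 1). With a single haplotype Hd is *undefined*, not
zero: the statistic is reported as NaN in machine-readable output and as
an em-dash in pretty tables. Samples of n < 2 are errors, not NaN.

**Nucleotide diversity.** π is the mean pairwise p-distance over all
C(n,2) specimen pairs. On gap-free data this equals the
frequency-weighted form Σᵢ<ⱼ xᵢxⱼ dᵢⱼ / C(n,2) over haplotype counts x
and haplotype distances d, which is what the pipeline uses when only an
occurrence matrix (no alignment) is supplied — except that without
sequences no distances exist at all, in which case π is reported missing.

## Faith's phylogenetic diversity

PD of a tip subset is the sum of branch lengths of the tree structure
connecting the subset. The default convention, `root_inclusive`, also
counts the path from the subset's most recent common ancestor to the
root, so a singleton's PD is its tip-to-root path length. This matches
the common default of R phylogenetic-diversity tooling and is the only
convention compatible with strictly positive PD on single-haplotype
islands. `mrca_subtree` (singleton → 0) is available by flag. Branch
lengths are mandatory; polytomies are allowed; absent lengths raise
rather than being silently treated as unit lengths.

The implementation marks the union of tip-to-root paths (O(subset ×
depth)) and is tested against a brute-force oracle that unions edges
along all pairwise tip paths, and against scikit-bio's implementation
for the root-inclusive case.

## Accumulation curves and ζ

Islands are sorted by area (ties broken by island id, stable — this is
documented because Ψ can shift under re-ordering of equal-area islands);
the k-th point of a curve has x = cumulative area and y = diversity of
the accumulated haplotype union. By construction the STL and LTS curves
share their final point exactly.

Between accumulation points the curves are interpolated linearly
(matching how such trajectories are drawn); a step mode is available.
Ψ = ∫(STL − LTS) dA is evaluated by the trapezoid rule on the merged
breakpoint grid, which is exact for piecewise-linear integrands; ζ =
Ψ/ΔA.

Two integration supports are computed and reported side by side, because
the extent over which such integrals are taken is a genuine convention
choice: `common` uses the overlap of the two curves' x-extents (from the
largest single island's area to the total area — the region where both
strategies are defined without extrapolation), and `full` extends both
curves to (0, 0) and integrates from zero. Nothing in the package
hard-codes any particular ΔA value. Curves are *not* rarefied by
specimen count; unions of raw haplotype sets are accumulated.

## Environmental-driver statistics

**VIF screening.** VIFⱼ = 1/(1 − R²ⱼ) from regressing predictor j on the
others; predictors are excluded iteratively (largest offender first,
recompute) at the conventional threshold 10. Because "expected VIF under
no collinearity" depends on n and k, a permutation reference
distribution — each column permuted independently, 999 times by
default — is computed and its 95% quantile reported per predictor as
context for the fixed threshold. Perfect collinearity yields +inf and
exclusion.

**RDA and hierarchical partitioning.** The response (islands ×
haplotypes) is Hellinger-transformed by default (square root of
row-relative counts), the standard pre-transformation for RDA on
community-like count data; raw and presence/absence modes are available
since the appropriate transformation is data-dependent and materially
changes explained-variance figures. Predictors are z-scored. The full
model's explained variance is the redundancy statistic R² =
‖ŶC‖²/‖YC‖² (sums over all response columns); the overall test is the
standard pseudo-F, F = (R²/k)/((1 − R²)/(n − 1 − k)). Each predictor's
independent contribution is its incremental R² averaged over all k!
orderings (computed over the 2^k subsets with factorial weights —
Chevan & Sutherland); these contributions sum exactly to the full-model
unadjusted R², which the tests assert to 1e-8. Significance of the model
and of each contribution comes from permuting response rows (999 by
default, explicit seed). k > 12 predictors is refused outright.

**Mantel tests.** r is the Pearson correlation of lower-triangle
vectors; the null permutes rows and columns of the second matrix
simultaneously; p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), one-sided
"greater" by default since the working hypothesis is positive
association. Distances for both environment variables and diversity
metrics are Euclidean on standardized values — a documented choice, as
is the sidedness. Islands with an undefined metric value (Hd on
monomorphic islands) are dropped pairwise. No multiple-testing
correction is applied across the variable × metric grid; p-values are
per-test and flagged as such in the output.

**Linear models.** Ordinary least squares of a diversity metric on one
predictor, with log10 transforms for AREA and POP (spanning 2–3 orders
of magnitude); slope p-values are two-sided t-tests.

## Synthetic island systems

The generator emulates the study design the analysis was built for: a
~28-island continental archipelago, ~350 specimens of one wall moss,
high small-island endemism, and one dominant widespread haplotype.

* **Areas** are log-normal; the defaults ln-mean 1.674 and ln-SD 1.677
  are least-squares fits to the published per-island areas of the
  target archipelago (0.2–500 km², strongly right-skewed).
* **Sampling effort** per island is deterministic given area:
  max(1, round(5.16 + 10.19·log₁₀AREA)) — a fit to the published
  per-island specimen counts; on the real areas it totals 354 vs the
  study's 352.
* **Genealogy** is a Yule pure-birth tree over the haplotype pool
  (default 90 tips, birth rate 1). The simulator stops at the n-th
  birth, which would leave two zero-length tip edges; every tip edge is
  extended by the Exp(nλ) residual time to the next unrealised event, the
  standard way to sample a Yule tree at a uniform time.
* **Sequences** evolve under Jukes–Cantor along branches (d = branch
  length × mutation rate; per-site difference probability
  ¾(1 − e^(−4d/3))). Identical tips may arise and are legitimately
  collapsed downstream. The default rate 0.05/unit makes maximum
  pairwise tip distances ≈ 0.3, matching the upper range of real
  intraspecific ITS2 divergence in the target system.
* **Assignment.** The first `n_shared` (10) pool haplotypes are
  potentially widespread; the first of them is dominant. On the largest
  island each specimen is the dominant haplotype with probability
  `dominance` (0.75); otherwise, and on all other islands, a specimen is
  with probability `endemism_rate` an endemic draw from the island's
  private sub-pool (target size max(1, round(√nᵢ) − 1), drawn without
  replacement from the pool tail), else a shared draw (dominant with
  probability `dominance`, otherwise uniform over the other shared
  haplotypes). If the pool tail is exhausted, endemic draws fall back to
  shared draws with a logged warning.

`endemism_rate` is a per-specimen probability, not the realised
single-island haplotype fraction; the default 0.65 was calibrated once so
that the *emergent* structure matches the target system — across 200
seeds: ≈356 specimens, ≈74 observed haplotypes, ≈0.89 single-island
fraction, dominant frequency ≈0.75 on the largest island.

All stochastic stages draw from one `numpy` Generator seeded by the
single config seed, in fixed order (island table → tree → sequences →
assignment), so a config and seed determine the system byte-for-byte.

**What the generator does not emulate:** spatially explicit dispersal
(no distance-dependent colonization), selection, diploid genetics, ITS
pseudogenes/paralogy, sequencing error, and any real geography (island
coordinates are decorative). Pipeline tests passing on synthetic systems
therefore demonstrate the correctness and sign-recovery behaviour of the
*method*, not biological claims about any real archipelago.

## Base calling

Secondary-peak calling operates on L×4 peak-height tables. The primary
base is the argmax (ties broken A<C<G<T); a secondary peak whose ratio
to the primary *strictly exceeds* the threshold (0.50; 0.30 in repeat
regions) yields the two-base IUPAC code. "Repeat region" defaults to
positions inside homopolymer runs of length ≥ 4 in the primary-base
sequence and can be overridden with an explicit mask. Triplicate
consensus keeps per-position calls supported by ≥ 2 of 3 replicates;
full three-way disagreement yields `N` plus an entry in the returned
disagreement report (a convention — treating it as an error would
discard otherwise usable traces). Calling is invariant to rescaling all
heights, and raising either threshold can only reduce the number of
ambiguity codes; both properties are tested.

## Numerical and degenerate-input choices

* Undefined Hd → NaN; single-specimen islands report H=1, Hd NaN, π=0.
* Zero-specimen islands are excluded from tables with a warning.
* Mutation rate 0 end-to-end: one haplotype, flat PD curves, ζ = 0 for
  both metrics (asserted in tests).
* Trapezoid integration is exact on the piecewise-linear curves it is
  applied to; tests compare it against symbolic integration.
* Permutation p-values use the (1 + hits)/(n_perm + 1) estimator, which
  never returns 0.

## Problem sizes

Default test-suite simulations use the calibrated 28-island, ~350
specimen, 90-haplotype-pool conditions; replicate counts (200 for
endemism calibration, 100 for sign-recovery, 2000 for the OLS type-I
check) were chosen to make binomial/Monte-Carlo noise small relative to
the asserted margins while keeping a full run in a few minutes.

## Known limitations

* The greedy ambiguity-merging rule in haplotype collapsing is
  order-dependent in edge cases (see above).
* Occurrence-only input cannot produce π (no sequence distances).
* The Mantel distance/sidedness and RDA response transformation are
  conventions; results that depend on them (notably explained-variance
  percentages) should be compared across modes before interpretation.
* ζ depends on the integration-support convention; both supported modes
  are always reported and should be quoted with the result.
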