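# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genotype space

Genotypes are strings over {0,1} of length L (default 14): the allele
index at each variable position of a combinatorially complete library
spanning two reference ribozyme sequences that differ at every one of
those positions. Internally a genotype is the integer whose bit p is
the allele at position p, so the single-mutant neighbor at position p of
genotype `i` is `i ^ (1 << p)`; all landscape scans and the simulator
work directly on dense vectors indexed by this code. Nucleotide
identities are a display concern only (an optional per-position allele
map); every computation depends solely on the biallelic structure.
Position indices are 0-based everywhere, including file formats.

## Fitness estimation

**Self-cleavage assay.** Per replicate, a genotype's activity is its
fraction cleaved, `cleaved / (cleaved + uncleaved)`, divided by the
fraction cleaved of a designated normalizer genotype (so the normalizer
scores exactly 1). The normalizer is a required parameter: the
published analyses normalized to a previously characterized prototype
whose identity is not part of the data files, and any complete table can
be re-anchored by supplying a different genotype.

**Ligation assay.** Per replicate, enrichment is the post-selection
relative abundance divided by the pre-selection relative abundance,
normalized by the same ratio for the normalizer. Normalization is
applied per replicate before averaging; a pooled variant (average first,
normalize once) is provided for sensitivity analysis since the order is
not identifiable from the published description.

For both assays, fitness is the mean of per-replicate values and
*delta* the standard error of that mean. A genotype is **active** only
if its detection counts (cleaved reads, or post-selection reads) are ≥ 1
in every replicate and ≥ 3 in total; inactive genotypes get fitness 0 —
not missing — so that every downstream consumer sees a total function on
the hypercube. Genotypes absent pre-selection are flagged in a QC tally
rather than silently dropped. Fitness-to-rate conversion is linear
through the origin, anchored by one (fitness, rate) calibration pair;
literature rate constants for the uncatalyzed background reactions
(7×10⁻⁷ min⁻¹ cleavage; 2.4×10⁻¹⁰ and 1.5×10⁻⁸ min⁻¹ nonenzymatic
ligation for 2′,5′ and 3′,5′ linkages) are bundled as defaults for
context.

## Landscape topography

**Peaks.** A genotype is a strict peak when every single-mutant
neighbor has lower fitness; ties break toward "not a peak". The
error-aware rule demands the advantage be resolvable given replicate
error: `W(g) − m·δ(g) > W(h) + m·δ(h)` for every neighbor h, with
margin multiplier m. The exact inequality used in the original
analysis of the measured landscapes is not published, so m is exposed
(`calibrate_peak_margin` scans a grid against an external reference
peak count); the default is m = 1, chosen a priori as the plain reading
of "incorporates the measurement error".

**Ruggedness** is the mean number of within-subgraph peaks over all
k-position sub-hypercubes (k = 4: C(14,4)·2¹⁰ = 1,025,024 subgraphs of
16 genotypes), with the neighbor relation restricted to the subgraph.
Because the subgraphs of a fixed position set partition the space, the
scan is vectorized per position set. Enumerating one background per
position set versus all backgrounds yields the same average (every
subgraph is counted exactly once either way); both enumeration modes
are accepted. An additive landscape scores exactly 1; a constant one
scores 0 (no strict maxima).

**Pairwise epistasis** for a 2-position subgraph with corners W_0, W_A,
W_B, W_AB is `ε = log10(W_AB·W_0 / (W_A·W_B))` — the second difference
of log-fitness. Re-labeling a single-mutant corner as the background
negates ε while the opposite corner preserves it, so each subgraph
carries equal positive and negative values and only the magnitude |ε|
is reported, once per subgraph. Subgraphs with any corner at fitness 0
are skipped (log undefined) and counted; no pseudocount is applied,
because any choice of pseudocount would dominate the statistic exactly
where the data say "below detection". Sign-epistasis classification
(none / magnitude / sign / reciprocal) compares the sign of each
mutation's effect across the two backgrounds; reciprocal sign epistasis
— both effects flip — is the configuration that separates peaks by
fitness valleys.

**Escape trajectories** from a genotype g count ordered choices of k
distinct positions whose combined flip lands on a fitter genotype, out
of L·(L−1)···(L−k+1) possible (182 and 2,184 at L = 14 for k = 2, 3).
Local peaks with few escape routes are the stasis genotypes at which
simulated populations plateau.

## Network proximity

A genotype network at cutoff c is {g : W(g) ≥ c}. For each member of
one network the package reports the minimum Hamming distance to a
qualifying member of the other network, under two threshold readings:
`cutoff` (both networks use the same c) and `matched` (the target must
meet the *source genotype's own* fitness — "equivalent or greater").
Both are exposed because the published description admits either;
`cutoff` is the default. Distances are computed by a chunked
XOR/popcount scan over the full space — exact, oracle-checked against
breadth-first search — and distance 0 is allowed for genotypes on both
networks. Intersection sequences are genotypes with nonzero fitness
for both functions; exact dominance ties resolve deterministically to
the first function and are tallied.

## Wright–Fisher simulation

Each generation of the constant-size population is rebuilt by rejection
sampling: draw a parent uniformly, accept iff its fitness ≥ u with
u ~ Uniform(0,1), then mutate the accepted offspring with probability μ
at one uniformly chosen position; repeat until N placements. Two
consequences of this published scheme are kept deliberately: fitness
above 1 always survives (selection is flattened among genotypes all
above 1), and the offspring distribution given the current population
is multinomial with probabilities ∝ count·min(W,1) — which is how the
test suite checks the sampler (chi-square on 20,000 draws), along with
the neutral-drift martingale and the two-genotype selection expectation
2/3. The implementation draws parents in numpy batches; batching does
not change the offspring law. Defaults N = 1,000, μ = 0.01,
1,000 generations follow the parameter regime established for these
landscapes (higher μ reaches summits too fast to resolve differences
between starting genotypes; lower μ shows no evolution on this time
scale).

Scenarios: `select` (selection for the target function from generation
0 — the post-duplication model), `neutral_then_select` (drift only for
the first n generations: every parent accepted, including zero-fitness
ones), and `coselect` (fitness = β_HDV·Ŵ_HDV + β_Ligase·Ŵ_Ligase with
each landscape first normalized by its own maximum). A run whose
population is entirely at fitness 0 under selection raises an
extinction error (provably no offspring); a draw-budget guard
(N×10⁶ parent draws per generation) converts near-zero-fitness
pathologies into the same diagnosable error instead of hanging.
Replicate i of a batch uses seed base+i; traces are bit-reproducible
from the seed and record mean fitness (selection-relevant and both
components), the number of unique genotypes present, and the cumulative
set of genotypes ever observed.

Founder choice for duplication scenarios mirrors the original design:
candidates are ranked by old-function fitness among genotypes with
nonzero new-function fitness (`rank_start_genotypes`); immediate
selection from a fitness-0 founder is biologically an extinction, not
an adaptation experiment.

## Adaptation statistics

The initial rate is `(f[200] − f[0]) / 200` on the replicate-averaged
trace (a caption-style variant, endpoint fitness divided by the
horizon, is available behind a flag; the difference formula is treated
as authoritative). The maximum growth rate is the largest first
derivative of a cubic smoothing spline fit to the whole trace,
evaluated on a dense grid; the smoothing level follows generalized
cross-validation (`scipy.interpolate.make_smoothing_spline` with
lam=None) because no published smoothing parameter exists — exact
replication of previously printed maximum growth rates is therefore not
attempted, and a fixed-lam override is provided. Constant traces
return 0. Batch summaries add final fitness, unique genotypes explored
(per replicate and pooled) and the fraction of replicates in which the
summit genotype was ever present.

## Synthetic data generator

The generator provides the study conditions for every test and for the
acceptance run, emulating the statistical structure of the measured
system without shipping any data.

**Landscapes.** Rough-Mount-Fuji:
`W(g) = max(0, 1 − s·d(g, ref) + η_g)` with η_g ~ N(0, σ²) i.i.d. The
slope s = 0.07 keeps baseline fitness slightly positive across the
whole space (on the measured landscapes, ligation activity is detected
for every genotype), and σ is the single ruggedness knob. The default
dual pair places the two references at maximal distance L and is
deliberately asymmetric — σ_a = 0.2 yields a severely rugged landscape
(hundreds of local peaks whose surrounding drops can trap an adapting
population), σ_b = 0.03 a gently rough, nearly single-peaked one —
reproducing the qualitative contrast between the self-cleavage and
ligation landscapes that motivates the simulation experiments. A
`dual_fraction` (default 0.3) of mid-distance genotypes is guaranteed a
small activity floor (0.02) on both landscapes: synthetic intersection
sequences. A multiplicative (zero-epistasis, single-peak) generator
serves as the control family.

**Read counts.** Cleavage assay: per replicate, Poisson read totals
(mean 369/genotype) with binomial cleaved counts at probability
`clamp(W·p_ref, 0, 1)`, p_ref = 0.5 the normalizer's true cleaved
fraction. Ligation assay: Poisson pre-counts (mean 230) and Poisson
post-counts proportional to fitness, rescaled per replicate so the mean
post depth stays nominal. Clamped probabilities are tallied in QC.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequencing errors that create spurious
genotypes, PCR amplification bias, overdispersion beyond Poisson,
correlated replicate errors, and any secondary-structure-driven
correlation structure in the fitness values themselves. Conclusions
about the *estimators* (recovery, depth scaling) and the *simulator*
transfer; conclusions about any particular measured landscape's
topography of course do not.

## Problem sizes

The default test and acceptance runs use the full 2¹⁴ space for
combinatorics, estimation and topography; exhaustive brute-force
cross-checks run at L ≤ 8. Simulation experiments use 17 founders × 6
replicates per direction for the duplication comparison, 100 replicates
for the neutral-phase experiment, and 50 replicates per β setting for
coselection, all at N = 1,000 for 1,000 generations (600 for
coselection, which resolves by then). These sizes give stable rate
contrasts while keeping a complete run within minutes on one CPU.

## Known limitations

* The error-aware peak margin cannot be calibrated without an external
  reference peak count; with the bundled synthetic data only the strict
  and default (m = 1) rules are exercised.
* Rates above fitness 1 are not distinguished by the sampler (by
  design, see above); landscapes whose interesting structure lies above
  1 should be rescaled before simulation.
* The spreadsheet converter restores leading zeros stripped by
  spreadsheet software by left-padding all-digit genotype columns; a
  workbook mixing genuine variable-length genotypes would be
  misinterpreted (not a case that arises for fixed-L libraries).
* `matched`-mode proximity is quadratic in the space size (chunked
  popcount scan); at L = 14 it runs in seconds, but the approach does
  not extend far beyond L ≈ 16.
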