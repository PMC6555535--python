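# riboland

Analysis of a fitness landscape where two genotype networks intersect —
and of what that intersection means for the evolution of new molecular
functions.

## The problem

Two catalytic RNAs — a self-cleaving HDV ribozyme and a ligase ribozyme
— have reference sequences that differ at L = 14 nucleotide positions.
The 2^14 = 16,384 combinations of those differences form a biallelic
hypercube on which *both* activities can be measured by high-throughput
sequencing: self-cleavage as a normalized fraction-cleaved, ligation as
normalized enrichment through one round of selection.  The result is a
pair of complete empirical fitness landscapes, W_HDV(g) and
W_Ligase(g), over the same genotype space.  Where both are detectably
active, the two genotype networks intersect; whether and how fast a
population can evolve from one function to the other depends on the
topography in between.

This package implements the full analysis stack for such dual
landscapes, for anyone studying empirical fitness landscapes, genotype
networks or in-silico evolutionary dynamics:

* **`genotype_space`** — hypercube combinatorics: enumeration,
  neighbors, Hamming shells, mutation trajectories, k-position
  sub-hypercubes.
* **`fitness_ingest`** — fitness and replicate error (delta) from
  read-count tables; activity detection ("seen at least once in every
  replicate, three times overall"); fitness-to-rate calibration.
* **`landscape_metrics`** — peaks (strict or error-aware via delta),
  ruggedness (mean peaks per 4-position, 16-genotype subgraph),
  pairwise epistasis `ε = log10(W_AB·W_0 / (W_A·W_B))` with
  magnitude/sign/reciprocal-sign classification, escape trajectories.
* **`network_proximity`** — cutoff-dependent nearest cross-network
  distances, connection counts, dual-function intersection sequences.
* **`wf_sim`** — Wright–Fisher rejection-sampling simulation (N =
  1,000, μ = 0.01 defaults) with three scenarios: selection after gene
  duplication, neutral-then-select, and β-weighted coselection of both
  functions.
* **`adaptation_stats`** — initial adaptation rate (Δfitness over the
  first 200 generations), cubic-smoothing-spline maximum growth rate,
  genotypes explored, summit-reach probability.
* **`synthetic_data`** — seeded generators (Rough-Mount-Fuji dual
  pairs, multiplicative controls, Poisson/binomial read counts) so that
  every stage is testable without any download.
* **`io` / `cli`** — TSV interchange formats, a converter for published
  spreadsheet fitness tables, and the `riboland` command with
  `synth | ingest | metrics | proximity | simulate | stats` subcommands.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
synthetic dual landscape (all outputs land in `results/`):

```bash
python analysis/01_generate_landscapes.py
python analysis/02_estimate_fitness.py
python analysis/03_landscape_topography.py
python analysis/04_network_proximity.py
python analysis/05_adaptation_simulations.py
python analysis/06_neutral_and_coselection.py
```

Output of steps 01–03 (seeded, so reproducible):

```
rugged landscape: 950 strict peaks, summit 1.322
smooth landscape: 25 strict peaks, summit 0.994
hdv: Pearson r(est, truth) = 0.9942, MAE = 0.0281, 231 genotypes below detection
ligase: Pearson r(est, truth) = 0.9791, MAE = 0.0252, 0 genotypes below detection
rugged_hdv_like: 950 peaks, ruggedness 3.056, median |epistasis| 0.2511
smooth_ligase_like: 25 peaks, ruggedness 1.144, median |epistasis| 0.0358
```

Read: the generator produced one severely rugged landscape (950 local
peaks; on average ~3 peaks inside every 16-genotype subgraph) and one
nearly smooth one, and the sequencing-noise pipeline recovers the true
fitness values with r > 0.97 at realistic read depths (369 and 230 mean
reads per genotype, 3 replicates).  Steps 05–06 then show the
evolutionary consequences:

```
toward_smooth: mean initial rate 0.00325 (range 0.00191-0.00389), mean final fitness 0.985
toward_rugged: mean initial rate 0.00279 (range 0.00160-0.00389), mean final fitness 0.849
adaptation toward the smooth landscape is 1.2x faster on average
neutral   0 generations: rate from onset 0.00129, 115 unique genotypes explored
neutral 250 generations: rate from onset 0.00330, 550 unique genotypes explored
neutral 500 generations: rate from onset 0.00324, 1000 unique genotypes explored
beta=(0.7, 0.3): optimized hdv in 49/50, ligase in 1/50 replicates
beta=(0.5, 0.5): optimized hdv in 37/50, ligase in 13/50 replicates
beta=(0.3, 0.7): optimized hdv in 2/50, ligase in 48/50 replicates
```

Read: populations adapt faster and further toward the smooth landscape
than toward the rugged one (final fitness 0.985 vs 0.849); on the
rugged landscape, starting from the best founder, a drift phase before
selection more than doubles the subsequent adaptation rate and the
number of genotypes explored; and under coselection the heavier β
weight decides which function gets optimized, while equal weights give a
stochastic winner — never a stably split population.

The same machinery applies to a measured dual-fitness table: convert the
published spreadsheet with `riboland.io.convert_s1_spreadsheet`, then
point `riboland metrics / proximity / simulate` at the TSV.

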