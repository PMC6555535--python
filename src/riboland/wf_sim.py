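"""Wright-Fisher simulation of evolution on tabulated fitness landscapes.

The model is a discrete-generation, constant-size (N) population of
genotypes evolving on the hypercube.  Each generation is rebuilt by
rejection sampling, following the scheme used for the ribozyme
landscapes this package analyzes:

1. draw a parent uniformly at random from the current population;
2. draw u ~ Uniform(0, 1); the parent reproduces iff fitness >= u
   (fitness above 1 therefore always reproduces — relative advantage
   among genotypes all above 1 vanishes, a deliberate property of the
   published scheme that is kept here);
3. the offspring mutates with probability mu at one uniformly chosen
   position (the space is biallelic, so a mutation always changes the
   genotype);
4. repeat until N offspring are placed.

Conditional on the current population, the offspring counts are
multinomial with probabilities proportional to count_g * min(w_g, 1) —
a property the test suite checks by chi-square goodness of fit.

Three scenarios mirror three evolutionary hypotheses about innovation
after gene duplication:

``select``
    selection for the new function from generation 0 (duplication
    immediately followed by selection);
``neutral_then_select``
    a drift-only phase (every parent accepted) for the first
    ``neutral_generations`` generations — the population spreads over
    its genotype network — followed by selection;
``coselect``
    both functions under selection at once, fitness being the
    beta-weighted sum of the two max-normalized landscape fitnesses.

Defaults (N=1,000, mu=0.01, 1,000 generations, 100 replicates per
condition) are the parameter regime under which the landscape
comparisons this package reproduces were established.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotype_space import Genotype, genotype_to_index, validate_genotype
from .landscape import Landscape

__all__ = [
    "SimulationConfig",
    "PopulationTrace",
    "BatchResult",
    "ExtinctionError",
    "coselect_fitness",
    "coselect_landscape",
    "step_generation",
    "run_scenario",
    "run_batch",
]

SCENARIOS = ("select", "neutral_then_select", "coselect")

#: parent draws permitted per generation before declaring extinction
EXTINCTION_DRAW_FACTOR = 1_000_000


class ExtinctionError(RuntimeError):
    """No parent was accepted within the draw budget (fitness ~ 0 everywhere)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    ``target`` names the landscape under selection ("hdv" or "ligase")
    for the select and neutral_then_select scenarios; coselect uses both
    with weights ``beta_hdv``/``beta_ligase``.
    """

    start_genotype: Genotype
    N: int = 1000
    mu: float = 0.01
    generations: int = 1000
    neutral_generations: int = 0
    scenario: str = "select"
    target: str = "ligase"
    beta_hdv: float = 0.5
    beta_ligase: float = 0.5
    seed: int = 0
    replicates: int = 1
    record_snapshots: bool = False

    def __post_init__(self) -> None:
        validate_genotype(self.start_genotype)
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 <= self.mu <= 1:
            raise ValueError("mu must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0 <= self.neutral_generations <= self.generations:
            raise ValueError("neutral_generations must be in [0, generations]")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.target not in ("hdv", "ligase"):
            raise ValueError("target must be 'hdv' or 'ligase'")
        if self.beta_hdv < 0 or self.beta_ligase < 0:
            raise ValueError("beta weights must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PopulationTrace:
    """Per-generation record of one replicate.

    Arrays have length generations+1; entry t describes the population
    at generation t (entry 0 is the founding monomorphic population).
    ``visited`` is the set of integer genotype codes ever present.
    """

    config: SimulationConfig
    seed: int
    mean_fitness: np.ndarray
    mean_hdv: np.ndarray
    mean_ligase: np.ndarray
    diversity: np.ndarray
    visited: set[int]
    summit_hit_generation: int | None
    snapshots: list[dict[int, int]] | None = None

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.mean_fitness.size)

    @property
    def final_fitness(self) -> float:
        return float(self.mean_fitness[-1])

    @property
    def n_unique_genotypes(self) -> int:
        return len(self.visited)


@dataclass
class BatchResult:
    """A batch of independently seeded replicates plus their mean trace."""

    config: SimulationConfig
    traces: list[PopulationTrace]

    @property
    def mean_trace(self) -> np.ndarray:
        return np.mean([t.mean_fitness for t in self.traces], axis=0)

    @property
    def pooled_visited(self) -> set[int]:
        out: set[int] = set()
        for t in self.traces:
            out |= t.visited
        return out


def rank_start_genotypes(
    source: Landscape, target: Landscape, n: int = 1
) -> list[Genotype]:
    """Top-n starting genotypes for innovation simulations.

    Genotypes are ranked by *source* fitness among those with nonzero
    *target* fitness — the natural founders for a duplication scenario:
    highly fit for the old function, but with at least detectable
    activity for the new one so that immediate selection is viable.
    Ties break by genotype index (deterministic).
    """
    if source.L != target.L:
        raise ValueError("landscapes have different dimensions")
    ok = np.flatnonzero(target.fitness > 0)
    if ok.size == 0:
        raise ValueError("no genotype has nonzero target fitness")
    order = ok[np.lexsort((ok, -source.fitness[ok]))][:n]
    from .genotype_space import index_to_genotype

    return [index_to_genotype(int(i), source.L) for i in order]


def coselect_fitness(
    w_hdv: float, w_ligase: float, beta_hdv: float, beta_ligase: float,
    max_hdv: float, max_ligase: float,
) -> float:
    """Weighted two-function fitness:
    (w_hdv/max_hdv)*beta_hdv + (w_ligase/max_ligase)*beta_ligase.

    Each landscape is first normalized by its own maximum so both summits
    sit at 1 before weighting.
    """
    if max_hdv <= 0 or max_ligase <= 0:
        raise ValueError("landscape maxima must be > 0")
    return (w_hdv / max_hdv) * beta_hdv + (w_ligase / max_ligase) * beta_ligase


def coselect_landscape(
    hdv: Landscape, ligase: Landscape, beta_hdv: float, beta_ligase: float
) -> Landscape:
    """Vectorized coselection landscape over the whole space."""
    if hdv.L != ligase.L:
        raise ValueError("landscapes have different dimensions")
    fit = coselect_fitness(
        hdv.fitness, ligase.fitness, beta_hdv, beta_ligase,
        hdv.summit_fitness, ligase.summit_fitness,
    )
    return Landscape(L=hdv.L, fitness=fit, name="coselect")


def step_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    mu: float,
    L: int,
    rng: np.random.Generator,
    selection_on: bool = True,
) -> np.ndarray:
    """Produce the next generation of the same size by rejection sampling.

    *population* is an array of integer genotype codes; *fitness* is the
    dense per-code fitness vector.  With selection off every drawn parent
    is accepted (pure drift).  Raises :class:`ExtinctionError` if the
    per-generation draw budget (N x 10^6) is exhausted, which happens
    only when the whole population sits at fitness ~ 0.
    """
    N = population.size
    if selection_on:
        if float(fitness[population].max()) <= 0.0:
            raise ExtinctionError(
                "every individual has fitness 0 under selection; no offspring possible"
            )
        out = np.empty(N, dtype=population.dtype)
        filled = 0
        draws = 0
        max_draws = N * EXTINCTION_DRAW_FACTOR
        while filled < N:
            p_acc = float(np.mean(np.minimum(fitness[population], 1.0)))
            batch = min(
                int((N - filled) / max(p_acc, 1e-4) * 1.2) + 64,
                max_draws - draws,
                4_000_000,
            )
            if batch <= 0:
                raise ExtinctionError(
                    "no offspring accepted within the draw budget; "
                    "population fitness is effectively zero under selection"
                )
            parents = population[rng.integers(0, N, size=batch)]
            u = rng.random(batch)
            accepted = parents[fitness[parents] >= u]
            take = min(accepted.size, N - filled)
            out[filled : filled + take] = accepted[:take]
            filled += take
            draws += batch
            if filled < N and draws >= max_draws:
                raise ExtinctionError(
                    "no offspring accepted within the draw budget; "
                    "population fitness is effectively zero under selection"
                )
    else:
        out = population[rng.integers(0, N, size=N)]
    if mu > 0:
        mutate = rng.random(N) < mu
        k = int(mutate.sum())
        if k:
            # both branches above produced fresh arrays; in-place is safe
            flips = (np.int64(1) << rng.integers(0, L, size=k)).astype(out.dtype)
            out[mutate] ^= flips
    return out


def _selection_vector(config: SimulationConfig, hdv: Landscape, ligase: Landscape):
    if config.scenario == "coselect":
        return coselect_landscape(hdv, ligase, config.beta_hdv, config.beta_ligase).fitness
    return (hdv if config.target == "hdv" else ligase).fitness


def run_scenario(
    config: SimulationConfig, hdv: Landscape, ligase: Landscape
) -> PopulationTrace:
    """Run one replicate of the configured scenario; fully seeded.

    The trace records, every generation, the population mean of the
    selection-relevant fitness as well as of both component landscapes,
    the number of unique genotypes present, and (cumulatively) every
    genotype ever observed.  ``summit_hit_generation`` is the first
    generation at which the selection landscape's summit genotype is
    present, or None.
    """
    if hdv.L != ligase.L:
        raise ValueError("landscapes have different dimensions")
    L = hdv.L
    validate_genotype(config.start_genotype, L=L)
    sel_fit = _selection_vector(config, hdv, ligase)
    summit_idx = int(np.argmax(sel_fit))
    rng = np.random.default_rng(config.seed)
    pop = np.full(config.N, genotype_to_index(config.start_genotype), dtype=np.int64)

    T = config.generations
    mean_sel = np.empty(T + 1)
    mean_hdv = np.empty(T + 1)
    mean_lig = np.empty(T + 1)
    diversity = np.empty(T + 1, dtype=int)
    visited: set[int] = set()
    snapshots: list[dict[int, int]] | None = [] if config.record_snapshots else None
    summit_hit: int | None = None

    neutral_until = (
        config.neutral_generations if config.scenario == "neutral_then_select" else 0
    )

    def record(t: int) -> None:
        nonlocal summit_hit
        uniq, counts = np.unique(pop, return_counts=True)
        mean_sel[t] = sel_fit[pop].mean()
        mean_hdv[t] = hdv.fitness[pop].mean()
        mean_lig[t] = ligase.fitness[pop].mean()
        diversity[t] = uniq.size
        visited.update(int(u) for u in uniq)
        if summit_hit is None and summit_idx in uniq:
            summit_hit = t
        if snapshots is not None:
            snapshots.append({int(u): int(c) for u, c in zip(uniq, counts)})

    record(0)
    for t in range(1, T + 1):
        selection_on = t > neutral_until
        pop = step_generation(pop, sel_fit, config.mu, L, rng, selection_on=selection_on)
        record(t)

    return PopulationTrace(
        config=config,
        seed=config.seed,
        mean_fitness=mean_sel,
        mean_hdv=mean_hdv,
        mean_ligase=mean_lig,
        diversity=diversity,
        visited=visited,
        summit_hit_generation=summit_hit,
        snapshots=snapshots,
    )


def run_batch(
    config: SimulationConfig, hdv: Landscape, ligase: Landscape,
    replicates: int | None = None,
) -> BatchResult:
    """Independent replicates (replicate i seeded with base seed + i)."""
    R = config.replicates if replicates is None else replicates
    if R < 1:
        raise ValueError("replicates must be >= 1")
    traces = []
    for i in range(R):
        cfg_i = replace(config, seed=config.seed + i, replicates=1)
        traces.append(run_scenario(cfg_i, hdv, ligase))
    return BatchResult(config=config, traces=traces)
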