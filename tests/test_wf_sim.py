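"""Wright-Fisher simulator: offspring law, drift, selection, scenarios."""

import numpy as np
import pytest
from scipy import stats

from riboland import wf_sim
from riboland.genotype_space import genotype_to_index
from riboland.landscape import Landscape


def flat_landscape(L, value=1.0, name="flat"):
    return Landscape(L=L, fitness=np.full(1 << L, value), name=name)


def two_level_landscape(L, fit_map, default=0.5):
    fit = np.full(1 << L, default)
    for g, w in fit_map.items():
        fit[genotype_to_index(g)] = w
    return Landscape(L=L, fitness=fit)


class TestCoselectFitness:
    def test_single_function_weighting(self):
        assert wf_sim.coselect_fitness(2.0, 5.0, 1.0, 0.0, 2.0, 5.0) == pytest.approx(1.0)

    def test_summit_with_equal_weights(self):
        w = wf_sim.coselect_fitness(2.0, 1.0, 0.5, 0.5, 2.0, 4.0)
        assert w == pytest.approx(0.5 + 0.125)

    def test_symmetric_under_function_swap(self):
        a = wf_sim.coselect_fitness(1.2, 0.3, 0.7, 0.2, 2.0, 0.9)
        b = wf_sim.coselect_fitness(0.3, 1.2, 0.2, 0.7, 0.9, 2.0)
        assert a == pytest.approx(b)

    def test_zero_maxima_rejected(self):
        with pytest.raises(ValueError):
            wf_sim.coselect_fitness(1, 1, 1, 1, 0.0, 1.0)


class TestStepGeneration:
    def test_population_size_constant(self, rng):
        land = flat_landscape(6, 0.7)
        pop = np.full(500, 3, dtype=np.int64)
        for _ in range(5):
            pop = wf_sim.step_generation(pop, land.fitness, 0.05, 6, rng)
            assert pop.size == 500

    def test_supercritical_monomorphic_without_mutation_is_fixed(self, rng):
        land = flat_landscape(5, 1.3)
        pop = np.full(200, 7, dtype=np.int64)
        out = wf_sim.step_generation(pop, land.fitness, 0.0, 5, rng)
        assert (out == 7).all()

    def test_offspring_distribution_is_multinomial_min_w_1(self):
        # 3 genotypes with fitness (1.5, 0.8, 0.3): expected offspring
        # probabilities proportional to count * min(w, 1)
        rng = np.random.default_rng(2024)
        land = two_level_landscape(4, {"0000": 1.5, "0001": 0.8, "0011": 0.3})
        counts = {"0000": 5000, "0001": 10000, "0011": 5000}
        pop = np.concatenate(
            [np.full(n, genotype_to_index(g), dtype=np.int64) for g, n in counts.items()]
        )
        out = wf_sim.step_generation(pop, land.fitness, 0.0, 4, rng)
        observed = np.array(
            [(out == genotype_to_index(g)).sum() for g in counts]
        )
        weights = np.array([5000 * 1.0, 10000 * 0.8, 5000 * 0.3])
        expected = weights / weights.sum() * out.size
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 0.001

    def test_neutral_drift_martingale(self):
        # selection off: allele frequency is a martingale; mean over
        # 10,000 single-generation replicates within 3 SE of start
        rng = np.random.default_rng(77)
        N, p0, reps = 50, 0.3, 10000
        pop = np.concatenate(
            [np.ones(int(N * p0), dtype=np.int64), np.zeros(N - int(N * p0), dtype=np.int64)]
        )
        fitness = np.ones(2)
        freqs = np.empty(reps)
        for i in range(reps):
            out = wf_sim.step_generation(pop, fitness, 0.0, 1, rng, selection_on=False)
            freqs[i] = (out == 1).mean()
        se = np.sqrt(p0 * (1 - p0) / N / reps)
        assert abs(freqs.mean() - p0) < 3 * se

    def test_two_genotype_selection_expectation(self):
        # fitness (1.0, 0.5) at p=0.5 each: expected next-generation
        # frequency of the fitter is (0.5*1)/(0.5*1 + 0.5*0.5) = 2/3
        rng = np.random.default_rng(88)
        N, reps = 100, 10000
        pop = np.concatenate(
            [np.zeros(N // 2, dtype=np.int64), np.ones(N // 2, dtype=np.int64)]
        )
        fitness = np.array([1.0, 0.5])
        freqs = np.empty(reps)
        for i in range(reps):
            out = wf_sim.step_generation(pop, fitness, 0.0, 1, rng)
            freqs[i] = (out == 0).mean()
        target = 2.0 / 3.0
        se = freqs.std(ddof=1) / np.sqrt(reps)
        assert abs(freqs.mean() - target) < 3 * se

    def test_heterozygosity_decays_geometrically_under_drift(self):
        # E[H'] = (1 - 1/N) H for neutral resampling
        rng = np.random.default_rng(99)
        N, reps = 50, 20000
        pop = np.concatenate([np.zeros(25, dtype=np.int64), np.ones(25, dtype=np.int64)])
        h0 = 2 * 0.5 * 0.5
        hs = np.empty(reps)
        for i in range(reps):
            out = wf_sim.step_generation(pop, np.ones(2), 0.0, 1, rng, selection_on=False)
            p = (out == 1).mean()
            hs[i] = 2 * p * (1 - p)
        expected = (1 - 1 / N) * h0
        se = hs.std(ddof=1) / np.sqrt(reps)
        assert abs(hs.mean() - expected) < 3 * se

    def test_extinction_guard(self):
        land = Landscape(L=3, fitness=np.zeros(8))
        pop = np.zeros(10, dtype=np.int64)
        with pytest.raises(wf_sim.ExtinctionError):
            wf_sim.step_generation(pop, land.fitness, 0.0, 3, np.random.default_rng(0))


class TestRunScenario:
    def test_identical_seeds_identical_traces(self, default_pair):
        a, b = default_pair
        cfg = wf_sim.SimulationConfig(
            start_genotype="0" * 14, generations=50, seed=42, target="ligase"
        )
        t1 = wf_sim.run_scenario(cfg, a, b)
        t2 = wf_sim.run_scenario(cfg, a, b)
        assert np.array_equal(t1.mean_fitness, t2.mean_fitness)
        assert np.array_equal(t1.diversity, t2.diversity)
        assert t1.visited == t2.visited

    def test_mean_fitness_bounded_by_summit(self, default_pair):
        a, b = default_pair
        cfg = wf_sim.SimulationConfig(
            start_genotype=b.summit, generations=200, seed=7, target="ligase"
        )
        tr = wf_sim.run_scenario(cfg, a, b)
        assert (tr.mean_fitness <= b.summit_fitness + 1e-12).all()
        # started at the summit: stays within the drift-mutation band
        assert tr.mean_fitness[-1] > 0.9 * b.summit_fitness

    def test_neutral_phase_shows_no_systematic_improvement(self, default_pair):
        # start mid-way between the references, where drift plus mutation
        # has no directional fitness pressure on the linear-decay landscape
        a, b = default_pair
        cfg = wf_sim.SimulationConfig(
            start_genotype="0" * 7 + "1" * 7,
            scenario="neutral_then_select",
            neutral_generations=150,
            generations=200,
            seed=11,
            target="ligase",
        )
        batch = wf_sim.run_batch(cfg, a, b, replicates=40)
        m = batch.mean_trace[:150]
        slope, _, _, p, _ = stats.linregress(np.arange(m.size), m)
        # no trend, or a drift far below selection-driven slopes (~4e-3)
        assert p > 0.01 or abs(slope) < 2e-4

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            wf_sim.SimulationConfig(start_genotype="00", scenario="bogus")

    def test_trace_records_every_generation(self, default_pair):
        cfg = wf_sim.SimulationConfig(start_genotype="0" * 14, generations=30, seed=3)
        tr = wf_sim.run_scenario(cfg, *default_pair)
        assert tr.mean_fitness.size == 31
        assert tr.diversity.size == 31
        assert tr.diversity[0] == 1


class TestRunBatch:
    def test_single_replicate_reduces_to_run_scenario(self, default_pair):
        cfg = wf_sim.SimulationConfig(start_genotype="0" * 14, generations=40, seed=9)
        batch = wf_sim.run_batch(cfg, *default_pair, replicates=1)
        solo = wf_sim.run_scenario(cfg, *default_pair)
        assert np.array_equal(batch.traces[0].mean_fitness, solo.mean_fitness)

    def test_mean_trace_within_replicate_envelope(self, default_pair):
        cfg = wf_sim.SimulationConfig(start_genotype="0" * 14, generations=60, seed=21)
        batch = wf_sim.run_batch(cfg, *default_pair, replicates=5)
        stack = np.vstack([t.mean_fitness for t in batch.traces])
        assert (batch.mean_trace <= stack.max(axis=0) + 1e-12).all()
        assert (batch.mean_trace >= stack.min(axis=0) - 1e-12).all()

    def test_distinct_starts_reproducibly_ordered_rates(self, default_pair):
        a, b = default_pair
        starts = wf_sim.rank_start_genotypes(a, b, n=3)
        rates = {}
        for s in starts:
            cfg = wf_sim.SimulationConfig(
                start_genotype=s, generations=250, seed=5, target="ligase"
            )
            m = wf_sim.run_batch(cfg, a, b, replicates=10).mean_trace
            rates[s] = (m[200] - m[0]) / 200
        again = {}
        for s in starts:
            cfg = wf_sim.SimulationConfig(
                start_genotype=s, generations=250, seed=5, target="ligase"
            )
            m = wf_sim.run_batch(cfg, a, b, replicates=10).mean_trace
            again[s] = (m[200] - m[0]) / 200
        assert rates == again  # bit-reproducible ordering


class TestRankStartGenotypes:
    def test_requires_nonzero_target_fitness(self, default_pair):
        a, b = default_pair
        picks = wf_sim.rank_start_genotypes(a, b, n=10)
        assert len(picks) == 10
        assert all(b[g] > 0 for g in picks)
        # ranked by source fitness, descending
        fits = [a[g] for g in picks]
        assert fits == sorted(fits, reverse=True)
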