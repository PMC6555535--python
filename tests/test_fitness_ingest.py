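"""Fitness estimation from read counts: estimators, filters, QC checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riboland import fitness_ingest as fi
from riboland.genotype_space import enumerate_space
from riboland.landscape import Landscape
from riboland.synthetic_data import SyntheticSpec, make_rmf_landscape, simulate_read_counts


def hdv_table(rows):
    return pd.DataFrame(rows, columns=["genotype", "replicate", "cleaved", "uncleaved"])


def ligase_table(rows):
    return pd.DataFrame(rows, columns=["genotype", "replicate", "pre", "post"])


class TestFractionCleaved:
    @pytest.mark.parametrize(
        "c,u,expected", [(0, 100, 0.0), (50, 50, 0.5), (37, 63, 0.37), (100, 0, 1.0)]
    )
    def test_values(self, c, u, expected):
        assert fi.fraction_cleaved(c, u) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            fi.fraction_cleaved(0, 0)


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 1, 1), True), ((3, 0, 0), False), ((0, 0, 0), False),
         ((5, 2, 9), True), ((1, 1), False)],
    )
    def test_rule(self, counts, expected):
        # active requires detection in every replicate and >= 3 overall
        assert fi.detection_filter(counts) is expected


class TestHdvFitness:
    def test_normalizer_scores_exactly_one(self):
        tab = hdv_table(
            [("00", r, c, u) for r, (c, u) in enumerate([(50, 50), (40, 60), (60, 40)], 1)]
            + [("01", r, 30, 70) for r in (1, 2, 3)]
            + [("10", r, 90, 10) for r in (1, 2, 3)]
            + [("11", r, 2, 98) for r in (1, 2, 3)]
        )
        out = fi.hdv_fitness(tab, "00").set_index("genotype")
        assert out.loc["00", "fitness"] == pytest.approx(1.0)

    def test_identical_replicates_give_zero_delta(self):
        tab = hdv_table(
            [("0", r, 50, 50) for r in (1, 2, 3)] + [("1", r, 25, 75) for r in (1, 2, 3)]
        )
        out = fi.hdv_fitness(tab, "0").set_index("genotype")
        assert out["delta"].to_numpy() == pytest.approx([0.0, 0.0])
        assert out.loc["1", "fitness"] == pytest.approx(0.5)

    def test_all_cleaved_zero_is_inactive_zero_fitness(self):
        tab = hdv_table(
            [("0", r, 50, 50) for r in (1, 2, 3)] + [("1", r, 0, 100) for r in (1, 2, 3)]
        )
        out = fi.hdv_fitness(tab, "0").set_index("genotype")
        assert out.loc["1", "fitness"] == 0.0
        assert out.loc["1", "delta"] == 0.0
        assert not out.loc["1", "active"]

    def test_depth_invariance(self):
        rows = [("0", r, 40, 60) for r in (1, 2, 3)] + [("1", r, 10, 90) for r in (1, 2, 3)]
        out1 = fi.hdv_fitness(hdv_table(rows), "0")
        scaled = [(g, r, 7 * c, 7 * u) for g, r, c, u in rows]
        out2 = fi.hdv_fitness(hdv_table(scaled), "0")
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_normalizer_rejected(self):
        tab = hdv_table([("0", 1, 10, 10), ("1", 1, 5, 15)])
        with pytest.raises(ValueError, match="normalizer"):
            fi.hdv_fitness(tab, "11")

    def test_binomial_recovery_within_three_standard_errors(self):
        # known truth -> binomial counts -> estimator, one genotype at a time
        rng = np.random.default_rng(7)
        depth, p_ref, truth = 2000, 0.5, 0.6
        rows = []
        for r in (1, 2, 3):
            c_ref = rng.binomial(depth, p_ref)
            c_g = rng.binomial(depth, truth * p_ref)
            rows += [("0", r, c_ref, depth - c_ref), ("1", r, c_g, depth - c_g)]
        out = fi.hdv_fitness(hdv_table(rows), "0").set_index("genotype")
        se = np.sqrt(truth * p_ref * (1 - truth * p_ref) / depth) / p_ref
        assert abs(out.loc["1", "fitness"] - truth) < 3 * se


class TestLigaseFitness:
    def make_table(self, rng, truth: dict, depth=230, reps=3):
        rows = []
        mean_f = np.mean(list(truth.values()))
        for r in range(1, reps + 1):
            for g, f in truth.items():
                pre = rng.poisson(depth)
                post = rng.poisson(depth * f / mean_f)
                rows.append((g, r, pre, post))
        return ligase_table(rows)

    def test_normalizer_scores_one_and_zero_post_scores_zero(self):
        tab = ligase_table(
            [("00", r, 100, 100) for r in (1, 2, 3)]
            + [("01", r, 100, 200) for r in (1, 2, 3)]
            + [("10", r, 100, 0) for r in (1, 2, 3)]
            + [("11", r, 100, 50) for r in (1, 2, 3)]
        )
        out = fi.ligase_fitness(tab, "00").set_index("genotype")
        assert out.loc["00", "fitness"] == pytest.approx(1.0)
        assert out.loc["10", "fitness"] == 0.0
        assert not out.loc["10", "active"]

    def test_absent_preselection_flagged_and_zeroed(self):
        tab = ligase_table(
            [("00", r, 100, 100) for r in (1, 2, 3)]
            + [("01", r, 0, 10) for r in (1, 2, 3)]
        )
        out = fi.ligase_fitness(tab, "00")
        assert out.attrs["qc"]["n_absent_preselection"] == 1
        row = out.set_index("genotype").loc["01"]
        assert row["fitness"] == 0.0 and not row["active"]

    def test_poisson_recovery_correlates_with_truth(self, rng):
        truth = {g: max(0.02, 1 - 0.2 * g.count("1")) for g in enumerate_space(6)}
        tab = self.make_table(rng, truth, depth=230)
        out = fi.ligase_fitness(tab, "000000").set_index("genotype")
        active = out[out["fitness"] > 0]
        r = stats.pearsonr(
            np.log([truth[g] for g in active.index]), np.log(active["fitness"])
        ).statistic
        assert r > 0.95


class TestRecoveryImprovesWithDepth:
    def test_hdv_mae_decreases_with_depth(self):
        truth = make_rmf_landscape(8, "0" * 8, slope=0.1, noise_sd=0.05, seed=11)
        maes = []
        for depth in (50, 369, 2000):
            spec = SyntheticSpec(L=8, depth_hdv=depth, seed=5)
            counts = simulate_read_counts(truth, spec, "hdv")
            est = fi.hdv_fitness(counts, "0" * 8).set_index("genotype")
            tr = np.array([truth[g] for g in est.index])
            maes.append(float(np.abs(est["fitness"].to_numpy() - tr).mean()))
        assert maes[0] > maes[1] > maes[2]


class TestRateEstimate:
    def test_linear_through_origin(self):
        c = fi.RateConstants(anchor_fitness=2.0, anchor_rate=1e-3)
        assert fi.ligation_rate_estimate(2.0, c) == pytest.approx(1e-3)
        assert fi.ligation_rate_estimate(0.0, c) == 0.0
        assert fi.ligation_rate_estimate(4.0, c) == pytest.approx(2e-3)

    def test_nonpositive_anchor_rejected(self):
        with pytest.raises(ValueError):
            fi.RateConstants(anchor_fitness=0.0, anchor_rate=1e-3)


class TestFrequencyFitnessCorrelation:
    def test_fitness_equal_to_frequency_gives_r_one(self):
        genotypes = enumerate_space(4)
        rng = np.random.default_rng(0)
        pre = rng.integers(50, 500, size=len(genotypes))
        tab = ligase_table(
            [(g, 1, p, 1) for g, p in zip(genotypes, pre)]
        )
        fit = pd.DataFrame({"genotype": genotypes, "fitness": pre / pre.sum()})
        out = fi.frequency_fitness_correlation(tab, fit)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_independent_fitness_uncorrelated(self):
        genotypes = enumerate_space(8)
        rng = np.random.default_rng(1)
        tab = ligase_table([(g, 1, rng.integers(100, 400), 1) for g in genotypes])
        fit = pd.DataFrame({"genotype": genotypes, "fitness": rng.uniform(0, 1, len(genotypes))})
        out = fi.frequency_fitness_correlation(tab, fit)
        assert abs(out["pearson_r"]) < 0.15
        assert out["pearson_p"] > 0.01

    def test_constant_fitness_warns(self):
        genotypes = enumerate_space(3)
        tab = ligase_table([(g, 1, 100, 1) for g in genotypes])
        fit = pd.DataFrame({"genotype": genotypes, "fitness": 1.0})
        with pytest.warns(UserWarning):
            out = fi.frequency_fitness_correlation(tab, fit)
        assert out["pearson_r"] == 0.0


class TestValidation:
    def test_duplicate_entry_rejected(self):
        tab = hdv_table([("0", 1, 1, 1), ("0", 1, 2, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            fi.validate_read_counts(tab, ("cleaved", "uncleaved"))

    def test_negative_counts_rejected(self):
        tab = hdv_table([("0", 1, -1, 1)])
        with pytest.raises(ValueError, match="non-negative"):
            fi.validate_read_counts(tab, ("cleaved", "uncleaved"))
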