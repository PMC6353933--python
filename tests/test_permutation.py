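"""Permutation null: exhaustive oracles, p-value convention, CIs, determinism."""

import itertools

import numpy as np
import pytest
from scipy import stats

from vhratio import (
    ConfigurationError,
    DegenerateFitError,
    StatisticKind,
    exact_p_two_tailed,
    exhaustive_null,
    generate_pair,
    permutation_test,
    randomized_ci,
    SyntheticConfig,
)
from vhratio.permutation import pair_seed_sequence

from conftest import make_dataset


class TestExhaustiveNull:
    def test_spearman_three_monotone_points(self):
        d = make_dataset([1, 10, 100], [2, 20, 200])
        null = sorted(exhaustive_null(d, StatisticKind.SPEARMAN_RHO))
        assert null == pytest.approx([-1.0, -0.5, -0.5, 0.5, 0.5, 1.0])
        assert exact_p_two_tailed(1.0, np.array(null)) == pytest.approx(2 / 6)

    def test_factorial_length(self):
        d = make_dataset([1, 10, 100], [2, 5, 9])
        assert len(exhaustive_null(d)) == 6

    def test_n2_reflection_symmetry(self):
        d = make_dataset([1, 10], [3, 7])
        null = exhaustive_null(d, StatisticKind.PM_SLOPE)
        assert len(null) == 2
        assert null[0] == pytest.approx(-null[1])

    def test_size_bound(self, random_dataset_factory):
        with pytest.raises(ConfigurationError):
            exhaustive_null(random_dataset_factory(n=9))

    def test_naive_scipy_loop_agrees(self, random_dataset_factory):
        """The vectorized null equals statistic-by-statistic recomputation."""
        d = random_dataset_factory(n=5)
        x = np.log10(d.host_abundance)
        y = np.log10(d.virus_abundance)
        for kind, func in [
            (StatisticKind.PEARSON_R, lambda yp: stats.pearsonr(x, yp).statistic),
            (StatisticKind.SPEARMAN_RHO, lambda yp: stats.spearmanr(x, yp).statistic),
            (StatisticKind.PM_SLOPE, lambda yp: stats.linregress(x, yp).slope),
        ]:
            ours = sorted(exhaustive_null(d, kind))
            ref = sorted(func(np.array(p)) for p in itertools.permutations(y))
            np.testing.assert_allclose(ours, ref, rtol=1e-10)


class TestPermutationTest:
    def test_monte_carlo_converges_to_exact(self, random_dataset_factory):
        d = random_dataset_factory(n=4)
        null = exhaustive_null(d, StatisticKind.PM_SLOPE)
        res = permutation_test(d, StatisticKind.PM_SLOPE, n_perm=10_000, seed=30)
        p_exact = exact_p_two_tailed(res.observed, null)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p_two_tailed - p_exact) < 3 * se + 2 / 10_000

    def test_null_length_matches_n_perm(self, random_dataset_factory):
        res = permutation_test(random_dataset_factory(n=10), n_perm=10_000, seed=31)
        assert len(res.null_values) == 10_000

    def test_observed_zero_gives_p_one(self):
        # symmetric host design with constant virus: slope 0 every permutation
        d = make_dataset([1, 10, 100], [5, 5, 5])
        res = permutation_test(d, StatisticKind.PM_SLOPE, n_perm=500, seed=32)
        assert res.observed == pytest.approx(0.0)
        assert res.p_two_tailed == 1.0

    def test_add_one_convention_bounds(self, random_dataset_factory):
        res = permutation_test(random_dataset_factory(n=6), n_perm=99, seed=33)
        assert 1 / 100 <= res.p_two_tailed <= 1.0

    def test_determinism_bitwise(self, random_dataset_factory):
        d = random_dataset_factory(n=12)
        a = permutation_test(d, "pm_slope", n_perm=1000, seed=34)
        b = permutation_test(d, "pm_slope", n_perm=1000, seed=34)
        np.testing.assert_array_equal(a.null_values, b.null_values)
        assert a.p_two_tailed == b.p_two_tailed
        assert (a.ci_low, a.ci_median, a.ci_high) == (b.ci_low, b.ci_median, b.ci_high)

    def test_pair_substream_independent_of_other_pairs(self):
        seq1 = pair_seed_sequence(42, "Vibrio")
        seq2 = pair_seed_sequence(42, "Vibrio")
        seq3 = pair_seed_sequence(42, "Synechococcus")
        assert seq1.entropy == seq2.entropy
        assert seq1.entropy != seq3.entropy

    def test_slope_and_pearson_give_identical_p(self, random_dataset_factory):
        """Slope = r * sd_y/sd_x with permutation-invariant sds: same rejections."""
        for i in range(5):
            d = random_dataset_factory(n=15, pair_id=f"eq{i}")
            p_slope = permutation_test(d, "pm_slope", n_perm=500, seed=35).p_two_tailed
            p_r = permutation_test(d, "pearson_r", n_perm=500, seed=35).p_two_tailed
            assert p_slope == p_r

    def test_null_centered_at_zero(self):
        cfg = SyntheticConfig(alpha=0.8, noise_sd=0.3, seed=36)
        d = generate_pair(cfg, "centered", 0)
        res = permutation_test(d, "pm_slope", n_perm=10_000, seed=36)
        sd = res.null_values.std()
        assert abs(res.null_values.mean()) < 4 * sd / np.sqrt(10_000)

    def test_theil_sen_statistic_supported(self, random_dataset_factory):
        d = random_dataset_factory(n=8)
        res = permutation_test(d, "theil_sen_slope", n_perm=200, seed=37)
        ref = stats.theilslopes(
            np.log10(d.virus_abundance), np.log10(d.host_abundance)
        )
        assert res.observed == pytest.approx(ref.slope, rel=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateFitError):
            permutation_test(make_dataset([5, 5, 5], [1, 2, 3]), seed=0)
        with pytest.raises(DegenerateFitError):
            permutation_test(
                make_dataset([1, 10, 100], [5, 5, 5]), "pearson_r", seed=0
            )
        with pytest.raises(ConfigurationError):
            permutation_test(make_dataset([1, 10], [1, 2]), n_perm=0, seed=0)


class TestRandomizedCI:
    def test_percentiles_of_1_to_100(self):
        lo, med, hi = randomized_ci(np.arange(1.0, 101.0))
        assert lo == pytest.approx(3.475)
        assert med == pytest.approx(50.5)
        assert hi == pytest.approx(97.525)

    def test_constant_null(self):
        assert randomized_ci(np.full(50, 2.5)) == (2.5, 2.5, 2.5)

    def test_symmetric_null_median_near_zero(self, random_dataset_factory):
        res = permutation_test(random_dataset_factory(n=20), n_perm=5000, seed=38)
        assert abs(res.ci_median) < res.null_values.std()
        assert res.ci_low <= res.ci_median <= res.ci_high

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            randomized_ci(np.arange(10.0), lower=97.5, upper=2.5)
        with pytest.raises(ConfigurationError):
            randomized_ci(np.array([]))
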