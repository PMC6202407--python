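"""Tests for the permutation empirical-null differential-expression test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import degnet
from degnet.errors import (CalibrationError, DegenerateVarianceError,
                           InvalidDesignError, ParameterError)


class TestTStatistic:
    def test_equal_means_give_zero(self):
        assert degnet.t_statistic([1, 2], [1, 2]) == 0.0

    def test_hand_evaluated_pooled_t(self):
        # (3-2) / sqrt(2 * (1/2 + 1/2)) = 1/sqrt(2)
        t = degnet.t_statistic([2, 4], [1, 3])
        assert t == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    @pytest.mark.parametrize("a,b", [([2, 4], [1, 3]), ([5.5, 8.0], [1, 2]),
                                     ([0, 1, 4], [2, 2, 7])])
    def test_matches_reference_implementation(self, a, b):
        expected = sps.ttest_ind(a, b, equal_var=True).statistic
        assert degnet.t_statistic(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_signaled(self):
        with pytest.raises(DegenerateVarianceError):
            degnet.t_statistic([1, 1], [2, 2])

    def test_group_size_floor(self):
        with pytest.raises(ParameterError):
            degnet.t_statistic([1], [2, 3])


class TestLog2FoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        ([3, 3], [1, 1], 2.0),
        ([1, 2], [1, 2], 0.0),
        ([8.0, 8.4], [6.0, 6.4], 2.0),
    ])
    def test_mean_difference(self, a, b, expected):
        assert degnet.log2_fold_change(a, b) == pytest.approx(expected)


class TestPermutedPool:
    def test_two_vs_two_pool_size(self, design2):
        m = degnet.null_dataset(100, design2, 0.25, seed=1)
        pool, skipped = degnet.permuted_t_pool(
            m, design2, degnet.Contrast("test", "MEF"))
        assert len(pool) == 5 * 100 and skipped == 0

    def test_three_vs_three_pool_size(self):
        d = degnet.make_design(3, ("MEF", "test"))
        m = degnet.null_dataset(10, d, 0.25, seed=1)
        pool, skipped = degnet.permuted_t_pool(
            m, d, degnet.Contrast("test", "MEF"))
        assert len(pool) == 19 * 10 and skipped == 0  # C(6,3)-1 = 19

    def test_constant_matrix_gives_empty_pool(self, design2):
        m = pd.DataFrame(np.ones((5, 4)), columns=design2.sample_ids)
        pool, skipped = degnet.permuted_t_pool(
            m, design2, degnet.Contrast("test", "MEF"))
        assert len(pool) == 0 and skipped == 5 * 5

    def test_identity_assignment_excluded(self, design2):
        assignments = degnet.balanced_assignments(
            design2.samples_for("test"), design2.samples_for("MEF"))
        observed = frozenset(design2.samples_for("test"))
        assert len(assignments) == 5
        assert all(frozenset(a) != observed for a, _ in assignments)


@pytest.fixture(scope="module")
def normal_pool():
    return np.random.default_rng(0).normal(size=10_000)


@pytest.fixture(scope="module")
def normal_null(normal_pool):
    return degnet.fit_empirical_null(normal_pool)


class TestEmpiricalNull:
    def test_cdf_center_matches_empirical_cdf(self, normal_pool, normal_null):
        empirical = (normal_pool <= 0).mean()  # independent oracle
        assert normal_null.cdf(0.0) == pytest.approx(empirical, abs=0.01)
        assert 0.49 <= normal_null.cdf(0.0) <= 0.51

    def test_density_integrates_to_one(self, normal_null):
        assert normal_null.total_mass == pytest.approx(1.0, abs=1e-3)
        assert normal_null.cdf(normal_null.grid[0]) == 0.0
        assert normal_null.cdf(normal_null.grid[-1]) == 1.0

    def test_cdf_nondecreasing(self, normal_null):
        x = np.linspace(-6, 6, 500)
        assert (np.diff(normal_null.cdf(x)) >= 0).all()

    def test_symmetric_pool_gives_symmetric_density(self):
        x = np.random.default_rng(1).normal(size=500)
        null = degnet.fit_empirical_null(np.concatenate([x, -x]))
        probe = np.array([0.3, 1.1, 2.5])
        assert np.allclose(null.density(probe), null.density(-probe),
                           atol=1e-9)

    def test_small_pool_rejected(self):
        with pytest.raises(CalibrationError):
            degnet.fit_empirical_null(np.arange(50.0))

    def test_p_at_empirical_quantile(self, normal_pool, normal_null):
        t = np.quantile(normal_pool, 0.975)  # empirical-quantile oracle
        assert degnet.empirical_p(t, normal_null) == pytest.approx(0.05,
                                                                   abs=0.01)

    def test_p_center_and_tail_clamp(self, normal_pool, normal_null):
        center = float(np.median(normal_pool))
        assert degnet.empirical_p(center, normal_null) > 0.95
        beyond = normal_pool.max() + 10
        assert degnet.empirical_p(beyond, normal_null) == normal_null.p_floor
        assert normal_null.p_floor == pytest.approx(1 / 10_001)

    def test_p_monotone_in_distance_from_center(self, normal_null):
        t = np.linspace(0.0, 8.0, 100)
        p = degnet.empirical_p(t, normal_null)
        assert (np.diff(p) <= 1e-12).all()


class TestSelectDegs:
    @pytest.mark.parametrize("p,lfc,call", [
        (0.05, 1.0, "up"),      # boundary-inclusive on both thresholds
        (0.051, 3.0, "ns"),
        (0.01, -1.2, "down"),
        (0.05, -1.0, "down"),
        (0.04, 0.99, "ns"),
    ])
    def test_threshold_rules(self, p, lfc, call):
        table = pd.DataFrame({"t_value": [0.0], "log2fc": [lfc],
                              "p_adj": [p]})
        assert degnet.select_degs(table)["call"].iloc[0] == call


class TestRunContrast:
    def test_antisymmetry(self, design2):
        """Swapping test/reference flips t and log2fc, preserves p."""
        m = degnet.null_dataset(500, design2, 0.25, seed=9)
        fwd = degnet.run_contrast(m, design2, degnet.Contrast("test", "MEF"))
        rev = degnet.run_contrast(m, design2, degnet.Contrast("MEF", "test"))
        assert np.allclose(fwd["t_value"], -rev["t_value"])
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.abs(fwd["p_adj"] - rev["p_adj"]).max() < 1e-9

    def test_degenerate_genes_called_ns(self, design2):
        m = degnet.null_dataset(300, design2, 0.25, seed=4)
        m.iloc[0] = 1.0  # constant gene
        m.iloc[1] = [5.0, 5.0, 1.0, 1.0]  # zero variance, unequal means
        table = degnet.run_contrast(m, design2,
                                    degnet.Contrast("test", "MEF"))
        assert (table.iloc[:2]["p_adj"] == 1.0).all()
        assert (table.iloc[:2]["call"] == "ns").all()

    def test_fdr_switch_is_more_conservative(self, design2):
        m, _ = degnet.simulate_dataset(500, design2, deg_fraction=0.1,
                                       effect_size=2.0, noise_sd=0.25, seed=2)
        c = degnet.Contrast("test", "MEF")
        raw = degnet.run_contrast(m, design2, c)
        adj = degnet.run_contrast(m, design2, c, fdr_adjust=True)
        assert (adj["p_adj"] >= raw["p_adj"] - 1e-12).all()

    def test_invalid_permutation_scope(self, design2):
        m = degnet.null_dataset(120, design2, 0.25, seed=4)
        with pytest.raises(ParameterError):
            degnet.run_all_contrasts(m, design2, permutation_scope="bogus")

    def test_contrast_needs_distinct_conditions(self):
        with pytest.raises(InvalidDesignError):
            degnet.Contrast("MEF", "MEF")
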