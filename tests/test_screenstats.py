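"""Screen statistics: thresholds, hit confirmation, permutation tests, FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from mlpquant.screenstats import (
    HitConfig,
    bh_fdr,
    bonferroni,
    confirm_hits,
    correlate_phenotype,
    elbow_threshold,
    median_ratio_size_factors,
    percentile_threshold,
    permutation_t_test,
    strong_adhesion_call,
)


@pytest.mark.parametrize(
    "ratio,expected",
    [(0.19, False), (0.21, True), (0.2, False), (0.0, False), (1.5, True)],
)
def test_strong_adhesion_cutoff_is_strict(ratio, expected):
    assert strong_adhesion_call(ratio) is expected


class TestPercentileThreshold:
    def test_linear_interpolation_on_1_to_100(self):
        assert percentile_threshold(np.arange(1, 101)) == pytest.approx(95.05)

    def test_constant_values_return_the_constant(self):
        assert percentile_threshold([3.3] * 10) == 3.3

    def test_needs_at_least_two_values(self):
        with pytest.raises(ValueError):
            percentile_threshold([1.0])

    def test_separates_planted_positives_from_nulls(self):
        rng = np.random.default_rng(0)
        nulls = rng.normal(0.03, 0.01, size=950)
        positives = rng.normal(0.4, 0.05, size=50)
        cut = percentile_threshold(np.concatenate([nulls, positives]))
        assert nulls.max() < cut < positives.min()


class TestElbowThreshold:
    def test_matches_brute_force_distance_to_chord(self):
        values = np.array([10.0, 9.0, 8.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        y = np.sort(values)[::-1]
        x = np.arange(len(y), dtype=float)
        # independent brute force: perpendicular distance to the chord
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        dist = [
            abs(dy * (xi - x[0]) - dx * (yi - y[0])) / np.hypot(dx, dy)
            for xi, yi in zip(x, y)
        ]
        # the maximum-distance point is the cliff bottom of the 8 -> 1 break
        assert elbow_threshold(values) == y[int(np.argmax(dist))] == 1.0

    def test_linear_ramp_warns_and_returns_midpoint(self):
        with pytest.warns(UserWarning, match="linear"):
            out = elbow_threshold(np.arange(10.0))
        assert out == 4.0  # middle of the descending-sorted curve

    def test_all_equal_warns_and_returns_common_value(self):
        with pytest.warns(UserWarning, match="equal"):
            assert elbow_threshold([2.0, 2.0, 2.0]) == 2.0

    def test_separates_a_planted_two_component_mixture(self):
        # the geometric elbow lands at the corner of the null tail: every
        # planted strong value must sit above it and at most 1% of nulls may
        # leak over (the corner can sit a couple of points into the tail)
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            low = rng.normal(0.05, 0.01, size=190)
            high = rng.normal(0.6, 0.05, size=10)
            cut = elbow_threshold(np.concatenate([low, high]))
            leaked = (low > cut).sum()
            hits += (high > cut).all() and leaked <= 2
        assert hits >= 38  # >= 95% of seeds


class TestConfirmHits:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["strain", "pre_density", "post_density", "ratio"]
        )

    def test_too_few_valid_repeats_is_not_a_hit(self):
        table = self._table([("a", 0.5, 0.3, 0.5)] * 4)
        out = confirm_hits(table)
        assert not out["hit"].iloc[0] and out["n_valid"].iloc[0] == 4

    def test_mean_ratio_above_cutoff_with_enough_repeats_is_a_hit(self):
        table = self._table([("a", 0.5, 0.3, 0.09)] * 6)
        out = confirm_hits(table, HitConfig(ratio_min=0.086))
        assert bool(out["hit"].iloc[0])

    def test_low_density_replicates_are_invalid(self):
        table = self._table([("a", 0.05, 0.2, 2.0)] * 6)
        out = confirm_hits(table)
        assert out["n_valid"].iloc[0] == 0 and not out["hit"].iloc[0]

    def test_relaxing_thresholds_never_removes_hits(self):
        rng = np.random.default_rng(1)
        table = self._table(
            [
                (f"s{i}", rng.uniform(0, 0.8), rng.uniform(0, 0.4), rng.uniform(0, 0.3))
                for i in range(40)
                for _ in range(6)
            ]
        )
        strict = confirm_hits(table, HitConfig(min_repeats=5, ratio_min=0.1))
        relaxed = confirm_hits(table, HitConfig(min_repeats=3, pre_min=0.05,
                                                post_min=0.02, ratio_min=0.05))
        assert set(strict.loc[strict.hit, "strain"]) <= set(
            relaxed.loc[relaxed.hit, "strain"]
        )


class TestPermutationTTest:
    def test_identical_samples_give_p_one_exhaustively(self):
        result = permutation_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=1000)
        assert result.exhaustive and result.p == 1.0

    def test_exhaustive_enumeration_small_case(self):
        # all C(4,2)=6 splits by hand: only one split has a smaller mean
        # difference than the observed -9, so p = (1+1)/(1+6) = 2/7
        result = permutation_t_test(
            [1.0, 2.0], [10.0, 11.0], n_perm=100, alternative="less"
        )
        assert result.exhaustive and result.n_permutations == 6
        assert result.p == pytest.approx(2 / 7)

    def test_tiny_samples_are_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1.0], [2.0, 3.0])

    def test_sampled_agrees_with_exhaustive_within_monte_carlo_error(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        exact = permutation_t_test(x, y, n_perm=10**6, alternative="greater")
        assert exact.exhaustive
        sampled = permutation_t_test(x, y, n_perm=500, alternative="greater", seed=0)
        se = np.sqrt(exact.p * (1 - exact.p) / 500)
        assert abs(sampled.p - exact.p) <= 3 * se + 2 / 500

    def test_type_i_error_is_calibrated(self):
        # reduced-size calibration check; the acceptance suite runs 2,000
        rng = np.random.default_rng(11)
        rejections = 0
        n_runs = 300
        for i in range(n_runs):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = permutation_t_test(x, y, n_perm=400, seed=i)
            rejections += res.p <= 0.05
        rate = rejections / n_runs
        assert 0.02 <= rate <= 0.09


class TestMultipleTesting:
    def test_bonferroni_scales_and_caps(self):
        out = bonferroni([0.01, 0.5, 0.2, 0.03, 0.9])
        assert out[0] == pytest.approx(0.05)
        assert out[1] == 1.0

    def test_single_test_is_unchanged(self):
        assert bonferroni([0.2])[0] == pytest.approx(0.2)
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_bh_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_pvalues_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.07] * 5), [0.07] * 5)

    def test_against_statsmodels_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.001, 1.0, size=200)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )
        np.testing.assert_allclose(
            bonferroni(p), multipletests(p, method="bonferroni")[1], atol=1e-12
        )

    def test_adjustments_never_decrease_and_bh_below_bonferroni(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=50)
        q, b = bh_fdr(p), bonferroni(p)
        assert np.all(q >= p - 1e-15) and np.all(b >= p - 1e-15)
        assert np.all(q <= b + 1e-15)

    def test_invalid_pvalues_are_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestSizeFactors:
    def test_doubled_sample_gets_doubled_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(60, 1))
        counts = np.hstack([base, base * 2])
        factors = median_ratio_size_factors(counts)
        assert factors[1] / factors[0] == pytest.approx(2.0)

    def test_identical_samples_get_equal_factors(self):
        base = np.tile(np.arange(1, 31)[:, None], (1, 4))
        factors = median_ratio_size_factors(base)
        assert np.allclose(factors, factors[0])

    def test_matches_textbook_brute_force(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(50, size=(50, 4)) + 1
        # independent recomputation straight from the definition
        expected = []
        geo = np.exp(np.mean(np.log(counts), axis=1))
        for j in range(4):
            expected.append(np.median(counts[:, j] / geo))
        np.testing.assert_allclose(median_ratio_size_factors(counts), expected)

    def test_requires_a_gene_expressed_everywhere(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            median_ratio_size_factors(counts)


class TestCorrelatePhenotype:
    def _data(self, seed=0, n_strains=50, n_null=300, n_signal=10):
        rng = np.random.default_rng(seed)
        pheno = pd.Series(rng.normal(size=n_strains),
                          index=[f"s{i}" for i in range(n_strains)])
        null = rng.normal(size=(n_null, n_strains))
        signal = pheno.to_numpy() * 1.0 + rng.normal(0, 0.5, size=(n_signal, n_strains))
        X = pd.DataFrame(
            np.vstack([signal, null]),
            index=[f"g{i}" for i in range(n_signal + n_null)],
            columns=pheno.index,
        )
        return X, pheno, n_signal

    def test_gene_identical_to_phenotype_has_perfect_correlation(self):
        X, pheno, _ = self._data()
        X.loc["g0"] = pheno
        out = correlate_phenotype(X, pheno)
        assert out.loc["g0", "r"] == pytest.approx(1.0)
        assert bool(out.loc["g0", "significant"])

    def test_constant_gene_is_excluded_from_fdr(self):
        X, pheno, _ = self._data()
        X.loc["g1"] = 5.0
        out = correlate_phenotype(X, pheno)
        assert np.isnan(out.loc["g1", "r"]) and not out.loc["g1", "significant"]

    def test_planted_signal_genes_are_recovered(self):
        X, pheno, n_signal = self._data(seed=2)
        out = correlate_phenotype(X, pheno)
        signal_names = [f"g{i}" for i in range(n_signal)]
        assert out.loc[signal_names, "significant"].sum() >= n_signal - 1
        null_rate = out.drop(index=signal_names)["significant"].mean()
        assert null_rate <= 0.05

    def test_permuted_phenotype_controls_false_discoveries(self):
        X, pheno, _ = self._data(seed=3)
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            perm = pd.Series(rng.permutation(pheno.to_numpy()), index=pheno.index)
            rates.append(correlate_phenotype(X, perm)["significant"].mean())
        assert np.mean(rates) <= 0.05

    def test_requires_three_shared_strains(self):
        X = pd.DataFrame(np.ones((2, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            correlate_phenotype(X, pd.Series([1.0, 2.0], index=["a", "b"]))
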