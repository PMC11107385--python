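import math

import numpy as np
import pytest

from atmm.core import (
    CountMatrix,
    DegeneratePairError,
    DegenerateSampleError,
    PairwiseMA,
    TrimConfig,
    aggregate_factors,
    alpha_trimmed_mean,
    classic_tmm,
    dual_trim,
    factor_matrix,
    jaeckel_variance,
    library_sizes,
    normalize,
    optimal_alpha,
    pairwise_log_factor,
    pairwise_ma,
)


class TestCountMatrix:
    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            CountMatrix([[1, -1]], ["g"], ["a", "b"])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            CountMatrix([[1.5, 2.0]], ["g"], ["a", "b"])

    def test_integral_floats_cast(self):
        cm = CountMatrix(np.array([[1.0, 2.0]]), ["g"], ["a", "b"])
        assert cm.counts.dtype == np.int64

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate gene"):
            CountMatrix([[1, 2], [3, 4]], ["g", "g"], ["a", "b"])
        with pytest.raises(ValueError, match="duplicate sample"):
            CountMatrix([[1, 2], [3, 4]], ["g1", "g2"], ["a", "a"])

    def test_id_length_mismatch(self):
        with pytest.raises(ValueError):
            CountMatrix([[1, 2]], ["g1", "g2"], ["a", "b"])


class TestLibrarySizes:
    def test_column_sums(self, tiny_cm):
        assert library_sizes(tiny_cm).tolist() == [4, 6]

    def test_zero_column_errors(self):
        cm = CountMatrix([[1, 0], [2, 0]], ["g1", "g2"], ["ok", "empty"])
        with pytest.raises(DegenerateSampleError, match="empty"):
            library_sizes(cm)

    def test_all_ones(self):
        cm = CountMatrix(np.ones((7, 3), dtype=int),
                         [f"g{i}" for i in range(7)], ["a", "b", "c"])
        assert library_sizes(cm).tolist() == [7, 7, 7]


class TestPairwiseMA:
    def test_identical_columns_zero_m(self, identical_cm):
        stats = pairwise_ma(identical_cm, 1, 0)
        assert np.allclose(stats.M, 0.0, atol=1e-14)

    def test_scaled_column_zero_m(self, identical_cm):
        counts = identical_cm.counts.copy()
        counts[:, 1] = counts[:, 1] * 3
        cm = CountMatrix(counts, identical_cm.gene_ids, identical_cm.sample_ids)
        stats = pairwise_ma(cm, 1, 0)
        assert np.allclose(stats.M, 0.0, atol=1e-12)

    def test_hand_computed_values(self):
        # sample 0: library 100 with gene0=10; sample 1: library 400 with gene0=20
        cm = CountMatrix([[10, 20], [90, 380]], ["g0", "g1"], ["k", "r"])
        stats = pairwise_ma(cm, 0, 1)
        i = list(stats.gene_index).index(0)
        assert stats.M[i] == pytest.approx(1.0, abs=1e-12)
        assert stats.A[i] == pytest.approx(0.5 * math.log2(0.005), abs=1e-12)
        assert stats.var[i] == pytest.approx(0.1375, abs=1e-15)

    def test_zero_count_genes_excluded(self):
        cm = CountMatrix([[0, 5], [3, 0], [4, 4], [9, 2]],
                         ["g0", "g1", "g2", "g3"], ["k", "r"])
        stats = pairwise_ma(cm, 0, 1)
        assert stats.gene_index.tolist() == [2, 3]
        assert np.all(np.isfinite(stats.M))
        assert np.all(np.isfinite(stats.A))
        assert np.all(stats.var > 0)

    def test_too_few_genes(self):
        cm = CountMatrix([[0, 5], [3, 0], [4, 4]], ["g0", "g1", "g2"], ["k", "r"])
        with pytest.raises(DegeneratePairError):
            pairwise_ma(cm, 0, 1)

    def test_same_sample_rejected(self, tiny_cm):
        with pytest.raises(ValueError):
            pairwise_ma(tiny_cm, 1, 1)


class TestAlphaTrimmedMean:
    def test_one_from_each_tail(self):
        assert alpha_trimmed_mean([1, 2, 3, 4, 100], 0.2) == pytest.approx(3.0)

    def test_alpha_zero_is_mean(self):
        x = [3.5, -1.0, 2.25, 9.0]
        assert alpha_trimmed_mean(x, 0.0) == pytest.approx(np.mean(x), abs=0)

    def test_constant_vector(self):
        for alpha in (0.0, 0.1, 0.3, 0.49):
            assert alpha_trimmed_mean([7.0] * 9, alpha) == 7.0

    def test_over_trim_errors(self):
        # alpha*n snaps to n/2 -> nothing left
        with pytest.raises(ValueError, match="removes all"):
            alpha_trimmed_mean(list(range(10)), 0.49999999999)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            alpha_trimmed_mean([], 0.0)


class TestJaeckelVariance:
    def test_alpha_zero_mean_squared_deviation(self):
        assert jaeckel_variance([1, 2, 3], 0.0) == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_constant_vector_zero(self):
        for alpha in (0.0, 0.2, 0.4):
            assert jaeckel_variance([4.0] * 11, alpha) == 0.0
            assert jaeckel_variance([4.2] * 11, alpha) == pytest.approx(0.0, abs=1e-25)

    def test_matches_literal_formula(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=50)
        alpha = 0.1
        xs = sorted(x)
        n = 50
        t = math.floor(alpha * n)
        core = xs[t:n - t]
        mu = sum(core) / len(core)
        expected = (
            sum((v - mu) ** 2 for v in core) / n
            + alpha * (xs[t] - mu) ** 2
            + alpha * (xs[n - t - 1] - mu) ** 2
        ) / (1 - 2 * alpha) ** 2
        assert jaeckel_variance(x, alpha) == pytest.approx(expected, abs=1e-12)


class TestOptimalAlpha:
    def test_constant_vector_smallest_alpha(self):
        alpha, v = optimal_alpha([3.0] * 20)
        assert alpha == 0.0
        assert v == 0.0

    def test_outliers_force_positive_alpha(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        x[:5] = 50.0
        x[5:10] = -50.0
        alpha, v = optimal_alpha(x)
        assert alpha > 0
        # exhaustive check over the full documented grid
        n = len(x)
        bound = min(0.5, 0.4, (n - 1) / (2 * n))
        grid = [t / n for t in range(int(math.ceil(n * bound - 1e-9)))]
        values = [jaeckel_variance(x, a) for a in grid]
        best = int(np.argmin(values))
        assert alpha == pytest.approx(grid[best], abs=0)
        assert v == pytest.approx(values[best], abs=0)

    def test_vmin_self_consistent(self):
        rng = np.random.default_rng(11)
        x = rng.exponential(size=77)
        alpha, v = optimal_alpha(x)
        assert v == jaeckel_variance(x, alpha)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            optimal_alpha([1.0, 2.0])

    def test_delta_caps_grid(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        alpha, _ = optimal_alpha(x, delta=0.05)
        assert alpha < 0.05


class TestDualTrim:
    @staticmethod
    def _stats(m, a):
        m = np.asarray(m, dtype=float)
        a = np.asarray(a, dtype=float)
        return PairwiseMA(sample_index=0, reference_index=1,
                          gene_index=np.arange(len(m)), M=m, A=a,
                          var=np.ones(len(m)))

    def test_no_trim_keeps_all(self):
        stats = self._stats([3, 1, 2], [5, 6, 4])
        assert dual_trim(stats, 0.0, 0.0).tolist() == [0, 1, 2]

    def test_m_trim_only(self):
        # n=10, alpha_m=0.3 -> 3 removed from each M tail, |G*| = 4
        stats = self._stats(np.arange(10), np.zeros(10))
        keep = dual_trim(stats, 0.3, 0.0)
        assert keep.tolist() == [3, 4, 5, 6]

    def test_set_logic_oracle(self):
        rng = np.random.default_rng(19)
        m = rng.normal(size=40)
        a = rng.normal(size=40)
        stats = self._stats(m, a)
        alpha_m, alpha_a = 0.25, 0.1
        t_m = math.floor(alpha_m * 40)
        t_a = math.floor(alpha_a * 40)
        surv_m = set(np.argsort(m, kind="stable")[t_m:40 - t_m].tolist())
        surv_a = set(np.argsort(a, kind="stable")[t_a:40 - t_a].tolist())
        expected = sorted(surv_m & surv_a)
        assert dual_trim(stats, alpha_m, alpha_a).tolist() == expected


class TestPairwiseLogFactor:
    @staticmethod
    def _stats(m, var):
        m = np.asarray(m, dtype=float)
        var = np.asarray(var, dtype=float)
        return PairwiseMA(sample_index=0, reference_index=1,
                          gene_index=np.arange(len(m)), M=m,
                          A=np.zeros(len(m)), var=var)

    def test_constant_m(self):
        stats = self._stats([2.5] * 4, [0.1, 0.2, 0.3, 0.4])
        keep = np.arange(4)
        assert pairwise_log_factor(stats, keep) == pytest.approx(2.5, abs=1e-14)

    def test_equal_weights(self):
        stats = self._stats([1.0, 3.0], [1.0, 1.0])
        assert pairwise_log_factor(stats, np.array([0, 1])) == pytest.approx(2.0)

    def test_unequal_weights(self):
        stats = self._stats([1.0, 3.0], [0.5, 1.5])
        expected = (2 * 1 + (2 / 3) * 3) / (2 + 2 / 3)
        assert pairwise_log_factor(stats, np.array([0, 1])) == pytest.approx(expected, abs=1e-14)

    def test_empty_set_errors(self):
        stats = self._stats([1.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            pairwise_log_factor(stats, np.array([], dtype=int))


class TestFactorMatrix:
    def test_identical_columns_zero_matrix(self, identical_cm):
        cfg = TrimConfig(min_genes_after_trim=2)
        matrix, _, warnings = factor_matrix(identical_cm, cfg)
        assert np.allclose(matrix, 0.0, atol=1e-12)
        assert warnings == []

    def test_diagonal_zero(self, nb_matrix):
        matrix, _, _ = factor_matrix(nb_matrix(0))
        assert np.all(np.diag(matrix) == 0)

    def test_depth_scaling(self, nb_matrix):
        # M, A and the trim selection are exactly depth invariant (Y/N
        # cancellation); the weighted average is only approximately so,
        # because the precision weights (N-Y)/(N*Y) depend on library size.
        cm = nb_matrix(1)
        scaled = cm.counts.copy()
        scaled[:, 2] = scaled[:, 2] * 5
        cm2 = CountMatrix(scaled, cm.gene_ids, cm.sample_ids)
        s1 = pairwise_ma(cm, 2, 0)
        s2 = pairwise_ma(cm2, 2, 0)
        assert np.allclose(s1.M, s2.M, atol=1e-12)
        assert np.allclose(s1.A, s2.A, atol=1e-12)
        m1, a1, _ = factor_matrix(cm)
        m2, a2, _ = factor_matrix(cm2)
        assert a1 == a2  # selected trims unchanged
        assert np.allclose(m1, m2, atol=0.1)

    def test_fixed_alpha_matches_classic(self, nb_matrix):
        cm = nb_matrix(2)
        cfg = TrimConfig(fixed_alpha_m=0.30, fixed_alpha_a=0.05)
        matrix, alphas, _ = factor_matrix(cm, cfg)
        classic = classic_tmm(cm, ref=0)
        assert np.allclose(2.0 ** matrix[0], classic, atol=1e-12)
        assert all(a == (0.30, 0.05) for a in alphas.values())


class TestAggregateFactors:
    def test_zero_matrix_unit_factors(self):
        assert np.allclose(aggregate_factors(np.zeros((3, 3))), 1.0)

    def test_two_sample_geometric_mean(self):
        a, b = 0.8, -0.3
        matrix = np.array([[0.0, b], [a, 0.0]])
        cfg = TrimConfig(renormalize_factors=False)
        factors = aggregate_factors(matrix, cfg)
        assert factors[0] == pytest.approx(2 ** (a / 2), abs=1e-14)
        assert factors[1] == pytest.approx(2 ** (b / 2), abs=1e-14)

    def test_renormalized_product_one(self, nb_matrix):
        matrix, _, _ = factor_matrix(nb_matrix(3))
        factors = aggregate_factors(matrix)
        assert np.prod(factors) == pytest.approx(1.0, abs=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            aggregate_factors(np.zeros((2, 3)))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            aggregate_factors(np.eye(3))


class TestNormalize:
    def test_identical_samples_unit_factors(self, identical_cm):
        result = normalize(identical_cm, TrimConfig(min_genes_after_trim=2))
        assert np.allclose(result.factors, 1.0, atol=1e-12)
        assert np.allclose(result.effective_library_sizes,
                           library_sizes(identical_cm), atol=1e-9)

    def test_deterministic(self, nb_matrix):
        cm = nb_matrix(4)
        r1 = normalize(cm)
        r2 = normalize(cm)
        assert np.array_equal(r1.factors, r2.factors)
        assert np.array_equal(r1.log2_factor_matrix, r2.log2_factor_matrix)
        assert r1.alpha_table == r2.alpha_table

    def test_alpha_table_in_range(self, nb_matrix):
        result = normalize(nb_matrix(5))
        for alpha_m, alpha_a in result.alpha_table.values():
            assert 0.0 <= alpha_m < 0.5
            assert 0.0 <= alpha_a < 0.5

    def test_permutation_equivariance(self, nb_matrix):
        cm = nb_matrix(6)
        perm = [2, 0, 3, 1]
        permuted = CountMatrix(cm.counts[:, perm], cm.gene_ids,
                               [cm.sample_ids[j] for j in perm])
        f1 = normalize(cm).factors
        f2 = normalize(permuted).factors
        assert np.allclose(f2, f1[perm], atol=1e-12)

    def test_single_sample_rejected(self):
        cm = CountMatrix([[1], [2]], ["g1", "g2"], ["only"])
        with pytest.raises(ValueError):
            normalize(cm)


class TestClassicTmm:
    def test_identical_samples(self, identical_cm):
        factors = classic_tmm(identical_cm, 0, min_genes_after_trim=2)
        assert np.allclose(factors, 1.0, atol=1e-12)

    def test_reference_factor_is_one(self, nb_matrix):
        factors = classic_tmm(nb_matrix(8), ref=2)
        assert factors[2] == 1.0

    def test_ref_out_of_range(self, nb_matrix):
        with pytest.raises(ValueError):
            classic_tmm(nb_matrix(9), ref=10)


class TestTrimConfig:
    def test_delta_bounds(self):
        with pytest.raises(ValueError):
            TrimConfig(delta=0.0)
        with pytest.raises(ValueError):
            TrimConfig(delta=0.6)

    def test_fixed_alpha_bounds(self):
        with pytest.raises(ValueError):
            TrimConfig(fixed_alpha_m=0.5)
        with pytest.raises(ValueError):
            TrimConfig(delta=0.2, fixed_alpha_m=0.3)

    def test_alpha_cap_bounds(self):
        with pytest.raises(ValueError):
            TrimConfig(alpha_cap=0.0)
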