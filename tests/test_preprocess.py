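"""Count preprocessing chain: filtering, normalization, HVG selection, scaling."""

import numpy as np
import pytest

from rhopca import (
    CountMatrix,
    depth_normalize_log1p,
    filter_high_expression,
    preprocess_pair,
    sample_covariance,
    select_highly_variable,
    simulate_counts,
    standard_scale,
)
from rhopca.errors import AlignmentError, EmptySampleError, InvalidInputError


def _cm(counts, groups=None):
    counts = np.asarray(counts, float)
    n, g = counts.shape
    return CountMatrix(counts, [f"s{i}" for i in range(n)],
                       [f"g{i}" for i in range(g)], groups)


class TestFilterHighExpression:
    def test_linear_interpolation_percentile(self):
        # totals 1..10: 80th percentile = 8.2, so only totals 9 and 10 survive
        cm = _cm(np.arange(1, 11, dtype=float)[None, :].repeat(2, 0) / 2)
        kept = filter_high_expression(cm, 80)
        assert kept.feature_names == ["g8", "g9"]

    def test_percentile_zero_keeps_all(self):
        cm = _cm([[1.0, 2.0, 3.0]])
        assert filter_high_expression(cm, 0).n_features == 3

    def test_ties_at_threshold_kept(self):
        cm = _cm(np.full((3, 7), 2.0))
        assert filter_high_expression(cm, 80).n_features == 7

    def test_invalid_percentile(self):
        with pytest.raises(InvalidInputError):
            filter_high_expression(_cm([[1.0]]), 100)


class TestDepthNormalizeLog1p:
    def test_proportional_rescale(self):
        sm = depth_normalize_log1p(_cm([[1.0, 1.0, 2.0]]), target_sum=10_000)
        assert np.allclose(np.expm1(sm.values), [2500.0, 2500.0, 5000.0])
        assert sm.depth_normalized and sm.log1p

    def test_zero_column_is_fixed_point(self):
        sm = depth_normalize_log1p(_cm([[1.0, 0.0], [3.0, 0.0]]))
        assert np.all(sm.values[:, 1] == 0.0)

    def test_row_sums_hit_target(self, rng):
        counts = rng.integers(1, 50, size=(5, 4)).astype(float)
        sm = depth_normalize_log1p(_cm(counts))
        sums = np.expm1(sm.values).sum(axis=1)
        assert np.allclose(sums, 10_000.0, atol=1e-6)

    def test_empty_sample_error_names_rows(self):
        with pytest.raises(EmptySampleError, match="s1"):
            depth_normalize_log1p(_cm([[1.0, 2.0], [0.0, 0.0]]))


class TestSelectHighlyVariable:
    def test_all_features_when_n_top_is_total(self):
        sm = depth_normalize_log1p(_cm(np.random.default_rng(0).integers(1, 20, (30, 12)).astype(float)))
        assert select_highly_variable(sm, n_top=12, n_bins=3) == sm.feature_names

    def test_planted_dispersion_recovered(self, rng):
        """Features with inflated variance at matched means win within every bin."""
        from rhopca import ScaledMatrix

        n, g = 400, 100
        # 50 distinct mean levels, two features each: matched-mean pairs
        mu = np.repeat(np.linspace(2.0, 8.0, 50), 2)
        values = rng.normal(loc=mu, scale=np.sqrt(mu), size=(n, g))  # dispersion ~ 1
        planted = np.arange(0, 100, 10)  # one member of 10 pairs, spread over means
        values[:, planted] = rng.normal(
            loc=mu[planted], scale=np.sqrt(5.0 * mu[planted]), size=(n, 10)
        )
        sm = ScaledMatrix(values, [f"s{i}" for i in range(n)],
                          [f"g{i}" for i in range(g)], log1p=True)
        top = select_highly_variable(sm, n_top=10, n_bins=5)
        assert set(top) == {f"g{i}" for i in planted}

    def test_exact_count_returned(self, rng):
        counts = rng.integers(0, 30, size=(50, 2500)).astype(float) + 1
        sm = depth_normalize_log1p(_cm(counts))
        assert len(select_highly_variable(sm, n_top=2000, n_bins=20)) == 2000

    def test_n_top_too_large_rejected(self):
        sm = depth_normalize_log1p(_cm([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(InvalidInputError):
            select_highly_variable(sm, n_top=3)


class TestStandardScale:
    def test_idempotent_on_standardized_input(self, rng):
        sm = depth_normalize_log1p(_cm(rng.integers(1, 30, (20, 5)).astype(float)))
        once = standard_scale(sm)
        twice = standard_scale(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_mean_zero_unit_variance(self, rng):
        sm = standard_scale(depth_normalize_log1p(_cm(rng.integers(1, 30, (20, 5)).astype(float))))
        assert np.max(np.abs(sm.values.mean(axis=0))) <= 1e-8
        assert np.max(np.abs(sm.values.var(axis=0, ddof=1) - 1)) <= 1e-6

    def test_constant_column_zeroed_and_warned(self, caplog):
        sm = depth_normalize_log1p(_cm([[1.0, 5.0], [2.0, 10.0], [3.0, 15.0]]))
        sm.values[:, 1] = 7.0  # make column constant post-normalization
        with caplog.at_level("WARNING", logger="rhopca.preprocess"):
            out = standard_scale(sm)
        assert np.all(out.values[:, 1] == 0.0)
        assert "constant" in caplog.text

    def test_closed_form_column(self):
        sm = depth_normalize_log1p(_cm([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]))
        sm.values = np.array([[1.0], [2.0], [3.0]])
        sm.feature_names = ["g0"]
        out = standard_scale(sm)
        a = 1.0  # (3-2)/std([1,2,3], ddof=1) = 1/1
        assert np.allclose(out.values[:, 0], [-a, 0.0, a])

    def test_single_row_rejected(self):
        sm = depth_normalize_log1p(_cm([[1.0, 2.0]]))
        with pytest.raises(InvalidInputError):
            standard_scale(sm)


class TestSampleCovariance:
    def test_unit_diagonal_after_scaling(self, rng):
        sm = standard_scale(depth_normalize_log1p(_cm(rng.integers(1, 30, (25, 6)).astype(float))))
        cov = sample_covariance(sm)
        assert np.allclose(np.diag(cov), 1.0, atol=1e-6)

    def test_perfect_correlation(self):
        sm = depth_normalize_log1p(_cm([[1.0, 1.0], [2.0, 2.0], [4.0, 4.0]]))
        sm.values = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        cov = sample_covariance(sm)
        assert np.allclose(cov, [[1.0, 1.0], [1.0, 1.0]])


class TestPreprocessPair:
    def test_pipeline_composes_into_valid_pair(self):
        cm_t, cm_b = simulate_counts(80, 120, planted_variable_genes=[0, 1, 2], seed=4)
        sm_t, sm_b, pair = preprocess_pair(cm_t, cm_b, percentile=20, n_top=50, n_bins=5)
        assert sm_t.feature_names == sm_b.feature_names == pair.feature_names
        assert len(pair.feature_names) == 50
        assert np.allclose(np.diag(pair.sigma_t), 1.0, atol=1e-6)

    def test_separate_vs_joint_scaling_differ_on_heterogeneous_groups(self):
        cm_t, cm_b = simulate_counts(60, 80, planted_variable_genes=list(range(10)), seed=5)
        _, _, pair_sep = preprocess_pair(cm_t, cm_b, percentile=0, n_top=None)
        # joint scaling: pool, scale, then split
        pooled = CountMatrix(
            np.vstack([cm_t.counts, cm_b.counts]),
            cm_t.sample_names + [s + "_b" for s in cm_b.sample_names],
            cm_t.feature_names,
        )
        sm = standard_scale(depth_normalize_log1p(pooled))
        from rhopca.preprocess import _subset_scaled
        half = cm_t.n_samples
        top_t = _subset_scaled(sm, list(range(sm.n_features)))
        cov_t_joint = np.cov(top_t.values[:half], rowvar=False)
        assert not np.allclose(cov_t_joint, pair_sep.sigma_t, atol=1e-3)

    def test_feature_divergence_is_an_error(self):
        cm_t, cm_b = simulate_counts(20, 30, seed=6)
        cm_b.feature_names[5] = "renamed"
        with pytest.raises(AlignmentError, match="gene5|renamed"):
            preprocess_pair(cm_t, cm_b)
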