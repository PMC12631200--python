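"""ISIC arithmetic, D-threshold filtering, SPA chains and chained selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_spa, residual_norms_along_chain
from defoliascan.bandselect import (
    CVConfig,
    GridConfig,
    di_series,
    filter_by_threshold,
    isic_spa_select,
    isic_values,
    optimize_threshold,
    retained_mask,
    spa_chain,
    spa_select,
)
from defoliascan.errors import DegenerateSelectionError, InvalidInputError

SQ2 = np.sqrt(2.0)


class TestISIC:
    def test_three_class_worked_example(self):
        """A={1,3}, B={5,7}, C={9,11}: pair terms 2sqrt2/4, 2sqrt2/8, 2sqrt2/4."""
        X = np.array([[1.0], [3.0], [5.0], [7.0], [9.0], [11.0]])
        y = np.array([1, 1, 2, 2, 3, 3])
        expected = (2 * SQ2 / 4 + 2 * SQ2 / 8 + 2 * SQ2 / 4) / 3
        assert isic_values(X, y)[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_within_class_sd_gives_zero(self):
        X = np.array([[0.2], [0.2], [0.4], [0.4]])
        assert isic_values(X, np.array([1, 1, 2, 2]))[0] == 0.0

    def test_identical_class_means_give_infinity(self):
        X = np.array([[0.1], [0.5], [0.1], [0.5]])
        assert np.isinf(isic_values(X, np.array([1, 1, 2, 2]))[0])

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            isic_values(np.ones((4, 2)), np.array([1, 1, 1, 1]))

    def test_small_class_rejected(self):
        with pytest.raises(InvalidInputError):
            isic_values(np.ones((3, 2)), np.array([1, 1, 2]))

    @settings(max_examples=30, deadline=None)
    @given(
        c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_scale_invariance(self, c, seed):
        """Multiplying all reflectances by c > 0 leaves every ISIC unchanged."""
        rng = np.random.default_rng(seed)
        X = rng.uniform(0.1, 0.9, (9, 4))
        y = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        a, b = isic_values(X, y), isic_values(c * X, y)
        finite = np.isfinite(a)
        np.testing.assert_array_equal(finite, np.isfinite(b))
        np.testing.assert_allclose(a[finite], b[finite], rtol=1e-9)

    def test_larger_separation_strictly_lowers_isic(self):
        """With within-class spread fixed, wider class means are more stable."""

        def two_class(sep):
            X = np.array([[0.0], [2.0], [sep], [sep + 2.0]])
            return isic_values(X, np.array([1, 1, 2, 2]))[0]

        assert two_class(8.0) < two_class(4.0)


class TestDSeries:
    def test_constant_isic_gives_zero_d(self):
        np.testing.assert_array_equal(di_series([0.3, 0.3, 0.3]), [0.0, 0.0])

    def test_forced_arithmetic(self):
        np.testing.assert_allclose(di_series([0.1, 0.4, 0.2]), [0.3, 0.2])

    def test_infinity_propagates_to_both_neighbors(self):
        d = di_series([0.1, np.inf, 0.2, 0.3])
        assert np.isinf(d[0]) and np.isinf(d[1]) and d[2] == pytest.approx(0.1)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            di_series([1.0])


class TestThresholdFilter:
    def test_infinite_threshold_retains_all(self):
        d = np.array([0.5, np.inf, 0.1])
        np.testing.assert_array_equal(filter_by_threshold(d, np.inf), [0, 1, 2, 3])

    def test_worked_example(self):
        """D=(0.3,0.2), T=0.25: first band removed, bands 2 and 3 kept."""
        np.testing.assert_array_equal(filter_by_threshold([0.3, 0.2], 0.25), [1, 2])

    def test_zero_threshold_on_strictly_varying_series_errors(self):
        with pytest.raises(DegenerateSelectionError):
            filter_by_threshold([0.1, 0.2, 0.3], 0.0)

    def test_zero_threshold_keeps_exactly_equal_neighbors(self):
        # ISIC (1,1,2): D=(0,1): bands 0 kept, 1 and 2 removed
        np.testing.assert_array_equal(filter_by_threshold([0.0, 1.0], 0.0), [0])

    @settings(max_examples=50, deadline=None)
    @given(
        d=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12),
        t1=st.floats(0, 10),
        t2=st.floats(0, 10),
    )
    def test_monotone_in_threshold(self, d, t1, t2):
        lo, hi = sorted((t1, t2))
        kept_lo = set(np.flatnonzero(retained_mask(np.array(d), lo)).tolist())
        kept_hi = set(np.flatnonzero(retained_mask(np.array(d), hi)).tolist())
        assert kept_lo <= kept_hi


class TestSPAChain:
    def test_orthogonal_columns_follow_norm_order(self):
        X = np.diag([3.0, 2.0, 1.0])
        assert spa_chain(X, start=1, k_max=3) == [1, 0, 2]

    def test_duplicate_column_never_follows_its_twin(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        X[:, 3] = X[:, 1]
        for start in range(4):
            chain = spa_chain(X, start, 4)
            assert not ({1, 3} <= set(chain))

    def test_kmax_one_returns_start(self):
        X = np.random.default_rng(1).normal(size=(5, 3))
        assert spa_chain(X, 2, 1) == [2]

    def test_rank_deficiency_truncates_without_error(self):
        X = np.zeros((4, 3))
        X[:, 0] = [1, 2, 3, 4]
        X[:, 1] = 2 * X[:, 0]
        X[:, 2] = -X[:, 0]
        assert len(spa_chain(X, 0, 3)) == 1

    def test_matches_gram_schmidt_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n, B = rng.integers(3, 9), rng.integers(2, 7)
            X = rng.normal(size=(n, B))
            for start in range(B):
                assert spa_chain(X, start, B) == brute_force_spa(X, start, B)

    def test_no_repeats_and_residuals_nonincreasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 8))
        chain = spa_chain(X, 0, 8)
        assert len(chain) == len(set(chain))
        norms = residual_norms_along_chain(X, chain)
        assert all(a >= b - 1e-9 for a, b in zip(norms[1:-1], norms[2:]))


def _separable_two_class(reps=6):
    """Four perfectly separable bands with two distinct ISIC levels.

    Bands 2-3 share the class separation of bands 0-1 but have four times
    the within-class spread, hence four times the ISIC value; the D series
    is (0, gap, 0).
    """
    col0 = np.concatenate([np.linspace(0.0, 0.1, reps), np.linspace(1.0, 1.1, reps)])
    col2 = np.concatenate([np.linspace(0.0, 0.4, reps), np.linspace(1.0, 1.4, reps)])
    X = np.column_stack([col0, col0, col2, col2])
    y = np.array([1] * reps + [2] * reps)
    return X, y


class TestOptimizeThreshold:
    def test_recovers_planted_band_among_noise(self):
        """The tuned threshold keeps the only class-informative band."""
        hits = 0
        cv = CVConfig(folds=10, seed=0, n_estimators=30)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(0.4, 0.05, (60, 15))
            y = np.repeat([1, 2, 3], 20)
            X[:, 7] += 0.2 * (y - 1)
            result = optimize_threshold(X, y, cv_cfg=cv)
            hits += 7 in result.retained
        assert hits == 5

    def test_single_point_grid_returns_that_point(self):
        X, y = _separable_two_class()
        cv = CVConfig(folds=3, seed=0, n_estimators=10)
        result = optimize_threshold(
            X, y, cv_cfg=cv, grid_cfg=GridConfig(n_coarse=1, refine_rounds=0)
        )
        assert result.threshold == 0.0

    def test_equal_accuracy_prefers_fewer_bands(self):
        """Every subset separates perfectly, so the smaller retention wins."""
        X, y = _separable_two_class()
        cv = CVConfig(folds=3, seed=0, n_estimators=10)
        result = optimize_threshold(
            X, y, cv_cfg=cv, grid_cfg=GridConfig(n_coarse=4, refine_rounds=0)
        )
        # D = (0, gap, 0): threshold 0 keeps 3 of 4 bands, anything larger keeps 4
        assert result.threshold == 0.0
        assert len(result.retained) == 3


def _planted_two_band_table(seed):
    from defoliascan.synthgen import generate_planted_spectra

    return generate_planted_spectra(
        n_per_class=(15, 15, 15),
        planted_nm=(686.0, 759.0),
        offsets=[[0.0, 0.0], [0.08, 0.0], [0.08, -0.08]],
        wavelengths=np.linspace(400, 1000, 40),
        seed=seed,
    )


class TestSPASelect:
    def test_recovers_planted_bands(self):
        hits = 0
        for seed in range(5):
            table = _planted_two_band_table(seed)
            cv = CVConfig(folds=5, seed=seed, n_estimators=30)
            result = spa_select(table, cv_cfg=cv, k_max=4, starts=10)
            planted = {table.band_nearest(686), table.band_nearest(759)}
            hits += planted <= set(result.band_indices)
        assert hits >= 4

    def test_huge_tolerance_forces_single_band(self):
        table = _planted_two_band_table(0)
        cv = CVConfig(folds=5, seed=0, n_estimators=20, tol=1.0)
        result = spa_select(table, cv_cfg=cv, k_max=3, starts=5)
        assert result.chosen_size == 1

    def test_accuracy_curve_in_unit_interval(self):
        table = _planted_two_band_table(1)
        cv = CVConfig(folds=5, seed=0, n_estimators=20)
        result = spa_select(table, cv_cfg=cv, k_max=3, starts=5)
        assert all(0.0 <= acc <= 1.0 for _, acc in result.accuracy_curve)


class TestISICSPASelect:
    def test_infinite_threshold_reduces_to_spa(self):
        table = _planted_two_band_table(2)
        cv = CVConfig(folds=5, seed=0, n_estimators=20)
        plain = spa_select(table, cv_cfg=cv, k_max=3, starts=8)
        chained = isic_spa_select(
            table, cv_cfg=cv, k_max=3, starts=8, threshold=np.inf
        )
        assert chained.band_indices == plain.band_indices
        assert chained.chosen_size == plain.chosen_size

    def test_selection_restricted_to_retained_bands(self):
        X, y = _separable_two_class()
        cv = CVConfig(folds=3, seed=0, n_estimators=10)
        # threshold 0 retains bands {0, 2, 3}; SPA must choose inside them
        result = isic_spa_select(X, y, cv_cfg=cv, k_max=2, threshold=0.0)
        assert set(result.band_indices) <= {0, 2, 3}
        assert result.n_retained_by_isic == 3

    def test_too_few_retained_bands_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        y = np.array([1] * 6 + [2] * 6)
        X[:, 0] += y  # informative band so ISIC is finite somewhere
        isic = isic_values(X, y)
        d = di_series(isic)
        # pick a threshold retaining exactly one band, if one exists
        for t in np.sort(d[np.isfinite(d)]):
            kept = retained_mask(d, t * 0.999).sum()
            if kept < 2:
                with pytest.raises(DegenerateSelectionError):
                    isic_spa_select(X, y, k_max=2, threshold=float(t) * 0.999)
                return
        pytest.skip("no threshold yields a <2-band retention for this draw")
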