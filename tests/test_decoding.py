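import numpy as np
import pytest
from scipy.stats import norm

from npil.decoding import (
    cv_linear_decoding_accuracy,
    dprime,
    dprime_spatial_shuffle_test,
    patch_size_sweep,
    population_size_sweep,
    rank_filter_columns,
)


class TestCvDecoding:
    def test_separable_classes_perfect(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)])[:, None]
        y = np.repeat([0, 1], 50)
        assert cv_linear_decoding_accuracy(x, y, seed=0) == 1.0

    def test_chance_level_for_identical_distributions(self, rng):
        accs = [
            cv_linear_decoding_accuracy(
                rng.normal(size=(160, 5)), np.tile([0, 1], 80), seed=s
            )
            for s in range(40)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_dprime_one_matches_bayes_accuracy(self, rng):
        # 1-D unit-variance Gaussians one mean apart: optimal accuracy Phi(1/2)
        n = 10000
        x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)])[:, None]
        y = np.repeat([0, 1], n // 2)
        acc = cv_linear_decoding_accuracy(x, y, seed=1)
        assert acc == pytest.approx(norm.cdf(0.5), abs=0.02)

    def test_affine_feature_rescaling_invariant(self, rng):
        X = rng.normal(size=(120, 4))
        X[:60] += 0.8
        y = np.repeat([0, 1], 60)
        a0 = cv_linear_decoding_accuracy(X, y, seed=3)
        X2 = X.copy()
        X2[:, 2] = 13.0 * X2[:, 2] - 5.0
        assert cv_linear_decoding_accuracy(X2, y, seed=3) == pytest.approx(a0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.tile([0, 1], 30)
        assert cv_linear_decoding_accuracy(X, y, seed=5) == cv_linear_decoding_accuracy(
            X, y, seed=5
        )

    def test_singular_covariance_handled(self, rng):
        X = rng.normal(size=(40, 2))
        X = np.hstack([X, X[:, :1]])  # duplicated feature: singular pooled cov
        y = np.tile([0, 1], 20)
        acc = cv_linear_decoding_accuracy(X, y, folds=5, seed=0)
        assert 0.0 <= acc <= 1.0


class TestPopulationSizeSweep:
    def test_full_population_single_resample_equals_cv(self, rng):
        X = rng.normal(size=(80, 4))
        X[:40] += 1.0
        y = np.repeat([0, 1], 40)
        out = population_size_sweep(X, y, [4], resamples=1, seed=9)
        # replay the sweep's draws: the feature subset is all 4 columns
        # (in some order), then the inner fold seed
        r = np.random.default_rng(9)
        cols = r.choice(4, size=4, replace=False)
        direct = cv_linear_decoding_accuracy(X[:, cols], y, seed=int(r.integers(2**31 - 1)))
        assert out["accuracy"].iloc[0] == pytest.approx(direct)

    def test_accuracy_grows_with_population(self, rng):
        X = rng.normal(size=(200, 8)) + np.repeat([0.0, 0.6], 100)[:, None]
        y = np.repeat([0, 1], 100)
        out = population_size_sweep(X, y, [1, 2, 4, 8], resamples=20, seed=2)
        acc = out["accuracy"].to_numpy()
        assert np.all(np.diff(acc) > -0.02)  # non-decreasing up to MC noise

    def test_reproducible(self, rng):
        X = rng.normal(size=(60, 5))
        y = np.tile([0, 1], 30)
        a = population_size_sweep(X, y, [2], resamples=5, seed=4)
        b = population_size_sweep(X, y, [2], resamples=5, seed=4)
        assert a.equals(b)

    def test_oversized_population_rejected(self, rng):
        with pytest.raises(ValueError):
            population_size_sweep(rng.normal(size=(20, 3)), np.tile([0, 1], 10), [4])


class TestRankFilter:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        assert rank_filter_columns(X) == [0]

    def test_linear_combination_dropped(self, rng):
        a, b = rng.normal(size=(20, 1)), rng.normal(size=(20, 1))
        X = np.hstack([a, b, a + b])
        assert rank_filter_columns(X) == [0, 1]

    def test_independent_columns_kept(self, rng):
        X = rng.normal(size=(30, 5))
        assert rank_filter_columns(X) == [0, 1, 2, 3, 4]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rank_filter_columns(np.zeros((10, 3)))


class TestPatchSizeSweep:
    def test_overlapping_patches_reduced_and_decoded(self, rng):
        # two cells close together: at large radii their annuli coincide
        n_trials = 60
        y = np.tile([0, 1], 30)
        H = W = 40
        pix = rng.normal(0, 0.1, size=(n_trials, H, W))
        pix[y == 1, :, :20] += 1.0  # left half carries the direction signal
        centers = [(20, 18), (20, 22)]
        out = patch_size_sweep(
            pix, centers, [(2.0, 4.0), (2.0, 30.0)], 1.0, y, folds=5, seed=0
        )
        assert out.loc[out["r_out"] == 4.0, "n_patches"].iloc[0] == 2
        assert np.all(out["accuracy"] > 0.9)


class TestDprime:
    def test_equal_means_zero(self, rng):
        x = rng.normal(size=50)
        assert dprime(x, x) == 0.0

    def test_unit_case(self):
        x_h = np.array([0.0, 2.0])  # mean 1, var 2
        x_v = np.array([-1.0, 1.0])  # mean 0, var 2
        assert dprime(x_h, x_v) == pytest.approx(1.0 / np.sqrt(2.0))

    def test_hand_arithmetic(self, rng):
        x_h = rng.normal(2.0, np.sqrt(0.5), 200000)
        x_v = rng.normal(0.0, np.sqrt(0.5), 200000)
        assert dprime(x_h, x_v) == pytest.approx(2.828, abs=0.03)

    def test_zero_variance_unequal_means_flagged(self):
        with pytest.warns(UserWarning):
            assert dprime(np.ones(3), np.zeros(3)) == np.inf

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            dprime(np.ones(1), np.zeros(5))


class TestSpatialShuffle:
    def test_identical_maps_maximally_significant(self, rng):
        m = rng.normal(size=30)
        r, z, p = dprime_spatial_shuffle_test(m, m, n_shuffles=10000, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 1.0 / 10001 + 1e-12
        assert z > 4.0

    def test_independent_maps_not_significant_on_average(self, rng):
        rejections = sum(
            dprime_spatial_shuffle_test(
                rng.normal(size=25), rng.normal(size=25), n_shuffles=500, seed=s
            )[2]
            < 0.05
            for s in range(100)
        )
        assert rejections <= 12  # ~5 expected

    def test_too_few_rois(self):
        with pytest.raises(ValueError):
            dprime_spatial_shuffle_test(np.ones(2), np.ones(2))

    def test_deterministic(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert dprime_spatial_shuffle_test(a, b, 200, seed=3) == dprime_spatial_shuffle_test(
            a, b, 200, seed=3
        )
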