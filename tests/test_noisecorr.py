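import numpy as np
import pandas as pd
import pytest

from npil.noisecorr import (
    annular_cell_np_correlation,
    annulus_radii_sequence,
    condition_residuals,
    distance_profile_fit,
    noise_correlation,
    pairwise_noise_correlations,
    slope_difference_test,
    subtract_cell_component,
)
from npil.responses import TABLE_COLUMNS
from npil.roi import make_neuropil_annulus


def _conditions(n_trials):
    dirs = np.repeat([0.0, 90.0], 3 * n_trials)
    cons = np.tile(np.repeat([100.0, 40.0, 15.0], n_trials), 2)
    return dirs, cons


class TestResiduals:
    def test_zero_mean_per_condition(self, rng):
        rows = [
            ("r0", "cell", d, c, t, rng.normal(5.0, 2.0))
            for d in (0.0, 90.0) for c in (100.0, 40.0) for t in range(20)
        ]
        table = condition_residuals(pd.DataFrame(rows, columns=TABLE_COLUMNS))
        sums = table.groupby(["direction", "contrast"])["residual"].sum()
        assert np.allclose(sums, 0.0, atol=1e-10)


class TestNoiseCorrelation:
    def test_identical_residuals_give_one(self, rng):
        dirs, cons = _conditions(40)
        x = rng.normal(size=dirs.size)
        cc = noise_correlation(x, x, dirs, cons)
        assert np.allclose(cc.to_numpy(), 1.0)

    def test_independent_residuals_near_zero(self, rng):
        dirs, cons = _conditions(80)  # 160 trials per contrast
        cc = noise_correlation(
            rng.normal(size=dirs.size), rng.normal(size=dirs.size), dirs, cons
        )
        assert np.all(np.abs(cc.to_numpy()) < 0.2)

    def test_shared_signal_analytic_level(self, rng):
        # x = s + e1, y = s + e2 with unit variances: rho = 1/2
        dirs, cons = _conditions(400)
        s = rng.normal(size=dirs.size)
        x = s + rng.normal(size=dirs.size)
        y = s + rng.normal(size=dirs.size)
        cc = noise_correlation(x, y, dirs, cons)
        assert np.allclose(cc.to_numpy(), 0.5, atol=0.08)

    def test_zero_variance_condition_skipped(self, rng):
        dirs, cons = _conditions(10)
        x = rng.normal(size=dirs.size)
        y = rng.normal(size=dirs.size)
        x[(dirs == 0.0) & (cons == 100.0)] = 3.14  # constant in one condition
        cc = noise_correlation(x, y, dirs, cons)
        assert np.isfinite(cc[100.0])  # the other direction still contributes


class TestDistanceProfile:
    def test_exact_linear_recovered(self):
        d = np.linspace(10, 190, 100)
        coef = 0.8 - 2e-3 * d
        prof = distance_profile_fit(coef, d)
        assert prof.slope == pytest.approx(-2e-3, abs=1e-10)
        assert prof.intercept == pytest.approx(0.8, abs=1e-9)

    def test_binning_rule(self):
        # a pair at 45 um falls in the [30, 60) bin
        prof = distance_profile_fit(np.array([0.5, 0.3]), np.array([45.0, 75.0]))
        assert prof.bin_edges[0] == 30.0 and prof.bin_edges[1] == 60.0
        assert prof.bin_centers[0] == 45.0

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            distance_profile_fit(np.array([0.5, 0.4]), np.array([31.0, 32.0]))

    def test_generative_slope_within_ci(self, rng):
        # noisy linear profile: the fitted slope straddles the truth
        slope_true = -2e-4
        hits = 0
        for _ in range(50):
            d = rng.uniform(10, 200, size=200)
            coef = 0.6 + slope_true * d + rng.normal(0, 0.02, size=200)
            prof = distance_profile_fit(coef, d)
            if abs(prof.slope - slope_true) <= 1.96 * prof.slope_se:
                hits += 1
        assert hits >= 40  # ~95% coverage with binomial slack


class TestSlopeDifferenceTest:
    def test_identical_fits_null(self):
        d = np.linspace(10, 190, 60)
        coef = 0.5 - 1e-3 * d + np.sin(d) * 0.01
        f = distance_profile_fit(coef, d)
        t, df, p = slope_difference_test(f, f)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degrees_of_freedom_formula(self, rng):
        d1 = rng.uniform(0, 300, 500)
        d2 = rng.uniform(0, 300, 400)
        f1 = distance_profile_fit(rng.normal(0.5, 0.1, 500), d1)
        f2 = distance_profile_fit(rng.normal(0.5, 0.1, 400), d2)
        _, df, _ = slope_difference_test(f1, f2)
        assert df == f1.n_points + f2.n_points - 4

    def test_separated_slopes_detected(self, rng):
        detected = 0
        for _ in range(40):
            d = rng.uniform(10, 200, 100)
            f1 = distance_profile_fit(0.8 - 1e-3 * d + rng.normal(0, 0.01, 100), d)
            f2 = distance_profile_fit(0.8 - 3e-3 * d + rng.normal(0, 0.01, 100), d)
            _, _, p = slope_difference_test(f1, f2)
            detected += p < 0.001
        assert detected >= 38  # 5+ SE apart: essentially always significant


class TestSubtractCellComponent:
    def test_exact_linear_relation_removed(self, rng):
        x = rng.normal(size=100)
        y = 2.0 * x + 1.0
        assert np.allclose(subtract_cell_component(y, x), 0.0, atol=1e-10)

    def test_independent_regressor_no_change(self, rng):
        x = rng.normal(size=2000)
        y = rng.normal(size=2000)
        y_r = subtract_cell_component(y, x)
        assert np.corrcoef(y, y_r)[0, 1] > 0.99

    def test_shared_component_survives(self, rng):
        # y = 0.3 x + s: after removing the x-component, y residuals are s
        n = 5000
        x = rng.normal(size=n)
        s = rng.normal(size=n)
        y1 = 0.3 * x + s + rng.normal(0, 0.1, n)
        y_r = subtract_cell_component(y1, x)
        assert abs(np.corrcoef(y_r, x)[0, 1]) < 0.05
        assert np.corrcoef(y_r, s)[0, 1] > 0.99

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            subtract_cell_component(np.arange(5.0), np.ones(5))


class TestPairwise:
    def test_distance_and_exclusion(self, rng):
        rows = []
        for roi, kind in [("c0", "cell"), ("c1", "cell"), ("n0", "neuropil")]:
            for d in (0.0, 90.0):
                for t in range(10):
                    rows.append((roi, kind, d, 100.0, t, rng.normal()))
        table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        pos = {"c0": (0.0, 0.0), "c1": (50.0, 0.0), "n0": (10.0, 0.0)}
        cc = pairwise_noise_correlations(table, pos, ("cell", "cell"))
        assert set(cc["distance"]) == {50.0}
        # c0-n0 pair at 10 um < 30 um is excluded; c1-n0 at 40 um stays
        cn = pairwise_noise_correlations(table, pos, ("cell", "neuropil"))
        assert set(zip(cn["roi_a"], cn["roi_b"])) == {("c1", "n0")}


class TestAnnularCorrelation:
    def test_consecutive_annuli_disjoint(self):
        masks = [
            make_neuropil_annulus((100, 100), (200, 200), 1.0, r_in=a, r_out=b)
            for a, b in annulus_radii_sequence(n=5)
        ]
        for m1, m2 in zip(masks, masks[1:]):
            assert not np.any(m1 & m2)

    def test_shared_latent_detected_and_independent_flat(self, rng):
        n_trials, H, W = 240, 60, 60
        dirs = np.repeat([0.0, 90.0], 120)
        cons = np.full(240, 100.0)
        latent = rng.normal(size=n_trials)
        pix = rng.normal(0, 1.0, size=(n_trials, H, W))
        pix += latent[:, None, None]  # all pixels share the latent
        cell_coupled = latent + rng.normal(0, 1.0, size=n_trials)
        cell_indep = rng.normal(size=n_trials)
        radii = [(10.0, 12.0), (20.0, 22.0)]
        out_c = annular_cell_np_correlation(
            cell_coupled, pix, (30, 30), 1.0, dirs, cons, radii
        )
        out_i = annular_cell_np_correlation(
            cell_indep, pix, (30, 30), 1.0, dirs, cons, radii
        )
        # analytic rho ~ 1/sqrt(2) for the coupled cell vs the patch mean
        assert np.all(out_c["coefficient"] > 0.5)
        assert np.all(np.abs(out_i["coefficient"]) < 0.2)

    def test_empty_annulus_skipped(self, rng):
        out = annular_cell_np_correlation(
            rng.normal(size=20), rng.normal(size=(20, 10, 10)), (5, 5), 1.0,
            np.repeat([0.0, 90.0], 10), np.full(20, 100.0),
            radii=[(3.0, 5.0), (50.0, 52.0)],
        )
        assert set(out["r_in"]) == {3.0}
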