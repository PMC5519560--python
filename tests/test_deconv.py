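import numpy as np
import pytest

from npil.deconv import (
    DegenerateFilterError,
    SpikeDeconvolution,
    TraceMatrix,
    solve_filter_subproblem,
    solve_spike_subproblem,
    threshold_spikes,
    update_noise_scale,
    weighted_mean_dff,
)
from npil.dynamics import apply_P
from npil.optimize import nnls_l1_objective
from npil.synth import oracle_nonneg_l1_grid, simulate_calcium_trace, simulate_spike_train
from conftest import make_noisy_trace


class TestTraceMatrix:
    def test_1d_promoted_to_column(self):
        t = TraceMatrix(np.zeros(5) + 1.0, 8.0)
        assert t.values.shape == (5, 1)

    @pytest.mark.parametrize("bad", [np.array([[np.inf, 1.0]]), np.ones((1, 3))])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            TraceMatrix(bad, 8.0)


class TestSpikeSubproblem:
    def test_noise_free_inversion(self, rng, ogb_params):
        r = ogb_params.decay_factor
        n_true = np.zeros(40)
        n_true[[5, 12, 30]] = [1.0, 0.5, 2.0]
        a = np.array([0.6, 0.4])
        C = np.outer(apply_P(r, n_true), a)
        n_hat = solve_spike_subproblem(C, r, a, k1=1e-10, gap_tol=1e-13)
        assert np.allclose(n_hat, n_true, atol=1e-5)

    def test_zero_trace_gives_zero(self, ogb_params):
        r = ogb_params.decay_factor
        n = solve_spike_subproblem(np.zeros((20, 2)), r, np.array([0.5, 0.5]), k1=0.01)
        assert np.allclose(n, 0.0, atol=1e-5)

    def test_matches_grid_oracle_small(self, rng, ogb_params):
        # the multi-pixel Frobenius objective collapses to a single weighted
        # least-squares problem; check the collapsed objective against the
        # exhaustive grid on a tiny instance
        r = ogb_params.decay_factor
        T, npix = 4, 2
        C = rng.normal(size=(T, npix)) * 0.5
        a = np.array([0.7, 0.3])
        k1 = 0.05
        n_hat = solve_spike_subproblem(C, r, a, k1)
        P = np.linalg.inv(np.eye(T) - np.diag(np.full(T - 1, r), -1))
        A = np.linalg.norm(a) * P
        b = C @ a / np.linalg.norm(a)
        n_gr = oracle_nonneg_l1_grid(A, b, k1, step=1e-3)
        assert nnls_l1_objective(A, b, n_hat, k1) <= nnls_l1_objective(A, b, n_gr, k1) + 1e-4

    def test_degenerate_filter_raises(self, ogb_params):
        with pytest.raises(DegenerateFilterError):
            solve_spike_subproblem(np.ones((5, 1)), ogb_params.decay_factor, np.zeros(1), 0.1)


class TestFilterSubproblem:
    def test_noise_free_recovery(self, rng, ogb_params):
        r = ogb_params.decay_factor
        n = np.abs(rng.normal(size=30))
        a_true = np.array([0.2, 0.5, 0.3])
        C = np.outer(apply_P(r, n), a_true)
        a_hat = solve_filter_subproblem(C, r, n, k2=1e-12)
        assert np.allclose(a_hat, a_true, atol=1e-6)

    def test_per_pixel_closed_form(self, rng, ogb_params):
        r = ogb_params.decay_factor
        n = np.abs(rng.normal(size=20))
        C = rng.normal(size=(20, 3))
        k2 = 0.3
        c = apply_P(r, n)
        expected = np.clip((C.T @ c - k2 / 2) / (c @ c), 0.0, None)
        assert np.allclose(solve_filter_subproblem(C, r, n, k2), expected)

    def test_dominant_penalty_zeroes_filter(self, rng, ogb_params):
        r = ogb_params.decay_factor
        n = np.abs(rng.normal(size=20))
        C = rng.normal(size=(20, 2))
        c = apply_P(r, n)
        k2 = 2.0 * float(np.max(C.T @ c)) + 1.0
        assert np.all(solve_filter_subproblem(C, r, n, k2) == 0.0)

    def test_zero_spikes_warns(self, ogb_params):
        with pytest.warns(UserWarning):
            a = solve_filter_subproblem(np.ones((5, 2)), ogb_params.decay_factor, np.zeros(5), 0.1)
        assert np.all(a == 0.0)


class TestNoiseScale:
    def test_stationary_point(self, ogb_params):
        # lambda0 = 2 R / N: with R = 1 over N = 2 entries -> 1
        r = ogb_params.decay_factor
        C = np.array([[1.0], [0.0]])  # n = a = 0 -> R = 1
        assert update_noise_scale(C, r, np.zeros(2), np.zeros(1)) == pytest.approx(1.0)

    def test_linear_in_residual(self, rng, ogb_params):
        r = ogb_params.decay_factor
        C = rng.normal(size=(10, 2))
        lam = update_noise_scale(C, r, np.zeros(10), np.zeros(2))
        lam2 = update_noise_scale(np.sqrt(2.0) * C, r, np.zeros(10), np.zeros(2))
        assert lam2 == pytest.approx(2.0 * lam)

    def test_zero_residual_clamped(self, ogb_params):
        with pytest.warns(UserWarning):
            lam = update_noise_scale(np.zeros((5, 1)), ogb_params.decay_factor,
                                     np.zeros(5), np.zeros(1))
        assert lam == 1e-12


class TestThresholdSpikes:
    def test_constant_unchanged(self):
        assert np.array_equal(threshold_spikes(np.ones(4)), np.ones(4))

    def test_small_entries_suppressed(self):
        # population SD of [0.1, 0.1, 5, 0.1] is ~2.122; half-SD ~1.061
        out = threshold_spikes(np.array([0.1, 0.1, 5.0, 0.1]))
        assert np.array_equal(out, [0.0, 0.0, 5.0, 0.0])

    def test_sparse_train_stable(self):
        x = np.array([0.0, 0.0, 5.0, 0.0])
        assert np.array_equal(threshold_spikes(x), x)


class TestWeightedMeanDff:
    def test_uniform_filter_identical_pixels(self, rng):
        trace = rng.normal(size=20)
        C = np.column_stack([trace, trace, trace])
        assert np.allclose(weighted_mean_dff(C, np.full(3, 1 / 3)), trace)

    def test_selector_filter(self, rng):
        C = rng.normal(size=(10, 3))
        assert np.allclose(weighted_mean_dff(C, np.array([0.0, 1.0, 0.0])), C[:, 1])

    def test_weighted_average(self):
        assert weighted_mean_dff(np.array([[2.0, 6.0]]), np.array([1.0, 3.0]))[0] == 5.0

    def test_zero_filter_raises(self):
        with pytest.raises(DegenerateFilterError):
            weighted_mean_dff(np.ones((5, 2)), np.zeros(2))


class TestDeconvolve:
    def test_zero_trace_degenerate(self):
        res = SpikeDeconvolution(np.zeros(50), frame_rate=8.0).fit()
        assert res.status == "degenerate"
        assert np.all(res.rates == 0.0) and np.all(res.spatial_filter == 0.0)

    def test_monotone_learning_curve(self, rng, ogb_params):
        for _ in range(5):
            trace, _ = make_noisy_trace(rng, ogb_params, n_frames=240)
            res = SpikeDeconvolution(trace).fit()
            hist = np.asarray(res.state.objective_history)
            assert np.all(np.diff(hist) >= -1e-9)

    def test_recovers_spike_rate(self, rng, ogb_params):
        trace, n_true = make_noisy_trace(rng, ogb_params, n_frames=2400)
        res = SpikeDeconvolution(trace).fit()
        assert np.corrcoef(res.rates, n_true)[0, 1] > 0.8

    def test_noise_free_support_recovery(self, rng, ogb_params):
        # rate <= 1 spike per 2 frames, no noise: support must match exactly
        r = ogb_params.decay_factor
        n_true = np.zeros(120)
        idx = np.arange(4, 120, 6)
        n_true[idx] = 0.1
        C = apply_P(r, n_true)[:, None]
        res = SpikeDeconvolution(TraceMatrix(C, 8.0)).fit()
        est = res.thresholded_rates()
        assert set(np.nonzero(est)[0]) == set(idx)

    def test_spatial_filter_recovery_noise_free(self, rng, ogb_params):
        counts = simulate_spike_train(2.0, 8.0, 400, rng)
        a_true = np.array([0.5, 0.3, 0.15, 0.05])
        trace, _ = simulate_calcium_trace(
            counts, ogb_params, 0.0, rng, amplitude=0.1, true_filter=a_true
        )
        res = SpikeDeconvolution(trace).fit()
        cos = res.spatial_filter @ a_true / (
            np.linalg.norm(res.spatial_filter) * np.linalg.norm(a_true)
        )
        assert cos > 0.95

    def test_scale_consistency(self, rng, ogb_params):
        trace, _ = make_noisy_trace(rng, ogb_params, n_frames=400)
        base = SpikeDeconvolution(trace).fit()
        prod0 = np.outer(base.rates, base.spatial_filter)
        for s in (0.5, 2.0):
            scaled = TraceMatrix(trace.values * s, trace.frame_rate)
            res = SpikeDeconvolution(scaled).fit()
            prod = np.outer(res.rates, res.spatial_filter)
            ratio = prod.sum() / prod0.sum()
            assert ratio == pytest.approx(s, rel=0.05)

    def test_filter_normalized_to_unit_sum(self, rng, ogb_params):
        trace, _ = make_noisy_trace(rng, ogb_params, n_frames=300)
        res = SpikeDeconvolution(trace).fit()
        assert np.sum(res.spatial_filter) == pytest.approx(1.0)

    def test_summary_mentions_status(self, rng, ogb_params):
        trace, _ = make_noisy_trace(rng, ogb_params, n_frames=240)
        res = SpikeDeconvolution(trace).fit()
        assert "status" in res.summary() and str(res.state.n_iter) in res.summary()
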