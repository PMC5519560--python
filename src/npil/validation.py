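"""Property-based validation battery for the whole pipeline.

Each function recomputes one calibration or recovery quantity from scratch
on synthetic data at the study conditions and returns plain numbers; the
acceptance tests assert on them and ``scripts/acceptance.py`` reports them.
All randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .decoding import cv_linear_decoding_accuracy, dprime_spatial_shuffle_test
from .deconv import SpikeDeconvolution, solve_spike_subproblem
from .dynamics import CalciumDynamicsParams
from .noisecorr import (
    condition_residuals,
    distance_profile_fit,
    noise_correlation,
    pairwise_noise_correlations,
    slope_difference_test,
)
from .optimize import nnls_l1_objective
from .responses import StimulusProtocol, fano_ratio
from .synth import (
    SimConfig,
    oracle_nonneg_l1_grid,
    simulate_calcium_trace,
    simulate_spike_train,
    simulate_trial_responses,
)

OGB_PARAMS = CalciumDynamicsParams.from_frame_rate(8.0, 1.0)


def solver_oracle_gap(seed: int, n_instances: int = 50) -> float:
    """Worst objective gap between the subproblem solvers and the exhaustive
    grid oracle on tiny instances.

    Cycles through three families: generic non-negative-L1 designs (up to 8
    rows, <= 4 unknowns), spike subproblems (T <= 4, Npix <= 3, so the
    unknown dimension stays within the oracle's 4-D limit), and filter
    subproblems (Npix <= 3).
    """
    from .deconv import solve_filter_subproblem
    from .dynamics import apply_P
    from .optimize import nonneg_l1_least_squares

    rng = np.random.default_rng(seed)
    r = OGB_PARAMS.decay_factor
    worst = 0.0
    for i in range(n_instances):
        family = i % 3
        if family == 0:
            A = rng.normal(size=(int(rng.integers(3, 9)), int(rng.integers(1, 5))))
            b = rng.normal(size=A.shape[0])
            k = float(rng.uniform(0.0, 0.5))
            x_hat = nonneg_l1_least_squares(A, b, k)
        elif family == 1:
            T = int(rng.integers(3, 5))
            npix = int(rng.integers(1, 4))
            C = rng.normal(0.0, 0.5, size=(T, npix))
            a = rng.uniform(0.1, 1.0, size=npix)
            k = float(rng.uniform(0.0, 0.5))
            x_hat = solve_spike_subproblem(C, r, a, k)
            P = np.linalg.inv(np.eye(T) - np.diag(np.full(T - 1, r), -1))
            A = np.linalg.norm(a) * P
            b = C @ a / np.linalg.norm(a)
        else:
            T = int(rng.integers(4, 9))
            npix = int(rng.integers(1, 4))
            n = np.abs(rng.normal(size=T))
            C = rng.normal(0.0, 0.5, size=(T, npix))
            k = float(rng.uniform(0.0, 0.5))
            x_hat = solve_filter_subproblem(C, r, n, k)
            # per-pixel objective stacks into one block-diagonal problem;
            # compare pixel by pixel against the 1-D oracle
            c = apply_P(r, n)
            gap_f = 0.0
            for j in range(npix):
                A1 = c[:, None]
                x_gr = oracle_nonneg_l1_grid(A1, C[:, j], k, step=1e-4)
                gap_f += nnls_l1_objective(A1, C[:, j], x_hat[j : j + 1], k) - \
                    nnls_l1_objective(A1, C[:, j], x_gr, k)
            worst = max(worst, abs(gap_f))
            continue
        x_gr = oracle_nonneg_l1_grid(A, b, k, step=1e-3)
        gap = nnls_l1_objective(A, b, x_hat, k) - nnls_l1_objective(A, b, x_gr, k)
        worst = max(worst, abs(gap))
    return worst


def monotonicity_check(seed: int, n_traces: int = 100, n_frames: int = 240) -> dict:
    """Largest log-posterior decrease over the learning curves of random
    synthetic traces (the alternation must be non-decreasing)."""
    rng = np.random.default_rng(seed)
    worst_drop = 0.0
    violations = 0
    for _ in range(n_traces):
        counts = simulate_spike_train(rng.uniform(0.8, 5.0), 8.0, n_frames, rng)
        trace, _ = simulate_calcium_trace(
            counts, OGB_PARAMS, rng.uniform(0.01, 0.05), rng, amplitude=0.1
        )
        res = SpikeDeconvolution(trace).fit()
        diffs = np.diff(res.state.objective_history)
        if diffs.size and diffs.min() < -1e-9:
            violations += 1
            worst_drop = max(worst_drop, -float(diffs.min()))
    return {"violations": violations, "worst_drop": worst_drop}


def spike_recovery(seed: int, n_traces: int = 20, duration_s: float = 300.0) -> dict:
    """Median correlation between estimated and true per-frame spike rates on
    OGB-like traces (8 Hz, tau 1 s, rates 0.8-5 Hz, noise = 0.25 x spike
    amplitude), plus the worst spatial-filter cosine on noise-free
    multi-pixel traces."""
    rng = np.random.default_rng(seed)
    T = int(duration_s * 8.0)
    corrs = []
    for _ in range(n_traces):
        counts = simulate_spike_train(rng.uniform(0.8, 5.0), 8.0, T, rng)
        trace, n_true = simulate_calcium_trace(
            counts, OGB_PARAMS, 0.25 * 0.1, rng, amplitude=0.1
        )
        res = SpikeDeconvolution(trace).fit()
        corrs.append(float(np.corrcoef(res.rates, n_true)[0, 1]))
    cosines = []
    for _ in range(5):
        counts = simulate_spike_train(2.0, 8.0, 400, rng)
        a_true = rng.dirichlet(np.ones(4))
        trace, _ = simulate_calcium_trace(
            counts, OGB_PARAMS, 0.0, rng, amplitude=0.1, true_filter=a_true
        )
        res = SpikeDeconvolution(trace).fit()
        cosines.append(
            float(res.spatial_filter @ a_true
                  / (np.linalg.norm(res.spatial_filter) * np.linalg.norm(a_true)))
        )
    return {"median_corr": float(np.median(corrs)), "min_filter_cosine": min(cosines)}


def contamination_roundtrip(seed: int) -> dict:
    """Mix cell and neuropil signals at known S, re-estimate S from a
    simulated vessel lumen, correct, and correlate with the truth."""
    from .preprocess import correct_contamination, estimate_contamination_scale
    from .synth import simulate_fov_dataset
    from .dynamics import apply_P

    worst_corr, worst_S_err = 1.0, 0.0
    for i, S in enumerate((0.4, 0.5, 0.6)):
        cfg = SimConfig(seed=seed + i, n_cells=6, contamination_scale=S, noise_sd=0.0,
                        protocol=StimulusProtocol(repeats=8))
        ds = simulate_fov_dataset(cfg)
        S_hat = estimate_contamination_scale(ds.lumen_trace, ds.np_raw[0])
        worst_S_err = max(worst_S_err, abs(S_hat - S))
        truth = apply_P(cfg.dynamics.decay_factor,
                        cfg.spike_amplitude * ds.truth.spikes, axis=1)
        for j in range(cfg.n_cells):
            rec = correct_contamination(ds.cell_traces[j].values[:, 0], ds.np_traces[j], S_hat)
            worst_corr = min(worst_corr, float(np.corrcoef(rec, truth[j])[0, 1]))
    return {"min_corr": worst_corr, "max_S_error": worst_S_err}


def correlation_calibration(seed: int, n_sims: int = 200, repeats: int = 80) -> dict:
    """Bias of the noise-correlation estimator for known bivariate-Gaussian
    rho at the full trial count (6 conditions x 80 repeats), plus the mean
    coefficient after trial shuffling (must be centred at zero)."""
    rng = np.random.default_rng(seed)
    dirs = np.repeat([0.0, 90.0], 3 * repeats)
    cons = np.tile(np.repeat([100.0, 40.0, 15.0], repeats), 2)
    n = dirs.size
    out = {}
    shuffled_means = []
    for rho in (0.0, 0.25, 0.5, 0.8):
        ests = np.empty(n_sims)
        for s in range(n_sims):
            z = rng.normal(size=(n, 2))
            x = z[:, 0]
            y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
            ests[s] = noise_correlation(x, y, dirs, cons).mean()
            if rho == 0.8:  # reuse draws for the shuffle control
                y_sh = y.copy()
                for d in (0.0, 90.0):
                    for c in (100.0, 40.0, 15.0):
                        m = (dirs == d) & (cons == c)
                        y_sh[m] = rng.permutation(y_sh[m])
                shuffled_means.append(noise_correlation(x, y_sh, dirs, cons).mean())
        out[rho] = float(ests.mean())
    bias = max(abs(v - rho) for rho, v in out.items())
    return {
        "max_bias": float(bias),
        "estimates": out,
        "shuffled_mean": float(np.mean(shuffled_means)),
    }


def profile_recovery(seed: int, n_fovs: int = 50) -> dict:
    """Recover the generative correlation-distance slope across synthetic
    FOVs and calibrate the two-slope test's type-I error at equal slopes."""
    measured, expected = [], []
    for i in range(n_fovs):
        cfg = SimConfig(seed=seed + i, n_cells=20)
        table, pos, truth = simulate_trial_responses(cfg)
        table = condition_residuals(table)
        pw = pairwise_noise_correlations(table, pos, ("neuropil", "neuropil"))
        measured.append(distance_profile_fit(pw["coefficient"], pw["distance"]).slope)
        P = truth.cell_positions_um
        E = truth.expected_profiles["neuropil-neuropil"]
        iu = np.triu_indices(len(P), k=1)
        d = np.hypot(P[iu[0], 0] - P[iu[1], 0], P[iu[0], 1] - P[iu[1], 1])
        expected.append(distance_profile_fit(E[iu], d).slope)
    diff = np.asarray(measured) - np.asarray(expected)
    sem = diff.std(ddof=1) / np.sqrt(n_fovs)
    t_abs = abs(diff.mean()) / sem

    rng = np.random.default_rng(seed + 10_000)
    rejections = 0
    n_sims = 2000
    for _ in range(n_sims):
        d1 = rng.uniform(0, 240, 200)
        d2 = rng.uniform(0, 240, 200)
        y1 = 0.7 - 4e-4 * d1 + rng.normal(0, 0.05, 200)
        y2 = 0.7 - 4e-4 * d2 + rng.normal(0, 0.05, 200)
        f1 = distance_profile_fit(y1, d1)
        f2 = distance_profile_fit(y2, d2)
        _, _, p = slope_difference_test(f1, f2)
        rejections += p < 0.05
    return {
        "mean_measured_slope": float(np.mean(measured)),
        "mean_expected_slope": float(np.mean(expected)),
        "slope_t_abs": float(t_abs),
        "type1_rate": rejections / n_sims,
    }


def decoder_calibration(seed: int) -> dict:
    """Chance-level, analytic d'=1, and separable-data calibration of the
    cross-validated linear decoder."""
    rng = np.random.default_rng(seed)
    shuffled = [
        cv_linear_decoding_accuracy(
            rng.normal(size=(160, 5)), rng.permutation(np.tile([0, 1], 80)),
            seed=int(rng.integers(2**31 - 1)),
        )
        for _ in range(200)
    ]
    n = 10_000
    x = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(1, 1, n // 2)])[:, None]
    y = np.repeat([0, 1], n // 2)
    acc_d1 = cv_linear_decoding_accuracy(x, y, seed=seed)
    xs = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(2, 3, 100)])[:, None]
    acc_sep = cv_linear_decoding_accuracy(xs, np.repeat([0, 1], 100), seed=seed)
    return {
        "shuffled_mean": float(np.mean(shuffled)),
        "dprime1_accuracy": float(acc_d1),
        "separable_accuracy": float(acc_sep),
    }


def shuffle_null_calibration(seed: int, n_runs: int = 1000, n_rois: int = 25,
                             n_shuffles: int = 10_000) -> dict:
    """Rejection rate of the d' spatial-shuffle test at alpha = 0.05 for
    independent maps (must sit in the binomial band around 5%)."""
    rng = np.random.default_rng(seed)
    rej = 0
    for i in range(n_runs):
        _, _, p = dprime_spatial_shuffle_test(
            rng.normal(size=n_rois), rng.normal(size=n_rois),
            n_shuffles=n_shuffles, seed=int(rng.integers(2**31 - 1)),
        )
        rej += p < 0.05
    return {"rejection_rate": rej / n_runs, "n_runs": n_runs}


def qualitative_fov(seed: int) -> dict:
    """Qualitative reproductions on the bundled synthetic FOV: Fano ratio,
    the correlation-strength ordering, and patch-population decoding vs the
    FOV-mean patch feature."""
    cfg = SimConfig(seed=seed)
    table, pos, _ = simulate_trial_responses(cfg)
    tab = condition_residuals(table)
    coefs = {}
    for kinds in (("neuropil", "neuropil"), ("cell", "neuropil"), ("cell", "cell")):
        pw = pairwise_noise_correlations(tab, pos, kinds)
        coefs["-".join(kinds)] = float(pw["coefficient"].mean())
    sub = table[(table["kind"] == "neuropil") & (table["contrast"] == 100.0)]
    piv = sub.pivot_table(index=["direction", "trial"], columns="roi", values="response")
    y = (piv.index.get_level_values("direction") == 90.0).astype(int)
    acc_pop = cv_linear_decoding_accuracy(piv.to_numpy(), y, seed=seed)
    acc_mean = cv_linear_decoding_accuracy(
        piv.to_numpy().mean(axis=1, keepdims=True), y, seed=seed
    )
    subc = table[(table["kind"] == "cell") & (table["contrast"] == 100.0)]
    pivc = subc.pivot_table(index=["direction", "trial"], columns="roi", values="response")
    acc_cells = cv_linear_decoding_accuracy(pivc.to_numpy(), y, seed=seed)
    return {
        "fano_ratio": float(fano_ratio(table, 100.0)),
        **coefs,
        "np_population_accuracy": float(acc_pop),
        "cell_population_accuracy": float(acc_cells),
        "fov_mean_accuracy": float(acc_mean),
    }
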