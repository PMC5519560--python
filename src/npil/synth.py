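"""Ground-truth simulator for two-photon calcium-imaging experiments.

Emulates the study conditions end to end so every pipeline stage can be
tested without recordings: Poisson spike trains with direction-tuned gains
(mean rates 0.8-5 Hz), OGB/GCaMP-like calcium traces (geometric decay,
tau ~ 1 s, additive photon noise), spatially coherent neuropil fields whose
pairwise correlation decays linearly with distance, neuropil-to-soma
contamination mixing at scale S, and the 6-condition (2 directions x 3
contrasts) x 80-repeat trial structure at 7-10 Hz frame rates.

Two generation paths exist: ``simulate_fov_dataset`` produces frame-level
traces (optionally rendered to a pixel movie) for preprocessing and
deconvolution tests, while ``simulate_trial_responses`` produces trial
response tables directly — the fast path for correlation, Fano and decoding
statistics.  The neuropil field is built from a multivariate normal whose
correlation matrix is ``1 - slope * distance`` (projected to the nearest
PSD matrix); its generative form is an assumption of the simulator, chosen
to produce the approximately linear correlation-distance profiles seen in
cortical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dynamics import CalciumDynamicsParams, apply_P
from .deconv import TraceMatrix
from .responses import StimulusProtocol, TABLE_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FovDataset",
    "simulate_spike_train",
    "simulate_spikes",
    "simulate_calcium_trace",
    "simulate_trial_responses",
    "simulate_fov_dataset",
    "oracle_nonneg_l1_grid",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the acquisition described for the OGB experiments:
    7-10 Hz frame rates (8 Hz default), 1.2-1.9 um pixels (1.5 default),
    tau ~ 1 s decay, mean firing rates 0.8-5 Hz, 2 x 3 stimulus conditions
    presented 80 times (600 ms stimulus, 1500 ms ISI), and contamination
    scale S = 0.6.  Noise SD is expressed in dF/F units; the default equals
    0.25 x the single-spike amplitude.
    """

    seed: int
    frame_rate: float = 8.0
    duration_s: float = 300.0
    n_cells: int = 25
    fov_size_um: float = 200.0
    pixel_size_um: float = 1.5
    tau: float = 1.0
    spike_amplitude: float = 0.1
    noise_sd: float = 0.025
    rate_range: tuple = (0.8, 5.0)
    tuning_depth: float = 0.3
    contrast_gains: tuple = ((100.0, 1.0), (40.0, 0.7), (15.0, 0.4))
    # trial-response model (percent dF/F units)
    cell_mean_pct: float = 2.5
    cell_noise_pct: float = 4.0
    cell_field_weight_pct: float = 1.0
    np_mean_pct: float = 6.0
    np_noise_pct: float = 0.45
    np_field_weight_pct: float = 0.9
    np_tuning_sd: float = 0.05
    balanced_np_tuning: bool = True
    field_corr_slope: float = 4e-4  # per um, linear decay of field correlation
    contamination_scale: float = 0.6
    min_separation_um: float = 15.0
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("frame_rate", "duration_s", "pixel_size_um", "tau",
                     "spike_amplitude", "fov_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dynamics(self) -> CalciumDynamicsParams:
        return CalciumDynamicsParams.from_frame_rate(self.frame_rate, self.tau)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Per-component child generator fanned out from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class GroundTruth:
    """Generative quantities stored alongside a synthetic dataset."""

    spikes: np.ndarray | None = None
    spatial_filters: np.ndarray | None = None
    cell_positions_um: np.ndarray | None = None
    cell_tuning: np.ndarray | None = None
    np_tuning: np.ndarray | None = None
    field_correlation: np.ndarray | None = None
    expected_profiles: dict = field(default_factory=dict)
    contamination_scale: float | None = None

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: conv(u) for k, u in v.items()}
            return v

        return json.dumps({k: conv(v) for k, v in asdict(self).items()})


def simulate_spike_train(
    rate_hz: float,
    frame_rate: float,
    n_frames: int,
    rng: np.random.Generator,
    gain: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Per-frame Poisson spike counts at ``rate_hz`` modulated by ``gain``."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    lam = rate_hz / frame_rate * np.broadcast_to(np.asarray(gain, dtype=float), (n_frames,))
    return rng.poisson(np.clip(lam, 0.0, None))


def simulate_spikes(config: SimConfig, stim_gain: np.ndarray | None = None) -> np.ndarray:
    """(n_cells, T) spike-count trains; per-cell rates drawn from the
    configured range, optionally gain-modulated during stimulus frames."""
    rng = config.rng(0)
    T = int(round(config.duration_s * config.frame_rate))
    rates = rng.uniform(*config.rate_range, size=config.n_cells)
    gain = np.ones(T) if stim_gain is None else stim_gain
    return np.vstack(
        [simulate_spike_train(r, config.frame_rate, T, rng, gain) for r in rates]
    )


def simulate_calcium_trace(
    spikes: np.ndarray,
    params: CalciumDynamicsParams,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    amplitude: float = 0.1,
    true_filter: np.ndarray | None = None,
    frame_rate: float | None = None,
) -> tuple[TraceMatrix, np.ndarray]:
    """Render spike counts to a (possibly multi-pixel) noisy dF/F trace.

    ``C = P n a^T + noise`` with ``n = amplitude * counts``; a single spike
    decays by the factor ``r`` per frame.  Returns the trace and the true
    per-frame spike signal ``n``.
    """
    counts = np.asarray(spikes, dtype=float)
    n = amplitude * counts
    c = apply_P(params.decay_factor, n)
    a = np.ones(1) if true_filter is None else np.asarray(true_filter, dtype=float)
    C = np.outer(c, a) + rng.normal(0.0, noise_sd, size=(c.size, a.size))
    fr = frame_rate if frame_rate is not None else 1.0 / params.frame_duration
    return TraceMatrix(C, fr), n


def _place_cells(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform cell positions (um) with a minimum pairwise separation."""
    lo = config.min_separation_um / 2.0
    hi = config.fov_size_um - lo
    if hi <= lo:
        raise ValueError("FOV too small for the requested cell placement")
    pos: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= config.min_separation_um for p in pos):
            pos.append(cand)
            if len(pos) == config.n_cells:
                return np.vstack(pos)
    raise ValueError(f"FOV too small to place {config.n_cells} cells")


def _field_correlation(config: SimConfig, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PSD-projected linear-decay correlation matrix of the shared field.

    Returns (Cholesky-like mixing matrix L, realized correlation matrix).
    """
    d = np.hypot(
        positions[:, 0][:, None] - positions[:, 0][None, :],
        positions[:, 1][:, None] - positions[:, 1][None, :],
    )
    K = 1.0 - config.field_corr_slope * d
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    K_real = L @ L.T
    s = np.sqrt(np.diag(K_real))
    K_real = K_real / np.outer(s, s)
    L = L / s[:, None]
    return L, K_real


def _condition_grid(protocol: StimulusProtocol):
    return [(d, c) for c in protocol.contrasts for d in protocol.directions]


def expected_pair_correlation(
    config: SimConfig, K: np.ndarray, kind: tuple[str, str]
) -> np.ndarray:
    """Model pairwise noise correlation implied by the generative mixture."""
    w = {"cell": config.cell_field_weight_pct, "neuropil": config.np_field_weight_pct}
    s = {"cell": config.cell_noise_pct, "neuropil": config.np_noise_pct}
    wa, wb = w[kind[0]], w[kind[1]]
    va = w[kind[0]] ** 2 + s[kind[0]] ** 2
    vb = w[kind[1]] ** 2 + s[kind[1]] ** 2
    return wa * wb * K / np.sqrt(va * vb)


def simulate_trial_responses(config: SimConfig):
    """Fast-path generator: tidy trial-response table for cells and their
    neuropil patches, with a shared spatially coherent field.

    Per trial, every ROI receives ``mean(direction, contrast) + w * f + e``
    where ``f`` is the shared field (correlation ``1 - slope * d``), ``e``
    is private noise, and the means carry salt-and-pepper direction tuning
    for cells and a small (optionally exactly balanced) tuning bias for
    neuropil patches.  Responses are in percent dF/F.  Returns
    ``(table, positions, GroundTruth)``.
    """
    rng = config.rng(1)
    positions = _place_cells(config, rng)
    L, K = _field_correlation(config, positions)
    nc = config.n_cells
    cell_pref = rng.choice([-1.0, 1.0], size=nc)  # salt & pepper
    np_bias = rng.normal(0.0, config.np_tuning_sd, size=nc)
    if config.balanced_np_tuning:
        np_bias = np_bias - np_bias.mean()
    gains = dict(config.contrast_gains)
    rows = []
    for direction, contrast in _condition_grid(config.protocol):
        dsign = 1.0 if direction == config.protocol.directions[0] else -1.0
        g = gains[contrast]
        mu_cell = config.cell_mean_pct * g * (1.0 + config.tuning_depth * cell_pref * dsign)
        mu_np = config.np_mean_pct * g * (1.0 + np_bias * dsign)
        for t in range(config.protocol.repeats):
            f = L @ rng.normal(size=nc)
            cell_resp = mu_cell + config.cell_field_weight_pct * f + rng.normal(
                0.0, config.cell_noise_pct, size=nc
            )
            np_resp = mu_np + config.np_field_weight_pct * f + rng.normal(
                0.0, config.np_noise_pct, size=nc
            )
            for i in range(nc):
                rows.append((f"c{i}", "cell", direction, contrast, t, cell_resp[i]))
                rows.append((f"n{i}", "neuropil", direction, contrast, t, np_resp[i]))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    pos = {f"c{i}": tuple(positions[i]) for i in range(nc)}
    pos.update({f"n{i}": tuple(positions[i]) for i in range(nc)})
    truth = GroundTruth(
        cell_positions_um=positions,
        cell_tuning=cell_pref * config.tuning_depth,
        np_tuning=np_bias,
        field_correlation=K,
        expected_profiles={
            kinds: expected_pair_correlation(config, K, tuple(kinds.split("-")))
            for kinds in ("neuropil-neuropil", "cell-cell", "cell-neuropil")
        },
    )
    return table, pos, truth


@dataclass
class FovDataset:
    """Frame-level synthetic dataset for one field of view."""

    config: SimConfig
    cell_traces: list          # observed (contaminated) TraceMatrix per cell
    np_traces: np.ndarray      # (n_cells, T) neuropil-patch dF/F traces
    np_raw: np.ndarray         # (n_cells, T) raw-fluorescence neuropil traces
    lumen_trace: np.ndarray    # raw vessel-lumen trace (pure contamination)
    trial_table: pd.DataFrame  # trial, start_frame, end_frame, direction, contrast
    motion: np.ndarray         # (T, 2) displacement, um
    truth: GroundTruth
    movie: np.ndarray | None = None


def simulate_fov_dataset(config: SimConfig, *, render_movie: bool = False) -> FovDataset:
    """Frame-level dataset: contaminated cell traces, neuropil patch traces,
    a vessel-lumen trace for estimating S, and the full trial structure.

    Observed cell fluorescence mixes the true somatic signal with the local
    neuropil field at scale S; the lumen trace is the pure scaled field, as
    in a vessel that carries no indicator.
    """
    rng = config.rng(2)
    params = config.dynamics
    protocol = config.protocol
    trial_len = protocol.trial_frames(config.frame_rate)
    conditions = _condition_grid(protocol) * protocol.repeats
    rng.shuffle(conditions)
    n_trials = len(conditions)
    T = n_trials * trial_len
    stim_frames = protocol.stim_frames(config.frame_rate)
    positions = _place_cells(config, rng)
    L, K = _field_correlation(config, positions)
    nc = config.n_cells
    cell_pref = rng.choice([-1.0, 1.0], size=nc)
    gains = dict(config.contrast_gains)

    # per-frame stimulus drive and trial table; stimulus onset sits 3 frames
    # into each trial window so every trial carries its own baseline
    drive = np.zeros(T)
    rows = []
    dir_sign = np.zeros(T)
    for k, (direction, contrast) in enumerate(conditions):
        s0 = k * trial_len
        on = s0 + 3
        rows.append(
            {"trial": k, "start_frame": s0, "end_frame": s0 + trial_len - 1,
             "direction": direction, "contrast": contrast}
        )
        drive[on : on + stim_frames] = gains[contrast]
        dir_sign[on : on + stim_frames] = 1.0 if direction == protocol.directions[0] else -1.0
    trial_table = pd.DataFrame(rows)

    # spikes and true somatic calcium
    rates = rng.uniform(*config.rate_range, size=nc)
    spikes = np.empty((nc, T))
    for i in range(nc):
        gain = 1.0 + drive * (1.0 + config.tuning_depth * cell_pref[i] * dir_sign)
        spikes[i] = simulate_spike_train(rates[i], config.frame_rate, T, rng, gain)
    n_true = config.spike_amplitude * spikes
    calcium = apply_P(params.decay_factor, n_true, axis=1)

    # neuropil field: shared slow visual drive (with a small, balanced,
    # per-patch direction bias) plus spatially correlated fluctuations
    np_bias = rng.normal(0.0, config.np_tuning_sd, size=nc)
    np_bias -= np_bias.mean()
    fluct = (L @ rng.normal(size=(nc, T))) * 0.01
    np_traces = np.empty((nc, T))
    for i in range(nc):
        evoked_i = apply_P(params.decay_factor, 0.02 * drive * (1.0 + np_bias[i] * dir_sign))
        np_traces[i] = evoked_i + fluct[i] + rng.normal(0.0, 0.002, size=T)
    # raw-fluorescence versions: the vessel lumen holds no indicator, so its
    # measured signal is pure neuropil spillover at scale S
    np_baseline = 80.0
    np_raw = np_baseline * (1.0 + np_traces)
    lumen_trace = config.contamination_scale * np_raw[0] + rng.normal(0.0, 0.1, size=T)

    # observed cell traces: true calcium + S * local neuropil + photon noise
    cell_traces = []
    for i in range(nc):
        obs = (
            calcium[i]
            + config.contamination_scale * np_traces[i]
            + rng.normal(0.0, config.noise_sd, size=T)
        )
        cell_traces.append(TraceMatrix(obs, config.frame_rate))

    truth = GroundTruth(
        spikes=spikes,
        cell_positions_um=positions,
        cell_tuning=cell_pref * config.tuning_depth,
        np_tuning=np_bias,
        field_correlation=K,
        contamination_scale=config.contamination_scale,
    )
    movie = None
    if render_movie:
        movie = _render_movie(config, positions, calcium, np_traces, rng)
    return FovDataset(
        config=config, cell_traces=cell_traces, np_traces=np_traces,
        np_raw=np_raw, lumen_trace=lumen_trace, trial_table=trial_table,
        motion=np.zeros((T, 2)), truth=truth, movie=movie,
    )


def _render_movie(config, positions, calcium, np_traces, rng):
    """Rasterize traces to a small T x H x W pixel stack (Gaussian somata on
    a neuropil background)."""
    px = config.pixel_size_um
    H = W = int(np.ceil(config.fov_size_um / px))
    T = calcium.shape[1]
    yy, xx = np.mgrid[0:H, 0:W]
    movie = np.zeros((T, H, W), dtype=np.float32)
    sigma_px = 3.0 / px  # ~3 um soma radius
    for i, (y, x) in enumerate(positions / px):
        blob = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2))
        near = blob > 0.05
        movie[:, near] += np.outer(calcium[i], blob[near]).astype(np.float32)
        ring = (~near) & (np.hypot(yy - y, xx - x) * px < 15.0)
        movie[:, ring] += np_traces[i][:, None].astype(np.float32)
    movie += rng.normal(0.0, config.noise_sd, size=movie.shape).astype(np.float32)
    return movie


def oracle_nonneg_l1_grid(
    A: np.ndarray,
    b: np.ndarray,
    k: float,
    step: float = 1e-3,
    *,
    grid_points: int = 15,
) -> np.ndarray:
    """Brute-force oracle: exhaustive multiresolution grid minimization of
    ``||A x - b||^2 + k ||x||_1`` over the non-negative box.

    The full grid over ``[0, 2 max|x_ls|]`` is searched at ``grid_points``
    per axis, then the box shrinks around the incumbent (two cells on each
    side) and the search repeats until the cell width reaches ``step``.
    The objective is convex so the refinement converges to the global
    minimum; the search never consults the interior-point path.  Refuses
    more than 4 dimensions.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    d = A.shape[1]
    if d > 4:
        raise ValueError("grid oracle limited to 4 dimensions")
    xls, *_ = np.linalg.lstsq(A, b, rcond=None)
    hi = np.full(d, max(2.0 * float(np.max(np.abs(xls))), 10.0 * step))
    lo = np.zeros(d)

    def objective(X):
        R = X @ A.T - b
        return np.einsum("ij,ij->i", R, R) + k * X.sum(axis=1)

    best = None
    while True:
        axes = [np.linspace(lo[i], hi[i], grid_points) for i in range(d)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
        vals = objective(mesh)
        best = mesh[int(np.argmin(vals))]
        width = (hi - lo) / (grid_points - 1)
        if np.all(width <= step):
            return best
        lo = np.clip(best - 2.0 * width, 0.0, None)
        hi = np.maximum(best + 2.0 * width, lo + grid_points * step / 2)
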