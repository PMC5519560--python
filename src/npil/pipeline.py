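"""End-to-end pipeline tying the stages together on one dataset.

Stages run in a fixed dependency order — preprocess -> deconvolve ->
responses -> noisecorr -> decoding — and emit a JSON-serializable summary
carrying every seed and parameter, plus an audit trail of dropped trials
and ROIs (exclusions should never be silent).
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import decoding as dec
from . import noisecorr as nc
from . import preprocess as pp
from .deconv import SpikeDeconvolution
from .io import RunConfig
from .responses import TABLE_COLUMNS, evoked_response, find_peak_frame, select_responsive, fano_ratio
from .synth import SimConfig, simulate_fov_dataset
from .responses import StimulusProtocol

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "deconvolve", "responses", "noisecorr", "decoding")


class StageOrderError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, stages=STAGES, dataset=None) -> dict:
    """Execute the requested stages and return the summary bundle.

    ``dataset`` defaults to a synthetic FOV generated from the config seed.
    Requesting a stage without its prerequisites raises ``StageOrderError``.
    """
    stages = tuple(stages)
    for s in stages:
        if s not in STAGES:
            raise StageOrderError(f"unknown stage {s!r}")
        need = STAGES[: STAGES.index(s)]
        missing = [p for p in need if p not in stages]
        if missing:
            raise StageOrderError(f"stage {s!r} requires {missing}")

    summary: dict = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": list(stages),
        "timings_s": {},
        "audit": {"dropped_trials": [], "dropped_rois": []},
    }
    if dataset is None:
        dataset = simulate_fov_dataset(
            SimConfig(
                seed=config.seed,
                n_cells=config.n_cells,
                protocol=StimulusProtocol(repeats=config.repeats),
                contamination_scale=config.contamination_scale,
            )
        )
    cfg = dataset.config
    fr = cfg.frame_rate
    ctx: dict = {}

    if "preprocess" in stages:
        t0 = time.perf_counter()
        kept = pp.motion_exclude_trials(
            dataset.motion, dataset.trial_table, cfg.pixel_size_um,
            absolute_factor=config.motion_absolute_factor,
            step_factor=config.motion_step_factor,
        )
        dropped = sorted(set(dataset.trial_table["trial"]) - set(kept))
        summary["audit"]["dropped_trials"] = dropped
        S_hat = pp.estimate_contamination_scale(dataset.lumen_trace, dataset.np_raw[0])
        corrected = [
            pp.correct_contamination(tr.values[:, 0], npt, config.contamination_scale)
            for tr, npt in zip(dataset.cell_traces, dataset.np_traces)
        ]
        ctx["kept_trials"] = kept
        ctx["corrected"] = [pp.dct_highpass(c, fr) for c in corrected]
        ctx["np_filtered"] = [pp.dct_highpass(t, fr) for t in dataset.np_traces]
        summary["preprocess"] = {
            "n_trials_kept": int(len(kept)),
            "estimated_S": float(S_hat),
        }
        summary["timings_s"]["preprocess"] = time.perf_counter() - t0

    if "deconvolve" in stages:
        t0 = time.perf_counter()
        fits = [
            SpikeDeconvolution(c, frame_rate=fr, tau=config.tau).fit()
            for c in ctx["corrected"]
        ]
        ctx["spikes"] = [f.thresholded_rates(config.spike_threshold_sd) for f in fits]
        summary["deconvolve"] = {
            "n_cells": len(fits),
            "all_monotone": bool(
                all(np.all(np.diff(f.state.objective_history) >= -1e-9) for f in fits)
            ),
        }
        summary["timings_s"]["deconvolve"] = time.perf_counter() - t0

    if "responses" in stages:
        t0 = time.perf_counter()
        table = _build_response_table(dataset, ctx, config, fr)
        ctx["table"] = table
        responsive = select_responsive(
            table[table["kind"] == "cell"], config.indicator
        )
        summary["responses"] = {
            "n_responsive_cells": int(len(responsive)),
            "fano_ratio_100": _safe(lambda: fano_ratio(table, 100.0)),
        }
        summary["timings_s"]["responses"] = time.perf_counter() - t0

    if "noisecorr" in stages:
        t0 = time.perf_counter()
        table = nc.condition_residuals(ctx["table"])
        pos = {
            f"c{i}": tuple(p) for i, p in enumerate(dataset.truth.cell_positions_um)
        }
        pos.update(
            {f"n{i}": tuple(p) for i, p in enumerate(dataset.truth.cell_positions_um)}
        )
        out = {}
        for kinds in (("neuropil", "neuropil"), ("cell", "cell"), ("cell", "neuropil")):
            pw = nc.pairwise_noise_correlations(table, pos, kinds)
            out["-".join(kinds)] = float(pw["coefficient"].mean()) if len(pw) else None
        summary["noisecorr"] = out
        summary["timings_s"]["noisecorr"] = time.perf_counter() - t0

    if "decoding" in stages:
        t0 = time.perf_counter()
        table = ctx["table"]
        accs = {}
        for kind in ("cell", "neuropil"):
            sub = table[(table["kind"] == kind) & (table["contrast"] == 100.0)]
            piv = sub.pivot_table(
                index=["direction", "trial"], columns="roi", values="response"
            ).dropna()
            y = (piv.index.get_level_values("direction") == 90.0).astype(int)
            folds = min(config.folds, int(np.bincount(y).min()))
            accs[kind] = dec.cv_linear_decoding_accuracy(
                piv.to_numpy(), y, folds=folds, seed=config.seed
            )
        summary["decoding"] = {f"accuracy_{k}": float(v) for k, v in accs.items()}
        summary["timings_s"]["decoding"] = time.perf_counter() - t0

    return summary


def _build_response_table(dataset, ctx, config, fr) -> pd.DataFrame:
    """Per-trial evoked responses for cells (spikes or dF/F) and patches."""
    protocol = dataset.config.protocol
    stim_ms = protocol.stim_duration_ms
    kept = set(ctx.get("kept_trials", dataset.trial_table["trial"]))
    cell_sig = (
        ctx.get("spikes")
        if config.cell_features == "spikes" and "spikes" in ctx
        else ctx["corrected"]
    )
    # population-mean high-contrast response locates the peak frame
    trials = dataset.trial_table
    high = trials[trials["contrast"].isin([100.0, 40.0]) & trials["trial"].isin(kept)]
    tlen = int((trials["end_frame"] - trials["start_frame"]).iloc[0]) + 1
    mean_resp = np.zeros(tlen)
    pop = np.mean(ctx["np_filtered"], axis=0)
    for row in high.itertuples(index=False):
        mean_resp += pop[row.start_frame : row.start_frame + tlen]
    peak_rel = find_peak_frame(mean_resp / max(len(high), 1), 3, fr, stim_ms) if tlen > 4 else 3

    rows = []
    for row in trials.itertuples(index=False):
        if row.trial not in kept:
            continue
        onset = row.start_frame + 3  # stimulus starts 3 frames into the window
        peak = row.start_frame + peak_rel
        for i, sig in enumerate(cell_sig):
            rows.append(
                (f"c{i}", "cell", row.direction, row.contrast, row.trial,
                 100.0 * evoked_response(np.asarray(sig), onset, peak, fr, stim_ms))
            )
        for i, npt in enumerate(ctx["np_filtered"]):
            rows.append(
                (f"n{i}", "neuropil", row.direction, row.contrast, row.trial,
                 100.0 * evoked_response(npt, onset, peak, fr, stim_ms))
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _safe(fn):
    try:
        return float(fn())
    except Exception as e:
        logger.info("summary entry skipped: %s", e)
        return None
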