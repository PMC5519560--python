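"""Trial-wise evoked responses, responsiveness selection and Fano factors.

Trial responses live in a tidy table (one row per ROI x condition x trial)
with columns ``roi``, ``kind`` ("cell" | "neuropil"), ``direction`` (deg),
``contrast`` (%), ``trial``, ``response`` (dF/F in percent, or spike-rate
units for deconvolved cell responses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusProtocol",
    "find_peak_frame",
    "evoked_response",
    "select_responsive",
    "fano_factor",
    "fano_ratio",
    "TABLE_COLUMNS",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["roi", "kind", "direction", "contrast", "trial", "response"]


class UndefinedFanoError(ValueError):
    """Fano factor undefined (non-positive mean or too few trials)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-grating protocol: 2 directions x 3 contrasts, 6 conditions.

    Durations in ms; ``repeats`` is the nominal presentation count per
    condition (80-100 in practice; motion exclusion may reduce it).
    """

    directions: tuple = (0.0, 90.0)
    contrasts: tuple = (100.0, 40.0, 15.0)
    stim_duration_ms: float = 600.0
    isi_ms: float = 1500.0
    repeats: int = 80

    def __post_init__(self):
        if self.repeats < 2:
            raise ValueError("need at least 2 repeats per condition")
        if len(self.directions) != 2:
            raise ValueError("protocol assumes 2 directions")

    @property
    def n_conditions(self) -> int:
        return len(self.directions) * len(self.contrasts)

    def stim_frames(self, frame_rate: float) -> int:
        return max(1, round(self.stim_duration_ms / 1000.0 * frame_rate))

    def trial_frames(self, frame_rate: float) -> int:
        return max(2, round((self.stim_duration_ms + self.isi_ms) / 1000.0 * frame_rate))


def find_peak_frame(
    mean_response: np.ndarray,
    onset: int,
    frame_rate: float,
    stim_duration_ms: float = 600.0,
) -> int:
    """Peak frame of the population-mean response within the evoked window.

    ``mean_response`` should be the response averaged across cells and across
    the high-contrast (100% and 40%) trials.  The search window runs from
    stimulus onset to onset + stimulus duration + 1 s; ties break to the
    earliest frame.
    """
    mean_response = np.asarray(mean_response, dtype=float)
    stop = onset + round((stim_duration_ms / 1000.0 + 1.0) * frame_rate) + 1
    stop = min(stop, mean_response.size)
    if stop <= onset:
        raise ValueError("empty evoked window")
    window = mean_response[onset:stop]
    if np.all(window == window[0]):
        warnings.warn("flat response in evoked window; using the earliest frame", UserWarning)
    return onset + int(np.argmax(window))


def evoked_response(
    trace: np.ndarray,
    onset: int,
    peak_frame: int,
    frame_rate: float,
    stim_duration_ms: float = 600.0,
) -> float:
    """Baseline-subtracted evoked scalar for one trial.

    Baseline: mean of the 3 frames before onset.  Response: mean over a
    window one stimulus-duration long centered at the peak frame (floor
    centering for even window lengths), minus baseline.
    """
    trace = np.asarray(trace, dtype=float)
    if onset < 3:
        raise ValueError("need at least 3 baseline frames before onset")
    w = max(1, round(stim_duration_ms / 1000.0 * frame_rate))
    start = peak_frame - w // 2
    stop = start + w
    if start < 0 or stop > trace.size:
        raise ValueError("response window outside the trace")
    baseline = float(trace[onset - 3 : onset].mean())
    return float(trace[start:stop].mean()) - baseline


def select_responsive(table: pd.DataFrame, indicator: str = "OGB") -> np.ndarray:
    """ROI ids passing the visual-responsiveness threshold.

    OGB: mean evoked dF/F across all 100%-contrast stimuli > 0.5 (percent).
    GCaMP6s: mean dF/F across all stimulus conditions > 5 (percent).
    Both thresholds are strict.
    """
    if indicator == "OGB":
        sub = table[table["contrast"] == 100.0]
        thr = 0.5
    elif indicator == "GCaMP6s":
        sub = table
        thr = 5.0
    else:
        raise ValueError(f"unknown indicator {indicator!r}")
    means = sub.groupby("roi")["response"].mean()
    return means.index[means > thr].to_numpy()


def fano_factor(table: pd.DataFrame, roi, contrast: float) -> float:
    """Trial-to-trial variance/mean of dF/F(%) responses at one contrast.

    Computed per direction (sample variance, ddof=1) and averaged over the
    two directions.  Raises ``UndefinedFanoError`` when a direction has a
    non-positive mean response or fewer than 2 trials.
    """
    sub = table[(table["roi"] == roi) & (table["contrast"] == contrast)]
    vals = []
    for _, grp in sub.groupby("direction"):
        x = grp["response"].to_numpy(dtype=float)
        if x.size < 2:
            raise UndefinedFanoError(f"roi {roi}: <2 trials at contrast {contrast}")
        m = x.mean()
        if m <= 0:
            raise UndefinedFanoError(f"roi {roi}: non-positive mean response")
        vals.append(x.var(ddof=1) / m)
    if not vals:
        raise UndefinedFanoError(f"roi {roi}: no trials at contrast {contrast}")
    return float(np.mean(vals))


def fano_ratio(table: pd.DataFrame, contrast: float) -> float:
    """FOV-level reliability contrast: mean cell Fano / mean neuropil Fano.

    ROIs whose Fano factor is undefined are skipped (logged).
    """
    means = {}
    for kind in ("cell", "neuropil"):
        vals = []
        for roi in table.loc[table["kind"] == kind, "roi"].unique():
            try:
                vals.append(fano_factor(table, roi, contrast))
            except UndefinedFanoError as e:
                logger.info("skipping %s", e)
        if not vals:
            raise UndefinedFanoError(f"no defined Fano factors for kind {kind!r}")
        means[kind] = float(np.mean(vals))
    return means["cell"] / means["neuropil"]
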