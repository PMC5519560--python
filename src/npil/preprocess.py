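"""Movie-to-trace preprocessing: motion-based trial exclusion, DCT high-pass
filtering, dF/F with an outlier-excluding baseline, and neuropil-contamination
correction.

The contamination model is linear: observed somatic fluorescence is the true
cell signal plus a fraction ``S`` of the surrounding neuropil signal (optical
spread is dominated by the z-axis, and the neuropil surrounds the soma), so
``F_correct = F - S * F_n``.  ``S`` is estimated as the ratio of the mean
calcium signal inside a blood-vessel lumen — which contains no indicator, so
any signal there is pure contamination — to the mean signal of the
surrounding neuropil; its typical value is 0.6.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.fft import dct, idct

__all__ = [
    "motion_exclude_trials",
    "dct_highpass",
    "compute_dff",
    "correct_contamination",
    "estimate_contamination_scale",
    "contamination_sensitivity_sweep",
]


def motion_exclude_trials(
    displacement: np.ndarray,
    trials: pd.DataFrame,
    pixel_size: float,
    *,
    absolute_factor: float = 2.0,
    step_factor: float = 0.5,
) -> np.ndarray:
    """Trial indices that survive the motion criterion.

    A trial is excluded if any of its frames is displaced more than
    ``absolute_factor * pixel_size`` (Euclidean, in um) from the first frame
    of the movie, or moves more than ``step_factor * pixel_size`` between
    consecutive frames.

    Parameters
    ----------
    displacement : (T, 2) array
        Per-frame XY displacement in um relative to the first movie frame.
    trials : DataFrame with columns ``trial``, ``start_frame``, ``end_frame``
        (end inclusive).
    """
    disp = np.atleast_2d(np.asarray(displacement, dtype=float))
    if disp.shape[1] != 2:
        raise ValueError("displacement must be (T, 2)")
    if not np.all(np.isfinite(disp)):
        raise ValueError("non-finite displacement values")
    abs_dist = np.hypot(disp[:, 0], disp[:, 1])
    step = np.zeros(len(disp))
    step[1:] = np.hypot(*np.diff(disp, axis=0).T)
    abs_thr = absolute_factor * pixel_size
    step_thr = step_factor * pixel_size
    kept = []
    for row in trials.itertuples(index=False):
        lo, hi = int(row.start_frame), int(row.end_frame)
        if lo < 0 or hi >= len(disp):
            raise IndexError(
                f"trial {row.trial} frames [{lo}, {hi}] outside motion trace of length {len(disp)}"
            )
        if np.all(abs_dist[lo : hi + 1] <= abs_thr) and np.all(step[max(lo, 1) : hi + 1] <= step_thr):
            kept.append(row.trial)
    return np.asarray(kept)


def dct_highpass(trace: np.ndarray, frame_rate: float, cutoff: float = 0.05) -> np.ndarray:
    """Remove slow drift by zeroing DCT components below ``cutoff`` Hz.

    DCT-II coefficient ``j`` over ``T`` samples at rate ``fs`` represents
    frequency ``j * fs / (2 T)``; all coefficients strictly below the cutoff
    (including DC) are zeroed, so the output is mean-free and the operation
    is idempotent.
    """
    trace = np.asarray(trace, dtype=float)
    T = trace.shape[0]
    if T < 4:
        raise ValueError("trace too short for high-pass filtering")
    if frame_rate <= 2.0 * cutoff:
        raise ValueError(f"cutoff {cutoff} Hz too high for frame rate {frame_rate} Hz")
    coef = dct(trace, type=2, norm="ortho", axis=0)
    freqs = np.arange(T) * frame_rate / (2.0 * T)
    coef[freqs < cutoff] = 0.0
    return idct(coef, type=2, norm="ortho", axis=0)


def compute_dff(F: np.ndarray) -> np.ndarray:
    """dF/F with the outlier-excluding baseline.

    F0 is the mean of samples below ``mean(F) + 2 * SD(F)`` (population SD),
    which excludes transient-dominated frames so the baseline is not biased
    upward by spiking activity.  Returns ``(F - F0) / F0`` as a fraction.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 1 or F.size < 4:
        raise ValueError("F must be a 1-D trace with at least 4 samples")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite fluorescence values")
    thr = F.mean() + 2.0 * F.std()
    sel = F if F.std() == 0 else F[F < thr]
    if sel.size == 0:
        warnings.warn("baseline selection empty; falling back to the global mean", UserWarning)
        F0 = float(F.mean())
    else:
        F0 = float(sel.mean())
    if F0 <= 0:
        raise ValueError(f"non-positive baseline F0={F0}")
    return (F - F0) / F0


def correct_contamination(F_cell: np.ndarray, F_np: np.ndarray, S: float = 0.6) -> np.ndarray:
    """Subtract the scaled neuropil trace: ``F - S * F_np``."""
    F_cell = np.asarray(F_cell, dtype=float)
    F_np = np.asarray(F_np, dtype=float)
    if F_cell.shape != F_np.shape:
        raise ValueError(f"shape mismatch: {F_cell.shape} vs {F_np.shape}")
    if not (0.0 <= S < 1.0):
        raise ValueError("contamination scale S must lie in [0, 1)")
    return F_cell - S * F_np


def estimate_contamination_scale(F_lumen: np.ndarray, F_np: np.ndarray) -> float:
    """Contamination scale from a blood-vessel lumen: mean(F_lumen)/mean(F_np).

    The lumen holds no indicator, so its apparent signal is neuropil spillover;
    the ratio to the surrounding neuropil signal estimates ``S``.  Clipped to
    [0, 1).
    """
    F_lumen = np.asarray(F_lumen, dtype=float)
    F_np = np.asarray(F_np, dtype=float)
    if F_lumen.size == 0 or F_np.size == 0:
        raise ValueError("empty trace")
    m_np = float(F_np.mean())
    if m_np <= 0:
        raise ValueError("non-positive mean neuropil signal")
    S = float(F_lumen.mean()) / m_np
    if S >= 1.0:
        warnings.warn("estimated S >= 1 clipped below 1", UserWarning)
        S = np.nextafter(1.0, 0.0)
    return max(S, 0.0)


def contamination_sensitivity_sweep(
    F_cell: np.ndarray,
    F_np: np.ndarray,
    scales=(0.4, 0.5, 0.6),
) -> dict[float, np.ndarray]:
    """Corrected traces over the empirically tolerated range of S (0.4-0.6)."""
    return {float(S): correct_contamination(F_cell, F_np, S) for S in scales}
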