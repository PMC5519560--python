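"""Readers/writers for the standard on-disk formats and the run configuration.

Formats: TIFF movies (tifffile), HDF5 trace groups ``{values, frame_rate}``
(h5py), CSV trial tables / motion traces / trace matrices (pandas), JSON
ROI lists and summaries, YAML run configs.  Units are normalized on load:
um, seconds, dF/F fractions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .deconv import TraceMatrix

__all__ = [
    "RunConfig",
    "load_trace_hdf5",
    "save_trace_hdf5",
    "load_trace_csv",
    "save_trace_csv",
    "load_trial_table",
    "save_trial_table",
    "load_motion_csv",
    "load_movie_tiff",
    "save_movie_tiff",
    "load_roi_json",
    "save_deconvolution",
]

TRIAL_COLUMNS = ["trial", "start_frame", "end_frame", "direction", "contrast"]


class DataError(ValueError):
    """Schema or content violation in an input file."""


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the study values."""

    seed: int = 0
    indicator: str = "OGB"
    contamination_scale: float = 0.6
    responsiveness_threshold_pct: float | None = None  # derived from indicator
    motion_absolute_factor: float = 2.0
    motion_step_factor: float = 0.5
    spike_threshold_sd: float = 0.5
    bin_width_um: float = 30.0
    folds: int = 10
    resamples: int = 1000
    shuffles: int = 10000
    tau: float = 1.0
    cell_features: str = "spikes"  # "spikes" | "dff"
    brain_state: str = "awake"
    n_cells: int = 10
    repeats: int = 10
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.indicator not in ("OGB", "GCaMP6s"):
            raise DataError(f"unknown indicator {self.indicator!r}")
        if not (0.0 <= self.contamination_scale < 1.0):
            raise DataError("contamination_scale must lie in [0, 1)")
        if self.cell_features not in ("spikes", "dff"):
            raise DataError("cell_features must be 'spikes' or 'dff'")
        if self.responsiveness_threshold_pct is None:
            self.responsiveness_threshold_pct = 0.5 if self.indicator == "OGB" else 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def save_trace_hdf5(path, trace: TraceMatrix) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=trace.values)
        fh.attrs["frame_rate"] = trace.frame_rate


def load_trace_hdf5(path) -> TraceMatrix:
    with h5py.File(path, "r") as fh:
        if "values" not in fh:
            raise DataError(f"{path}: missing 'values' dataset")
        return TraceMatrix(fh["values"][...], float(fh.attrs["frame_rate"]))


def save_trace_csv(path, trace: TraceMatrix) -> None:
    df = pd.DataFrame(
        trace.values, columns=[f"pixel{j}" for j in range(trace.n_pixels)]
    )
    df.insert(0, "frame", np.arange(trace.n_frames))
    df.attrs["frame_rate"] = trace.frame_rate
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={trace.frame_rate}\n")
        df.to_csv(fh, index=False)


def load_trace_csv(path) -> TraceMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# frame_rate="):
            raise DataError(f"{path}:1: expected '# frame_rate=' header")
        frame_rate = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    cols = [c for c in df.columns if c.startswith("pixel")]
    if not cols:
        raise DataError(f"{path}: no pixel columns")
    return TraceMatrix(df[cols].to_numpy(dtype=float), frame_rate)


def save_trial_table(path, table: pd.DataFrame) -> None:
    table[TRIAL_COLUMNS].to_csv(path, index=False)


def load_trial_table(path, n_frames: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if n_frames is not None and (df["end_frame"] >= n_frames).any():
        raise IndexError(f"{path}: trial frames exceed movie length {n_frames}")
    return df


def load_motion_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("dx_um", "dy_um"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col}")
    return df[["dx_um", "dy_um"]].to_numpy(dtype=float)


def load_movie_tiff(path) -> np.ndarray:
    try:
        movie = tifffile.imread(path)
    except Exception as e:  # truncated/corrupt stack
        raise DataError(f"{path}: cannot read TIFF ({e})") from e
    return np.atleast_3d(movie)


def save_movie_tiff(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def load_roi_json(path) -> list[dict]:
    """ROI list: [{"id", "center": [row, col], "radius_px"}, ...]."""
    with open(path) as fh:
        rois = json.load(fh)
    for i, roi in enumerate(rois):
        if "center" not in roi:
            raise DataError(f"{path}: roi #{i} missing 'center'")
    return rois


def save_deconvolution(prefix, result) -> None:
    """Persist a fit as HDF5 (full state) and CSV (spikes + filter)."""
    prefix = Path(prefix)
    with h5py.File(prefix.with_suffix(".h5"), "w") as fh:
        fh.create_dataset("rates", data=result.rates)
        fh.create_dataset("spatial_filter", data=result.spatial_filter)
        fh.create_dataset("objective_history", data=np.asarray(result.state.objective_history))
        fh.attrs["lambda0"] = result.state.lambda0
        fh.attrs["status"] = result.status
    pd.DataFrame({"frame": np.arange(result.rates.size), "rate": result.rates}).to_csv(
        prefix.with_suffix(".spikes.csv"), index=False
    )
    pd.DataFrame(
        {"pixel": np.arange(result.spatial_filter.size), "weight": result.spatial_filter}
    ).to_csv(prefix.with_suffix(".filter.csv"), index=False)
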