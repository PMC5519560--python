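"""Noise correlations: residuals, distance-binned profiles with linear fits,
the two-slope test, common-scale cell subtraction, and annular cell-neuropil
cross-correlation.

Noise correlations are Pearson coefficients of trial residuals (single-trial
response minus the condition mean) computed within each stimulus condition;
the two direction values at each contrast are then averaged.  Cell responses
enter as deconvolved spike estimates, neuropil responses as dF/F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .roi import make_neuropil_annulus

__all__ = [
    "condition_residuals",
    "noise_correlation",
    "pairwise_noise_correlations",
    "CorrelationProfile",
    "distance_profile_fit",
    "slope_difference_test",
    "subtract_cell_component",
    "annular_cell_np_correlation",
    "annulus_radii_sequence",
]

logger = logging.getLogger(__name__)


def condition_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``residual`` column: response minus its condition mean.

    Means are per (roi, direction, contrast) over the trials that survived
    motion exclusion; within each condition residuals sum to zero.
    """
    out = table.copy()
    out["residual"] = out["response"] - out.groupby(["roi", "direction", "contrast"])[
        "response"
    ].transform("mean")
    return out


def noise_correlation(
    x: np.ndarray,
    y: np.ndarray,
    direction: np.ndarray,
    contrast: np.ndarray,
) -> pd.Series:
    """Mean noise-correlation coefficient per contrast for one ROI pair.

    ``x`` and ``y`` are trial-aligned residual vectors; the Pearson
    coefficient is computed within each (direction, contrast) condition and
    the two direction values at each contrast are averaged.  Zero-variance
    conditions are skipped (logged); a contrast with no valid condition is
    NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    direction = np.asarray(direction)
    contrast = np.asarray(contrast)
    if not (x.shape == y.shape == direction.shape == contrast.shape):
        raise ValueError("inputs must be trial-aligned 1-D arrays")
    out = {}
    for c in np.unique(contrast):
        vals = []
        for d in np.unique(direction[contrast == c]):
            m = (contrast == c) & (direction == d)
            xs, ys = x[m], y[m]
            if xs.size < 2 or xs.std() == 0 or ys.std() == 0:
                logger.info("zero-variance/short condition (dir=%s, c=%s) skipped", d, c)
                continue
            vals.append(float(np.corrcoef(xs, ys)[0, 1]))
        out[float(c)] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out, name="coefficient").sort_index()


def pairwise_noise_correlations(
    table: pd.DataFrame,
    positions: dict,
    kinds: tuple[str, str] = ("cell", "cell"),
    *,
    min_cell_np_distance: float = 30.0,
) -> pd.DataFrame:
    """Long-format pairwise noise correlations with anchor-center distances.

    ``positions`` maps roi id -> (x, y) in um; a neuropil patch inherits the
    position of its anchor cell.  Mixed cell-neuropil pairs closer than
    ``min_cell_np_distance`` are excluded to avoid local contamination.
    """
    if "residual" not in table.columns:
        table = condition_residuals(table)
    rows = []
    ids_a = sorted(table.loc[table["kind"] == kinds[0], "roi"].unique())
    ids_b = sorted(table.loc[table["kind"] == kinds[1], "roi"].unique())
    mixed = kinds[0] != kinds[1]
    pairs = (
        [(i, j) for i in ids_a for j in ids_b if i != j]
        if mixed
        else list(combinations(ids_a, 2))
    )
    pivot = table.pivot_table(
        index=["direction", "contrast", "trial"], columns=["kind", "roi"], values="residual"
    )
    dirs = pivot.index.get_level_values("direction").to_numpy()
    cons = pivot.index.get_level_values("contrast").to_numpy()
    for i, j in pairs:
        d = float(np.hypot(*(np.subtract(positions[i], positions[j]))))
        if mixed and d < min_cell_np_distance:
            continue
        cc = noise_correlation(
            pivot[(kinds[0], i)].to_numpy(),
            pivot[(kinds[1], j)].to_numpy(),
            dirs,
            cons,
        )
        for c, v in cc.items():
            rows.append(
                {"roi_a": i, "roi_b": j, "kind": "-".join(kinds), "distance": d,
                 "contrast": c, "coefficient": v}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationProfile:
    """Distance-binned noise-correlation profile with its linear fit."""

    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_distances: np.ndarray  # mean pair distance per occupied bin (fit abscissa)
    slope: float
    intercept: float
    slope_se: float
    n_points: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def predict(self, d):
        return self.intercept + self.slope * np.asarray(d, dtype=float)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_distances, self.bin_means, "o")
        ax.plot(self.bin_distances, self.predict(self.bin_distances), "-")
        ax.set_xlabel("distance (um)")
        ax.set_ylabel("noise correlation")
        return ax


def distance_profile_fit(
    coefficients: np.ndarray,
    distances: np.ndarray,
    bin_width: float = 30.0,
) -> CorrelationProfile:
    """Bin pairwise coefficients into ``bin_width``-um distance bins and fit
    an ordinary least-squares line through the bin means.

    The fit abscissa is the mean pair distance within each occupied bin (not
    the geometric bin center), so an exactly linear coefficient-distance
    relation is recovered exactly.  Pairs with NaN coefficients are dropped;
    the fit needs at least 2 occupied bins.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    distances = np.asarray(distances, dtype=float)
    ok = np.isfinite(coefficients) & np.isfinite(distances)
    coefficients, distances = coefficients[ok], distances[ok]
    if coefficients.size == 0:
        raise ValueError("no valid pairs")
    idx = np.floor(distances / bin_width).astype(int)
    uniq = np.unique(idx)
    if uniq.size < 2:
        raise ValueError("all pairs fall into one distance bin; cannot fit a line")
    xs = np.array([distances[idx == u].mean() for u in uniq])
    means = np.array([coefficients[idx == u].mean() for u in uniq])
    fit = stats.linregress(xs, means)
    edges = np.concatenate([uniq * bin_width, [(uniq[-1] + 1) * bin_width]])
    return CorrelationProfile(
        bin_edges=edges,
        bin_means=means,
        bin_distances=xs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        n_points=int(uniq.size),
    )


def slope_difference_test(
    fit1: CorrelationProfile, fit2: CorrelationProfile
) -> tuple[float, int, float]:
    """t-test for the difference between two independent regression slopes.

    t = (a1 - a2) / sqrt(SE1^2 + SE2^2) with df = n1 + n2 - 4, where n counts
    the binned points entering each fit.  Returns (t, df, two-sided p).
    """
    se = float(np.hypot(fit1.slope_se, fit2.slope_se))
    if se == 0:
        raise ValueError("both slope standard errors are zero")
    t = (fit1.slope - fit2.slope) / se
    df = fit1.n_points + fit2.n_points - 4
    if df < 1:
        raise ValueError("not enough binned points for the slope test")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def subtract_cell_component(
    y: np.ndarray, x: np.ndarray, fov: np.ndarray | None = None
) -> np.ndarray:
    """Remove the common linear cell contribution from neuropil responses.

    One (scale, intercept) pair per FOV is estimated by least squares of all
    neuropil responses ``y`` on the paired cell responses ``x``; returns the
    residuals ``y - X beta``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if fov is None:
        fov = np.zeros(y.size, dtype=int)
    fov = np.asarray(fov)
    out = np.empty_like(y)
    for f in np.unique(fov):
        m = fov == f
        xs = x[m]
        if np.all(xs == xs[0]):
            raise ValueError(f"constant cell responses in FOV {f}: rank-deficient design")
        X = np.column_stack([xs, np.ones(xs.size)])
        beta, *_ = np.linalg.lstsq(X, y[m], rcond=None)
        out[m] = y[m] - X @ beta
    return out


def annulus_radii_sequence(
    start: float = 31.0, step: float = 20.0, thickness: float = 2.0, n: int = 8
) -> list[tuple[float, float]]:
    """Radii of thin concentric annuli at increasing distance (um):
    (31, 33), (51, 53), and so forth."""
    return [(start + i * step, start + i * step + thickness) for i in range(n)]


def annular_cell_np_correlation(
    cell_residuals: np.ndarray,
    pixel_residuals: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    direction: np.ndarray,
    contrast: np.ndarray,
    radii: list[tuple[float, float]] | None = None,
    *,
    exclusion_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noise correlation between a cell and thin neuropil annuli at
    progressively larger radii from its center.

    ``cell_residuals`` are the cell's (spike-estimate) trial residuals;
    ``pixel_residuals`` is (n_trials, H, W) per-pixel dF/F trial residuals.
    Empty annuli are skipped with a log entry.  Returns a tidy frame with
    columns r_in, r_out, contrast, coefficient.
    """
    if radii is None:
        radii = annulus_radii_sequence()
    pixel_residuals = np.asarray(pixel_residuals, dtype=float)
    n_trials, H, W = pixel_residuals.shape
    rows = []
    for r_in, r_out in radii:
        try:
            mask = make_neuropil_annulus(
                center, (H, W), pixel_size, r_in=r_in, r_out=r_out,
                exclusion_mask=exclusion_mask,
            )
        except ValueError:
            logger.info("empty annulus [%s, %s) um skipped", r_in, r_out)
            continue
        patch = pixel_residuals[:, mask].mean(axis=1)
        cc = noise_correlation(cell_residuals, patch, direction, contrast)
        for c, v in cc.items():
            rows.append({"r_in": r_in, "r_out": r_out, "contrast": c, "coefficient": v})
    return pd.DataFrame(rows)
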