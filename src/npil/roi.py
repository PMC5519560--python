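"""ROI geometry: half-max cell segmentation and exclusion-aware neuropil annuli.

Coordinates are 0-based pixel indices (row, col); physical distances are in
um via ``pixel_size``.  Annulus membership uses the pixel-center distance
and the half-open interval [r_in, r_out).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.draw import polygon

__all__ = ["RoiGeometry", "segment_cell_roi", "make_neuropil_annulus"]


@dataclass
class RoiGeometry:
    """Cell mask plus its exclusion-aware neuropil annulus (boolean images)."""

    center: tuple[float, float]
    cell_mask: np.ndarray
    annulus_mask: np.ndarray | None = None
    inner_radius_um: float | None = None
    outer_radius_um: float | None = None
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.annulus_mask is not None and np.any(self.cell_mask & self.annulus_mask):
            raise ValueError("cell and annulus masks overlap")


def segment_cell_roi(
    image: np.ndarray,
    seed_center: tuple[float, float],
    seed_radius: float,
    *,
    n_rays: int = 72,
    threshold: float = 0.5,
    pixel_size: float = 1.0,
) -> RoiGeometry:
    """Segment a cell body by half-max thresholding along polar rays.

    The brightest pixel inside the seed disk becomes the cell center; along
    each of ``n_rays`` polar rays (linear interpolation of the image) the
    boundary sits at the first radius where fluorescence drops below
    ``threshold`` x the center maximum.  The enclosed polygon is the mask.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    rr, cc = np.mgrid[0:H, 0:W]
    in_disk = (rr - seed_center[0]) ** 2 + (cc - seed_center[1]) ** 2 <= seed_radius**2
    if not np.any(in_disk):
        raise ValueError("seed disk outside the image")
    vals = np.where(in_disk, image, -np.inf)
    peak = float(np.max(vals))
    if not np.isfinite(peak) or np.all(vals[in_disk] == vals[in_disk].flat[0]):
        raise ValueError("flat image in the seed disk: no cell peak")
    cy, cx = np.unravel_index(np.argmax(vals), image.shape)
    half = threshold * peak

    max_r = float(np.hypot(H, W))
    radii_samples = np.arange(0.0, max_r, 0.25)
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    boundary_r = np.empty(n_rays)
    for i, th in enumerate(angles):
        ys = cy + radii_samples * np.sin(th)
        xs = cx + radii_samples * np.cos(th)
        prof = map_coordinates(image, np.vstack([ys, xs]), order=1, mode="constant", cval=0.0)
        below = np.nonzero(prof < half)[0]
        boundary_r[i] = radii_samples[below[0]] if below.size else radii_samples[-1]
    ys = cy + boundary_r * np.sin(angles)
    xs = cx + boundary_r * np.cos(angles)
    mask = np.zeros_like(image, dtype=bool)
    pr, pc = polygon(ys, xs, shape=image.shape)
    mask[pr, pc] = True
    mask[cy, cx] = True
    return RoiGeometry(
        center=(float(cy), float(cx)),
        cell_mask=mask,
        pixel_size=pixel_size,
        meta={"boundary_radii": boundary_r, "angles": angles},
    )


def make_neuropil_annulus(
    center: tuple[float, float],
    shape: tuple[int, int],
    pixel_size: float,
    *,
    r_in: float = 7.0,
    r_out: float = 15.0,
    other_centers=(),
    exclusion_radius: float = 7.0,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean annulus mask with distances in um; pixels within
    ``exclusion_radius`` of any other cell center, and any pixels flagged in
    ``exclusion_mask`` (vessels, astrocytes, other somata), are removed.

    Membership is half-open: r_in <= d < r_out, pixel-center distances.
    """
    if not (r_out > r_in > 0):
        raise ValueError("need r_out > r_in > 0")
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    d = np.hypot(rr - center[0], cc - center[1]) * pixel_size
    mask = (d >= r_in) & (d < r_out)
    for oc in other_centers:
        d_other = np.hypot(rr - oc[0], cc - oc[1]) * pixel_size
        mask &= d_other >= exclusion_radius
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("annulus empty after exclusions")
    return mask
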