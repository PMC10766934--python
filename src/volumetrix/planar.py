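"""Planar ROI delineation, area/length measurement and the Allen volume formula.

Planar scintigraphy estimates thyroid volume from the anterior projection as

    V [mL] = S * L * K

with S the bilateral frontal projected area (cm^2), L the mean craniocaudal
extent of the two lobes (cm) and K an empirical shape constant (0.32 here;
0.23–0.32 in the literature).  The vendor's proprietary boundary tool is
approximated by a 20% iso-contour, which the vendor workflow itself describes
as producing a similar boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .emulator import PlanarImage
from .errors import EmptyRoiError, InvalidParameterError

__all__ = [
    "PlanarMeasurement",
    "delineate_planar_roi",
    "split_merged_lobes",
    "default_background_roi",
    "measure_area_and_length",
    "allen_volume",
    "planar_tb",
]

_CONN8 = np.ones((3, 3), dtype=int)

K_DEFAULT = 0.32
K_RANGE = (0.23, 0.32)


@dataclass
class PlanarMeasurement:
    """Planar volumetry result for one acquisition."""

    S: float  # cm^2, bilateral frontal projected area
    L: float  # cm, mean craniocaudal lobe extent
    K: float  # dimensionless
    V: float  # mL, Allen volume = S * L * K
    planar_tb: float | None = None


def delineate_planar_roi(image: PlanarImage, boundary_fraction: float = 0.20,
                         smooth_sigma_px: float = 1.0) -> list[np.ndarray]:
    """Per-lobe ROI masks: 8-connected components above ``boundary_fraction`` x max.

    The two largest components (by pixel count) are returned, largest first;
    a single component is returned alone.  No component above threshold raises
    :class:`EmptyRoiError`.

    Delineation operates on a lightly smoothed copy of the image
    (``smooth_sigma_px`` Gaussian, 0 disables it): a boundary drawn on the
    displayed image is not destabilized by single-pixel Poisson excursions,
    and neither is its reference maximum.
    """
    if not 0 < boundary_fraction < 1:
        raise InvalidParameterError("boundary_fraction must be in (0, 1)")
    img = image.counts_grid
    if smooth_sigma_px > 0:
        img = ndimage.gaussian_filter(img.astype(float), smooth_sigma_px)
    level = boundary_fraction * float(img.max())
    above = img >= level
    if level <= 0 or not above.any():
        raise EmptyRoiError("no pixels above the boundary threshold")
    labels, n_comp = ndimage.label(above, structure=_CONN8)
    sizes = ndimage.sum_labels(np.ones_like(img), labels=labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1][: min(2, n_comp)]
    return [labels == (k + 1) for k in order]


def split_merged_lobes(image: PlanarImage, mask: np.ndarray) -> list[np.ndarray]:
    """Split one merged bilateral blob into two lobe masks at the count valley.

    When blur bridges the inter-lobe gap the iso-contour yields a single
    component; the cut is placed at the minimum of the column count profile
    over the central 60% of the blob's horizontal span (the isthmus valley),
    mimicking how an operator separates the lobes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("cannot split an empty mask")
    cols = np.nonzero(mask.any(axis=0))[0]
    c0, c1 = int(cols.min()), int(cols.max())
    span = c1 - c0 + 1
    if span < 3:
        raise EmptyRoiError("blob too narrow to split into two lobes")
    lo = c0 + max(int(0.2 * span), 1)
    hi = c1 - max(int(0.2 * span), 1)
    profile = np.where(mask, image.counts_grid, 0.0).sum(axis=0)
    cut = lo + int(np.argmin(profile[lo:hi + 1]))
    left = mask.copy()
    left[:, cut:] = False
    right = mask.copy()
    right[:, :cut] = False
    if not left.any() or not right.any():
        raise EmptyRoiError("valley split produced an empty lobe")
    return [left, right]


def default_background_roi(image: PlanarImage, size_fraction: float = 0.1,
                           row_center: float = 0.80, col_center: float = 0.50) -> np.ndarray:
    """Fixed rectangular background ROI inferior to the thyroid, inside the body.

    A ``size_fraction``-sized rectangle centred at the fractional position
    (``row_center``, ``col_center``) of the image — by default below the gland
    on the midline, where only background tissue projects.  Placement is fixed
    by the config, not data-driven, so it is identical across replicates.
    """
    img = image.counts_grid
    h = max(int(img.shape[0] * size_fraction), 1)
    w = max(int(img.shape[1] * size_fraction), 1)
    r0 = int(np.clip(row_center * img.shape[0] - h / 2, 0, img.shape[0] - h))
    c0 = int(np.clip(col_center * img.shape[1] - w / 2, 0, img.shape[1] - w))
    mask = np.zeros(img.shape, dtype=bool)
    mask[r0:r0 + h, c0:c0 + w] = True
    return mask


def measure_area_and_length(rois: list[np.ndarray], pixel_size: float) -> tuple[float, float]:
    """Bilateral projected area S (cm^2) and mean craniocaudal extent L (cm).

    S is the total pixel count over both ROIs times the pixel area; L averages
    each lobe's row-extent (rows are the craniocaudal axis of PlanarImage).
    """
    if len(rois) < 2 or any(not np.asarray(r).any() for r in rois):
        raise EmptyRoiError("two non-empty lobe ROIs are required")
    area_mm2 = sum(int(np.count_nonzero(r)) for r in rois) * pixel_size**2
    lengths_mm = []
    for r in rois:
        rows = np.nonzero(np.asarray(r).any(axis=1))[0]
        lengths_mm.append((rows.max() - rows.min() + 1) * pixel_size)
    return area_mm2 / 100.0, float(np.mean(lengths_mm)) / 10.0


def allen_volume(S: float, L: float, K: float = K_DEFAULT) -> float:
    """Allen planar volume S * L * K in mL (S in cm^2, L in cm)."""
    if S < 0 or L < 0 or K < 0:
        raise InvalidParameterError("S, L and K must be non-negative")
    if not K_RANGE[0] <= K <= K_RANGE[1]:
        warnings.warn(f"K = {K} is outside the customary range {K_RANGE}", stacklevel=2)
    return S * L * K


def planar_tb(image: PlanarImage, target_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """Measured planar target-to-background ratio (mean counts per pixel)."""
    t = np.asarray(target_roi, dtype=bool)
    b = np.asarray(background_roi, dtype=bool)
    if not t.any() or not b.any():
        raise EmptyRoiError("both ROIs must be non-empty")
    bg_mean = float(image.counts_grid[b].mean())
    if bg_mean == 0:
        raise ZeroDivisionError("background ROI mean count is zero")
    return float(image.counts_grid[t].mean()) / bg_mean
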