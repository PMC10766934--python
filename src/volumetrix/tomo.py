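"""Iso-contour threshold VOI delineation and the threshold sweep.

A VOI is the set of voxels whose value is at least a fixed fraction of the
regional maximum uptake, restricted to the connected components (26-neighbour
connectivity) that carry the two most intense peaks — the bilateral lobes.
Because superlevel sets are nested, the measured volume is non-increasing in
the threshold fraction for any fixed image; the partial volume effect makes it
strongly threshold-dependent, which is why an optimal fraction exists at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .emulator import TomoImage, max_uptake
from .errors import EmptyRoiError, InvalidParameterError

__all__ = [
    "VoiResult",
    "ThresholdSweepTable",
    "segment_voi",
    "volume_error",
    "threshold_sweep",
    "select_optimal_threshold",
    "default_search_region",
]

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class VoiResult:
    """One segmented VOI and its volume bookkeeping."""

    voxel_mask: np.ndarray  # bool
    measured_volume: float  # mL
    threshold_fraction: float
    reference_max: float  # counts (or concentration units)
    volume_error_pct: float | None = None  # vs supplied true volume
    empty: bool = False  # True when component filtering left nothing


def volume_error(measured: float, true: float) -> float:
    """Percent volume error 100 * |measured - true| / true."""
    if true <= 0:
        raise InvalidParameterError(f"true volume must be positive, got {true}")
    return 100.0 * abs(measured - true) / true


def default_search_region(lobe_mask: np.ndarray, fwhm_mm: float, voxel_size: float) -> np.ndarray:
    """Axis-aligned box around the lobes dilated by 2 x FWHM on every side.

    This is the "target area" handed to the maximum search; the dilation keeps
    all blur spill inside the box while excluding remote background.
    """
    if not lobe_mask.any():
        raise EmptyRoiError("lobe mask is empty")
    pad = int(np.ceil(2.0 * fwhm_mm / voxel_size))
    region = np.zeros(lobe_mask.shape, dtype=bool)
    idx = np.nonzero(lobe_mask)
    sl = tuple(slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, n))
               for i, n in zip(idx, lobe_mask.shape))
    region[sl] = True
    return region


def segment_voi(image: TomoImage, threshold_fraction: float,
                search_region: np.ndarray | None = None,
                true_volume: float | None = None,
                max_bias_model: str = "raw", hottest_n: int = 4) -> VoiResult:
    """Threshold the image at ``threshold_fraction`` x regional max and keep the lobes.

    The superlevel set (>= comparison, whole-voxel volumes) is reduced to the
    connected components holding the two highest peaks; with a single component
    above threshold that one is kept.  An empty result is returned with
    ``empty=True`` and a warning rather than an exception.
    """
    if not 0 < threshold_fraction < 1:
        raise InvalidParameterError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    if search_region is None:
        search_region = np.ones(image.counts_grid.shape, dtype=bool)
    search_region = np.asarray(search_region, dtype=bool)
    if not search_region.any():
        raise EmptyRoiError("search_region is empty")

    ref_max = max_uptake(image, search_region, model=max_bias_model, hottest_n=hottest_n)
    level = threshold_fraction * ref_max
    if ref_max <= 0:  # no signal: a fraction of a non-positive max selects nothing
        above = np.zeros(image.counts_grid.shape, dtype=bool)
    else:
        above = (image.counts_grid >= level) & search_region

    mask = np.zeros_like(above)
    if above.any():
        labels, n_comp = ndimage.label(above, structure=_CONN26)
        # rank components by their peak intensity, keep the two hottest
        peaks = ndimage.maximum(image.counts_grid, labels=labels, index=np.arange(1, n_comp + 1))
        order = np.argsort(peaks)[::-1][: min(2, n_comp)]
        for k in order:
            mask |= labels == (k + 1)

    measured = float(np.count_nonzero(mask)) * image.voxel_volume_ml
    empty = not mask.any()
    if empty:
        warnings.warn("segment_voi: no voxels survived thresholding; returning zero volume",
                      stacklevel=2)
    err = volume_error(measured, true_volume) if true_volume is not None else None
    return VoiResult(voxel_mask=mask, measured_volume=measured,
                     threshold_fraction=threshold_fraction, reference_max=ref_max,
                     volume_error_pct=err, empty=empty)


@dataclass
class ThresholdSweepTable:
    """Long-format sweep results plus the mean ± SD summary."""

    rows: pd.DataFrame  # columns: tb_ratio, threshold, replicate, volume_ml, error_pct

    def summary(self) -> pd.DataFrame:
        """Mean and SD of volume and error per (tb_ratio, threshold)."""
        g = self.rows.groupby(["tb_ratio", "threshold"], sort=True)
        out = g.agg(volume_mean=("volume_ml", "mean"), volume_sd=("volume_ml", "std"),
                    error_mean=("error_pct", "mean"), error_sd=("error_pct", "std"))
        return out.reset_index()

    def mean_error_by_threshold(self) -> pd.Series:
        """Mean error over every (tb_ratio, replicate) cell, per threshold fraction."""
        return self.rows.groupby("threshold")["error_pct"].mean()


def threshold_sweep(images: list[dict], fractions: list[float]) -> ThresholdSweepTable:
    """Run :func:`segment_voi` over every image x fraction combination.

    ``images`` holds dicts with keys ``image`` (TomoImage), ``true_volume``
    (mL) and optional ``tb_ratio``, ``replicate``, ``search_region``,
    ``max_bias_model``, ``hottest_n``.
    """
    fr = list(fractions)
    if fr != sorted(fr) or not all(0 < f < 1 for f in fr):
        raise InvalidParameterError("fractions must be ascending and in (0, 1)")
    records = []
    for item in images:
        for f in fr:
            res = segment_voi(item["image"], f,
                              search_region=item.get("search_region"),
                              true_volume=item["true_volume"],
                              max_bias_model=item.get("max_bias_model", "raw"),
                              hottest_n=item.get("hottest_n", 4))
            records.append({"tb_ratio": item.get("tb_ratio", np.nan),
                            "threshold": f,
                            "replicate": item.get("replicate", 0),
                            "volume_ml": res.measured_volume,
                            "error_pct": res.volume_error_pct})
    return ThresholdSweepTable(pd.DataFrame.from_records(records))


def select_optimal_threshold(table: ThresholdSweepTable) -> float:
    """Fraction with the smallest mean volume error; ties go to the smaller fraction."""
    if table.rows.empty:
        raise InvalidParameterError("sweep table is empty")
    means = table.mean_error_by_threshold().sort_index()
    return float(means.index[np.argmin(means.to_numpy())])
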