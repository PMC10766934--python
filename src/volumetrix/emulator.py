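"""Planar and tomographic image emulation.

The scanner chain (projection, OSEM reconstruction, CT attenuation correction,
scatter correction, resolution recovery) is not simulated step by step.  The
quantity every downstream result depends on is the *corrected reconstructed*
image, which this module models directly as

    tomo  =  truth ⊛ Gaussian PSF  (+ Poisson counting noise)

with the PSF full width at half maximum equal to the system's effective
tomographic resolution.  The planar image is an anterior-posterior line
integral with optional Beer-Lambert attenuation, blurred with the planar PSF
and scaled to a target total count before noise is applied.

FWHM and sigma are related by FWHM = sigma * 2 * sqrt(2 ln 2) ≈ 2.3548 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, InvalidParameterError
from .phantom import ActivityMap

__all__ = [
    "AcquisitionConfig",
    "TomoImage",
    "PlanarImage",
    "FWHM_TO_SIGMA",
    "emulate_tomo",
    "poissonize_tomo",
    "emulate_planar",
    "max_uptake",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class AcquisitionConfig:
    """Physics and acquisition knobs for the emulator.

    Defaults mirror the modelled system: effective tomographic resolution
    10.59 mm FWHM (no resolution recovery), system sensitivity 73.4 cps/MBq,
    planar acquisitions stopped at 300/500/800 kilocounts, tomographic
    acquisitions of 60 frames at 12/15/18 s per frame.  ``calibration_factor``
    converts the idealized cps to recorded counts; 1.0 yields roughly 1e6
    total tomographic counts for the default phantom, which is the regime the
    count-level knobs span.
    """

    tomo_fwhm: float = 10.59  # mm
    planar_fwhm: float = 8.0  # mm
    sensitivity: float = 73.4  # cps/MBq
    planar_target_counts: float = 500.0  # kilocounts
    tomo_seconds_per_frame: float = 15.0  # s, one of 12/15/18
    frames: int = 60
    attenuation_mu: float = 0.15  # 1/cm at 140 keV in water, planar only
    calibration_factor: float = 1.0
    max_bias_model: str = "raw"  # "raw" | "hottest-n"
    hottest_n: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tomo_fwhm <= 0 or self.planar_fwhm <= 0:
            raise InvalidParameterError("PSF FWHM must be positive")
        if self.sensitivity <= 0:
            raise InvalidParameterError("sensitivity must be positive")
        if self.planar_target_counts <= 0:
            raise InvalidParameterError("planar_target_counts must be positive")
        if self.max_bias_model not in ("raw", "hottest-n"):
            raise InvalidParameterError("max_bias_model must be 'raw' or 'hottest-n'")

    @property
    def tomo_total_seconds(self) -> float:
        return self.tomo_seconds_per_frame * self.frames


@dataclass
class TomoImage:
    """3D reconstructed image: counts (noisy) or concentration units (noiseless)."""

    counts_grid: np.ndarray
    voxel_size: float  # mm
    provenance: AcquisitionConfig | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def save_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.counts_grid.astype(np.float32), affine), path)


@dataclass
class PlanarImage:
    """2D anterior projection image; axis 0 is craniocaudal (rows), axis 1 left-right."""

    counts_grid: np.ndarray
    pixel_size: float  # mm
    provenance: AcquisitionConfig | None = None


def _check_activity(activity: ActivityMap) -> None:
    grid = activity.concentration_grid
    if not np.all(np.isfinite(grid)) or np.any(grid < 0):
        raise InvalidParameterError("activity grid must be finite and non-negative")


def emulate_tomo(activity: ActivityMap, cfg: AcquisitionConfig | None = None,
                 noisy: bool = False) -> TomoImage:
    """Emulate the corrected tomographic reconstruction of an activity map.

    Noiseless mode returns the concentration grid convolved with the isotropic
    Gaussian PSF (same units as the input).  Noisy mode converts the blurred
    concentration to expected counts per voxel

        conc [Bq/mL] * voxel volume [mL] * sensitivity [cps/Bq] * time [s] * cal

    and draws one Poisson realization (seeded by ``cfg.rng_seed``).
    """
    cfg = cfg or AcquisitionConfig()
    _check_activity(activity)
    sigma_vox = cfg.tomo_fwhm * FWHM_TO_SIGMA / activity.voxel_size
    blurred = ndimage.gaussian_filter(activity.concentration_grid.astype(np.float64),
                                      sigma_vox, mode="constant", cval=0.0)
    if not noisy:
        return TomoImage(blurred, activity.voxel_size, cfg)
    return poissonize_tomo(TomoImage(blurred, activity.voxel_size, cfg), cfg)


def poissonize_tomo(noiseless: TomoImage, cfg: AcquisitionConfig,
                    rng: np.random.Generator | None = None) -> TomoImage:
    """Turn a noiseless blurred concentration image into a Poisson count image.

    Split out from :func:`emulate_tomo` so one expensive convolution can serve
    several count-level replicates.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed)
    cps_per_bq = cfg.sensitivity * 1e-6  # cps/MBq -> cps/Bq
    expected = (noiseless.counts_grid * noiseless.voxel_volume_ml * cps_per_bq
                * cfg.tomo_total_seconds * cfg.calibration_factor)
    counts = rng.poisson(expected).astype(np.float64)
    return TomoImage(counts, noiseless.voxel_size, cfg)


def emulate_planar(activity: ActivityMap, cfg: AcquisitionConfig | None = None,
                   noisy: bool = False) -> PlanarImage:
    """Emulate the anterior planar acquisition.

    The projection integrates concentration along the anterior-posterior axis
    (grid axis 1, anterior at the high-index face) with per-voxel Beer-Lambert
    weighting exp(-mu * depth); the projection is then blurred with the planar
    PSF.  Noisy mode rescales the image so its expected total equals
    ``planar_target_counts`` kilocounts and draws Poisson counts.

    Output axes: (craniocaudal rows, left-right columns) = grid (z, x).
    """
    cfg = cfg or AcquisitionConfig()
    _check_activity(activity)
    grid = activity.concentration_grid.astype(np.float64)
    ny = grid.shape[1]
    depth_cm = (ny - 0.5 - np.arange(ny)) * activity.voxel_size / 10.0
    weights = np.exp(-cfg.attenuation_mu * depth_cm)
    dz_ml_per_mm2 = activity.voxel_size / 1000.0  # mm -> mL per mm^2 column element
    proj = np.tensordot(grid, weights, axes=([1], [0])) * dz_ml_per_mm2  # (x, z)
    sigma_pix = cfg.planar_fwhm * FWHM_TO_SIGMA / activity.voxel_size
    proj = ndimage.gaussian_filter(proj, sigma_pix, mode="constant", cval=0.0)
    image = proj.T  # (z, x) = (rows craniocaudal, columns left-right)
    if not noisy:
        return PlanarImage(image, activity.voxel_size, cfg)
    total = image.sum()
    if total <= 0:
        raise InvalidParameterError("cannot scale an all-zero projection to a count target")
    expected = image * (cfg.planar_target_counts * 1000.0 / total)
    rng = np.random.default_rng(cfg.rng_seed)
    return PlanarImage(rng.poisson(expected).astype(np.float64), activity.voxel_size, cfg)


def max_uptake(image: TomoImage, region: np.ndarray,
               model: str = "raw", hottest_n: int = 4) -> float:
    """Reference maximum uptake within ``region``.

    ``model='raw'`` returns the single hottest voxel (the default convention);
    ``model='hottest-n'`` returns the mean of the ``hottest_n`` hottest voxels,
    which tames the upward bias of a noisy order statistic.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != image.counts_grid.shape:
        raise InvalidParameterError("region mask shape must match the image")
    values = image.counts_grid[region]
    if values.size == 0:
        raise EmptyRoiError("max_uptake called with an empty region")
    if model == "raw":
        return float(values.max())
    if model == "hottest-n":
        n = min(int(hottest_n), values.size)
        return float(np.sort(values)[-n:].mean())
    raise InvalidParameterError(f"unknown max_bias_model {model!r}")
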