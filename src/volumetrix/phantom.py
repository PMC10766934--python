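"""Digital thyroid phantom: torus-sector lobes inside an elliptical-cylinder tank.

The physical object being modelled is a butterfly-shaped container built from two
45-degree pipe elbows (inner diameter 25 mm, unilateral lumen volume 26.5 mL,
bilateral 53 mL) placed inside a NEMA IEC body-phantom tank of 10,122 mL.  Each
lobe lumen is modelled as a sector of a torus whose bend radius is calibrated by
Pappus' centroid theorem so the analytic lumen volume equals the measured one:

    V = pi * r^2 * R * theta        (theta in radians)

The tank's D-shaped cross-section is approximated by an elliptical cylinder of
equal volume; the background compartment is spatially uniform, so its exact
shape does not influence the volumetry downstream.

Voxelization rule: a voxel belongs to a region iff its *center* lies inside the
analytic surface (no partial-volume supersampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidParameterError, ResolutionError

__all__ = [
    "ElbowSpec",
    "Arrangement",
    "PhantomModel",
    "ActivityMap",
    "calibrate_bend_radius",
    "voxelize_elbow",
    "assemble_phantom",
    "assign_activity",
    "voxelize_patient_thyroid",
]

#: mm of clearance added around analytic surfaces when sizing bounding boxes
_BBOX_MARGIN_MM = 2.0

#: sanity bound on the lobe bounding box (the printed elbow height is 50 mm;
#: the full sector silhouette of the calibrated geometry extends slightly past it)
_MAX_LOBE_EXTENT_MM = 65.0


def calibrate_bend_radius(tube_radius: float, bend_angle: float, target_volume: float) -> float:
    """Bend radius R (mm) of a torus sector with lumen volume ``target_volume``.

    Parameters
    ----------
    tube_radius : float
        Lumen (inner) radius r in mm.
    bend_angle : float
        Sector angle in degrees, in (0, 360].
    target_volume : float
        Lumen volume in mm^3.

    Returns
    -------
    float
        R in mm such that ``pi * r**2 * R * radians(bend_angle)`` equals
        ``target_volume`` (exact by construction, Pappus' theorem).
    """
    if tube_radius <= 0 or target_volume <= 0:
        raise InvalidParameterError(
            f"tube_radius and target_volume must be positive, got {tube_radius}, {target_volume}"
        )
    if not 0 < bend_angle <= 360:
        raise InvalidParameterError(f"bend_angle must be in (0, 360], got {bend_angle}")
    theta = math.radians(bend_angle)
    radius = target_volume / (math.pi * tube_radius**2 * theta)
    if radius <= tube_radius:
        raise GeometryError(
            f"bend radius {radius:.3f} mm <= tube radius {tube_radius} mm: torus self-intersects"
        )
    return radius


@dataclass(frozen=True)
class ElbowSpec:
    """Geometry of one lobe (a 45-degree pipe elbow lumen).

    Wall thickness, outer diameter and height are metadata carried from the
    physical part; only the lumen enters the voxel model (the wall is cold
    background).  ``bend_radius`` is calibrated, not measured.
    """

    inner_diameter: float = 25.0  # mm
    wall_thickness: float = 3.5  # mm, metadata only
    outer_diameter: float = 32.0  # mm, metadata only
    height: float = 50.0  # mm, metadata / sanity bound only
    bend_angle: float = 45.0  # degrees
    target_lumen_volume: float = 26.5e3  # mm^3 (26.5 mL)
    bend_radius: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise InvalidParameterError("inner_diameter must be positive")
        if not 0 < self.bend_angle <= 360:
            raise InvalidParameterError("bend_angle must be in (0, 360]")
        if self.bend_radius == 0.0:
            object.__setattr__(
                self,
                "bend_radius",
                calibrate_bend_radius(self.tube_radius, self.bend_angle, self.target_lumen_volume),
            )
        if self.bend_radius <= self.tube_radius:
            raise GeometryError("bend_radius must exceed the tube radius")

    @property
    def tube_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def analytic_volume(self) -> float:
        """Lumen volume in mm^3 by Pappus' theorem."""
        return math.pi * self.tube_radius**2 * self.bend_radius * math.radians(self.bend_angle)

    def local_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds (lo, hi) of the sector in lobe-local mm coordinates.

        Local frame: the torus center circle lies in the y-z plane, the sector is
        symmetric about +y (angle measured from +y toward +/-z), and the whole
        sector is then recentred so its bounding box is centred at the origin.
        x is the tube-axis (left-right) direction, z is craniocaudal.
        """
        r, big_r = self.tube_radius, self.bend_radius
        half = math.radians(self.bend_angle) / 2.0
        y_lo = big_r * math.cos(half) - r
        y_hi = big_r + r
        z_hi = (big_r + r) * math.sin(half)
        lo = np.array([-r, y_lo, -z_hi])
        hi = np.array([r, y_hi, z_hi])
        center = (lo + hi) / 2.0
        return lo - center, hi - center

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Membership test for points in lobe-local mm coordinates (broadcastable)."""
        r, big_r = self.tube_radius, self.bend_radius
        half = math.radians(self.bend_angle) / 2.0
        # undo the recentring applied by local_bounds (shift acts on y only)
        y_lo = big_r * math.cos(half) - r
        y_hi = big_r + r
        y0 = y + (y_lo + y_hi) / 2.0
        rho = np.sqrt(y0**2 + z**2)
        in_tube = (rho - big_r) ** 2 + x**2 <= r**2
        ang = np.abs(np.arctan2(z, y0))
        return in_tube & (ang <= half) & (y0 > 0)


def voxelize_elbow(spec: ElbowSpec, voxel_size: float,
                   bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Boolean lumen mask of one elbow sampled at voxel centers.

    ``bounds`` (lo, hi in lobe-local mm) may restrict/extend the sampled box;
    by default the sector's own bounding box plus a margin is used.  Array axes
    are (x, y, z); the voxel grid origin is at ``lo`` + half a voxel.
    """
    if not 0 < voxel_size <= 2.0:
        raise InvalidParameterError(f"voxel_size must be in (0, 2] mm, got {voxel_size}")
    if voxel_size > spec.tube_radius:
        raise ResolutionError(
            f"voxel_size {voxel_size} mm cannot resolve tube radius {spec.tube_radius} mm"
        )
    if bounds is None:
        lo, hi = spec.local_bounds()
        lo = lo - _BBOX_MARGIN_MM
        hi = hi + _BBOX_MARGIN_MM
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    n = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 0)
    if np.any(n == 0):
        return np.zeros(tuple(n), dtype=bool)
    ax = [lo[i] + (np.arange(n[i]) + 0.5) * voxel_size for i in range(3)]
    x = ax[0][:, None, None]
    y = ax[1][None, :, None]
    z = ax[2][None, None, :]
    return spec.contains(x, y, z)


@dataclass(frozen=True)
class Arrangement:
    """Pose of the two lobes inside the tank (butterfly configuration).

    The two sectors are mirror images across the mid-sagittal (x = 0) plane,
    separated by ``gap`` mm between the lumen surfaces, with the anterior edge
    of the lobes ``anterior_depth`` mm below the tank's anterior surface.
    ``center_offset`` shifts the whole assembly (mm, tank frame).
    """

    gap: float = 5.0  # mm between the two lumens at the mid-sagittal plane
    anterior_depth: float = 20.0  # mm from tank anterior surface to lobe front
    center_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


# label values in PhantomModel.label_grid
LABEL_OUTSIDE = 0
LABEL_TANK = 1
LABEL_LOBE_LEFT = 2
LABEL_LOBE_RIGHT = 3


@dataclass
class PhantomModel:
    """Voxelized phantom: label grid plus geometry metadata.

    Axes are (x, y, z) with y the anterior-posterior axis (anterior = +y,
    the direction planar projection integrates along) and z craniocaudal.
    """

    label_grid: np.ndarray  # uint8, labels above
    voxel_size: float  # mm, isotropic
    tank_volume: float  # mL (nominal)
    arrangement: Arrangement | None = None

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def label_volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.label_grid == label)) * self.voxel_volume_ml

    @property
    def lobe_volume_ml(self) -> float:
        """Voxelized bilateral lobe volume in mL."""
        return self.label_volume_ml(LABEL_LOBE_LEFT) + self.label_volume_ml(LABEL_LOBE_RIGHT)

    @property
    def lobe_mask(self) -> np.ndarray:
        return self.label_grid >= LABEL_LOBE_LEFT

    def save_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.label_grid.astype(np.uint8), affine), path)


def _tank_cross_section(tank_volume_ml: float, semi_x: float = 150.0,
                        semi_y: float = 115.0) -> tuple[float, float, float]:
    """Semi-axes (mm) and length (mm) of the equal-volume elliptical cylinder."""
    length = tank_volume_ml * 1000.0 / (math.pi * semi_x * semi_y)
    return semi_x, semi_y, length


def assemble_phantom(spec: ElbowSpec | None = None,
                     arrangement: Arrangement | None = None,
                     tank_volume: float = 10_122.0,
                     voxel_size: float = 1.0) -> PhantomModel:
    """Build the full label grid: both lobes inside the elliptical-cylinder tank.

    Raises
    ------
    GeometryError
        If the two lobes overlap or any lobe voxel falls outside the tank.
    """
    spec = spec or ElbowSpec()
    arrangement = arrangement or Arrangement()

    lo, hi = spec.local_bounds()
    extent = hi - lo
    if float(np.max(extent)) > _MAX_LOBE_EXTENT_MM:
        raise GeometryError(
            f"lobe bounding box {np.max(extent):.1f} mm exceeds sanity bound "
            f"{_MAX_LOBE_EXTENT_MM} mm (printed part height {spec.height} mm)"
        )

    semi_x, semi_y, length = _tank_cross_section(tank_volume)
    nx = int(round(2 * semi_x / voxel_size))
    ny = int(round(2 * semi_y / voxel_size))
    nz = int(round(length / voxel_size))
    grid = np.zeros((nx, ny, nz), dtype=np.uint8)

    # tank interior: elliptical cylinder centred in the grid, axis along z
    cx = (np.arange(nx) + 0.5) * voxel_size - semi_x
    cy = (np.arange(ny) + 0.5) * voxel_size - semi_y
    inside = (cx[:, None] / semi_x) ** 2 + (cy[None, :] / semi_y) ** 2 <= 1.0
    grid[inside, :] = LABEL_TANK

    # lobe placement in tank-frame mm: mirror across x = 0 with the requested gap
    half_sep = arrangement.gap / 2.0 + spec.tube_radius  # lobe-centre |x|
    front_y = semi_y - arrangement.anterior_depth - extent[1] / 2.0  # lobe-centre y
    off = np.asarray(arrangement.center_offset)

    lobe_mask = voxelize_elbow(spec, voxel_size)
    for label, sign in ((LABEL_LOBE_LEFT, -1.0), (LABEL_LOBE_RIGHT, +1.0)):
        center = np.array([sign * half_sep, front_y, 0.0]) + off
        origin = center + lo - _BBOX_MARGIN_MM  # tank-frame mm of lobe grid corner
        idx0 = np.round((origin + np.array([semi_x, semi_y, length / 2.0])) / voxel_size).astype(int)
        sl = tuple(slice(idx0[i], idx0[i] + lobe_mask.shape[i]) for i in range(3))
        if any(s.start < 0 or s.stop > grid.shape[i] for i, s in enumerate(sl)):
            raise GeometryError("lobe extends outside the voxel grid / tank region")
        sub = grid[sl]
        if np.any(sub[lobe_mask] == LABEL_OUTSIDE):
            raise GeometryError("lobe voxels fall outside the tank interior")
        if np.any(sub[lobe_mask] >= LABEL_LOBE_LEFT):
            raise GeometryError("the two lobes overlap")
        sub[lobe_mask] = label

    return PhantomModel(label_grid=grid, voxel_size=voxel_size,
                        tank_volume=tank_volume, arrangement=arrangement)


@dataclass
class ActivityMap:
    """Per-voxel activity concentration (Bq/mL) over a PhantomModel's grid."""

    concentration_grid: np.ndarray  # float64, Bq/mL
    voxel_size: float  # mm
    target_concentration: float  # Bq/mL in the lobes
    background_concentration: float  # Bq/mL in the tank
    tb_ratio: float

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    @property
    def total_activity_bq(self) -> float:
        return float(self.concentration_grid.sum(dtype=np.float64)) * self.voxel_volume_ml

    def save_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.concentration_grid.astype(np.float32), affine), path)


def assign_activity(model: PhantomModel, target_conc: float, tb_ratio: float) -> ActivityMap:
    """Fill lobes at ``target_conc`` Bq/mL and tank at ``target_conc / tb_ratio``."""
    if target_conc <= 0:
        raise InvalidParameterError("target_conc must be positive")
    if tb_ratio <= 1:
        raise InvalidParameterError(f"tb_ratio must exceed 1, got {tb_ratio}")
    background = target_conc / tb_ratio
    conc = np.zeros(model.label_grid.shape, dtype=np.float64)
    conc[model.label_grid == LABEL_TANK] = background
    conc[model.label_grid >= LABEL_LOBE_LEFT] = target_conc
    return ActivityMap(concentration_grid=conc, voxel_size=model.voxel_size,
                       target_concentration=target_conc,
                       background_concentration=background, tb_ratio=tb_ratio)


def voxelize_patient_thyroid(record, voxel_size: float = 1.0,
                             gap: float = 8.0, margin: float = 40.0) -> PhantomModel:
    """Two-ellipsoid digital thyroid for one synthetic patient.

    Each lobe is an ellipsoid with axes (L, W, T) in cm — craniocaudal length,
    transverse width, anteroposterior thickness — so its volume is the
    ultrasound ellipsoid formula pi/6 * L * W * T.  The lobes sit side by side
    (``gap`` mm between surfaces) in a uniform background box (the "neck"),
    which takes the tank label so the imaging emulator can be reused unchanged.
    """
    dims = [record.L1, record.W1, record.T1, record.L2, record.W2, record.T2]
    if any(d <= 0 for d in dims):
        raise InvalidParameterError(f"all six lobe dimensions must be positive, got {dims}")
    if not 0 < voxel_size <= 2.0:
        raise InvalidParameterError("voxel_size must be in (0, 2] mm")

    # semi-axes in mm, per lobe, in grid order (x=width, y=thickness, z=length)
    semis = [np.array([record.W1, record.T1, record.L1]) * 10.0 / 2.0,
             np.array([record.W2, record.T2, record.L2]) * 10.0 / 2.0]
    half_sep = [gap / 2.0 + s[0] for s in semis]
    ext_x = sum(half_sep) + semis[0][0] + semis[1][0]
    ext_y = 2 * max(s[1] for s in semis)
    ext_z = 2 * max(s[2] for s in semis)
    size = np.array([ext_x, ext_y, ext_z]) + 2 * margin
    n = np.ceil(size / voxel_size).astype(int)
    grid = np.full(tuple(n), LABEL_TANK, dtype=np.uint8)

    ax = [((np.arange(n[i]) + 0.5) * voxel_size - n[i] * voxel_size / 2.0) for i in range(3)]
    x, y, z = ax[0][:, None, None], ax[1][None, :, None], ax[2][None, None, :]
    for label, sign, s in ((LABEL_LOBE_RIGHT, +1.0, semis[0]), (LABEL_LOBE_LEFT, -1.0, semis[1])):
        cxl = sign * half_sep[0 if sign > 0 else 1]
        inside = (((x - cxl) / s[0]) ** 2 + (y / s[1]) ** 2 + (z / s[2]) ** 2) <= 1.0
        grid[inside] = label

    box_volume_ml = float(np.prod(n)) * voxel_size**3 / 1000.0
    return PhantomModel(label_grid=grid, voxel_size=voxel_size, tank_volume=box_volume_ml)
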