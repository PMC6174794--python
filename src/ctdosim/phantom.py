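"""Voxelized computational phantoms.

Builds transport phantoms from CT-like Hounsfield volumes via a piecewise
HU -> (density, material) calibration table, rasterizes planar organ contours
into voxel masks, computes the patient effective diameter, and constructs the
water CTDI calibration cylinder with its central chamber volume.

Conventions: 0-based voxel indices; a voxel's value refers to its center;
all physical coordinates in mm with z along the scanner (table) axis; arrays
are indexed ``[ix, iy, iz]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .physics import MATERIAL_NAMES

__all__ = [
    "MaterialTable",
    "VoxelPhantom",
    "OrganMask",
    "BodyContour",
    "DEFAULT_MATERIAL_TABLE",
    "build_from_hu",
    "rasterize_contours",
    "effective_diameter",
    "make_ctdi_phantom",
]

ORGAN_NAMES = ("heart", "lungs", "esophagus", "trachea", "spinal_cord", "skin", "body")


@dataclass(frozen=True)
class MaterialTable:
    """Piecewise HU calibration: linear in density, constant in material id.

    ``breakpoints`` is an ordered list of ``(hu, density_g_cm3, material)``
    with strictly increasing HU and positive densities; the material of a
    voxel is that of the segment its HU falls in, the density is linearly
    interpolated between breakpoints and clamped at the extremes.
    """

    breakpoints: tuple

    def __post_init__(self):
        hus = [b[0] for b in self.breakpoints]
        if len(hus) < 2:
            raise ValueError("material table needs at least two breakpoints")
        if any(b >= a for b, a in zip(hus, hus[1:])):
            raise ValueError("HU breakpoints must be strictly increasing")
        if any(b[1] <= 0 for b in self.breakpoints):
            raise ValueError("densities must be positive")
        for _, _, mat in self.breakpoints:
            if mat not in MATERIAL_NAMES:
                raise ValueError(f"unknown material {mat!r}")

    @property
    def hu(self):
        return np.array([b[0] for b in self.breakpoints], dtype=float)

    @property
    def density(self):
        return np.array([b[1] for b in self.breakpoints], dtype=float)

    def density_of(self, hu):
        return np.interp(np.asarray(hu, dtype=float), self.hu, self.density)

    def material_of(self, hu):
        """Material id (index into :data:`ctdosim.physics.MATERIAL_NAMES`)."""
        ids = np.array([MATERIAL_NAMES.index(b[2]) for b in self.breakpoints])
        seg = np.clip(np.searchsorted(self.hu, np.asarray(hu, float), side="right") - 1,
                      0, len(ids) - 1)
        return ids[seg].astype(np.int16)


#: Default four-segment calibration (air / lung / soft tissue / bone) with the
#: intermediate anchors placed on the air-water line, so any HU in
#: [-1000, 0] maps to density 0.0012 + (HU + 1000)/1000 * 0.9988.
DEFAULT_MATERIAL_TABLE = MaterialTable(breakpoints=(
    (-1000.0, 0.00120, "air"),
    (-850.0, 0.15102, "lung"),
    (-200.0, 0.80024, "soft_tissue"),
    (0.0, 1.00000, "soft_tissue"),
    (120.0, 1.07600, "bone"),
    (1500.0, 1.92000, "bone"),
))


@dataclass
class VoxelPhantom:
    """Density + material-index grids with geometry; the transport medium."""

    density: np.ndarray  # (nx, ny, nz), g/cm^3
    material: np.ndarray  # (nx, ny, nz), int material ids
    spacing: np.ndarray  # (dx, dy, dz) mm
    origin: np.ndarray  # (x, y, z) of the corner of voxel (0,0,0), mm

    def __post_init__(self):
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        self.material = np.ascontiguousarray(self.material, dtype=np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.density.shape != self.material.shape:
            raise ValueError("density and material grids must be congruent")
        if self.density.ndim != 3:
            raise ValueError("phantom grids must be 3-D")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def shape(self):
        return self.density.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-3

    @property
    def mass_g(self) -> np.ndarray:
        """Per-voxel mass (g)."""
        return self.density * self.voxel_volume_cm3

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    @property
    def extent(self):
        """((xmin, xmax), (ymin, ymax), (zmin, zmax)) of the grid, mm."""
        hi = self.origin + np.array(self.shape) * self.spacing
        return tuple((float(self.origin[i]), float(hi[i])) for i in range(3))


@dataclass
class OrganMask:
    """Named boolean mask congruent with its phantom."""

    name: str
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.ascontiguousarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"organ mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BodyContour:
    """One closed planar polygon (mm) at axial position ``z``."""

    vertices: np.ndarray  # (n, 2)
    z: float

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 planar vertices")
        if not self.polygon.is_valid:
            raise ValueError("contour polygon must be simple (non-self-intersecting)")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def area_mm2(self) -> float:
        return float(self.polygon.area)


def build_from_hu(hu: np.ndarray, spacing, origin,
                  table: MaterialTable = DEFAULT_MATERIAL_TABLE) -> VoxelPhantom:
    """Convert a HU volume into a transport phantom via the calibration table."""
    hu = np.asarray(hu, dtype=float)
    if hu.ndim != 3:
        raise ValueError("HU volume must be 3-D")
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume contains non-finite values")
    return VoxelPhantom(
        density=table.density_of(hu),
        material=table.material_of(hu),
        spacing=spacing,
        origin=origin,
    )


def rasterize_contours(contours, phantom: VoxelPhantom, name: str) -> OrganMask:
    """Voxelize per-slice polygons: a voxel belongs to the organ iff its
    center lies strictly inside the polygon of its slice (boundary points are
    excluded; this fixed convention makes ties deterministic). Slices without
    a polygon stay empty.
    """
    if isinstance(contours, BodyContour):
        contours = [contours]
    mask = np.zeros(phantom.shape, dtype=bool)
    zc = phantom.centers(2)
    dz = phantom.spacing[2]
    xs = phantom.centers(0)
    ys = phantom.centers(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    for contour in contours:
        k = int(np.argmin(np.abs(zc - contour.z)))
        if abs(zc[k] - contour.z) > dz / 2 + 1e-9:
            continue  # polygon lies between/outside slices
        inside = shapely.contains_xy(contour.polygon, gx.ravel(), gy.ravel())
        mask[:, :, k] |= inside.reshape(gx.shape)
    if not mask.any():
        raise ValueError(f"rasterization of {name!r} produced an empty mask "
                         "(contours outside the phantom grid?)")
    return OrganMask(name=name, mask=mask)


def effective_diameter(contour: BodyContour) -> float:
    """Diameter (mm) of the circle with the same area as the body contour,
    ``2 sqrt(A / pi)`` with A from the polygon area."""
    area = contour.area_mm2
    if area <= 0:
        raise ValueError("degenerate contour: non-positive area")
    return 2.0 * math.sqrt(area / math.pi)


def make_ctdi_phantom(diameter_mm: float = 160.0, length_mm: float = 150.0,
                      voxel_mm: float = 1.0, chamber_radius_mm: float = 3.05,
                      chamber_length_mm: float = 24.4,
                      surround: str = "air"):
    """Homogeneous water CTDI cylinder + central ionization-chamber mask.

    The cylinder axis coincides with the scanner axis (z) and is centered at
    x = y = 0; the chamber volume is a coaxial cylinder at the phantom center
    emulating the active volume of a farmer-type chamber at isocenter.

    Returns ``(phantom, chamber_mask)``. The nominal chamber volume in cm^3 is
    ``pi * r^2 * L / 1000``.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("diameter and length must be positive")
    if voxel_mm > diameter_mm / 8:
        raise ValueError("voxel size too coarse to resolve the chamber volume")
    r = diameter_mm / 2.0
    nxy = int(math.ceil(diameter_mm / voxel_mm)) + 2
    nz = int(math.ceil(length_mm / voxel_mm))
    spacing = np.array([voxel_mm] * 3)
    origin = np.array([-nxy * voxel_mm / 2.0, -nxy * voxel_mm / 2.0, 0.0])
    x = origin[0] + (np.arange(nxy) + 0.5) * voxel_mm
    z = (np.arange(nz) + 0.5) * voxel_mm
    gx, gy = np.meshgrid(x, x, indexing="ij")
    in_cyl = (gx**2 + gy**2) <= r**2
    density = np.empty((nxy, nxy, nz))
    material = np.empty((nxy, nxy, nz), dtype=np.int16)
    air_id = MATERIAL_NAMES.index(surround)
    water_id = MATERIAL_NAMES.index("water")
    density[...] = 0.00120 if surround == "air" else 1.0
    material[...] = air_id
    density[in_cyl, :] = 1.0
    material[in_cyl, :] = water_id
    phantom = VoxelPhantom(density=density, material=material,
                           spacing=spacing, origin=origin)
    zc = length_mm / 2.0
    in_ch = (gx**2 + gy**2) <= chamber_radius_mm**2
    in_len = np.abs(z - zc) <= chamber_length_mm / 2.0
    chamber = in_ch[:, :, None] & in_len[None, None, :]
    if not chamber.any():
        raise ValueError("chamber volume unresolved at this voxel size")
    return phantom, OrganMask(name="chamber", mask=chamber)
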