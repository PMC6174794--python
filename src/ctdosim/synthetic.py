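"""Synthetic thorax phantoms, patient cohorts and organ-dose tables.

These generators give every pipeline stage a realistic, fully reproducible
input without any external data. The thorax is a stylized parametric
anatomy -- an elliptical soft-tissue body cylinder with two ellipsoidal
lungs, an ellipsoidal heart, a vertebral bone annulus around the spinal
cord, air-lumen trachea and soft-tissue esophagus tubes, and a skin shell --
sized so the recomputed effective diameter matches the requested one. Organ
shapes are quadrics and tubes, not anatomical meshes: the downstream
contracts need relative dose ordering and mask bookkeeping, not anatomy.

Cohorts emulate the demographic structure of a thoracic radiotherapy
population: effective diameters spanning 184.5-465.1 mm, ages 6-93, and a
balanced sex split. Diameters default to a stratified draw (evenly spaced
quantiles of the uniform range, shuffled) so the cohort has uniform density
and deterministically covers the stated extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import (DEFAULT_MATERIAL_TABLE, BodyContour, MaterialTable,
                      OrganMask, VoxelPhantom, build_from_hu, effective_diameter)

__all__ = [
    "ThoraxSpec",
    "CohortSpec",
    "make_thorax_phantom",
    "make_cohort",
    "make_dose_table",
    "organ_scan_range",
    "DOSE_SIZE_COEFFS",
    "DIAMETER_RANGE_MM",
    "AGE_RANGE_Y",
]

DIAMETER_RANGE_MM = (184.5, 465.1)
AGE_RANGE_Y = (6.0, 93.0)

#: Cohort-level linear dose-size coefficients (intercept cGy, slope cGy/mm)
#: for a 120 kV / 100 mAs thoracic protocol, per organ and protocol arm.
#: Used as generating truth for fast regression fixtures.
DOSE_SIZE_COEFFS = {
    ("trachea", "3DCT"): (2.43, -0.0045),
    ("trachea", "4DCT"): (30.95, -0.0574),
    ("lungs", "3DCT"): (2.04, -0.0039),
    ("lungs", "4DCT"): (25.90, -0.0491),
    ("spinal_cord", "3DCT"): (1.91, -0.0035),
    ("spinal_cord", "4DCT"): (24.24, -0.0435),
    ("esophagus", "3DCT"): (2.21, -0.0042),
    ("esophagus", "4DCT"): (29.17, -0.0559),
    ("heart", "3DCT"): (2.27, -0.0044),
    ("heart", "4DCT"): (29.43, -0.0576),
    ("skin", "3DCT"): (1.63, -0.0030),
    ("skin", "4DCT"): (17.17, -0.0278),
}

# HU assignments for the stylized anatomy (mapped through the default
# material table: lung HU -741 -> 0.26 g/cm^3).
_HU = {"air": -1000.0, "lung": -741.0, "soft": 0.0, "cord": 30.0,
       "esophagus": 20.0, "bone": 700.0}


@dataclass(frozen=True)
class ThoraxSpec:
    """Geometry parameters of one synthetic thorax."""

    effective_diameter_mm: float = 300.0
    ap_lat_ratio: float = 0.75  # anterior-posterior / lateral extent
    length_mm: float = 200.0
    voxel_mm: float = 4.0
    skin_thickness_mm: float = 4.0
    lung_density: float = 0.26

    def __post_init__(self):
        if not 100.0 <= self.effective_diameter_mm <= 600.0:
            raise ValueError("effective diameter must be within [100, 600] mm")
        if self.skin_thickness_mm < self.voxel_mm:
            raise ValueError("skin thickness must be at least one voxel")

    @property
    def semi_axes_mm(self):
        """(lateral, AP) semi-axes of the body ellipse."""
        a = self.effective_diameter_mm / (2.0 * math.sqrt(self.ap_lat_ratio))
        return a, self.ap_lat_ratio * a


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic patient cohort."""

    n_patients: int = 102
    diameter_range_mm: tuple = DIAMETER_RANGE_MM
    diameter_distribution: str = "stratified"  # "stratified" | "uniform"
    age_range_y: tuple = AGE_RANGE_Y
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.diameter_range_mm[1] <= self.diameter_range_mm[0] \
                or self.age_range_y[1] <= self.age_range_y[0]:
            raise ValueError("invalid range")


def _ellipse_mask(gx, gy, cx, cy, ax_, ay_):
    return ((gx - cx) / ax_) ** 2 + ((gy - cy) / ay_) ** 2 <= 1.0


def make_thorax_phantom(spec: ThoraxSpec = ThoraxSpec(),
                        table: MaterialTable = DEFAULT_MATERIAL_TABLE):
    """Build the stylized thorax.

    Returns ``(phantom, masks, body_contour)`` where ``masks`` maps organ
    name (heart, lungs, esophagus, trachea, spinal_cord, skin, body) to its
    :class:`~ctdosim.phantom.OrganMask`. Organ masks are pairwise disjoint
    except skin, which is the outermost body shell. The y axis points
    posterior (spine side), z along the scanner axis.
    """
    a, b = spec.semi_axes_mm
    v = spec.voxel_mm
    margin = 2 * v
    nx = int(math.ceil(2 * (a + margin) / v))
    ny = int(math.ceil(2 * (b + margin) / v))
    nz = int(round(spec.length_mm / v))
    origin = np.array([-nx * v / 2, -ny * v / 2, 0.0])
    xs = origin[0] + (np.arange(nx) + 0.5) * v
    ys = origin[1] + (np.arange(ny) + 0.5) * v
    zs = (np.arange(nz) + 0.5) * v
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    L = spec.length_mm
    mn = min(a, b)

    body2d = _ellipse_mask(gx, gy, 0, 0, a, b)
    if body2d.sum() < 16:
        raise ValueError("diameter too small for the voxel size")
    body = np.repeat(body2d[:, :, None], nz, axis=2)

    hu = np.full((nx, ny, nz), _HU["air"])
    hu[body] = _HU["soft"]

    def tube(cx, cy, r, z_lo, z_hi):
        in_xy = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
        in_z = (zs >= z_lo) & (zs <= z_hi)
        return in_xy[:, :, None] & in_z[None, None, :] & body

    def ellipsoid(cx, cy, cz, rx, ry, rz):
        m = (((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2)[:, :, None] \
            + (((zs - cz) / rz) ** 2)[None, None, :]
        return (m <= 1.0) & body

    # skin: outermost lateral shell of the body ellipse, reserved first so
    # every interior organ stays disjoint from it
    sa, sb = a - spec.skin_thickness_mm, b - spec.skin_thickness_mm
    inner2d = _ellipse_mask(gx, gy, 0, 0, sa, sb)
    skin = body & ~np.repeat(inner2d[:, :, None], nz, axis=2)
    if not skin.any():
        raise ValueError("skin shell is empty")

    # organs carved in priority order; later shapes yield to earlier ones
    taken = skin.copy()

    def claim(mask, name):
        m = mask & ~taken
        if not m.any():
            raise ValueError(f"organ {name!r} does not fit at this size")
        taken[:] |= m
        return m

    cord = claim(tube(0.0, 0.55 * b, max(0.04 * mn, v), 0, L), "spinal_cord")
    bone = tube(0.0, 0.55 * b, max(0.10 * mn, 2.5 * v), 0, L) & ~cord & ~taken
    taken |= bone
    # trachea = air lumen plus a soft-tissue wall (the contoured structure
    # includes the wall; a pure air lumen would make kerma scoring sparse)
    trachea_lumen = tube(0.0, -0.35 * b, max(0.035 * mn, v), 0.55 * L, L)
    trachea = claim(tube(0.0, -0.35 * b, max(0.035 * mn, v) + max(2.0, v),
                         0.55 * L, L), "trachea")
    trachea_lumen &= trachea
    esophagus = claim(tube(0.0, 0.32 * b, max(0.03 * mn, v), 0, 0.9 * L),
                      "esophagus")
    heart = claim(ellipsoid(0.06 * a, -0.10 * b, 0.45 * L,
                            0.16 * a, 0.20 * b, 0.20 * L), "heart")
    lungs = claim(ellipsoid(0.48 * a, -0.05 * b, 0.5 * L, 0.30 * a, 0.60 * b, 0.42 * L)
                  | ellipsoid(-0.48 * a, -0.05 * b, 0.5 * L,
                              0.30 * a, 0.60 * b, 0.42 * L), "lungs")

    lung_hu = float(np.interp(spec.lung_density, DEFAULT_MATERIAL_TABLE.density,
                              DEFAULT_MATERIAL_TABLE.hu)) \
        if table is not DEFAULT_MATERIAL_TABLE else _HU["lung"]
    hu[lungs] = lung_hu
    hu[heart] = _HU["soft"]
    hu[bone] = _HU["bone"]
    hu[cord] = _HU["cord"]
    hu[esophagus] = _HU["esophagus"]
    hu[trachea] = _HU["soft"]
    hu[trachea_lumen] = _HU["air"]

    phantom = build_from_hu(hu, spacing=(v, v, v), origin=origin, table=table)
    masks = {
        "body": OrganMask("body", body),
        "skin": OrganMask("skin", skin),
        "lungs": OrganMask("lungs", lungs),
        "heart": OrganMask("heart", heart),
        "esophagus": OrganMask("esophagus", esophagus),
        "trachea": OrganMask("trachea", trachea),
        "spinal_cord": OrganMask("spinal_cord", cord),
    }
    theta = np.linspace(0, 2 * math.pi, 257)[:-1]
    contour = BodyContour(
        vertices=np.column_stack([a * np.cos(theta), b * np.sin(theta)]),
        z=float(zs[nz // 2]))
    measured = effective_diameter(contour)
    if abs(measured - spec.effective_diameter_mm) > 0.02 * spec.effective_diameter_mm:
        raise AssertionError("generated contour fails the 2% diameter check")
    return phantom, masks, contour


def organ_scan_range(masks: dict, phantom: VoxelPhantom,
                     margin_mm: float = 20.0, organs=None):
    """(z_start, z_end) covering the organ masks plus a margin, clipped to
    the phantom."""
    organs = organs or [n for n in masks if n not in ("body", "skin")]
    zc = phantom.centers(2)
    lo, hi = np.inf, -np.inf
    for name in organs:
        kz = np.where(masks[name].mask.any(axis=(0, 1)))[0]
        lo = min(lo, zc[kz[0]] - phantom.spacing[2] / 2)
        hi = max(hi, zc[kz[-1]] + phantom.spacing[2] / 2)
    zmin, zmax = phantom.extent[2]
    return max(zmin, lo - margin_mm), min(zmax, hi + margin_mm)


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Generate the patient table: patient_id, effective_diameter_mm, age, sex.

    Deterministic given the spec's seed. With an even patient count and a
    50/50 split the sexes are exactly balanced.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    lo, hi = spec.diameter_range_mm
    if spec.diameter_distribution == "stratified":
        d = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
        rng.shuffle(d)
    elif spec.diameter_distribution == "uniform":
        d = rng.uniform(lo, hi, n)
    else:
        raise ValueError("diameter_distribution must be 'stratified' or 'uniform'")
    ages = rng.uniform(*spec.age_range_y, n)
    n_f = int(round(spec.female_fraction * n))
    sexes = np.array(["female"] * n_f + ["male"] * (n - n_f))
    rng.shuffle(sexes)
    return pd.DataFrame({
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "effective_diameter_mm": d,
        "age": ages,
        "sex": sexes,
    })


def make_dose_table(cohort: pd.DataFrame,
                    coeffs: dict = None,
                    noise_rel_sd: float = 0.10,
                    seed: int = 0) -> pd.DataFrame:
    """Fast organ-dose fixture: dose = intercept + slope * diameter + noise.

    ``coeffs`` maps (organ, protocol) to (intercept_cGy, slope_cGy_per_mm);
    defaults to :data:`DOSE_SIZE_COEFFS`. Gaussian noise has standard
    deviation ``noise_rel_sd`` times the cohort-mean dose of that organ and
    protocol; doses are floored at zero. Enables regression and risk tests
    without running the transport engine.
    """
    coeffs = DOSE_SIZE_COEFFS if coeffs is None else coeffs
    rng = np.random.default_rng(seed)
    rows = []
    d = cohort["effective_diameter_mm"].to_numpy()
    for (organ, protocol), (b0, b1) in coeffs.items():
        mean = b0 + b1 * d
        sd = noise_rel_sd * abs(mean.mean())
        dose = np.clip(mean + rng.normal(0.0, sd, len(d)) if sd > 0 else mean,
                       0.0, None)
        for i, row in cohort.iterrows():
            rows.append({
                "patient_id": row["patient_id"], "organ": organ,
                "protocol": protocol, "dose_cGy": dose[i],
                "sigma_cGy": sd,
                "effective_diameter_mm": row["effective_diameter_mm"],
                "age": row["age"], "sex": row["sex"],
            })
    return pd.DataFrame(rows)
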