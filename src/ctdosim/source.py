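"""kV source model and discretized CT trajectories.

A CT acquisition is represented as an ordered list of discrete beam fields:
12 coplanar fields per 360-degree rotation at 30-degree intervals. In axial
(3DCT) mode all 12 fields of a rotation share one isocenter z and successive
rotations step by the total collimation width W (contiguous coverage). In
helical (4DCT) mode the isocenter advances by ``pitch * W / 12`` between
consecutive fields, so the fluence delivered per unit scan length scales as
1/pitch at fixed per-rotation mAs.

The photon source is an extended circular focal spot at the X-ray target,
emitting a fan beam (uniform in-plane fan angle, uniform longitudinal
collimation aperture) aimed through the isocenter, with energies drawn from a
tabulated spectrum. The packaged 120 kVp spectrum is computed from a filtered
Kramers tungsten-anode model (2.5 mm Al inherent filtration) with K
characteristic lines; see :func:`tungsten_spectrum`.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .physics import aluminium_mu_rho

__all__ = [
    "ScanProtocol",
    "SourceModel",
    "BeamField",
    "axial_fields",
    "helical_fields",
    "sample_photon",
    "load_spectrum",
    "tungsten_spectrum",
    "PROTOCOL_3DCT",
    "PROTOCOL_4DCT",
]

FIELDS_PER_ROTATION = 12
ANGLE_STEP_DEG = 360.0 / FIELDS_PER_ROTATION


@dataclass(frozen=True)
class ScanProtocol:
    """One scan protocol: tube settings, collimation, pitch and z range."""

    kvp: float = 120.0
    mas: float = 100.0  # per rotation
    collimation: tuple = (16, 1.5)  # n_slices x slice width (mm)
    pitch: float | None = None  # dimensionless; helical only
    rotation_time_s: float = 0.44
    mode: str = "axial"  # "axial" | "helical"
    scan_range: tuple = (0.0, 100.0)  # (z_start, z_end) mm

    def __post_init__(self):
        if self.mode not in ("axial", "helical"):
            raise ValueError("mode must be 'axial' or 'helical'")
        if self.mode == "helical" and (self.pitch is None or self.pitch <= 0):
            raise ValueError("helical mode requires pitch > 0")
        if self.beam_width_mm <= 0:
            raise ValueError("total collimation width must be positive")
        if self.scan_range[1] < self.scan_range[0]:
            raise ValueError("scan_range must satisfy z_end >= z_start")

    @property
    def beam_width_mm(self) -> float:
        """Total longitudinal collimation W = n_slices * slice_width."""
        n, w = self.collimation
        return n * w

    @property
    def field_weight(self) -> float:
        """Relative fluence weight of one field, mAs_per_rotation / 12."""
        return self.mas / FIELDS_PER_ROTATION

    @property
    def protocol_id(self) -> str:
        n, w = self.collimation
        p = "ax" if self.mode == "axial" else f"p{self.pitch:g}"
        return f"{self.mode}-{self.kvp:g}kVp-{n}x{w:g}mm-{p}"


#: Thoracic protocols: 120 kV, 100 mAs, 0.44 s rotation; the 4DCT arm is the
#: low-pitch helical acquisition (pitch 0.059), the 3DCT arm contiguous axial.
PROTOCOL_4DCT = ScanProtocol(kvp=120, mas=100, collimation=(16, 1.5), pitch=0.059,
                             rotation_time_s=0.44, mode="helical")
PROTOCOL_3DCT = ScanProtocol(kvp=120, mas=100, collimation=(16, 1.5), pitch=None,
                             rotation_time_s=0.44, mode="axial")


@dataclass(frozen=True)
class SourceModel:
    """Spectrum + fan-beam geometry of the kV source."""

    spectrum_kev: np.ndarray
    spectrum_fluence: np.ndarray  # relative, normalized to unit sum
    sad_mm: float = 645.0  # source-to-axis distance
    fan_half_deg: float = 28.0
    focal_radius_mm: float = 1.0
    beam_width_mm: float = 24.0  # longitudinal width at isocenter (= W)

    def __post_init__(self):
        e = np.asarray(self.spectrum_kev, dtype=float)
        f = np.asarray(self.spectrum_fluence, dtype=float)
        if e.size == 0 or f.size != e.size:
            raise ValueError("empty or mismatched spectrum")
        if np.any(f < 0) or f.sum() <= 0:
            raise ValueError("spectrum fluences must be >= 0 and not all zero")
        object.__setattr__(self, "spectrum_kev", e)
        object.__setattr__(self, "spectrum_fluence", f / f.sum())

    @property
    def mean_energy_kev(self) -> float:
        return float(np.sum(self.spectrum_kev * self.spectrum_fluence))

    @classmethod
    def for_protocol(cls, protocol: ScanProtocol, **kwargs) -> "SourceModel":
        e, f = load_spectrum(protocol.kvp, path=kwargs.pop("spectrum_path", None))
        return cls(spectrum_kev=e, spectrum_fluence=f,
                   beam_width_mm=protocol.beam_width_mm, **kwargs)


@dataclass(frozen=True)
class BeamField:
    """One discretized source position on the trajectory."""

    angle_deg: float
    isocenter_z_mm: float
    weight: float = 1.0
    protocol: ScanProtocol | None = None

    def __post_init__(self):
        object.__setattr__(self, "angle_deg", float(self.angle_deg) % 360.0)


def axial_fields(protocol: ScanProtocol) -> list:
    """Discretized axial (3DCT) trajectory.

    Each rotation contributes 12 fields at 0, 30, ..., 330 degrees sharing one
    isocenter z; rotation centers are spaced by W for contiguous coverage and
    rotations continue until the scan range is covered.
    """
    if protocol.mode != "axial":
        raise ValueError("protocol is not axial")
    z0, z1 = protocol.scan_range
    w = protocol.beam_width_mm
    length = z1 - z0
    n_rot = max(1, math.ceil(length / w))
    if length < w:
        warnings.warn("scan range shorter than one beam width: single rotation",
                      stacklevel=2)
    fields = []
    for r in range(n_rot):
        zc = z0 + w / 2 + r * w
        for i in range(FIELDS_PER_ROTATION):
            fields.append(BeamField(angle_deg=i * ANGLE_STEP_DEG, isocenter_z_mm=zc,
                                    weight=protocol.field_weight, protocol=protocol))
    return fields


def helical_fields(protocol: ScanProtocol, overrange: bool = True) -> list:
    """Discretized helical (4DCT) trajectory.

    Consecutive fields advance 30 degrees in gantry angle and
    ``pitch * W / 12`` in isocenter z. With ``overrange`` (default) the
    trajectory starts half a beam width before the scan range and ends half a
    beam width after it, so edge slices are fully irradiated.
    """
    if protocol.mode != "helical":
        raise ValueError("protocol is not helical")
    if protocol.pitch is None or protocol.pitch <= 0:
        raise ValueError("pitch must be positive")
    w = protocol.beam_width_mm
    dz = protocol.pitch * w / FIELDS_PER_ROTATION
    z0, z1 = protocol.scan_range
    if overrange:
        z0, z1 = z0 - w / 2, z1 + w / 2
    n = int(math.floor((z1 - z0) / dz)) + 1
    zs = z0 + dz * np.arange(n)
    return [BeamField(angle_deg=(i % FIELDS_PER_ROTATION) * ANGLE_STEP_DEG,
                      isocenter_z_mm=float(z), weight=protocol.field_weight,
                      protocol=protocol)
            for i, z in enumerate(zs)]


def sample_photon(source: SourceModel, fld: BeamField, rng: np.random.Generator,
                  n: int = 1, isocenter_xy=(0.0, 0.0)):
    """Sample ``n`` source photons for one beam field.

    Returns ``(position (n,3) mm, direction (n,3) unit, energy (n,) keV,
    weight (n,))``. Energies follow the discrete spectrum; emission points
    are uniform on the focal disc; directions are uniform over the in-plane
    fan angle and the longitudinal collimation aperture at the isocenter.
    """
    if source.spectrum_kev.size == 0:
        raise ValueError("empty spectrum")
    cdf = np.cumsum(source.spectrum_fluence)
    e = source.spectrum_kev[np.searchsorted(cdf, rng.random(n), side="left")]
    ang = math.radians(fld.angle_deg)
    u = np.array([math.cos(ang), math.sin(ang), 0.0])  # iso -> source
    v = np.array([-math.sin(ang), math.cos(ang), 0.0])  # in-plane perpendicular
    iso = np.array([isocenter_xy[0], isocenter_xy[1], fld.isocenter_z_mm])
    s0 = iso + source.sad_mm * u
    # focal disc perpendicular to the central ray (spanned by v and z)
    rr = source.focal_radius_mm * np.sqrt(rng.random(n))
    ph = 2 * np.pi * rng.random(n)
    pos = s0[None, :] + rr[:, None] * (np.cos(ph)[:, None] * v[None, :])
    pos[:, 2] += rr * np.sin(ph)
    # aim points in the collimated aperture at the isocenter plane
    fan = math.radians(source.fan_half_deg) * (2 * rng.random(n) - 1)
    tu = source.sad_mm * np.tan(fan)
    tz = fld.isocenter_z_mm + source.beam_width_mm * (rng.random(n) - 0.5)
    tgt = iso[None, :] + tu[:, None] * v[None, :]
    tgt[:, 2] = tz
    d = tgt - pos
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return pos, d, e.astype(float), np.ones(n)


def tungsten_spectrum(kvp: float = 120.0, al_filtration_mm: float = 7.0):
    """Filtered-Kramers tungsten-anode spectrum on a 1 keV grid.

    Photon fluence ~ (kVp - E)/E attenuated by the aluminium-equivalent
    total filtration (CT scanners filter far more heavily than radiographic
    tubes; ~7 mm Al equivalent is typical of a body beam without the bowtie),
    plus tungsten K characteristic lines (for kVp above the K edge at
    69.5 keV) carrying ~9% of the total fluence in the usual
    Kalpha1 : Kalpha2 : Kbeta1 : Kbeta2 proportions. Returns
    ``(energies_kev, fluence)`` normalized to unit sum.
    """
    if kvp < 30 or kvp > 150:
        raise ValueError("supported kVp range is 30-150")
    e = np.arange(10.0, math.floor(kvp) + 1.0)
    flu = np.clip(kvp - e, 0.0, None) / e
    t_g_cm2 = 0.1 * al_filtration_mm * 2.699  # mm -> cm, x density
    flu *= np.exp(-aluminium_mu_rho(e) * t_g_cm2)
    if kvp > 69.5:
        lines = {59.0: 100.0, 58.0: 57.0, 67.0: 22.0, 69.0: 8.0}
        lw = np.zeros_like(e)
        for le, rel in lines.items():
            lw[int(le - e[0])] = rel
        flu = flu / flu.sum() * 0.91 + lw / lw.sum() * 0.09
    return e, flu / flu.sum()


def load_spectrum(kvp: float = 120.0, path=None):
    """Load a spectrum table: ``(energies_kev, fluence)`` normalized to unit sum.

    With ``path`` given, reads a two-column text file (energy keV, relative
    fluence; '#' comments). Otherwise the packaged 120 kVp table is returned;
    other tube potentials require a user-supplied table.
    """
    if path is not None:
        data = np.loadtxt(path, comments="#")
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError("spectrum file must have two columns")
        e, f = data[:, 0], data[:, 1]
    elif kvp == 120.0:
        ref = importlib.resources.files("ctdosim.data") / "spectrum_120kvp.tsv"
        with importlib.resources.as_file(ref) as p:
            data = np.loadtxt(p, comments="#")
        e, f = data[:, 0], data[:, 1]
    else:
        raise ValueError(f"no packaged spectrum for {kvp} kVp; supply a table")
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("spectrum fluences must be >= 0 and not all zero")
    return e, f / f.sum()
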