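"""CTDI conversion-factor calibration: per-history Monte Carlo dose -> cGy.

The absolute scale of the simulation is set the way CT dose audits do it:
the same protocol is run against the 16 cm water CTDI cylinder, the mean
simulated dose in the central chamber volume is compared with the measured
chamber dose, and their ratio (per unit beam weight) becomes the conversion
factor applied to patient simulations of the same protocol.

No physical chamber exists in this package: "measured" values come from user
configuration when real audit data are available, or from the packaged
synthetic fixture value below. The module's contract is the ratio
arithmetic, not metrology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .engine import DoseGrid, energy_to_dose, run_scan
from .phantom import OrganMask, VoxelPhantom, make_ctdi_phantom
from .source import ScanProtocol, SourceModel, axial_fields, helical_fields

__all__ = [
    "CalibrationRecord",
    "calibrate",
    "to_absolute",
    "AbsoluteDoseMap",
    "simulate_chamber_dose",
    "reference_calibration",
    "FIXTURE_MEASURED_CGY",
]

#: Synthetic stand-in for a measured central CTDI chamber dose: cGy for one
#: 360-degree axial rotation of the 120 kVp / 100 mAs protocol on the 16 cm
#: water cylinder. A plausible nominal value for a calibrated chamber
#: reading; it sets only the absolute scale of reported doses.
FIXTURE_MEASURED_CGY = 1.80


@dataclass(frozen=True)
class CalibrationRecord:
    """Conversion factor tying per-history dose to absolute dose.

    ``factor = measured_cgy / (simulated_per_history * scan_weight)`` where
    ``scan_weight`` is the summed field weight (mAs-like) of the calibration
    scan. Records store the protocol identity so factors are never applied
    across protocols without an explicit override.
    """

    protocol_id: str
    measured_cgy: float
    simulated_per_history: float
    scan_weight: float
    factor: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationRecord":
        return cls(**json.loads(text))


def calibrate(measured_cgy: float, simulated_per_history: float,
              protocol: ScanProtocol, scan_weight: float) -> CalibrationRecord:
    """Build a conversion-factor record from a measured/simulated dose pair."""
    if measured_cgy <= 0 or simulated_per_history <= 0 or scan_weight <= 0:
        raise ValueError("measured, simulated and weight must be positive")
    return CalibrationRecord(
        protocol_id=protocol.protocol_id,
        measured_cgy=float(measured_cgy),
        simulated_per_history=float(simulated_per_history),
        scan_weight=float(scan_weight),
        factor=float(measured_cgy / (simulated_per_history * scan_weight)),
    )


@dataclass
class AbsoluteDoseMap:
    """Per-voxel absolute dose (cGy) with per-batch values for uncertainty."""

    values_cgy: np.ndarray
    batch_values_cgy: np.ndarray  # (n_batches, nx, ny, nz)
    spacing: np.ndarray
    origin: np.ndarray
    protocol_id: str


def to_absolute(dose: DoseGrid, phantom: VoxelPhantom, record: CalibrationRecord,
                protocol: ScanProtocol, override: bool = False) -> AbsoluteDoseMap:
    """Scale a per-history dose grid to absolute dose (cGy).

    ``absolute = per_history_dose * factor * scan_weight`` with the scan
    weight taken from the dose grid itself, making absolute dose linear in
    mAs and independent of the number of histories (up to statistics).
    """
    if record.protocol_id != protocol.protocol_id and not override:
        raise ValueError(
            f"calibration {record.protocol_id!r} does not match protocol "
            f"{protocol.protocol_id!r}; pass override=True to force")
    scale = record.factor * dose.total_weight
    per_hist = energy_to_dose(dose, phantom)
    mass = phantom.mass_g
    batch = np.zeros_like(dose.batch_deposits)
    ok = mass > 0
    batch[:, ok] = dose.batch_deposits[:, ok] / mass[ok]
    # each batch, normalized by its own histories, independently estimates the map
    batch /= dose.batch_histories[:, None, None, None].astype(float)
    return AbsoluteDoseMap(values_cgy=per_hist * scale,
                           batch_values_cgy=batch * scale,
                           spacing=dose.spacing, origin=dose.origin,
                           protocol_id=protocol.protocol_id)


def simulate_chamber_dose(protocol: ScanProtocol, source: SourceModel,
                          n_histories: int, seed: int,
                          phantom: VoxelPhantom | None = None,
                          chamber: OrganMask | None = None,
                          voxel_mm: float = 2.0):
    """Mean per-history dose (keV/g/history) in the CTDI chamber volume.

    Builds the default 16 cm water cylinder when none is given, centers the
    protocol's scan range on it, runs the scan and averages the dose over the
    chamber mask. Returns ``(chamber_dose_per_history, dose_grid, phantom)``.
    """
    if phantom is None or chamber is None:
        phantom, chamber = make_ctdi_phantom(voxel_mm=voxel_mm)
    if protocol.mode == "axial":
        fields = axial_fields(protocol)
    else:
        fields = helical_fields(protocol)
    dose = run_scan(phantom, fields, source, n_histories, seed)
    per_hist = energy_to_dose(dose, phantom)
    return float(per_hist[chamber.mask].mean()), dose, phantom


def reference_calibration(measured_cgy: float = FIXTURE_MEASURED_CGY,
                          kvp: float = 120.0, mas: float = 100.0,
                          collimation=(16, 1.5), n_histories: int = 40_000,
                          seed: int = 0, voxel_mm: float = 2.0,
                          source: SourceModel | None = None) -> CalibrationRecord:
    """Calibrate against one axial reference rotation on the CTDI cylinder.

    This is the single-measurement pattern: the factor (cGy per per-history
    unit per mAs of tube output) is a property of the source output, so one
    reference record can be applied to other protocols of the same beam
    quality via the explicit ``override`` flag of :func:`to_absolute`.
    """
    phantom, chamber = make_ctdi_phantom(voxel_mm=voxel_mm)
    zc = phantom.extent[2][1] / 2.0
    w = collimation[0] * collimation[1]
    protocol = ScanProtocol(kvp=kvp, mas=mas, collimation=collimation,
                            mode="axial", scan_range=(zc - w / 2, zc + w / 2))
    if source is None:
        source = SourceModel.for_protocol(protocol)
    sim, dose, _ = simulate_chamber_dose(protocol, source, n_histories, seed,
                                         phantom=phantom, chamber=chamber)
    return calibrate(measured_cgy, sim, protocol, dose.total_weight)
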