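"""Monte Carlo photon transport through voxel phantoms (kerma scoring).

Two transport routes are provided:

* :func:`run_scan` -- the production path: a compiled Woodcock
  (delta-tracking) kernel transporting batched histories for a whole beam
  trajectory, with per-batch variance accumulators;
* :func:`trace` -- a readable single-photon reference transport using exact
  voxel-by-voxel ray traversal (Amanatides-Woo stepping) and the same
  interaction physics, used to cross-check the compiled kernel.

Dose is scored in the kerma approximation: the energy transferred to
electrons is deposited at the photon interaction site. At 120 kVp photon
energies the secondary-electron ranges are well below typical voxel sizes,
so electron transport (and the corresponding ECUT setting) is configuration
metadata rather than simulated physics. The photon tracking cutoff is
PCUT = 10 keV: photons at or below it deposit locally and stop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .phantom import OrganMask, VoxelPhantom
from .physics import MEC2_KEV, CrossSectionLibrary, build_default_library
from .source import BeamField, SourceModel

__all__ = [
    "Photon",
    "DoseGrid",
    "run_scan",
    "trace",
    "relative_uncertainty",
    "energy_to_dose",
    "PCUT_KEV",
]

PCUT_KEV = 10.0


@dataclass
class Photon:
    """Transport state of a single photon."""

    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    energy_kev: float
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.alive and self.energy_kev <= 0:
            raise ValueError("live photon must have positive energy")


@dataclass
class DoseGrid:
    """Per-voxel energy deposits with history-batched variance accumulators.

    ``batch_deposits`` holds the raw energy deposit (keV) of each batch;
    scalar per-batch emitted/deposited/escaped energies support the energy
    conservation contract. ``total_weight`` is the summed beam-field weight
    of the scan (mAs-like), used by the calibration module for absolute dose.
    """

    batch_deposits: np.ndarray  # (n_batches, nx, ny, nz), keV
    batch_histories: np.ndarray  # (n_batches,)
    batch_emitted: np.ndarray
    batch_escaped: np.ndarray
    mass_g: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray
    origin: np.ndarray
    total_weight: float
    seed: int
    n_aborted: int = 0

    @property
    def n_histories(self) -> int:
        return int(self.batch_histories.sum())

    @property
    def n_batches(self) -> int:
        return self.batch_deposits.shape[0]

    @property
    def deposit_kev(self) -> np.ndarray:
        """Total energy deposit per voxel (keV)."""
        return self.batch_deposits.sum(axis=0)

    @property
    def per_history_deposit_kev(self) -> np.ndarray:
        return self.deposit_kev / self.n_histories

    def energy_balance(self):
        """Per-batch (emitted, deposited + escaped) energies in keV."""
        dep = self.batch_deposits.reshape(self.n_batches, -1).sum(axis=1)
        return self.batch_emitted, dep + self.batch_escaped


def _xs_arrays(xs: CrossSectionLibrary):
    emin = float(xs.energies_kev[0])
    return (np.ascontiguousarray(xs.total), np.ascontiguousarray(xs.photoelectric),
            np.ascontiguousarray(xs.incoherent), np.ascontiguousarray(xs.coherent),
            emin)


def majorant_attenuation(phantom: VoxelPhantom, xs: CrossSectionLibrary) -> np.ndarray:
    """Per-energy majorant linear attenuation (1/mm) over the whole phantom."""
    mu_max = np.zeros(xs.energies_kev.size)
    for m in np.unique(phantom.material):
        dmax = float(phantom.density[phantom.material == m].max())
        mu_max = np.maximum(mu_max, xs.total[int(m)] * dmax * 0.1)
    return np.maximum(mu_max, 1e-12)


def run_scan(phantom: VoxelPhantom, fields, source: SourceModel,
             n_histories: int, seed: int, n_batches: int = 10,
             xs: CrossSectionLibrary | None = None,
             isocenter_xy=(0.0, 0.0), pcut_kev: float = PCUT_KEV) -> DoseGrid:
    """Simulate a scan: transport ``n_histories`` photons over the trajectory.

    Histories are allocated to beam fields proportional to their weight; the
    result is deterministic given ``seed``. Deposits are collected in
    ``n_batches`` history batches for variance estimation.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    fields = list(fields)
    if not fields:
        raise ValueError("no beam fields supplied")
    weights = np.array([f.weight for f in fields], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total field weight must be positive")
    if xs is None:
        xs = build_default_library()
    tot, pe, inc, coh, emin = _xs_arrays(xs)
    mu_max = majorant_attenuation(phantom, xs)
    angles = np.array([math.radians(f.angle_deg) for f in fields])
    zs = np.array([f.isocenter_z_mm for f in fields])
    field_cdf = np.cumsum(weights) / weights.sum()
    spec_cdf = np.cumsum(source.spectrum_fluence)
    batch_seeds = np.random.SeedSequence(seed).generate_state(n_batches) % (2**31)
    per = n_histories // n_batches
    counts = np.full(n_batches, per, dtype=np.int64)
    counts[: n_histories - per * n_batches] += 1
    counts = counts[counts > 0]
    shape = phantom.shape
    batch_dep = np.zeros((len(counts),) + shape)
    emitted = np.zeros(len(counts))
    escaped = np.zeros(len(counts))
    aborted = 0
    for b, (n_b, s_b) in enumerate(zip(counts, batch_seeds)):
        dep, emit, _, esc, ab = _kernel.run_batch(
            phantom.density, phantom.material, tot, pe, inc, coh, mu_max, emin,
            angles, zs, field_cdf,
            source.spectrum_kev, spec_cdf,
            source.sad_mm, math.radians(source.fan_half_deg),
            source.focal_radius_mm, source.beam_width_mm / 2.0,
            float(isocenter_xy[0]), float(isocenter_xy[1]),
            phantom.origin, phantom.spacing, int(n_b), int(s_b), pcut_kev)
        batch_dep[b] = dep
        emitted[b] = emit
        escaped[b] = esc
        aborted += ab
    if aborted:
        warnings.warn(f"{aborted} histories aborted on non-finite state",
                      stacklevel=2)
    return DoseGrid(batch_deposits=batch_dep, batch_histories=counts,
                    batch_emitted=emitted, batch_escaped=escaped,
                    mass_g=phantom.mass_g, spacing=phantom.spacing.copy(),
                    origin=phantom.origin.copy(), total_weight=float(weights.sum()),
                    seed=seed, n_aborted=int(aborted))


def energy_to_dose(dose: DoseGrid, phantom: VoxelPhantom) -> np.ndarray:
    """Per-voxel dose, keV per gram per history.

    Voxels with zero density and zero deposit map to zero; a deposit inside a
    zero-density voxel is a scoring error and raises.
    """
    dep = dose.per_history_deposit_kev
    if dep.shape != phantom.shape:
        raise ValueError("dose grid and phantom are not congruent")
    mass = phantom.mass_g
    bad = (mass <= 0) & (dep > 0)
    if bad.any():
        raise ValueError("energy deposited in zero-density voxels")
    out = np.zeros_like(dep)
    ok = mass > 0
    out[ok] = dep[ok] / mass[ok]
    return out


def relative_uncertainty(dose: DoseGrid, region: OrganMask) -> float:
    """1-sigma relative standard error of the region's mean dose, from batch
    statistics. Returns NaN (with a warning) if the region mean is zero."""
    if dose.n_batches < 2:
        raise ValueError("need >= 2 batches for an uncertainty estimate")
    m = region.mask
    if m.shape != dose.mass_g.shape:
        raise ValueError("region mask not congruent with dose grid")
    if not m.any():
        raise ValueError("region mask is empty")
    mass = dose.mass_g[m]
    if np.any(mass <= 0):
        raise ValueError("region contains zero-density voxels")
    batch_means = (dose.batch_deposits[:, m] / mass).mean(axis=1) / dose.batch_histories
    mean = batch_means.mean()
    if mean == 0:
        warnings.warn("zero mean dose in region: uncertainty undefined",
                      stacklevel=2)
        return float("nan")
    se = batch_means.std(ddof=1) / math.sqrt(dose.n_batches)
    return float(se / abs(mean))


# ---------------------------------------------------------------------------
# Reference single-photon transport (exact voxel traversal)
# ---------------------------------------------------------------------------


def _compton_py(k: float, rng: np.random.Generator):
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = -math.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if rng.random() * (a1 + a2) < a1:
            eps = eps0 * math.exp(a1 * rng.random())
        else:
            eps = math.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * rng.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if rng.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps, 1.0 - t


def _thomson_py(rng: np.random.Generator) -> float:
    while True:
        c = 2.0 * rng.random() - 1.0
        if 2.0 * rng.random() <= 1.0 + c * c:
            return c


def rotate_direction(u: np.ndarray, cost: float, phi: float) -> np.ndarray:
    """Rotate unit vector ``u`` by polar angle acos(cost) and azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    if abs(u[2]) < 0.99999:
        den = math.sqrt(1.0 - u[2] ** 2)
        n = np.array([
            u[0] * cost + sint * (u[0] * u[2] * math.cos(phi) - u[1] * math.sin(phi)) / den,
            u[1] * cost + sint * (u[1] * u[2] * math.cos(phi) + u[0] * math.sin(phi)) / den,
            u[2] * cost - sint * math.cos(phi) * den,
        ])
    else:
        n = np.array([sint * math.cos(phi), sint * math.sin(phi),
                      cost * (1.0 if u[2] > 0 else -1.0)])
    return n / np.linalg.norm(n)


def _ray_box(pos, d, lo, hi):
    tmin, tmax = 0.0, np.inf
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if pos[a] <= lo[a] or pos[a] >= hi[a]:
                return None
        else:
            t1, t2 = (lo[a] - pos[a]) / d[a], (hi[a] - pos[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin, tmax = max(tmin, t1), min(tmax, t2)
    return (tmin, tmax) if tmin < tmax else None


def trace(photon: Photon, phantom: VoxelPhantom, xs: CrossSectionLibrary,
          rng: np.random.Generator, deposit: np.ndarray,
          pcut_kev: float = PCUT_KEV):
    """Transport one photon by exact voxel stepping, accumulating deposits.

    Returns ``(escaped_energy_kev, events)`` where ``events`` is a list of
    ``(kind, position_mm, energy_deposited_kev)`` tuples for every real
    interaction. Serves as the independent reference for the Woodcock kernel.
    """
    if deposit.shape != phantom.shape:
        raise ValueError("deposit grid not congruent with phantom")
    pos = photon.position.copy()
    d = photon.direction.copy()
    e = float(photon.energy_kev)
    if not np.all(np.isfinite(pos)) or not np.isfinite(e):
        raise ValueError("non-finite photon state")
    lo = phantom.origin
    hi = phantom.origin + np.array(phantom.shape) * phantom.spacing
    events = []
    while True:
        hit = _ray_box(pos, d, lo, hi)
        if hit is None:
            return e, events
        pos = pos + (hit[0] + 1e-9) * d
        remaining = hit[1] - hit[0] - 2e-9
        # walk voxel boundaries, consuming the sampled optical depth
        tau = -math.log(rng.random())
        travelled = 0.0
        interacted = False
        while travelled < remaining:
            idx = np.floor((pos - lo) / phantom.spacing).astype(int)
            idx = np.clip(idx, 0, np.array(phantom.shape) - 1)
            # distance to the next voxel face along d
            t_exit = np.inf
            for a in range(3):
                if abs(d[a]) < 1e-12:
                    continue
                nxt = lo[a] + (idx[a] + (1 if d[a] > 0 else 0)) * phantom.spacing[a]
                t_exit = min(t_exit, (nxt - pos[a]) / d[a])
            t_exit = max(t_exit, 1e-9)
            seg = min(t_exit + 1e-9, remaining - travelled)
            m = int(phantom.material[tuple(idx)])
            mu = float(xs.mu_rho(m, e)) * phantom.density[tuple(idx)] * 0.1  # 1/mm
            if mu * seg >= tau:
                pos = pos + (tau / mu if mu > 0 else seg) * d
                interacted = True
                break
            tau -= mu * seg
            travelled += seg
            pos = pos + seg * d
        if not interacted:
            return e, events
        idx = tuple(np.clip(np.floor((pos - lo) / phantom.spacing).astype(int),
                            0, np.array(phantom.shape) - 1))
        pe = float(xs.mu_rho(phantom.material[idx], e, "photoelectric"))
        inc = float(xs.mu_rho(phantom.material[idx], e, "incoherent"))
        coh = float(xs.mu_rho(phantom.material[idx], e, "coherent"))
        r = rng.random() * (pe + inc + coh)
        if r < pe:
            deposit[idx] += e
            events.append(("photoelectric", pos.copy(), e))
            return 0.0, events
        elif r < pe + inc:
            eps, cost = _compton_py(e / MEC2_KEV, rng)
            edep = e * (1.0 - eps)
            deposit[idx] += edep
            events.append(("compton", pos.copy(), edep))
            e *= eps
            d = rotate_direction(d, cost, 2 * math.pi * rng.random())
            if e <= pcut_kev:
                deposit[idx] += e
                events.append(("cutoff", pos.copy(), e))
                return 0.0, events
        else:
            events.append(("rayleigh", pos.copy(), 0.0))
            d = rotate_direction(d, _thomson_py(rng), 2 * math.pi * rng.random())
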