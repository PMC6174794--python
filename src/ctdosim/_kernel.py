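"""Numba transport kernels: Woodcock (delta) tracking with kerma scoring.

Photons are tracked against the phantom's per-energy majorant attenuation;
at real interactions the transferred energy is deposited at the interaction
site (kerma approximation, no electron transport):

* photoelectric -- full photon energy deposited locally, history ends;
* Compton -- scattered energy sampled from Klein-Nishina (standard
  composition/rejection sampling), the transferred share deposited locally;
* Rayleigh -- direction resampled from the Thomson angular law
  (form factors omitted), no deposit.

Photons at or below PCUT deposit their remaining energy locally; photons
leaving the grid are scored as escaped energy so that per-batch energy
conservation (emitted = deposited + escaped) holds to accumulator precision.
"""

import math

import numpy as np
from numba import njit

MEC2_KEV = 510.99895


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _interp_mat(table, m, e, emin):
    """Linear interpolation of table[m] on the uniform 1 keV grid."""
    x = e - emin
    n = table.shape[1]
    if x <= 0.0:
        return table[m, 0]
    i = int(x)
    if i >= n - 1:
        return table[m, n - 1]
    f = x - i
    return table[m, i] * (1.0 - f) + table[m, i + 1] * f


@njit(cache=True, inline="always")
def _majorant(mu_max, e, emin):
    """Majorant at energy e: max of the bracketing grid bins (safe bound)."""
    x = e - emin
    n = mu_max.shape[0]
    if x <= 0.0:
        return mu_max[0]
    i = int(x)
    if i >= n - 1:
        return mu_max[n - 1]
    a = mu_max[i]
    b = mu_max[i + 1]
    return a if a > b else b


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    """Rotate unit vector u by polar angle acos(cost), azimuth phi."""
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) < 0.99999:
        den = math.sqrt(1.0 - uz * uz)
        nx = ux * cost + sint * (ux * uz * cosp - uy * sinp) / den
        ny = uy * cost + sint * (uy * uz * cosp + ux * sinp) / den
        nz = uz * cost - sint * cosp * den
    else:
        sign = 1.0 if uz > 0.0 else -1.0
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * sign
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _sample_compton(k):
    """Klein-Nishina energy/angle sampling; returns (eps, cos_theta)."""
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = -math.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = eps0 * math.exp(a1 * np.random.random())
        else:
            eps = math.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps, 1.0 - t


@njit(cache=True, inline="always")
def _sample_thomson():
    """cos(theta) from the Thomson law p(c) ~ 1 + c^2."""
    while True:
        c = 2.0 * np.random.random() - 1.0
        if 2.0 * np.random.random() <= 1.0 + c * c:
            return c


@njit(cache=True)
def run_batch(density, material, xs_total, xs_pe, xs_inc, xs_coh, mu_max, emin,
              field_angle, field_z, field_cdf,
              spec_e, spec_cdf,
              sad, fan_half, focal_r, half_w, iso_x, iso_y,
              origin, spacing, n_hist, seed, pcut):
    """Transport one batch of histories; returns
    (deposit grid keV, emitted, deposited, escaped, n_aborted)."""
    np.random.seed(seed)
    nx, ny, nz = density.shape
    dep = np.zeros((nx, ny, nz))
    x0 = origin[0]
    y0 = origin[1]
    z0 = origin[2]
    sx_ = spacing[0]
    sy_ = spacing[1]
    sz_ = spacing[2]
    hx = x0 + nx * sx_
    hy = y0 + ny * sy_
    hz = z0 + nz * sz_
    emitted = 0.0
    deposited = 0.0
    escaped = 0.0
    aborted = 0
    two_pi = 2.0 * math.pi
    for _ in range(n_hist):
        # --- source sampling -------------------------------------------------
        fi = np.searchsorted(field_cdf, np.random.random())
        if fi >= field_angle.shape[0]:
            fi = field_angle.shape[0] - 1
        ang = field_angle[fi]
        fz = field_z[fi]
        si = np.searchsorted(spec_cdf, np.random.random())
        if si >= spec_e.shape[0]:
            si = spec_e.shape[0] - 1
        e = spec_e[si]
        emitted += e
        cosg = math.cos(ang)
        sing = math.sin(ang)
        # central ray unit vectors: u iso->source, v in-plane perpendicular
        px = iso_x + sad * cosg
        py = iso_y + sad * sing
        pz = fz
        vx = -sing
        vy = cosg
        rr = focal_r * math.sqrt(np.random.random())
        ph = two_pi * np.random.random()
        px += rr * math.cos(ph) * vx
        py += rr * math.cos(ph) * vy
        pz += rr * math.sin(ph)
        fan = fan_half * (2.0 * np.random.random() - 1.0)
        tu = sad * math.tan(fan)
        tx = iso_x + tu * vx
        ty = iso_y + tu * vy
        tz = fz + half_w * (2.0 * np.random.random() - 1.0)
        dx = tx - px
        dy = ty - py
        dz = tz - pz
        dn = math.sqrt(dx * dx + dy * dy + dz * dz)
        dx /= dn
        dy /= dn
        dz /= dn
        # --- advance to the grid bounding box --------------------------------
        tmin = 0.0
        tmax = 1.0e30
        ok = True
        for axis in range(3):
            if axis == 0:
                p, d, lo, hi = px, dx, x0, hx
            elif axis == 1:
                p, d, lo, hi = py, dy, y0, hy
            else:
                p, d, lo, hi = pz, dz, z0, hz
            if abs(d) < 1.0e-12:
                if p <= lo or p >= hi:
                    ok = False
                    break
            else:
                t1 = (lo - p) / d
                t2 = (hi - p) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if (not ok) or tmin >= tmax:
            escaped += e
            continue
        adv = tmin + 1.0e-6
        px += adv * dx
        py += adv * dy
        pz += adv * dz
        # --- Woodcock tracking ----------------------------------------------
        alive = True
        steps = 0
        while alive:
            steps += 1
            if steps > 1000000 or not (math.isfinite(px) and math.isfinite(e)):
                aborted += 1
                escaped += e
                break
            mm = _majorant(mu_max, e, emin)
            s = -math.log(np.random.random()) / mm
            px += s * dx
            py += s * dy
            pz += s * dz
            i = int((px - x0) / sx_)
            j = int((py - y0) / sy_)
            k = int((pz - z0) / sz_)
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped += e
                break
            m = material[i, j, k]
            rho = density[i, j, k]
            mu = _interp_mat(xs_total, m, e, emin) * rho * 0.1  # 1/cm -> 1/mm
            if np.random.random() * mm > mu:
                continue  # null collision
            pe = _interp_mat(xs_pe, m, e, emin)
            inc = _interp_mat(xs_inc, m, e, emin)
            coh = _interp_mat(xs_coh, m, e, emin)
            r = np.random.random() * (pe + inc + coh)
            if r < pe:
                dep[i, j, k] += e
                deposited += e
                alive = False
            elif r < pe + inc:
                kk = e / MEC2_KEV
                eps, cost = _sample_compton(kk)
                edep = e * (1.0 - eps)
                dep[i, j, k] += edep
                deposited += edep
                e *= eps
                dx, dy, dz = _rotate(dx, dy, dz, cost, two_pi * np.random.random())
                if e <= pcut:
                    dep[i, j, k] += e
                    deposited += e
                    alive = False
            else:
                cost = _sample_thomson()
                dx, dy, dz = _rotate(dx, dy, dz, cost, two_pi * np.random.random())
    return dep, emitted, deposited, escaped, aborted


@njit(cache=True)
def first_interaction_depths(density, material, xs_total, mu_max, emin,
                             origin, spacing, e0, start, direction,
                             n, seed):
    """Depth (mm) from the start point to the first real interaction, for a
    monoenergetic pencil beam; -1 marks photons that left the grid first.
    Exercises the same Woodcock thinning as the transport kernel."""
    np.random.seed(seed)
    nx, ny, nz = density.shape
    out = np.empty(n)
    for h in range(n):
        px, py, pz = start[0], start[1], start[2]
        dx, dy, dz = direction[0], direction[1], direction[2]
        depth = 0.0
        while True:
            mm = _majorant(mu_max, e0, emin)
            s = -math.log(np.random.random()) / mm
            px += s * dx
            py += s * dy
            pz += s * dz
            depth += s
            i = int((px - origin[0]) / spacing[0])
            j = int((py - origin[1]) / spacing[1])
            k = int((pz - origin[2]) / spacing[2])
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                out[h] = -1.0
                break
            mu = _interp_mat(xs_total, material[i, j, k], e0, emin) \
                * density[i, j, k] * 0.1
            if np.random.random() * mm <= mu:
                out[h] = depth
                break
    return out


@njit(cache=True)
def compton_scatter_samples(e0, n, seed):
    """(eps, cos_theta) samples of the kernel's Klein-Nishina sampler."""
    np.random.seed(seed)
    eps = np.empty(n)
    cost = np.empty(n)
    k = e0 / MEC2_KEV
    for h in range(n):
        eps[h], cost[h] = _sample_compton(k)
    return eps, cost
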