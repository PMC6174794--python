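"""Monte Carlo engine: attenuation and scattering oracles, energy
conservation, reproducibility, uncertainty behaviour, and agreement between
the Woodcock kernel and the exact voxel-stepping reference transport."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import ctdosim as cd
from ctdosim import _kernel
from ctdosim.engine import _xs_arrays, majorant_attenuation
from ctdosim.phantom import OrganMask, VoxelPhantom
from ctdosim.physics import MEC2_KEV, CrossSectionLibrary


def _water_box(xs, shape=(40, 40, 40), voxel=10.0, dense_corner=True):
    density = np.ones(shape)
    material = np.full(shape, xs.index("water"), dtype=np.int16)
    if dense_corner:
        # a dense voxel far from the beam raises the majorant, exercising
        # Woodcock null collisions in the water bulk
        density[0, 0, 0] = 2.0
        material[0, 0, 0] = xs.index("bone")
    origin = -0.5 * voxel * np.array(shape)
    return VoxelPhantom(density=density, material=material,
                        spacing=(voxel,) * 3, origin=origin)


def _pencil_source(energy_kev, width=1.0):
    return cd.SourceModel(spectrum_kev=np.array([energy_kev]),
                          spectrum_fluence=np.array([1.0]),
                          fan_half_deg=0.05, focal_radius_mm=1e-6,
                          beam_width_mm=width)


class TestAttenuationOracle:
    @pytest.mark.parametrize("energy", [60.0, 100.0])
    def test_free_path_distribution_is_exponential(self, xs, energy):
        """First-interaction depths in water follow exp(-mu x) (KS test)."""
        ph = _water_box(xs)
        tot, *_ , emin = _xs_arrays(xs)
        mu_max = majorant_attenuation(ph, xs)
        start = np.array([ph.origin[0] + 1e-3, 0.0, 0.0])
        direction = np.array([1.0, 0.0, 0.0])
        depths = _kernel.first_interaction_depths(
            ph.density, ph.material, tot, mu_max, emin, ph.origin, ph.spacing,
            energy, start, direction, 100_000, 42)
        mu_mm = xs.mu_rho("water", energy) * 0.1
        inside = depths[depths > 0]
        assert len(inside) / len(depths) > 0.99  # box is many mean free paths
        res = stats.kstest(inside, "expon", args=(0, 1.0 / mu_mm))
        assert res.pvalue > 1e-3

    def test_primary_survival_through_10cm_water_at_60kev(self, xs):
        """Uncollided fraction beyond 100 mm equals exp(-0.2059 /cm * 10 cm)."""
        ph = _water_box(xs)
        tot, *_, emin = _xs_arrays(xs)
        mu_max = majorant_attenuation(ph, xs)
        start = np.array([ph.origin[0] + 1e-3, 0.0, 0.0])
        depths = _kernel.first_interaction_depths(
            ph.density, ph.material, tot, mu_max, emin, ph.origin, ph.spacing,
            60.0, start, np.array([1.0, 0.0, 0.0]), 200_000, 7)
        surv = ((depths < 0) | (depths > 100.0)).mean()
        expected = math.exp(-0.2059 * 10.0)
        assert surv == pytest.approx(expected, abs=3 * math.sqrt(expected / 2e5) + 1e-3)


class TestComptonOracle:
    def test_mean_scattered_energy_matches_quadrature(self):
        """Kernel KN sampler mean eps vs numerical integration, within 1%."""
        e0 = 60.0
        eps, _ = _kernel.compton_scatter_samples(e0, 300_000, 11)
        k = e0 / MEC2_KEV

        def dsig(c):
            e = 1.0 / (1.0 + k * (1.0 - c))
            return e * e * (e + 1.0 / e - (1.0 - c * c))

        num, _ = integrate.quad(lambda c: dsig(c) / (1.0 + k * (1.0 - c)), -1, 1)
        den, _ = integrate.quad(dsig, -1, 1)
        assert eps.mean() == pytest.approx(num / den, rel=0.01)

    def test_energy_angle_kinematics_consistent(self):
        eps, cost = _kernel.compton_scatter_samples(80.0, 20_000, 3)
        k = 80.0 / MEC2_KEV
        assert np.allclose(eps, 1.0 / (1.0 + k * (1.0 - cost)), atol=1e-12)


class TestRunScan:
    def test_energy_conservation_per_batch(self, thorax_dose):
        emitted, accounted = thorax_dose.energy_balance()
        assert np.all(np.abs(accounted / emitted - 1) < 1e-6)

    def test_deposit_bounded_by_emitted(self, thorax_dose):
        assert thorax_dose.deposit_kev.sum() <= thorax_dose.batch_emitted.sum()
        assert np.all(thorax_dose.batch_deposits >= 0)

    def test_same_seed_bit_identical(self, xs, thorax300, thorax_protocol,
                                     thorax_source):
        phantom, _, _ = thorax300
        fields = cd.helical_fields(thorax_protocol)[:200]
        a = cd.run_scan(phantom, fields, thorax_source, 5000, seed=99, xs=xs)
        b = cd.run_scan(phantom, fields, thorax_source, 5000, seed=99, xs=xs)
        c = cd.run_scan(phantom, fields, thorax_source, 5000, seed=100, xs=xs)
        assert np.array_equal(a.batch_deposits, b.batch_deposits)
        assert not np.array_equal(a.batch_deposits, c.batch_deposits)

    def test_uniform_weight_scaling_leaves_per_history_dose_unchanged(
            self, xs, thorax300, thorax_protocol, thorax_source):
        phantom, _, _ = thorax300
        fields = cd.helical_fields(thorax_protocol)[:100]
        doubled = [cd.BeamField(f.angle_deg, f.isocenter_z_mm, 2 * f.weight)
                   for f in fields]
        a = cd.run_scan(phantom, fields, thorax_source, 4000, seed=12, xs=xs)
        b = cd.run_scan(phantom, doubled, thorax_source, 4000, seed=12, xs=xs)
        assert np.array_equal(a.batch_deposits, b.batch_deposits)
        assert b.total_weight == pytest.approx(2 * a.total_weight)

    def test_uncertainty_scales_as_inverse_sqrt_histories(
            self, thorax300, thorax_protocol, thorax_source):
        phantom, masks, _ = thorax300
        fields = cd.helical_fields(thorax_protocol)
        u1 = cd.relative_uncertainty(
            cd.run_scan(phantom, fields, thorax_source, 50_000, seed=1,
                        n_batches=100), masks["lungs"])
        u2 = cd.relative_uncertainty(
            cd.run_scan(phantom, fields, thorax_source, 200_000, seed=1001,
                        n_batches=100), masks["lungs"])
        assert u1 / u2 == pytest.approx(2.0, rel=0.20)

    def test_zero_dose_region_reports_undefined(self, thorax_dose, thorax300):
        phantom, _, _ = thorax300
        # an air corner outside every beam: positive mass, zero dose
        m = np.zeros(phantom.shape, dtype=bool)
        m[0, 0, 0] = True
        assert thorax_dose.batch_deposits[:, 0, 0, 0].sum() == 0
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(
                cd.relative_uncertainty(thorax_dose, OrganMask("corner", m)))

    def test_rejects_invalid_inputs(self, thorax300, thorax_source):
        phantom, _, _ = thorax300
        with pytest.raises(ValueError):
            cd.run_scan(phantom, [], thorax_source, 100, seed=0)
        f = [cd.BeamField(0, 0, weight=0.0)]
        with pytest.raises(ValueError):
            cd.run_scan(phantom, f, thorax_source, 100, seed=0)


class TestEnergyToDose:
    def _unit_grid(self, deposit, density):
        ph = VoxelPhantom(density=density,
                          material=np.zeros(density.shape, dtype=np.int16),
                          spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0))
        dg = cd.DoseGrid(batch_deposits=deposit[None, ...],
                         batch_histories=np.array([1]),
                         batch_emitted=np.array([deposit.sum()]),
                         batch_escaped=np.array([0.0]),
                         mass_g=ph.mass_g, spacing=ph.spacing, origin=ph.origin,
                         total_weight=1.0, seed=0)
        return ph, dg

    def test_unit_fixture_1kev_per_mg(self):
        # 1 keV in a 1 mm^3 voxel of 1 g/cm^3 -> 1 keV/mg = 1000 keV/g
        dep = np.zeros((2, 2, 2))
        dep[0, 0, 0] = 1.0
        ph, dg = self._unit_grid(dep, np.ones((2, 2, 2)))
        dose = cd.energy_to_dose(dg, ph)
        assert dose[0, 0, 0] == pytest.approx(1000.0)

    def test_halving_density_doubles_dose(self):
        dep = np.full((2, 2, 2), 3.0)
        _, dg = self._unit_grid(dep, np.ones((2, 2, 2)))
        ph_half, _ = self._unit_grid(dep, np.full((2, 2, 2), 0.5))
        d1 = cd.energy_to_dose(dg, self._unit_grid(dep, np.ones((2, 2, 2)))[0])
        d2 = cd.energy_to_dose(dg, ph_half)
        assert np.allclose(d2, 2 * d1)
        assert np.ptp(d1) == 0  # uniform deposit over uniform phantom

    def test_deposit_in_zero_density_voxel_errors(self):
        dep = np.zeros((2, 2, 2))
        dep[1, 1, 1] = 5.0
        density = np.ones((2, 2, 2))
        density[1, 1, 1] = 0.0
        ph, dg = self._unit_grid(dep, density)
        with pytest.raises(ValueError, match="zero-density"):
            cd.energy_to_dose(dg, ph)


class TestReferenceTransport:
    def test_photon_missing_phantom_deposits_nothing(self, xs, rng):
        ph = _water_box(xs, shape=(10, 10, 10), dense_corner=False)
        dep = np.zeros(ph.shape)
        p = cd.Photon(position=[0.0, 0.0, 500.0], direction=[0.0, 0.0, 1.0],
                      energy_kev=60.0)
        escaped, events = cd.trace(p, ph, xs, rng, dep)
        assert escaped == 60.0 and not events and dep.sum() == 0

    def test_photoelectric_deposits_full_energy(self, xs, rng):
        # a library with only the photoelectric channel forces local absorption
        z = np.zeros_like(xs.photoelectric)
        pe_only = CrossSectionLibrary(
            energies_kev=xs.energies_kev, names=xs.names, z_over_a=xs.z_over_a,
            photoelectric=xs.total.copy(), incoherent=z, coherent=z,
            energy_transfer=xs.total.copy())
        ph = _water_box(pe_only, shape=(20, 20, 20), dense_corner=False)
        dep = np.zeros(ph.shape)
        p = cd.Photon(position=[ph.origin[0] + 1e-3, 0.0, 0.0],
                      direction=[1.0, 0.0, 0.0], energy_kev=60.0)
        escaped, events = cd.trace(p, ph, pe_only, rng, dep)
        assert escaped == 0.0
        assert len(events) == 1 and events[0][0] == "photoelectric"
        assert dep.sum() == pytest.approx(60.0)

    def test_woodcock_agrees_with_voxel_stepping(self, xs):
        """Dual-route check on a two-material slab phantom: mean energy
        deposited per history from the compiled Woodcock kernel matches the
        exact voxel-traversal reference within combined statistical error."""
        shape = (24, 16, 16)
        density = np.ones(shape)
        material = np.full(shape, xs.index("water"), dtype=np.int16)
        density[12:, :, :] = 1.85
        material[12:, :, :] = xs.index("bone")
        ph = VoxelPhantom(density=density, material=material,
                          spacing=(5.0, 5.0, 5.0),
                          origin=(-60.0, -40.0, -40.0))
        src = _pencil_source(80.0, width=2.0)
        fields = [cd.BeamField(angle_deg=0.0, isocenter_z_mm=0.0, weight=1.0)]
        dg = cd.run_scan(ph, fields, src, 40_000, seed=8, xs=xs, n_batches=20)
        kern_mean = dg.deposit_kev.sum() / dg.n_histories
        kb = dg.batch_deposits.reshape(dg.n_batches, -1).sum(axis=1) \
            / dg.batch_histories
        kern_se = kb.std(ddof=1) / math.sqrt(dg.n_batches)
        # reference route: python trace with the same source geometry
        rng = np.random.default_rng(77)
        n_ref = 3000
        totals = np.empty(n_ref)
        dep = np.zeros(ph.shape)
        for i in range(n_ref):
            pos, d, e, _ = cd.sample_photon(src, fields[0], rng, n=1)
            before = dep.sum()
            cd.trace(cd.Photon(position=pos[0], direction=d[0],
                               energy_kev=float(e[0])), ph, xs, rng, dep)
            totals[i] = dep.sum() - before
        ref_mean = totals.mean()
        ref_se = totals.std(ddof=1) / math.sqrt(n_ref)
        assert abs(kern_mean - ref_mean) < 3.5 * math.hypot(kern_se, ref_se)
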