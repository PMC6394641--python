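"""Particle population balance: binning, surface area, shrinking spheres."""

import math

import numpy as np
import pandas as pd
import pytest

import dissosim as ds
from dissosim.particles import _rate_constant_um2_min

RHO = 1.3  # g/mL


def make_pop(radius_um, number=1.0, form="free_base", age=0.0):
    return ds.ParticlePopulation(
        cohorts=[ds.ParticleCohort(radius_um=radius_um, number=number,
                                   form=form, wetted_age_min=age)]
    )


@pytest.fixture
def plain_base():
    """Free base with a convenient solubility for rate arithmetic."""
    return ds.IonizableCompound(
        name="base", ionization="monoprotic_base", pKa=7.6,
        intrinsic_solubility_mg_ml=0.15e-3, true_density_g_ml=RHO,
        diffusion_coefficient_cm2_s=8e-6, molecular_weight_g_mol=450.0,
    )


@pytest.fixture
def water_ph45():
    return ds.Medium(name="w", volume_ml=900.0, bulk_pH=4.5,
                     buffer_species=[(4.76, 50.0)])


class TestBoundaryLayer:
    @pytest.mark.parametrize("radius,expected", [(10.0, 10.0), (100.0, 30.0),
                                                 (30.0, 30.0), (0.0, 0.0)])
    def test_lesser_of_radius_or_cap(self, radius, expected):
        assert ds.boundary_layer_thickness(radius) == expected

    def test_configurable_cap(self):
        assert ds.boundary_layer_thickness(100.0, cap_um=50.0) == 50.0


class TestPopulationFromPsd:
    def test_monodisperse_mass_balance(self):
        psd = pd.DataFrame({"diameter_um": [50.0], "fraction": [1.0]})
        pop = ds.population_from_psd(psd, "volume", 5, dose_mg=12.0,
                                     density_g_ml=RHO)
        assert len(pop.cohorts) == 1
        r_cm = 25e-4
        per_particle = (4 / 3) * math.pi * r_cm**3 * RHO * 1e3
        assert pop.cohorts[0].number == pytest.approx(12.0 / per_particle)

    def test_lognormal_mass_conserved(self):
        psd = ds.gen_psd(30.0, 1.8, n_points=100, seed=2)
        pop = ds.population_from_psd(psd, "volume", 20, dose_mg=12.0,
                                     density_g_ml=RHO)
        assert pop.total_mass_mg(RHO) == pytest.approx(12.0, rel=1e-9)

    def test_weighting_modes_same_mass(self):
        psd = ds.gen_psd(30.0, 1.6, n_points=50, seed=3)
        pop_v = ds.population_from_psd(psd, "volume", 10, dose_mg=5.0,
                                       density_g_ml=RHO)
        pop_n = ds.population_from_psd(psd, "number", 10, dose_mg=5.0,
                                       density_g_ml=RHO)
        assert pop_v.total_mass_mg(RHO) == pytest.approx(pop_n.total_mass_mg(RHO))
        nv = [c.number for c in pop_v.cohorts]
        nn = [c.number for c in pop_n.cohorts]
        assert not np.allclose(nv, nn)

    def test_degenerate_psd_rejected(self):
        with pytest.raises(ValueError):
            ds.population_from_psd(
                pd.DataFrame({"diameter_um": [10.0], "fraction": [0.0]}), "volume", 5
            )


class TestSurfaceArea:
    def test_unit_sphere(self):
        pop = make_pop(radius_um=1e4, number=1.0)  # 1 cm
        assert ds.total_surface_area(pop) == pytest.approx(4 * math.pi)

    def test_split_invariance(self):
        whole = make_pop(radius_um=20.0, number=10.0)
        halves = ds.ParticlePopulation(cohorts=[
            ds.ParticleCohort(radius_um=20.0, number=5.0),
            ds.ParticleCohort(radius_um=20.0, number=5.0),
        ])
        assert ds.total_surface_area(whole) == pytest.approx(
            ds.total_surface_area(halves))

    def test_half_radius_doubles_area_at_same_mass(self):
        pop1 = make_pop(radius_um=40.0, number=1.0)
        pop2 = make_pop(radius_um=20.0, number=8.0)  # same total mass
        assert pop1.cohorts[0].mass_mg(RHO) == pytest.approx(
            pop2.cohorts[0].mass_mg(RHO))
        assert ds.total_surface_area(pop2) == pytest.approx(
            2 * ds.total_surface_area(pop1))


class TestStepDissolve:
    def test_zero_driving_force(self, plain_base, water_ph45):
        _, cs = ds.surface_solubility(plain_base, water_ph45)
        pop = make_pop(radius_um=25.0, number=1e6)
        new, inc = ds.step_dissolve(pop, cs, water_ph45, plain_base, dt_min=1.0)
        assert inc == 0.0
        assert new.cohorts[0].radius_um == 25.0

    def test_mass_conservation_each_step(self, plain_base, water_ph45):
        psd = ds.gen_psd(30.0, 1.8, 100, seed=4)
        pop = ds.population_from_psd(psd, "volume", 15, dose_mg=12.0,
                                     density_g_ml=RHO)
        m = pop.total_mass_mg(RHO)
        for _ in range(30):
            pop, inc = ds.step_dissolve(pop, 0.0, water_ph45, plain_base,
                                        dt_min=0.5)
            m_new = pop.total_mass_mg(RHO)
            assert m - m_new == pytest.approx(inc, rel=1e-9, abs=1e-12)
            m = m_new

    def test_small_particle_r_squared_linear_at_sink(self, plain_base, water_ph45):
        """h = r below the cap: r^2 falls linearly; closed-form slope 2k."""
        _, cs = ds.surface_solubility(plain_base, water_ph45)
        k = _rate_constant_um2_min(8e-6, RHO, cs)
        r0 = 25.0
        pop = make_pop(radius_um=r0, number=1.0)
        dt = 1e-3
        rs = [r0]
        for _ in range(50):
            pop, _ = ds.step_dissolve(pop, 0.0, water_ph45, plain_base, dt_min=dt)
            rs.append(pop.cohorts[0].radius_um)
        r2 = np.array(rs) ** 2
        slopes = np.diff(r2) / dt
        assert np.allclose(slopes, -2 * k, rtol=5e-3)

    def test_large_particle_radius_linear_at_sink(self, plain_base, water_ph45):
        """h capped at 30 um: radius falls linearly with slope k/30."""
        _, cs = ds.surface_solubility(plain_base, water_ph45)
        k = _rate_constant_um2_min(8e-6, RHO, cs)
        pop = make_pop(radius_um=200.0, number=1.0)
        dt = 0.05
        rs = [200.0]
        for _ in range(20):
            pop, _ = ds.step_dissolve(pop, 0.0, water_ph45, plain_base, dt_min=dt)
            rs.append(pop.cohorts[0].radius_um)
        slopes = np.diff(rs) / dt
        assert np.allclose(slopes, -k / 30.0, rtol=5e-3)

    def test_cube_root_law_for_coarse_particles(self, plain_base, water_ph45):
        """Hixson-Crowell: m^(1/3) linear in t while r >> cap, slope matching
        the closed form within 0.5%."""
        _, cs = ds.surface_solubility(plain_base, water_ph45)
        k = _rate_constant_um2_min(8e-6, RHO, cs)
        r0, n = 300.0, 100.0
        pop = make_pop(radius_um=r0, number=n)
        dt = 0.1
        t, masses = [0.0], [pop.total_mass_mg(RHO)]
        for i in range(40):
            pop, _ = ds.step_dissolve(pop, 0.0, water_ph45, plain_base, dt_min=dt)
            t.append((i + 1) * dt)
            masses.append(pop.total_mass_mg(RHO))
        cbrt = np.array(masses) ** (1 / 3)
        slope = np.polyfit(t, cbrt, 1)[0]
        # m^(1/3) = (4/3 pi rho n)^(1/3) * r(t) * 1e-4 cm/um, dr/dt = -k/cap
        expected = -((4 / 3) * math.pi * RHO * 1e3 * n) ** (1 / 3) * 1e-4 * k / 30.0
        assert slope == pytest.approx(expected, rel=5e-3)
        resid = cbrt - np.polyval(np.polyfit(t, cbrt, 1), t)
        assert np.max(np.abs(resid)) < 5e-3 * cbrt[0]

    def test_salt_age_crossing_two_phase_bookkeeping(self, plain_base, water_ph45):
        """A salt cohort at age 2.9 with a 3-min lag dissolves 0.1 min as salt
        then 0.1 min as free base, and comes out relabeled."""
        salt = ds.SaltForm(parent=plain_base, counterion_pKa=-1.0,
                           salt_solubility_mg_ml=1.8, conversion_lag_min=3.0)
        cs = {"salt": ds.surface_solubility(salt, water_ph45)[1],
              "free_base": ds.surface_solubility(plain_base, water_ph45)[1]}
        pop = make_pop(radius_um=25.0, number=1e5, form="salt", age=2.9)
        new, inc = ds.step_dissolve(pop, 0.0, water_ph45, plain_base, salt=salt,
                                    dt_min=0.2, cs_by_form=cs)
        assert new.cohorts[0].form == "free_base"
        assert new.cohorts[0].wetted_age_min == pytest.approx(3.1)

        # analytic two-phase radius: r^2 linear in each phase (r < cap)
        k_salt = _rate_constant_um2_min(8e-6, RHO, cs["salt"])
        k_base = _rate_constant_um2_min(8e-6, RHO, cs["free_base"])
        r_mid = math.sqrt(25.0**2 - 2 * k_salt * 0.1)
        r_end = math.sqrt(r_mid**2 - 2 * k_base * 0.1)
        assert new.cohorts[0].radius_um == pytest.approx(r_end, rel=1e-12)
        m0 = pop.cohorts[0].mass_mg(RHO)
        assert inc == pytest.approx(m0 * (1 - (r_end / 25.0) ** 3), rel=1e-9)

    def test_salt_never_slower_than_free_base(self, plain_base, water_ph45):
        """Above pH_max the salt surface solubility exceeds the free-base one,
        so identical cohorts lose mass at least as fast as salt."""
        salt = ds.SaltForm(parent=plain_base, counterion_pKa=-1.0,
                           salt_solubility_mg_ml=1.8, conversion_lag_min=30.0)
        rng = np.random.default_rng(11)
        ph_max = ds.compute_phmax(salt)
        for _ in range(5):
            med = ds.Medium(name="m", volume_ml=900,
                            bulk_pH=rng.uniform(ph_max + 0.2, 7.5),
                            buffer_species=[(rng.uniform(4, 8), rng.uniform(10, 80))])
            pop_s = make_pop(radius_um=25.0, number=1e5, form="salt")
            pop_b = make_pop(radius_um=25.0, number=1e5, form="free_base")
            _, inc_s = ds.step_dissolve(pop_s, 0.0, med, plain_base, salt=salt,
                                        dt_min=0.5)
            _, inc_b = ds.step_dissolve(pop_b, 0.0, med, plain_base, salt=salt,
                                        dt_min=0.5)
            assert inc_s >= inc_b

    def test_growth_disabled_when_supersaturated(self, plain_base, water_ph45):
        _, cs = ds.surface_solubility(plain_base, water_ph45)
        pop = make_pop(radius_um=25.0, number=1e5)
        new, inc = ds.step_dissolve(pop, cs * 2, water_ph45, plain_base, dt_min=1.0)
        assert inc == 0.0
        assert new.cohorts[0].radius_um == 25.0

    def test_extinction_exact_bookkeeping(self, plain_base, water_ph45):
        """Cohorts that vanish mid-step transfer exactly their whole mass."""
        pop = make_pop(radius_um=0.5, number=1e8)
        m0 = pop.total_mass_mg(RHO)
        new, inc = ds.step_dissolve(pop, 0.0, water_ph45, plain_base, dt_min=60.0)
        assert new.cohorts == []
        assert inc == pytest.approx(m0, rel=1e-12)
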