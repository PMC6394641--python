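"""Solubility chemistry: Henderson-Hasselbalch, pH_max, surface pH, BCS."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

import dissosim as ds
from dissosim.chemistry import (
    ConfigurationError,
    Ionization,
    _buffer_anion_mM,
    _h_mM,
    _oh_mM,
)


class TestHHSolubility:
    def test_base_doubles_at_pka(self, dsa):
        assert ds.hh_solubility(dsa, 7.6) == pytest.approx(2 * 0.15e-3, rel=1e-12)

    def test_base_at_ph_45(self, dsa):
        # 0.00015 * (1 + 10^3.1)
        assert ds.hh_solubility(dsa, 4.5) == pytest.approx(0.189, rel=5e-3)

    def test_gastric_span(self, dsa):
        assert ds.hh_solubility(dsa, 1.2) >= 10.0
        assert ds.hh_solubility(dsa, 1.2) == pytest.approx(377.0, rel=0.01)
        assert ds.hh_solubility(dsa, 6.0) <= 0.01

    def test_acid_mirror(self):
        acid = ds.IonizableCompound(name="acid", ionization="monoprotic_acid",
                                    pKa=4.0, intrinsic_solubility_mg_ml=0.1)
        assert ds.hh_solubility(acid, 4.0) == pytest.approx(0.2)
        assert ds.hh_solubility(acid, 6.0) > ds.hh_solubility(acid, 5.0)

    def test_neutral_flat(self):
        n = ds.IonizableCompound(name="n", intrinsic_solubility_mg_ml=1.0)
        assert ds.hh_solubility(n, 2.0) == ds.hh_solubility(n, 10.0) == 1.0

    def test_base_monotone_and_limit(self, dsa):
        grid = np.linspace(1.0, 13.0, 200)
        vals = [ds.hh_solubility(dsa, p) for p in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert ds.hh_solubility(dsa, 13.5) == pytest.approx(
            dsa.intrinsic_solubility_mg_ml, rel=1e-5)

    def test_missing_pka_rejected(self):
        with pytest.raises(ConfigurationError):
            ds.IonizableCompound(name="x", ionization="monoprotic_base",
                                 intrinsic_solubility_mg_ml=1.0)


class TestPhMax:
    def test_dsa_tosylate(self, dsa_tosylate):
        assert round(ds.compute_phmax(dsa_tosylate), 1) == 3.5

    def test_salt_solubility_twice_s0(self, dsa):
        salt = ds.SaltForm(parent=dsa, counterion_pKa=-1.0,
                           salt_solubility_mg_ml=2 * 0.15e-3 + 1e-12)
        assert ds.compute_phmax(salt) == pytest.approx(7.6, abs=1e-5)

    def test_closed_form_example(self):
        c = ds.IonizableCompound(name="b", ionization="monoprotic_base", pKa=8.0,
                                 intrinsic_solubility_mg_ml=1e-3)
        salt = ds.SaltForm(parent=c, counterion_pKa=-1.0,
                           salt_solubility_mg_ml=1.001)
        assert ds.compute_phmax(salt) == pytest.approx(5.0, abs=1e-4)

    def test_matches_closed_form_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            pka = rng.uniform(3.0, 10.0)
            s0 = 10.0 ** rng.uniform(-5, -1)
            ratio = 10.0 ** rng.uniform(0.5, 4.0)
            c = ds.IonizableCompound(name="r", ionization="monoprotic_base",
                                     pKa=pka, intrinsic_solubility_mg_ml=s0)
            salt = ds.SaltForm(parent=c, counterion_pKa=-1.0,
                               salt_solubility_mg_ml=s0 * ratio)
            closed = pka - math.log10(ratio - 1.0)
            if 0.1 < closed < 13.9:
                assert ds.compute_phmax(salt) == pytest.approx(closed, abs=1e-6)

    def test_no_root_rejected(self, dsa):
        with pytest.raises(ValueError):
            ds.SaltForm(parent=dsa, counterion_pKa=-1.0,
                        salt_solubility_mg_ml=0.1e-3)


class TestSurfaceSolubility:
    def test_neutral_passthrough(self, acetate_ph45):
        n = ds.IonizableCompound(name="n", intrinsic_solubility_mg_ml=0.5)
        assert ds.surface_solubility(n, acetate_ph45) == (4.5, 0.5)

    def test_salt_acidifies_surface(self, dsa, dsa_tosylate, phosphate_ph65):
        ph_s, cs = ds.surface_solubility(dsa_tosylate, phosphate_ph65)
        assert ph_s < 6.5
        assert cs > ds.hh_solubility(dsa, 6.5)

    def test_salt_cs_above_bulk_freebase_above_phmax(self, dsa, dsa_tosylate):
        rng = np.random.default_rng(3)
        ph_max = ds.compute_phmax(dsa_tosylate)
        for _ in range(10):
            ph = rng.uniform(ph_max + 0.1, 8.0)
            med = ds.Medium(name="m", volume_ml=900, bulk_pH=ph,
                            buffer_species=[(rng.uniform(3, 8), rng.uniform(5, 100))])
            _, cs = ds.surface_solubility(dsa_tosylate, med)
            assert cs >= ds.hh_solubility(dsa, ph)

    def test_matches_independent_bisection(self, dsa, dsa_tosylate):
        """Toy balance: single 50 mM buffer at pKa 7.0, 1:1 strong-acid
        counterion; compare to a from-scratch bisection of the residual."""
        med = ds.Medium(name="toy", volume_ml=900, bulk_pH=7.0,
                        buffer_species=[(7.0, 50.0)])
        ph_s, _ = ds.surface_solubility(dsa_tosylate, med)

        s_salt_mM = 1.8 / 450.0 * 1e3
        ph_b = 7.0

        def residual(ph):
            r = _h_mM(ph) - _h_mM(ph_b) - (_oh_mM(ph) - _oh_mM(ph_b))
            r += s_salt_mM / (1.0 + 10.0 ** (ph - 7.6))  # ionized base
            r -= s_salt_mM / (1.0 + 10.0 ** (-1.0 - ph))  # counterion anion
            r -= _buffer_anion_mM(ph, 7.0, 50.0) - _buffer_anion_mM(ph_b, 7.0, 50.0)
            return r

        oracle = bisect(residual, 1e-3, 13.9, xtol=1e-9)
        assert abs(ph_s - oracle) < 1e-6


class TestDoseNumber:
    def test_dsa_at_ph45(self, acetate_ph45):
        do, window = ds.dose_number(12.0, acetate_ph45, 0.189)
        assert do == pytest.approx(0.0705, abs=2e-4)
        assert not window

    def test_definition_unity(self, acetate_ph45):
        do, window = ds.dose_number(900.0 * 0.189, acetate_ph45, 0.189)
        assert do == pytest.approx(1.0)
        assert not window

    def test_in_window(self, acetate_ph45):
        do, window = ds.dose_number(12.0, acetate_ph45, 0.02)
        assert do == pytest.approx(0.667, abs=1e-3)
        assert window


class TestBcsSolubility:
    def test_soluble_neutral(self):
        n = ds.IonizableCompound(name="n", intrinsic_solubility_mg_ml=1.0)
        assert ds.bcs_solubility_high(n, 100.0)

    def test_insoluble_neutral(self):
        n = ds.IonizableCompound(name="n", intrinsic_solubility_mg_ml=0.1)
        assert not ds.bcs_solubility_high(n, 100.0)

    def test_dsa_free_base_fails(self, dsa):
        assert not ds.bcs_solubility_high(dsa, 12.0)

    def test_monotone_in_dose(self):
        n = ds.IonizableCompound(name="n", intrinsic_solubility_mg_ml=0.5)
        verdicts = [ds.bcs_solubility_high(n, d) for d in (50, 100, 125, 200, 400)]
        # once false, stays false as dose rises
        assert verdicts == sorted(verdicts, reverse=True)


class TestDiffusionEstimate:
    def test_viscosity_halves(self):
        d1 = ds.estimate_diffusion_coefficient(400.0, 37.0, 0.69)
        d2 = ds.estimate_diffusion_coefficient(400.0, 37.0, 1.38)
        assert d2 == pytest.approx(d1 / 2)

    def test_plausible_band(self):
        d = ds.estimate_diffusion_coefficient(400.0, 37.0, 0.69)
        assert 5e-6 <= d <= 1.5e-5

    def test_temperature_monotone(self):
        assert (ds.estimate_diffusion_coefficient(400.0, 25.0)
                < ds.estimate_diffusion_coefficient(400.0, 37.0))

    def test_mw_monotone(self):
        assert (ds.estimate_diffusion_coefficient(800.0)
                < ds.estimate_diffusion_coefficient(200.0))
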