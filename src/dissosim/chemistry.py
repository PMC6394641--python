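"""pH-dependent solubility, surface chemistry, and BCS solubility classification.

Solubility of ionizable drugs follows the Henderson-Hasselbalch relation: for a
monoprotic base with intrinsic (un-ionized) solubility ``S0`` and dissociation
constant ``pKa``, total solubility at a given pH is ``S0 * (1 + 10**(pKa - pH))``;
for a monoprotic acid the exponent flips sign. A salt of a weak base dissolves up
to its own (much higher) salt solubility; the pH at which the free-base curve
crosses the salt solubility is ``pH_max`` — above it the free base is the stable,
solubility-limiting phase.

At a dissolving particle's surface the local pH generally differs from bulk:
the ionized drug and (for salts) the acidic counterion it carries perturb the
local acid/base balance. The surface pH is obtained from a film-model flux
balance: the net flux of charge across the diffusion layer must vanish, with
every species taken at its surface saturation value and weighted by its own
diffusion coefficient. Solubility at the surface is then the
Henderson-Hasselbalch value at that surface pH, capped at the salt solubility
for salt particles.

All concentrations are handled internally in mg/mL; molar balances run in mM
and require a molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Ionization",
    "IonizableCompound",
    "SaltForm",
    "Medium",
    "hh_solubility",
    "compute_phmax",
    "surface_solubility",
    "dose_number",
    "bcs_solubility_high",
    "estimate_diffusion_coefficient",
]


class Ionization(str, Enum):
    MONOPROTIC_BASE = "monoprotic_base"
    MONOPROTIC_ACID = "monoprotic_acid"
    NEUTRAL = "neutral"


class ConfigurationError(ValueError):
    """Inconsistent or incomplete compound/medium description."""


@dataclass
class IonizableCompound:
    """A drug substance and the physical properties driving its dissolution.

    Parameters
    ----------
    intrinsic_solubility_mg_ml:
        Solubility of the un-ionized species (mg/mL).
    true_density_g_ml:
        Crystal (true) density (g/mL).
    diffusion_coefficient_cm2_s:
        Diffusivity across the boundary layer; if omitted it is estimated from
        molecular weight via Stokes-Einstein when needed.
    """

    name: str
    ionization: Ionization = Ionization.NEUTRAL
    pKa: float | None = None
    intrinsic_solubility_mg_ml: float = 0.0
    true_density_g_ml: float = 1.2
    diffusion_coefficient_cm2_s: float | None = None
    molecular_weight_g_mol: float | None = None

    def __post_init__(self) -> None:
        self.ionization = Ionization(self.ionization)
        if self.intrinsic_solubility_mg_ml <= 0:
            raise ConfigurationError("intrinsic solubility must be positive")
        if self.true_density_g_ml <= 0:
            raise ConfigurationError("true density must be positive")
        ionizable = self.ionization is not Ionization.NEUTRAL
        if ionizable and self.pKa is None:
            raise ConfigurationError(
                f"{self.name}: pKa required for ionization {self.ionization.value}"
            )
        if not ionizable and self.pKa is not None:
            raise ConfigurationError(f"{self.name}: pKa given for a neutral compound")

    def diffusivity(self, viscosity_mPa_s: float = 0.69,
                    temperature_C: float = 37.0) -> float:
        """Diffusion coefficient (cm²/s), measured if supplied else estimated."""
        if self.diffusion_coefficient_cm2_s is not None:
            return self.diffusion_coefficient_cm2_s
        if self.molecular_weight_g_mol is None:
            raise ConfigurationError(
                f"{self.name}: need diffusion coefficient or molecular weight"
            )
        return estimate_diffusion_coefficient(
            self.molecular_weight_g_mol, temperature_C, viscosity_mPa_s
        )


@dataclass
class SaltForm:
    """A salt of an ionizable parent compound.

    ``salt_solubility_mg_ml`` is expressed in parent-equivalents. A wetted salt
    particle behaves as salt for ``conversion_lag_min`` minutes and then as the
    free form (surface conversion of the crystal).
    """

    parent: IonizableCompound
    counterion_pKa: float
    counterion_stoichiometry: float = 1.0
    salt_solubility_mg_ml: float = 0.0
    conversion_lag_min: float = 0.0

    def __post_init__(self) -> None:
        if self.salt_solubility_mg_ml <= self.parent.intrinsic_solubility_mg_ml:
            raise ConfigurationError(
                "salt solubility must exceed the parent intrinsic solubility"
            )
        if self.conversion_lag_min < 0:
            raise ConfigurationError("conversion lag must be >= 0")
        if self.counterion_stoichiometry < 1:
            raise ConfigurationError("counterion stoichiometry must be >= 1")


@dataclass
class Medium:
    """A dissolution medium: vessel volume, bulk pH, and buffer composition.

    ``buffer_species`` is a list of ``(pKa, total_concentration_mM)`` pairs for
    monoprotic buffer components (e.g. acetate: ``(4.76, 50.0)``).
    """

    name: str
    volume_ml: float
    bulk_pH: float
    buffer_species: list[tuple[float, float]] = field(default_factory=list)
    temperature_C: float = 37.0
    surfactant_class: str = "none"
    apparatus: str = "USP-II-50rpm"

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ConfigurationError("medium volume must be positive")
        if not (0.0 < self.bulk_pH < 14.0):
            raise ConfigurationError("bulk pH must lie in (0, 14)")
        if self.surfactant_class not in ("none", "surfactant"):
            raise ConfigurationError("surfactant_class must be 'none' or 'surfactant'")
        self.buffer_species = [tuple(b) for b in self.buffer_species]
        for pka, conc in self.buffer_species:
            if conc < 0:
                raise ConfigurationError("buffer concentrations must be >= 0")


def hh_solubility(compound: IonizableCompound, pH: float) -> float:
    """Henderson-Hasselbalch total solubility (mg/mL) at a given pH."""
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH {pH} outside (0, 14)")
    s0 = compound.intrinsic_solubility_mg_ml
    if compound.ionization is Ionization.NEUTRAL:
        return s0
    if compound.pKa is None:  # pragma: no cover - blocked by __post_init__
        raise ConfigurationError("ionizable compound without pKa")
    if compound.ionization is Ionization.MONOPROTIC_BASE:
        return s0 * (1.0 + 10.0 ** (compound.pKa - pH))
    return s0 * (1.0 + 10.0 ** (pH - compound.pKa))


def compute_phmax(salt: SaltForm) -> float:
    """pH at which the free-form solubility curve meets the salt solubility.

    Solved numerically on the Henderson-Hasselbalch curve; agrees with the
    closed form ``pKa - log10(S_salt/S0 - 1)`` (base) to 1e-6.
    """
    parent = salt.parent
    if parent.ionization is Ionization.NEUTRAL:
        raise ConfigurationError("pH_max undefined for a neutral parent")
    f = lambda pH: hh_solubility(parent, pH) - salt.salt_solubility_mg_ml
    lo, hi = 1e-9, 14.0 - 1e-9
    if f(lo) * f(hi) > 0:
        raise ConfigurationError("salt solubility never intersects the free-form curve")
    return brentq(f, lo, hi, xtol=1e-12)


# -- surface pH / surface solubility -----------------------------------------

_KW = 10.0 ** (-13.62)  # ion product of water at 37 °C (mol²/L²), in mM²: Kw*1e6
_KW_mM = _KW * 1e6


def _h_mM(pH: float) -> float:
    return 1e3 * 10.0 ** (-pH)


def _oh_mM(pH: float) -> float:
    return _KW_mM / _h_mM(pH)


def _buffer_anion_mM(pH: float, pKa: float, total_mM: float) -> float:
    """Deprotonated fraction of a monoprotic buffer acid, in mM."""
    return total_mM / (1.0 + 10.0 ** (pKa - pH))


def surface_solubility(
    form: IonizableCompound | SaltForm,
    medium: Medium,
    diffusivity_ratios: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Surface pH and saturation solubility at a dissolving particle surface.

    Solves the single-unknown film flux balance: the diffusion-weighted net
    charge flux across the boundary layer,

        sum_i z_i * (D_i/D_ref) * ([X_i]_surface - [X_i]_bulk),

    must vanish, with the drug at its saturation value at the surface, the
    counterion (salt particles) supplied at one stoichiometric equivalent of
    the dissolving drug, and buffer species re-speciated at the surface pH.
    Species diffusivities default to equal (``diffusivity_ratios`` maps
    ``{"drug", "counterion", "buffer", "h", "oh"}`` to relative values).

    For a free form the surface saturation is the Henderson-Hasselbalch value
    at the surface pH. For a salt the dissolving solid is the salt crystal,
    whose congruent saturation pins the surface concentration at the salt
    solubility; above pH_max this is a supersaturation with respect to the
    free base that persists at the surface for the duration of the salt
    behaviour window (surface conversion to free base, not precipitation, is
    what ends it).

    Returns ``(surface_pH, cs_surface_mg_ml)``.
    """
    ratios = {"drug": 1.0, "counterion": 1.0, "buffer": 1.0, "h": 1.0, "oh": 1.0}
    if diffusivity_ratios:
        ratios.update(diffusivity_ratios)

    salt = form if isinstance(form, SaltForm) else None
    compound = salt.parent if salt else form

    if compound.ionization is Ionization.NEUTRAL:
        return medium.bulk_pH, compound.intrinsic_solubility_mg_ml

    if compound.molecular_weight_g_mol is None:
        raise ConfigurationError(
            f"{compound.name}: molecular weight required for the surface charge balance"
        )
    mw = compound.molecular_weight_g_mol

    def drug_total_mg_ml(pH: float) -> float:
        if salt is not None:
            return salt.salt_solubility_mg_ml
        return hh_solubility(compound, pH)

    base = compound.ionization is Ionization.MONOPROTIC_BASE
    pKa_drug = compound.pKa
    pH_b = medium.bulk_pH

    def residual(pH: float) -> float:
        # surface-minus-bulk charge flux; drug & counterion absent from bulk
        r = ratios["h"] * (_h_mM(pH) - _h_mM(pH_b))
        r -= ratios["oh"] * (_oh_mM(pH) - _oh_mM(pH_b))
        tot_mM = drug_total_mg_ml(pH) / mw * 1e3
        if base:
            ion_frac = 1.0 / (1.0 + 10.0 ** (pH - pKa_drug))
            r += ratios["drug"] * tot_mM * ion_frac
        else:
            ion_frac = 1.0 / (1.0 + 10.0 ** (pKa_drug - pH))
            r -= ratios["drug"] * tot_mM * ion_frac
        if salt is not None:
            ci_tot = salt.counterion_stoichiometry * tot_mM
            ci_anion = ci_tot / (1.0 + 10.0 ** (salt.counterion_pKa - pH))
            r -= ratios["counterion"] * ci_anion
        for pka_b, conc_b in medium.buffer_species:
            r -= ratios["buffer"] * (
                _buffer_anion_mM(pH, pka_b, conc_b)
                - _buffer_anion_mM(pH_b, pka_b, conc_b)
            )
        return r

    lo, hi = 1e-3, 13.999
    flo, fhi = residual(lo), residual(hi)
    if flo * fhi > 0:
        # scan for a sign change before giving up
        grid = np.linspace(lo, hi, 281)
        vals = [residual(p) for p in grid]
        bracket = None
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa == 0.0 or fa * fb < 0:
                bracket = (a, b)
                break
        if bracket is None:
            raise ArithmeticError(
                "surface charge balance has no root in (0, 14); "
                f"residual({lo})={flo:.3g}, residual({hi})={fhi:.3g}"
            )
        lo, hi = bracket
    pH_s = brentq(residual, lo, hi, xtol=1e-10)
    return pH_s, drug_total_mg_ml(pH_s)


def dose_number(dose_mg: float, medium: Medium, cs_mg_ml: float) -> tuple[float, bool]:
    """Dose number Do = dose / (V * cs) and whether it lies in the 0.35-0.9
    design window that lets both tails of the particle size distribution show
    up in the dissolution profile."""
    if dose_mg <= 0 or cs_mg_ml <= 0:
        raise ValueError("dose and solubility must be positive")
    do = dose_mg / (medium.volume_ml * cs_mg_ml)
    return do, 0.35 <= do <= 0.9


def bcs_solubility_high(
    form: IonizableCompound | SaltForm,
    highest_dose_mg: float,
    ph_step: float = 0.1,
) -> bool:
    """BCS high-solubility test: highest dose soluble in <= 250 mL at every pH
    on a grid over [1.2, 6.8] (worst case governs). For salts the solubility at
    each pH is capped at the salt solubility."""
    if highest_dose_mg <= 0:
        raise ValueError("highest dose must be positive")
    salt = form if isinstance(form, SaltForm) else None
    compound = salt.parent if salt else form
    grid = np.arange(1.2, 6.8 + ph_step / 2, ph_step)
    for pH in grid:
        s = hh_solubility(compound, float(pH))
        if salt is not None:
            s = min(s, salt.salt_solubility_mg_ml)
        if highest_dose_mg / s > 250.0:
            return False
    return True


_KB = 1.380649e-23  # J/K
_NA = 6.02214076e23


def estimate_diffusion_coefficient(
    molecular_weight_g_mol: float,
    temperature_C: float = 37.0,
    viscosity_mPa_s: float = 0.69,
) -> float:
    """Stokes-Einstein diffusivity (cm²/s) from molecular weight.

    The hydrodynamic radius is taken from the molar volume at an effective
    molecular density of 1.2 g/cm³ (typical for small-molecule organics).
    """
    if molecular_weight_g_mol <= 0:
        raise ValueError("molecular weight must be positive")
    t_K = temperature_C + 273.15
    eta = viscosity_mPa_s * 1e-3  # Pa s
    v_molec_cm3 = molecular_weight_g_mol / (1.2 * _NA)
    r_cm = (3.0 * v_molec_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    d_m2_s = _KB * t_K / (6.0 * math.pi * eta * (r_cm * 1e-2))
    return d_m2_s * 1e4
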