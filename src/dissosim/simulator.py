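"""The dissolution simulator: medium + particles + dosage form -> profile.

Couples the shrinking-sphere population balance to the bulk mass balance
``dc/dt = sum of particle fluxes / V`` and to the dosage-form release
schedule. Time integration is explicit with piecewise closed-form per-cohort
radius updates at fixed bulk concentration within each step; release events
and the requested output times are inserted into the internal step grid so no
event is straddled. The run is fully deterministic.

Bulk concentration is capped at the bulk-phase solubility ceiling (the
Henderson-Hasselbalch value at bulk pH for free forms, the salt solubility
for salts, whose supersaturation with respect to free base decays too slowly
to matter on immediate-release time scales); the cumulative-% plateau follows
from that cap and the dose.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .chemistry import IonizableCompound, Medium, SaltForm, hh_solubility, surface_solubility
from .dosage import (
    CapsuleModel,
    ReleaseEvent,
    ReleaseSchedule,
    TabletModel,
    capsule_release_schedule,
    tablet_wetting_schedule,
)
from .particles import ParticleCohort, ParticlePopulation, step_dissolve
from .profile import DissolutionProfile

__all__ = ["simulate", "virtual_doe", "SimulationError"]


class SimulationError(RuntimeError):
    pass


def _build_schedule(
    dosage_form,
    medium: Medium,
    cs_interstitial: float,
    dose_mg: float,
    n_release_events: int,
) -> ReleaseSchedule:
    if dosage_form is None:  # powder: everything available at t = 0
        return ReleaseSchedule(events=[ReleaseEvent(0.0, 1.0)])
    if isinstance(dosage_form, CapsuleModel):
        return capsule_release_schedule(dosage_form, n_events=n_release_events)
    if isinstance(dosage_form, TabletModel):
        return tablet_wetting_schedule(
            dosage_form, medium, cs_interstitial,
            n_shells=n_release_events, dose_mg=dose_mg,
        )
    raise TypeError(f"unknown dosage form {type(dosage_form).__name__}")


def simulate(
    compound: IonizableCompound,
    medium: Medium,
    psd_population: ParticlePopulation,
    dose_mg: float,
    t_grid_min,
    salt: SaltForm | None = None,
    dosage_form=None,
    driving_force_scale: float = 1.0,
    dt_internal_min: float = 0.05,
    n_release_events: int = 100,
    bulk_solubility_mg_ml: float | None = None,
    h_cap_um: float = 30.0,
) -> DissolutionProfile:
    """Simulate a full dissolution-time profile.

    Parameters
    ----------
    psd_population:
        Unit particle population describing the drug's size distribution; it
        is rescaled internally so each release event carries its mass share of
        ``dose_mg``. Cohort form labels are set from ``salt`` (salt present ->
        particles start as salt).
    dosage_form:
        ``None`` (powder), a :class:`CapsuleModel`, or a :class:`TabletModel`.
    driving_force_scale:
        Uniform multiplier on (cs - c), the calibration hook for
        difficult-to-model geometries.
    """
    t_grid = np.asarray(t_grid_min, dtype=float)
    if t_grid.size == 0 or t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and increase strictly")
    if dose_mg <= 0:
        raise ValueError("dose must be positive")

    rho = compound.true_density_g_ml
    form0 = "salt" if salt is not None else "free_base"

    cs_by_form: dict[str, float] = {}
    _, cs_by_form["free_base"] = surface_solubility(compound, medium)
    if salt is not None:
        _, cs_by_form["salt"] = surface_solubility(salt, medium)
    cs_release_form = cs_by_form[form0]

    if bulk_solubility_mg_ml is None:
        bulk_solubility_mg_ml = (
            salt.salt_solubility_mg_ml if salt is not None
            else hh_solubility(compound, medium.bulk_pH)
        )

    schedule = _build_schedule(
        dosage_form, medium, cs_release_form, dose_mg, n_release_events
    )
    # template cohorts normalized to unit mass
    unit_mass = psd_population.total_mass_mg(rho)
    if unit_mass <= 0:
        raise ValueError("particle population carries no mass")
    template = [
        replace(c, number=c.number / unit_mass, form=form0)
        for c in psd_population.cohorts
    ]

    pending = sorted(schedule.events, key=lambda e: e.release_time_min)
    pending_mass = dose_mg  # mass not yet in the vessel
    event_times = [e.release_time_min for e in pending]

    t_end = float(t_grid[-1])
    nodes = np.unique(np.concatenate([
        np.arange(0.0, t_end, dt_internal_min),
        t_grid,
        np.asarray([t for t in event_times if t <= t_end], dtype=float),
    ]))

    pop = ParticlePopulation(cohorts=[])
    dissolved = 0.0
    volume = medium.volume_ml
    out = np.empty_like(t_grid)
    out_idx = 0
    worst_residual = 0.0

    def release_due(now: float) -> None:
        nonlocal pending, pending_mass, dissolved, pop
        while pending and pending[0].release_time_min <= now + 1e-12:
            ev = pending.pop(0)
            ev_dose = ev.mass_fraction_solids * dose_mg
            inter = min(ev.interstitial_dissolved_mg, ev_dose)
            solids = ev_dose - inter
            dissolved += inter
            pending_mass -= ev_dose
            if solids > 0:
                scale = solids
                for c in template:
                    pop.cohorts.append(
                        replace(c, number=c.number * scale,
                                wetted_age_min=ev.pre_exposure_min)
                    )

    for i, t in enumerate(nodes):
        release_due(t)
        while out_idx < t_grid.size and abs(t_grid[out_idx] - t) <= 1e-12:
            out[out_idx] = 100.0 * dissolved / dose_mg
            total = dissolved + pop.total_mass_mg(rho) + pending_mass
            worst_residual = max(worst_residual, abs(total - dose_mg) / dose_mg)
            out_idx += 1
        if i + 1 >= nodes.size:
            break
        dt = nodes[i + 1] - t
        c_bulk = dissolved / volume
        if c_bulk < bulk_solubility_mg_ml and pop.cohorts:
            pop, inc = step_dissolve(
                pop, c_bulk, medium, compound, salt=salt, dt_min=dt,
                driving_force_scale=driving_force_scale,
                h_cap_um=h_cap_um, cs_by_form=cs_by_form,
            )
            dissolved += inc
        else:
            for c in pop.cohorts:
                c.wetted_age_min += dt

    if not np.all(np.isfinite(out)):
        raise SimulationError(
            f"non-finite state: dissolved={dissolved}, t_last={nodes[-1]}, "
            f"cohorts={len(pop.cohorts)}"
        )
    return DissolutionProfile(
        times_min=t_grid,
        pct_dissolved=np.clip(out, 0.0, None),
        metadata={
            "medium": medium.name,
            "dose_mg": dose_mg,
            "form": type(dosage_form).__name__ if dosage_form else "powder",
            "mass_balance_residual": worst_residual,
            "driving_force_scale": driving_force_scale,
        },
    )


def virtual_doe(base_config: dict, factors: dict[str, list[float]]):
    """Full-factorial sweep of multiplicative perturbations on a config.

    ``factors`` maps dotted config paths (e.g.
    ``"dosage_form.penetration_velocity_mm_min.none"``) to multiplier lists.
    Returns a list of (label dict, DissolutionProfile) for every combination.
    """
    from .config import apply_multiplier, simulate_config  # local: avoids cycle

    paths = list(factors)
    results = []
    for combo in itertools.product(*(factors[p] for p in paths)):
        cfg = {k: v for k, v in _deepcopy_dict(base_config).items()}
        for path, mult in zip(paths, combo):
            apply_multiplier(cfg, path, mult)
        profile = simulate_config(cfg)
        results.append((dict(zip(paths, combo)), profile))
    return results


def _deepcopy_dict(d):
    import copy

    return copy.deepcopy(d)
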