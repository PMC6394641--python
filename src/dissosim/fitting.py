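"""Calibration of simulator parameters against experimental profiles.

Capsule (Weibull shape/scale) and tablet (penetration velocities and shared
wetting time) parameters are fitted by pooled least squares of simulated
versus observed percent dissolved over all supplied profiles and media; a
single parameter set must explain every medium, as the dosage-form physics is
medium-independent apart from the surfactant split of the penetration
velocity. The optimizer is a bounded derivative-free local search (Powell)
started from the best point of a coarse grid — the simulator response is
piecewise smooth and gradients are unavailable.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from .chemistry import IonizableCompound, Medium, SaltForm
from .dosage import CapsuleModel, TabletModel
from .particles import ParticlePopulation
from .profile import DissolutionProfile
from .simulator import simulate

__all__ = ["SimConfig", "fit_capsule", "fit_tablet", "fit_driving_force_scale"]


class SimConfig:
    """Everything needed to run `simulate` except the parameters under fit."""

    def __init__(
        self,
        compound: IonizableCompound,
        psd_population: ParticlePopulation,
        dose_mg: float,
        salt: SaltForm | None = None,
        dosage_form=None,
        driving_force_scale: float = 1.0,
        dt_internal_min: float = 0.25,
        n_release_events: int = 30,
    ) -> None:
        self.compound = compound
        self.psd_population = psd_population
        self.dose_mg = dose_mg
        self.salt = salt
        self.dosage_form = dosage_form
        self.driving_force_scale = driving_force_scale
        self.dt_internal_min = dt_internal_min
        self.n_release_events = n_release_events

    def run(self, medium: Medium, t_grid, dosage_form=None,
            driving_force_scale=None) -> DissolutionProfile:
        return simulate(
            self.compound, medium, self.psd_population,
            dose_mg=self.dose_mg, t_grid_min=t_grid, salt=self.salt,
            dosage_form=self.dosage_form if dosage_form is None else dosage_form,
            driving_force_scale=(self.driving_force_scale
                                 if driving_force_scale is None
                                 else driving_force_scale),
            dt_internal_min=self.dt_internal_min,
            n_release_events=self.n_release_events,
        )


def _grid_for(profile: DissolutionProfile) -> np.ndarray:
    t = profile.times_min
    return t if t[0] == 0.0 else np.concatenate([[0.0], t])


def _pooled_rss(sim_profiles, data_profiles) -> float:
    rss = 0.0
    for sim, obs in zip(sim_profiles, data_profiles):
        pred = np.interp(obs.times_min, sim.times_min, sim.pct_dissolved)
        rss += float(np.sum((pred - obs.pct_dissolved) ** 2))
    return rss


def _multistart_powell(objective, grid_axes, bounds):
    best_x, best_f = None, math.inf
    for x0 in itertools.product(*grid_axes):
        f0 = objective(np.asarray(x0, dtype=float))
        if f0 < best_f:
            best_f, best_x = f0, np.asarray(x0, dtype=float)
    res = minimize(objective, best_x, method="Powell", bounds=bounds,
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxfev": 400})
    return (res.x, res.fun) if res.fun <= best_f else (best_x, best_f)


def fit_capsule(
    profiles: list[tuple[DissolutionProfile, Medium]],
    sim_config: SimConfig,
    n_grid: int = 4,
) -> CapsuleModel:
    """Fit one (shape, scale) Weibull release pair across all media."""
    if not profiles:
        raise ValueError("need at least one profile")
    bounds = [(0.3, 5.0), (0.05, 120.0)]

    def objective(x):
        shape, scale = x
        cap = CapsuleModel(weibull_shape=float(shape), weibull_scale_min=float(scale))
        sims = [sim_config.run(m, _grid_for(p), dosage_form=cap)
                for p, m in profiles]
        return _pooled_rss(sims, [p for p, _ in profiles])

    axes = [np.linspace(0.5, 3.0, n_grid), np.geomspace(0.5, 30.0, n_grid)]
    x, _ = _multistart_powell(objective, axes, bounds)
    return CapsuleModel(weibull_shape=float(x[0]), weibull_scale_min=float(x[1]))


def fit_tablet(
    profiles: list[tuple[DissolutionProfile, Medium]],
    sim_config: SimConfig,
    tablet_template: TabletModel,
    n_grid: int = 3,
) -> TabletModel:
    """Fit per-surfactant-class penetration velocities and a shared wetting
    time. Classes absent from the supplied media keep the template value."""
    if not profiles:
        raise ValueError("need at least one profile")
    classes = sorted({m.surfactant_class for _, m in profiles})

    def make_tablet(x):
        vels = dict(tablet_template.penetration_velocity_mm_min)
        for i, cls in enumerate(classes):
            vels[cls] = float(x[i])
        return TabletModel(
            mass_mg=tablet_template.mass_mg,
            solid_fraction=tablet_template.solid_fraction,
            true_density_g_ml=tablet_template.true_density_g_ml,
            semi_axes_mm=tablet_template.semi_axes_mm,
            penetration_velocity_mm_min=vels,
            wetting_time_min=float(x[-1]),
        )

    def objective(x):
        tab = make_tablet(x)
        sims = [sim_config.run(m, _grid_for(p), dosage_form=tab)
                for p, m in profiles]
        return _pooled_rss(sims, [p for p, _ in profiles])

    bounds = [(0.01, 10.0)] * len(classes) + [(0.0, 30.0)]
    axes = [np.geomspace(0.1, 2.0, n_grid)] * len(classes) + [
        np.linspace(0.5, 6.0, n_grid)
    ]
    x, _ = _multistart_powell(objective, axes, bounds)
    return make_tablet(x)


def fit_driving_force_scale(
    unformulated_profile: DissolutionProfile,
    medium: Medium,
    sim_config: SimConfig,
) -> float:
    """Scaling factor on (cs - c) calibrated on an unformulated-powder run —
    the hook for difficult-to-model particle geometries."""
    if sim_config.dosage_form is not None:
        raise ValueError("driving-force calibration requires a powder config")
    grid = _grid_for(unformulated_profile)

    def objective(x):
        sim = sim_config.run(medium, grid, driving_force_scale=float(x[0]))
        pred = np.interp(unformulated_profile.times_min, sim.times_min,
                         sim.pct_dissolved)
        return float(np.sum((pred - unformulated_profile.pct_dissolved) ** 2))

    x, _ = _multistart_powell(objective, [np.geomspace(0.2, 3.0, 5)],
                              [(0.01, 10.0)])
    return float(x[0])
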