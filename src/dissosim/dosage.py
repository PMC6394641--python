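"""Dosage-form models: how solids become available to the bulk medium.

A powder is available immediately. A capsule releases solids over time
following a Weibull cumulative distribution (shape, scale fitted to data).
A tablet is modeled as an ellipsoid that liquid penetrates at a fixed
velocity; material at a given depth is wetted when the front reaches it and
is shed into the bulk after a further fixed wetting time, during which the
particles sit in interstitial liquid assumed saturated with drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import Medium

__all__ = [
    "CapsuleModel",
    "TabletModel",
    "ReleaseEvent",
    "ReleaseSchedule",
    "capsule_release_fraction",
    "ellipsoid_from_tablet",
    "capsule_release_schedule",
    "tablet_wetting_schedule",
]


@dataclass
class CapsuleModel:
    weibull_shape: float
    weibull_scale_min: float

    def __post_init__(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale_min <= 0:
            raise ValueError("Weibull shape and scale must be positive")


@dataclass
class TabletModel:
    """An immediate-release tablet approximated as a solid ellipsoid.

    ``penetration_velocity_mm_min`` maps the medium's surfactant class
    ("none" / "surfactant") to a liquid penetration velocity; surfactants wet
    the matrix faster so the two are fitted separately. ``wetting_time_min``
    (time between wetting and shedding) is shared across media.
    """

    mass_mg: float
    solid_fraction: float
    true_density_g_ml: float
    semi_axes_mm: tuple[float, float, float]
    penetration_velocity_mm_min: dict[str, float]
    wetting_time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.solid_fraction <= 1.0):
            raise ValueError("solid fraction must be in (0, 1]")
        if self.wetting_time_min < 0:
            raise ValueError("wetting time must be >= 0")
        if any(v <= 0 for v in self.penetration_velocity_mm_min.values()):
            raise ValueError("penetration velocities must be positive")
        a, b, c = self.semi_axes_mm
        v_app_mm3 = self.mass_mg / (self.solid_fraction * self.true_density_g_ml)
        v_ell = (4.0 / 3.0) * math.pi * a * b * c
        if abs(v_ell - v_app_mm3) > 0.01 * v_app_mm3:
            raise ValueError(
                f"ellipsoid volume {v_ell:.4g} mm³ inconsistent with apparent "
                f"volume {v_app_mm3:.4g} mm³ (mass/(SF*rho))"
            )

    def velocity_for(self, medium: Medium) -> float:
        key = medium.surfactant_class
        if key not in self.penetration_velocity_mm_min:
            raise KeyError(f"no penetration velocity fitted for media class {key!r}")
        return self.penetration_velocity_mm_min[key]

    @property
    def apparent_volume_ml(self) -> float:
        return self.mass_mg / (self.solid_fraction * self.true_density_g_ml) * 1e-3


@dataclass
class ReleaseEvent:
    release_time_min: float
    mass_fraction_solids: float
    pre_exposure_min: float = 0.0
    interstitial_dissolved_mg: float = 0.0


@dataclass
class ReleaseSchedule:
    events: list[ReleaseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(e.mass_fraction_solids for e in self.events)
        if self.events and abs(total - 1.0) > 1e-6:
            raise ValueError(f"release mass fractions sum to {total}, not 1")
        times = [e.release_time_min for e in self.events]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("release times must be non-decreasing")


def capsule_release_fraction(t_min: float, cap: CapsuleModel) -> float:
    """Cumulative fraction of solids released from the capsule shell by t."""
    if t_min < 0:
        raise ValueError("time must be >= 0")
    return 1.0 - math.exp(-((t_min / cap.weibull_scale_min) ** cap.weibull_shape))


def capsule_release_schedule(
    cap: CapsuleModel, n_events: int = 100, coverage: float = 0.999
) -> ReleaseSchedule:
    """Discretize the Weibull release into events at equal-probability slices.

    Particles are dry inside the shell, so every event enters the bulk with
    zero pre-exposure and no interstitial dissolved mass; the tail beyond the
    coverage quantile is lumped into the final event.
    """
    if n_events < 1:
        raise ValueError("need at least one release event")
    qs = np.linspace(0.0, coverage, n_events + 1)
    events = []
    for q0, q1 in zip(qs[:-1], qs[1:]):
        q_mid = 0.5 * (q0 + q1)
        t = cap.weibull_scale_min * (-math.log(1.0 - q_mid)) ** (1.0 / cap.weibull_shape)
        frac = q1 - q0
        if q1 == coverage:
            frac += 1.0 - coverage  # lump the tail
        events.append(ReleaseEvent(release_time_min=t, mass_fraction_solids=frac))
    return ReleaseSchedule(events=events)


def ellipsoid_from_tablet(
    mass_mg: float,
    solid_fraction: float,
    true_density_g_ml: float,
    aspect_ratios: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float, float]:
    """Semi-axes (mm) of an ellipsoid matching the tablet's apparent volume.

    ``aspect_ratios`` gives (b/a, c/a), each in (0, 1].
    """
    ba, ca = aspect_ratios
    if mass_mg <= 0 or solid_fraction <= 0 or true_density_g_ml <= 0:
        raise ValueError("tablet mass, solid fraction and density must be positive")
    if not (0 < ba <= 1 and 0 < ca <= 1):
        raise ValueError("aspect ratios must lie in (0, 1]")
    v_mm3 = mass_mg / (solid_fraction * true_density_g_ml)  # mg/(g/mL) = mm³
    a = (v_mm3 / ((4.0 / 3.0) * math.pi * ba * ca)) ** (1.0 / 3.0)
    return a, ba * a, ca * a


def _wetted_fraction(delta: float, axes: tuple[float, float, float]) -> float:
    """Fraction of ellipsoid volume within depth ``delta`` of the surface,
    approximating the wet front by shrinking each semi-axis by delta."""
    a, b, c = axes
    core = max(a - delta, 0.0) * max(b - delta, 0.0) * max(c - delta, 0.0)
    return 1.0 - core / (a * b * c)


def tablet_wetting_schedule(
    tab: TabletModel,
    medium: Medium,
    cs_interstitial_mg_ml: float,
    n_shells: int = 100,
    dose_mg: float | None = None,
) -> ReleaseSchedule:
    """Shell-discretized release schedule for the wetting-front tablet model.

    The wet front advances at the fitted penetration velocity; the solid
    wetted between two front positions forms a shell, released to the bulk a
    fixed wetting time after it was wetted. While resident, the shell's
    interstitial pore liquid saturates with drug; that pre-dissolved mass
    (capped at the shell's drug content) enters solution at release.
    ``dose_mg`` is the drug content of the tablet (defaults to tablet mass,
    i.e. a pure-drug compact).
    """
    if n_shells < 1:
        raise ValueError("need at least one shell")
    dose = tab.mass_mg if dose_mg is None else dose_mg
    v = tab.velocity_for(medium)
    axes = tab.semi_axes_mm
    depth_full = min(axes)
    t_full = depth_full / v
    taus = np.linspace(0.0, t_full, n_shells + 1)
    porosity = 1.0 - tab.solid_fraction
    v_app_ml = tab.apparent_volume_ml

    events = []
    w_prev = 0.0
    for tau in taus[1:]:
        w = _wetted_fraction(v * tau, axes)
        frac = w - w_prev
        w_prev = w
        if frac <= 0:
            continue
        pore_ml = frac * v_app_ml * porosity
        interstitial = min(pore_ml * cs_interstitial_mg_ml, frac * dose)
        events.append(
            ReleaseEvent(
                release_time_min=tau + tab.wetting_time_min,
                mass_fraction_solids=frac,
                pre_exposure_min=tab.wetting_time_min,
                interstitial_dissolved_mg=interstitial,
            )
        )
    # numerical guard: force fractions to sum to exactly 1
    total = sum(e.mass_fraction_solids for e in events)
    if events and abs(total - 1.0) > 0:
        events[-1].mass_fraction_solids += 1.0 - total
    return ReleaseSchedule(events=events)
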