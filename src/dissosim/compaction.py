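"""Compaction surrogate: solid fraction, tensile strength, and the linear
correlation chain from tablet properties to early dissolution.

Solid fraction ``SF = (mass / V_apparent) / rho_true`` (porosity ``1 - SF``)
is a tablet-image-independent compaction descriptor: moisture uptake and
compression force both act on dissolution through it. Across dose strengths a
single linear relation links SF to disintegration time, and a second links
disintegration time to percent dissolved at 15 minutes, so the two compose
into a direct affine SF -> %D15 map. Tensile strength (diametral,
``2F / (pi D t)``), normalized for the tablet's surface-area-to-volume ratio,
gives an image-independent alternative regressor. Inverting a fitted link at
the edges of a clinically derived dissolution safe space yields in-process
control limits on the tablet property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TabletMeasurement",
    "LinearLink",
    "LinearSurrogateChain",
    "solid_fraction",
    "tensile_strength",
    "sa_v_normalize",
    "fit_chain",
    "derive_control_limits",
]

TYPICAL_SF_RANGE = (0.80, 0.95)


@dataclass
class TabletMeasurement:
    mass_mg: float
    apparent_volume_ml: float
    true_density_g_ml: float
    breaking_force_N: float | None = None
    diameter_mm: float | None = None
    thickness_mm: float | None = None
    surface_area_mm2: float | None = None
    volume_mm3: float | None = None
    disintegration_time_min: float | None = None
    pct_dissolved_15min: float | None = None
    strength_label: str = ""
    tensile_strength_MPa: float | None = None  # user-supplied for shaped tablets

    @property
    def solid_fraction(self) -> float:
        return solid_fraction(self.mass_mg, self.apparent_volume_ml,
                              self.true_density_g_ml)

    def tensile_strength_normalized(self, power: float = 1.0) -> float | None:
        ts = self.tensile_strength_MPa
        if ts is None:
            if None in (self.breaking_force_N, self.diameter_mm, self.thickness_mm):
                return None
            ts = tensile_strength(self.breaking_force_N, self.diameter_mm,
                                  self.thickness_mm)
        if self.surface_area_mm2 is None or self.volume_mm3 is None:
            return ts
        return sa_v_normalize(ts, self.surface_area_mm2, self.volume_mm3, power)


def solid_fraction(mass_mg: float, apparent_volume_ml: float,
                   true_density_g_ml: float) -> float:
    """Tablet solid fraction (apparent density over true density)."""
    if min(mass_mg, apparent_volume_ml, true_density_g_ml) <= 0:
        raise ValueError("mass, volume and density must be positive")
    sf = (mass_mg / apparent_volume_ml) / (true_density_g_ml * 1e3)
    if sf > 1.05:
        raise ValueError(
            f"solid fraction {sf:.3f} exceeds 1.05: apparent density above "
            "true density is physically impossible — check the inputs"
        )
    if not (TYPICAL_SF_RANGE[0] <= sf <= TYPICAL_SF_RANGE[1]):
        warnings.warn(
            f"solid fraction {sf:.3f} outside the typical compressed-tablet "
            f"range {TYPICAL_SF_RANGE}", stacklevel=2,
        )
    return sf


def tensile_strength(breaking_force_N: float, diameter_mm: float,
                     thickness_mm: float) -> float:
    """Diametral tensile strength of a round tablet, 2F/(pi D t), in MPa."""
    if min(breaking_force_N, diameter_mm, thickness_mm) <= 0:
        raise ValueError("force and dimensions must be positive")
    return 2.0 * breaking_force_N / (np.pi * diameter_mm * thickness_mm)


def sa_v_normalize(value: float, surface_area_mm2: float, volume_mm3: float,
                   power: float = 1.0) -> float:
    """Normalize a tablet property by (SA/V)**power to remove image size."""
    if surface_area_mm2 <= 0 or volume_mm3 <= 0:
        raise ValueError("surface area and volume must be positive")
    return value * (surface_area_mm2 / volume_mm3) ** power


@dataclass
class LinearLink:
    slope: float
    intercept: float
    r: float = float("nan")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, y: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope link")
        return (y - self.intercept) / self.slope


@dataclass
class LinearSurrogateChain:
    sf_to_dt: LinearLink
    dt_to_d15: LinearLink
    sf_to_d15: LinearLink  # exact affine composition of the two above
    ts_norm_to_d15: LinearLink | None = None
    safe_space_d15: tuple[float, float] | None = None
    fitted_range: dict = field(default_factory=dict)


def _ols(x, y) -> LinearLink:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("regression needs >= 2 points with varying x")
    res = stats.linregress(x, y)
    return LinearLink(slope=float(res.slope), intercept=float(res.intercept),
                      r=float(res.rvalue))


def fit_chain(
    measurements: list[TabletMeasurement],
    safe_space_d15: tuple[float, float] | None = None,
    sa_v_power: float = 1.0,
) -> LinearSurrogateChain:
    """Fit the SF -> disintegration -> %D15 chain by ordinary least squares.

    The direct SF -> %D15 link is the analytic affine composition of the two
    fitted links (slope product, composed intercept), not a third regression.
    A normalized-tensile-strength -> %D15 link is fitted when the measurements
    carry breaking force (or a precomputed tensile strength) plus SA/V data.
    """
    with_dt = [m for m in measurements if m.disintegration_time_min is not None]
    with_both = [m for m in with_dt if m.pct_dissolved_15min is not None]
    if len(with_dt) < 3 or len(with_both) < 3:
        raise ValueError("need >= 3 measurements with disintegration and %D15")

    sf_to_dt = _ols([m.solid_fraction for m in with_dt],
                    [m.disintegration_time_min for m in with_dt])
    dt_to_d15 = _ols([m.disintegration_time_min for m in with_both],
                     [m.pct_dissolved_15min for m in with_both])
    sf_to_d15 = LinearLink(
        slope=dt_to_d15.slope * sf_to_dt.slope,
        intercept=dt_to_d15.slope * sf_to_dt.intercept + dt_to_d15.intercept,
    )

    ts_link = None
    ts_pairs = [
        (m.tensile_strength_normalized(sa_v_power), m.pct_dissolved_15min)
        for m in measurements
        if m.pct_dissolved_15min is not None
        and m.tensile_strength_normalized(sa_v_power) is not None
    ]
    if len(ts_pairs) >= 3:
        ts_link = _ols([p[0] for p in ts_pairs], [p[1] for p in ts_pairs])

    sfs = [m.solid_fraction for m in measurements]
    return LinearSurrogateChain(
        sf_to_dt=sf_to_dt, dt_to_d15=dt_to_d15, sf_to_d15=sf_to_d15,
        ts_norm_to_d15=ts_link, safe_space_d15=safe_space_d15,
        fitted_range={
            "solid_fraction": (min(sfs), max(sfs)),
            "pct_dissolved_15min": (
                min(m.pct_dissolved_15min for m in with_both),
                max(m.pct_dissolved_15min for m in with_both),
            ),
        },
    )


def derive_control_limits(
    chain: LinearSurrogateChain,
    x_variable: str = "tensile_norm",
    friability_floor: float | None = None,
) -> tuple[float, float]:
    """Invert a fitted link at the dissolution safe-space boundaries.

    Returns ``(x_lower, x_upper)`` on the chosen tablet property
    (``"tensile_norm"`` or ``"solid_fraction"``), ordered correctly for either
    slope sign. A friability floor raises the lower limit (soft tablets chip).
    """
    if chain.safe_space_d15 is None:
        raise ValueError("chain has no dissolution safe space set")
    if x_variable == "tensile_norm":
        link = chain.ts_norm_to_d15
        if link is None:
            raise ValueError("no tensile-strength link was fitted")
    elif x_variable == "solid_fraction":
        link = chain.sf_to_d15
    else:
        raise ValueError(f"unknown control variable {x_variable!r}")

    d15_lo, d15_hi = chain.safe_space_d15
    lo_fit, hi_fit = chain.fitted_range.get("pct_dissolved_15min", (d15_lo, d15_hi))
    if d15_lo < lo_fit or d15_hi > hi_fit:
        warnings.warn(
            "safe space extends beyond the fitted %D15 range; control limits "
            "are extrapolated", stacklevel=2,
        )
    x1, x2 = link.invert(d15_lo), link.invert(d15_hi)
    lower, upper = (x1, x2) if x1 <= x2 else (x2, x1)
    if friability_floor is not None:
        lower = max(lower, friability_floor)
    return lower, upper
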