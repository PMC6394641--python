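"""Seeded synthetic-data generators for every input class.

Laser-diffraction-style particle size distributions, noisy dissolution
profiles from a known truth curve, and compaction datasets (solid fraction /
disintegration / %D15 with strength arms) — everything the fitting and
surrogate layers consume, generated as pure functions of (parameters, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compaction import LinearSurrogateChain, TabletMeasurement
from .metrics import ProfileFit
from .profile import DissolutionProfile

__all__ = ["gen_psd", "gen_profile", "gen_tablet_dataset"]


def gen_psd(
    median_diameter_um: float,
    geometric_sd: float,
    n_points: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Volume-weighted lognormal particle size distribution.

    Returns a table with columns ``diameter_um`` and ``fraction`` (volume
    fractions), emulating a laser-light-scattering measurement: log-spaced
    size channels spanning +/- 4 log-sd around the median, with small
    multiplicative channel noise.
    """
    if geometric_sd <= 1.0:
        raise ValueError("geometric SD must exceed 1")
    if median_diameter_um <= 0:
        raise ValueError("median diameter must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.log(geometric_sd)
    lo = np.log(median_diameter_um) - 4.0 * sigma
    hi = np.log(median_diameter_um) + 4.0 * sigma
    edges = np.linspace(lo, hi, n_points + 1)
    centers = np.exp(0.5 * (edges[:-1] + edges[1:]))
    z = (np.log(centers) - np.log(median_diameter_um)) / sigma
    density = np.exp(-0.5 * z**2)
    noise = rng.lognormal(mean=0.0, sigma=0.01, size=n_points)
    frac = density * noise
    frac /= frac.sum()
    return pd.DataFrame({"diameter_um": centers, "fraction": frac})


def gen_profile(
    truth: ProfileFit,
    t_grid_min,
    noise_sd_pct: float = 0.0,
    seed: int = 0,
) -> DissolutionProfile:
    """Dissolution profile from a truth model plus iid Gaussian noise,
    clipped to [0, 102] (assay values can slightly exceed 100%)."""
    if noise_sd_pct < 0:
        raise ValueError("noise SD must be >= 0")
    t = np.asarray(t_grid_min, dtype=float)
    y = truth.predict(t)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd_pct, size=t.shape)
    return DissolutionProfile(
        times_min=t,
        pct_dissolved=np.clip(y, 0.0, 102.0),
        metadata={"truth": truth.params, "noise_sd_pct": noise_sd_pct, "seed": seed},
    )


def gen_tablet_dataset(
    truth_chain: LinearSurrogateChain,
    n: int = 24,
    noise_dt_min: float = 0.0,
    noise_d15_pct: float = 0.0,
    seed: int = 0,
    sf_range: tuple[float, float] = (0.80, 0.95),
    true_density_g_ml: float = 1.25,
    mass_choices_mg: tuple[float, ...] = (100.0, 200.0, 400.0),
) -> list[TabletMeasurement]:
    """Compaction dataset with the structure of a multi-strength study.

    Solid fractions span ``sf_range``; disintegration time and %D15 follow
    the affine truth chain plus Gaussian noise. Tablets cycle through dose
    strengths (masses) and through compression / humidity arms — the humidity
    arm reaches its solid fraction through swelling (larger apparent volume)
    rather than lower compression, but lies on the same truth line.
    """
    if n < 6:
        raise ValueError("need at least 6 tablets")
    rng = np.random.default_rng(seed)
    sfs = np.linspace(sf_range[0], sf_range[1], n)
    arms = ("compression", "humidity")
    out: list[TabletMeasurement] = []
    for i, sf in enumerate(sfs):
        mass = mass_choices_mg[i % len(mass_choices_mg)]
        v_app_ml = mass / (sf * true_density_g_ml * 1e3)
        dt = float(truth_chain.sf_to_dt.predict(sf))
        d15 = float(truth_chain.dt_to_d15.predict(dt))
        if noise_dt_min > 0:
            dt += float(rng.normal(0.0, noise_dt_min))
        if noise_d15_pct > 0:
            d15 += float(rng.normal(0.0, noise_d15_pct))
        out.append(
            TabletMeasurement(
                mass_mg=mass,
                apparent_volume_ml=v_app_ml,
                true_density_g_ml=true_density_g_ml,
                disintegration_time_min=dt,
                pct_dissolved_15min=float(np.clip(d15, 0.0, 110.0)),
                strength_label=f"{mass:.0f}mg-{arms[i % 2]}",
            )
        )
    return out
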