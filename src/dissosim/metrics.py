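"""Profile parameterization, similarity factors, and rapid-dissolution rules.

Implements the regulatory model-independent comparison factors

    f1 = 100 * sum|R - T| / sum R          (difference factor)
    f2 = 50 * log10(100 / sqrt(1 + mean((R - T)^2)))   (similarity factor)

with the conventional policy of dropping time points after both profiles
exceed 85% dissolved (keeping the first such point), plus two
model-dependent parameterizations: a Weibull curve
``plateau * (1 - exp(-(t/scale)^shape))`` and a first-order "Z-rate" curve
``p * (1 - exp(-Z t))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .profile import DissolutionProfile

__all__ = [
    "ProfileFit",
    "f2_similarity",
    "f1_difference",
    "fit_profile",
    "pct_at_time",
    "time_to_pct",
    "rapid_dissolution_class",
    "NOT_REACHED",
]


@dataclass
class ProfileFit:
    model: str  # "weibull" | "zrate"
    params: dict
    rss: float
    n_points: int

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "weibull":
            p = self.params
            return p["plateau"] * (1.0 - np.exp(-((t / p["scale"]) ** p["shape"])))
        p = self.params
        return p["p"] * (1.0 - np.exp(-p["Z"] * t))


def _common_grid(reference: DissolutionProfile, test: DissolutionProfile,
                 drop_after_85: bool):
    """Interpolate the test profile onto the reference time grid and apply the
    85%-cutoff point policy."""
    t = reference.times_min
    r = reference.pct_dissolved
    tt = np.interp(t, test.times_min, test.pct_dissolved)
    if drop_after_85:
        both = (r > 85.0) & (tt > 85.0)
        if both.any():
            first = int(np.argmax(both))
            t, r, tt = t[: first + 1], r[: first + 1], tt[: first + 1]
    if t.size < 3:
        raise ValueError("need at least 3 common time points for profile comparison")
    return t, r, tt


def f2_similarity(reference: DissolutionProfile, test: DissolutionProfile,
                  drop_after_85: bool = True) -> float:
    """Similarity factor f2; 100 for identical profiles, >= 50 denotes
    similarity. Symmetric in its arguments up to the interpolation grid."""
    _, r, tt = _common_grid(reference, test, drop_after_85)
    msd = float(np.mean((r - tt) ** 2))
    return 50.0 * math.log10(100.0 / math.sqrt(1.0 + msd))


def f1_difference(reference: DissolutionProfile, test: DissolutionProfile,
                  drop_after_85: bool = True) -> float:
    """Difference factor f1 (not symmetric: normalized by the reference)."""
    _, r, tt = _common_grid(reference, test, drop_after_85)
    denom = float(np.sum(r))
    if denom == 0:
        raise ValueError("reference profile sums to zero; f1 undefined")
    return 100.0 * float(np.sum(np.abs(r - tt))) / denom


def _zrate_init(t, y):
    plateau0 = min(max(y.max() * 1.01, 1e-6), 110.0)
    frac = np.clip(1.0 - y / plateau0, 1e-9, 1.0)
    pos = t > 0
    if pos.sum() >= 2:
        z0 = max(-np.polyfit(t[pos], np.log(frac[pos]), 1)[0], 1e-4)
    else:
        z0 = 0.1
    return z0, plateau0


def fit_profile(profile: DissolutionProfile, model: str = "weibull") -> ProfileFit:
    """Least-squares fit of a Weibull or first-order (Z-rate) release curve.

    Initialization is deterministic: the Z-rate seed comes from a log-linear
    regression of the undissolved fraction, and the Weibull fit warm-starts
    from it with shape 1.
    """
    t = profile.times_min
    y = profile.pct_dissolved
    if t.size < 4:
        raise ValueError("need at least 4 points to fit a profile model")
    if not np.all(np.isfinite(y)):
        raise ValueError("percent values must be finite")
    z0, plateau0 = _zrate_init(t, y)
    try:
        if model == "zrate":
            f = lambda t, Z, p: p * (1.0 - np.exp(-Z * t))
            popt, _ = curve_fit(
                f, t, y, p0=[z0, plateau0],
                bounds=([1e-8, 1e-6], [np.inf, 110.0]), maxfev=20000,
            )
            params = {"Z": float(popt[0]), "p": float(popt[1])}
            resid = y - f(t, *popt)
        elif model == "weibull":
            f = lambda t, shape, scale, plateau: plateau * (
                1.0 - np.exp(-((np.maximum(t, 0.0) / scale) ** shape))
            )
            popt, _ = curve_fit(
                f, t, y, p0=[1.0, 1.0 / z0, plateau0],
                bounds=([1e-3, 1e-6, 1e-6], [20.0, 1e4, 110.0]), maxfev=20000,
            )
            params = {"shape": float(popt[0]), "scale": float(popt[1]),
                      "plateau": float(popt[2])}
            resid = y - f(t, *popt)
        else:
            raise ValueError(f"unknown profile model {model!r}")
    except RuntimeError as exc:
        raise RuntimeError(
            f"{model} fit failed to converge (init Z={z0:.4g}, "
            f"plateau={plateau0:.4g}): {exc}"
        ) from exc
    return ProfileFit(model=model, params=params,
                      rss=float(np.sum(resid**2)), n_points=int(t.size))


def pct_at_time(profile: DissolutionProfile, t_min: float) -> float:
    """Percent dissolved at time t by monotone piecewise-linear interpolation."""
    t = profile.times_min
    if not (t[0] <= t_min <= t[-1]):
        raise ValueError(f"t={t_min} outside the profile's time range")
    return float(np.interp(t_min, t, profile.pct_dissolved))


NOT_REACHED = float("nan")


def time_to_pct(profile: DissolutionProfile, q_pct: float) -> float:
    """First time at which the profile crosses q percent dissolved; NaN
    (NOT_REACHED) if the profile never gets there."""
    t = profile.times_min
    y = profile.pct_dissolved
    if q_pct > y.max():
        return NOT_REACHED
    idx = int(np.argmax(y >= q_pct))
    if idx == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[idx - 1], t[idx], y[idx - 1], y[idx]
    if y1 == y0:
        return float(t1)
    return float(t0 + (q_pct - y0) * (t1 - t0) / (y1 - y0))


def rapid_dissolution_class(profile: DissolutionProfile) -> str:
    """BCS rapid-dissolution check: >= 85% in 15 min supports a class III
    dissolution surrogate; >= 85% in 30 min supports class I; else neither."""
    t_max = profile.times_min[-1]
    t85 = time_to_pct(profile, 85.0)
    if t_max < 30.0 and math.isnan(t85):
        raise ValueError("profile must cover 30 min or reach 85% earlier")
    if not math.isnan(t85) and t85 <= 15.0:
        return "very_rapid_candidate_III"
    if not math.isnan(t85) and t85 <= 30.0:
        return "rapid_candidate_I"
    return "neither"
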