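"""Config-file surface: JSON/YAML descriptions of a simulation.

Schema (all units explicit in key names)::

    compound:
      name: DS-A
      ionization: monoprotic_base        # or monoprotic_acid, neutral
      pKa: 7.6
      intrinsic_solubility_ug_ml: 0.15   # or intrinsic_solubility_mg_ml
      true_density_g_ml: 1.3
      diffusion_coefficient_cm2_s: 8.0e-6  # optional
      molecular_weight_g_mol: 450
    salt:                                # optional
      counterion_pKa: -1.0
      counterion_stoichiometry: 1
      salt_solubility_mg_ml: 1.8
      conversion_lag_min: 3.0
    medium:
      name: pH45-acetate
      volume_ml: 900
      bulk_pH: 4.5
      buffer_species: [[4.76, 50.0]]     # (pKa, total mM) pairs
      surfactant_class: none             # or surfactant
    psd:                                 # either a generator block or a csv
      median_diameter_um: 30
      geometric_sd: 1.8
      n_points: 200
      seed: 7
      # csv: particles.csv   (columns diameter_um, fraction; '# weighting: volume')
    dosage_form:
      kind: tablet                       # powder | capsule | tablet
      # capsule: weibull_shape, weibull_scale_min
      # tablet: mass_mg, solid_fraction, true_density_g_ml, aspect_ratios,
      #         penetration_velocity_mm_min: {none: .., surfactant: ..},
      #         wetting_time_min
    dose_mg: 12
    t_end_min: 60
    t_step_min: 1.0                      # output grid spacing
    simulation:                          # optional numerical knobs
      dt_internal_min: 0.05
      n_release_events: 100
      driving_force_scale: 1.0
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemistry import IonizableCompound, Medium, SaltForm
from .dosage import CapsuleModel, TabletModel, ellipsoid_from_tablet
from .particles import ParticlePopulation, population_from_psd
from .profile import DissolutionProfile

__all__ = [
    "load_config",
    "build_compound",
    "build_salt",
    "build_medium",
    "build_psd_population",
    "build_dosage_form",
    "simulate_config",
    "apply_multiplier",
    "read_psd_csv",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def build_compound(block: dict) -> IonizableCompound:
    b = dict(block)
    if "intrinsic_solubility_ug_ml" in b:
        b["intrinsic_solubility_mg_ml"] = b.pop("intrinsic_solubility_ug_ml") / 1e3
    return IonizableCompound(**b)


def build_salt(block: dict | None, parent: IonizableCompound) -> SaltForm | None:
    if block is None:
        return None
    return SaltForm(parent=parent, **block)


def build_medium(block: dict) -> Medium:
    return Medium(**block)


def read_psd_csv(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a PSD CSV with a ``# weighting: volume|number`` header comment."""
    weighting = "volume"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "weighting" in line:
                weighting = line.split(":", 1)[1].strip()
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return df, weighting


def build_psd_population(block: dict, base_dir: Path | None = None) -> ParticlePopulation:
    if "csv" in block:
        path = Path(block["csv"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        df, weighting = read_psd_csv(path)
        return population_from_psd(df, weighting=weighting,
                                   n_bins=block.get("n_bins", 20))
    from .synthetic import gen_psd

    df = gen_psd(
        median_diameter_um=block["median_diameter_um"],
        geometric_sd=block["geometric_sd"],
        n_points=block.get("n_points", 200),
        seed=block.get("seed", 0),
    )
    return population_from_psd(df, weighting="volume",
                               n_bins=block.get("n_bins", 20))


def build_dosage_form(block: dict | None):
    if block is None:
        return None
    b = dict(block)
    kind = b.pop("kind", "powder")
    if kind == "powder":
        return None
    if kind == "capsule":
        return CapsuleModel(**b)
    if kind == "tablet":
        if "semi_axes_mm" not in b:
            aspect = tuple(b.pop("aspect_ratios", (1.0, 1.0)))
            b["semi_axes_mm"] = ellipsoid_from_tablet(
                b["mass_mg"], b["solid_fraction"], b["true_density_g_ml"], aspect
            )
        else:
            b.pop("aspect_ratios", None)
            b["semi_axes_mm"] = tuple(b["semi_axes_mm"])
        return TabletModel(**b)
    raise ValueError(f"unknown dosage form kind {kind!r}")


def simulate_config(cfg: dict, base_dir: Path | None = None) -> DissolutionProfile:
    """Run a full simulation from a config dict (see module docstring)."""
    from .simulator import simulate

    compound = build_compound(cfg["compound"])
    salt = build_salt(cfg.get("salt"), compound)
    medium = build_medium(cfg["medium"])
    pop = build_psd_population(cfg["psd"], base_dir=base_dir)
    form = build_dosage_form(cfg.get("dosage_form"))
    t_end = cfg.get("t_end_min", 60.0)
    t_step = cfg.get("t_step_min", 1.0)
    t_grid = np.arange(0.0, t_end + t_step / 2, t_step)
    sim = cfg.get("simulation", {})
    return simulate(
        compound, medium, pop,
        dose_mg=cfg["dose_mg"], t_grid_min=t_grid,
        salt=salt, dosage_form=form,
        driving_force_scale=sim.get("driving_force_scale", 1.0),
        dt_internal_min=sim.get("dt_internal_min", 0.05),
        n_release_events=sim.get("n_release_events", 100),
    )


def apply_multiplier(cfg: dict, dotted_path: str, multiplier: float) -> None:
    """Multiply the numeric config entry at ``dotted_path`` in place."""
    keys = dotted_path.split(".")
    node = cfg
    for k in keys[:-1]:
        if not isinstance(node, dict) or k not in node:
            raise KeyError(f"config path {dotted_path!r} not found at {k!r}")
        node = node[k]
    leaf = keys[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise KeyError(f"config path {dotted_path!r} not found at {leaf!r}")
    if not isinstance(node[leaf], (int, float)):
        raise TypeError(f"config path {dotted_path!r} is not numeric")
    node[leaf] = node[leaf] * multiplier
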