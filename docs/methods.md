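# Methods

This note documents the models implemented in `dissosim`, the assumptions
behind them, the defaults and why they were chosen, the numerical choices,
and what the synthetic-data generators do and do not emulate.

## Units

Internal canonical units are mg, mL, minutes, µm (particle radii), mm
(tablet dimensions), and cm²/s (diffusivities). Every I/O field name carries
its unit (`intrinsic_solubility_mg_ml`, `weibull_scale_min`, ...); config
files may give intrinsic solubility in µg/mL via `intrinsic_solubility_ug_ml`
because sub-µg/mL intrinsic solubilities are common for poorly soluble bases.
Temperature is fixed at 37 °C for all solubility inputs; no van't Hoff
correction is applied.

## Solubility and surface chemistry

**Henderson–Hasselbalch.** For a monoprotic base,
`S(pH) = S0 (1 + 10^(pKa − pH))`; for an acid the exponent flips; neutral
compounds are flat. Polyprotic species, ionic-strength activity corrections,
and micellar solubilization are out of scope.

**pH_max.** Solved as the root of `S(pH) = S_salt` with Brent's method on
(0, 14); this agrees with the closed form `pKa − log10(S_salt/S0 − 1)` to
10⁻⁶ and keeps the implementation form-agnostic.

**Surface pH.** The pH at a dissolving particle's surface is the single
unknown of a film flux balance: the diffusion-weighted net charge flux
`Σ z_i (D_i/D_ref)([X_i]_surface − [X_i]_bulk)` must vanish, where the drug
is at its surface saturation, a salt's counterion accompanies the drug at
its stoichiometric ratio, monoprotic buffer components re-speciate at the
surface pH with their totals held at bulk values, and H⁺/OH⁻ use the 37 °C
water ion product (pKw 13.62). All species diffusivities default to equal;
per-species ratios can be supplied. The residual is solved with Brent's
method after a sign-change bracket scan; non-convergence raises an error
carrying the residual values at the bracket ends.

**Salt surface solubility.** During the salt window the dissolving solid is
the salt crystal, whose congruent saturation pins the surface drug
concentration at the salt solubility — in buffered media above pH_max this
is a supersaturation with respect to the free base, maintained at the
surface because surface conversion (below), not precipitation, terminates
salt behaviour. This is what produces the characteristically faster salt
dissolution at equal particle size. The molar balance requires a molecular
weight; a compound without one cannot use the surface-pH solver.

**Salt→free-base conversion.** The counterion dissolves and diffuses away
faster than the drug, so the particle surface reforms as free base after a
lag (default 3 min in the example system, media-independent above pH_max).
Each particle cohort carries a wetted-age clock; when a cohort's age crosses
the lag mid-step, the step splits at the crossing (salt kinetics before,
free-base after) and the cohort is relabeled. Relabeling is instantaneous —
the surface is treated as fully free base from the crossing on; a gradual
surface transition is not modeled.

## Particle population balance

Particles are spheres (shape factor exposed but defaulting to 1.0, not
auto-estimated), binned geometrically from a measured or synthetic size
distribution. Volume weights convert to number weights via 1/r³; each bin's
representative radius is the cube-root (mass-conserving) mean, so the binned
population's mass matches the stated dose exactly.

Radius kinetics follow `dr/dt = −(D/ρh(r))(c_s − c)` with
`h(r) = min(r, 30 µm)` (cap configurable). Holding the bulk concentration
fixed within a step makes the update piecewise closed-form: `r` linear in
time above the cap, `r²` linear below it, with exact extinction handling.
Consequences: mass conservation to round-off at every step, the
Hixson–Crowell cube-root law for coarse particles, and no step-size
constraint from the radius update itself. Particle growth is disabled — when
bulk concentration exceeds surface solubility the driving force clamps to
zero (no precipitation on immediate-release time scales).

## Dosage forms

**Powder.** All mass enters the vessel at t = 0 with age 0.

**Capsule.** Solids release along the Weibull CDF
`1 − exp(−(t/scale)^shape)`, discretized into equal-probability events
(default 100) with the tail beyond the 99.9th percentile lumped into the
last event. Particles are dry inside the shell: they enter with age 0 and no
pre-dissolved mass.

**Tablet.** The compact is an ellipsoid matched to the apparent volume
`mass/(SF·ρ_true)` with user aspect ratios. Liquid penetrates at a fixed
velocity (mm/min), keyed by the medium's surfactant class because
surfactants wet the matrix much faster; the wetting time between wetting and
shedding is shared across media. The uniform-depth wet front is approximated
by shrinking each semi-axis by the same depth δ — a tractable closed-form
shell construction; full wetting occurs at δ = min(a, b, c). The front is
discretized into shells (default 100, merged onto the simulation grid); each
shell's interstitial pore volume `ΔV_apparent (1 − SF)` saturates with drug
at the release-form surface solubility, capped at the shell's drug content,
and that mass enters solution at shedding. During residence the shell's
particles do **not** shrink (the pore liquid is saturated) but their salt
age clocks **do** advance — the two assumptions (particles "exposed during
wetting" vs. "interstices saturate") are reconciled this way; the behaviour
is localized in the release-event `pre_exposure` field if a different
reading is wanted.

## Simulator

Explicit time stepping (default internal step 0.05 min) over the union of
the internal grid, the output grid, and all release-event times, so no event
is straddled. Per step: due events release their solids (as scaled copies of
the template population) and interstitial mass; cohorts advance by the
closed-form update at the current bulk concentration; the bulk concentration
updates from cumulative dissolved mass. Bulk pH is held constant (buffered
media); the bulk feeds back on dissolution only through (c_s − c). Bulk
concentration is ceilinged at the bulk solubility — the free-form
Henderson–Hasselbalch value at bulk pH, or the salt solubility for salt
systems — which sets the profile plateau. `driving_force_scale` multiplies
(c_s − c) uniformly, the calibration hook for hard-to-model geometries.
Halving the internal step changes the example profiles by < 0.1%; runs are
bit-reproducible (no hidden randomness).

## Profile metrics

f2 uses the regulatory formula on the reference time grid (test profile
linearly interpolated), with the conventional policy of dropping points
after both profiles exceed 85% (keeping the first); the policy is
configurable since different jurisdictions phrase it differently. f1 is
normalized by the reference and is deliberately asymmetric. Model fits
(Weibull, first-order Z-rate) use bounded Levenberg–Marquardt/TRF via
`scipy.optimize.curve_fit` with deterministic initialization: Z₀ from a
log-linear regression of the undissolved fraction, Weibull warm-started from
it with shape 1. Plateaus are bounded at 110% to absorb assay noise.

## Parameter fitting

Capsule (shape, scale), tablet (per-class penetration velocities + shared
wetting time), and the driving-force scale are fitted by pooled least
squares of simulated vs. observed percent dissolved on the experimental time
points, unweighted. The optimizer is bounded Powell search seeded from the
best point of a coarse grid — the simulator response is piecewise smooth and
derivative-free search is robust to the event-induced kinks. Bounds: shape ∈
[0.3, 5], scale ∈ (0, 120] min, velocities ∈ [0.01, 10] mm/min, wetting time
∈ [0, 30] min. Fits are deterministic given the data. Parameter recovery on
synthetic truth is the module's acceptance surface; the test suite uses
deliberately coarse simulator settings (≈8 cohorts, 0.25-min steps, ~20
release events) so each fit runs in seconds, with tolerances set
accordingly.

## Compaction surrogate

Solid fraction is `(mass/V_apparent)/ρ_true` with a warning outside the
typical compressed-tablet range [0.80, 0.95] and a hard error above 1.05.
Moisture effects enter only through their effect on measured apparent
volume — no explicit moisture regressor, since tablet density captures both
compression and swelling mechanisms. Tensile strength uses the round-tablet
diametral formula 2F/(πDt); shaped tablets must supply a precomputed value.
SA/V normalization multiplies by (SA/V)^power (default power 1). The
SF→disintegration and disintegration→%D15 links are unweighted OLS with
Pearson r; the direct SF→%D15 link is their exact affine composition, never
a third regression, so the composition identity holds to machine precision.
Control limits invert a chosen link at the safe-space boundaries, reorder
for negative slopes, apply an optional friability floor to the lower limit,
and warn when the safe space lies outside the fitted %D15 range.

## Release testing

The staged acceptance table is hard-coded to the compendial three-stage
scheme (6 units, then 6 more, then 12 more: stage-1 every unit ≥ Q+5;
stage-2 mean of 12 ≥ Q with no unit < Q−15; stage-3 mean of 24 ≥ Q, ≤ 2
units < Q−15, none < Q−25), with Q parameterized. RTRt plans: batch-pooled
mode emits 12 prediction slots with release on the predicted average meeting
Q+5 and failure routing to physical stage-3 testing; continuous mode
stratifies the run into 12 equal segments (count configurable) each held to
stage-2 criteria.

## Synthetic data

The generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`. `gen_psd` emulates laser-diffraction output:
log-spaced channels over ±4 log-SD with a lognormal volume density and 1%
multiplicative channel noise. It does not emulate detector truncation,
multi-modal blends, or shape-biased scattering. `gen_profile` adds iid
Gaussian noise to a Weibull/Z-rate truth curve, clipped to [0, 102] — real
assay noise is heteroscedastic and serially correlated; passing recovery
tests therefore demonstrates estimator correctness, not robustness to
structured measurement error. `gen_tablet_dataset` spans solid fractions
0.80–0.95 across cycled dose strengths and compression/humidity arms lying
on a single affine truth chain; real datasets scatter off the line and may
curve at the porosity extremes. The example system's defaults (pKa 7.6, S0
0.15 µg/mL, salt solubility 1.8 mg/mL, 3-min conversion lag, 12 mg dose,
900 mL pH 4.5 acetate) describe a realistic weak-base tosylate development
program; the quantities not fixed by that description (density 1.3 g/mL,
MW 450, D 8×10⁻⁶ cm²/s, median particle size 30 µm with geometric SD 1.8)
were chosen once as typical small-molecule values.

## Known limitations

- No gastric→intestinal transfer or multi-compartment apparatus; single
  well-mixed vessel with constant bulk pH.
- No mechanistic disintegration (swelling, erosion); the wetting-front model
  is a two-parameter empirical stand-in fitted to data.
- No precipitation/supersaturation decay, agglomeration, or particle
  breakage; no polymorph-specific boundary layers.
- The surface charge balance assumes monoprotic buffers and equal species
  diffusivities unless told otherwise, and needs a molecular weight.
- Stokes–Einstein diffusivity estimation assumes an effective molecular
  density of 1.2 g/cm³; measured D should be preferred when available.
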