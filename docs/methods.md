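# Methods

## The model

`phstrain` implements the Predicted Heat Strain (PHS) model — the rational
heat-balance model of ISO 7933 for assessing occupational heat stress — as a
minute-stepping simulation, and makes its *clothing path* pluggable: the
dynamic (movement-corrected) clothing insulation and evaporative resistance
that enter the heat balance can be computed with the ISO 7933 correction
factors, the ISO 9920 ones, or Lu's single-factor regression for light
clothing.

### Clothing dynamics

Static properties of an ensemble are its basic insulation `Icl` (clo), total
static evaporative resistance `Rt` (m²·kPa/W), moisture permeability index
`imt`, and (for cold-protective shells) an air permeability `pr` (L/m²·s).
The static total insulation is

    Itot = Icl + Ia/fcl,    fcl = 1 + 0.3·Icl,    Ia = 0.716 clo,

and every algorithm produces

    Itot,dyn = Corr_tot·Itot,   Ia,dyn = Corr_a·Ia,
    Icl,dyn  = Itot,dyn − Ia,dyn/fcl.

The correction factors are exponentials in the relative air velocity `var`
and walking speed `vw`:

* **ISO 7933** (all categories): `Corr_tot = exp(0.043 − 0.398·var +
  0.066·var² − 0.378·vw + 0.094·vw²)`, `Corr_a = exp(−0.472·var + 0.047·var²
  − 0.342·vw + 0.117·vw²)`; below 0.6 clo the two are blended linearly in
  `Icl` (the light-clothing "coefficient" rule).
* **ISO 9920**, normal clothing (0.6–1.4 clo): the revised regressions in
  `(var − 0.15)` with a 0.15 m/s still-air reference; cold-protective
  (> 1.4 clo): `exp(−0.0512·(var−0.4) + 0.000794·(var−0.4)² − 0.0639·vw)·
  pr^0.144`; light clothing: linear interpolation in `Icl` between the
  dynamic air layer `Ia,dyn` and the NC-corrected dressed total.
* **Lu** (light clothing only): a single exponential applied to `Itot`,
  sharing ISO 9920's `var − 0.15` reference; the boundary layer uses the
  ISO 9920 `Corr_a` so the `Icl,dyn` split remains well defined.

Evaporative resistance: ISO 7933 double-corrects — `imt,dyn = imt·(2.6·
Corr_tot² − 6.5·Corr_tot + 4.9)`, capped at 0.9 as in the standard's program,
then `Rt,dyn = Itot,dyn[SI]/(imt,dyn·16.7)` through the Lewis relation
(16.7 K/kPa) — while ISO 9920 applies the single factor `1.2·Corr_tot² −
0.5·Corr_tot + 0.3` to the static `Rt`. Lu ensembles reuse the ISO 7933
double correction with Lu's `Corr_tot`.

Numerical conventions:

* All insulation algebra is in clo; SI conversion (×0.155 m²·K/W) happens
  only at the Lewis relation and inside the heat-balance core.
* Inputs outside a regression's published validity range (notably the
  scenarios' vw = 1.25 m/s against ISO 9920's 1.2 m/s bound) are clamped to
  the nearest bound, flagged on the result and logged — the least surprising
  reading when a standard is applied slightly out of range.
* The ISO 7933 exponentials are used as published, uncapped; the standard's
  program caps them at 1, which differs only within ~0.11 m/s of still air,
  outside every condition simulated here.
* Category boundaries: 0.6 and 1.4 clo belong to NC. No studied ensemble
  sits on a boundary, so this is a tie-break convention only.
* `pr` defaults to 1 L/m²·s (airtight shell), making `pr^0.144` the
  identity; the cold-protective ISO 9920 results depend strongly on this
  unpublished parameter, which is why they are guarded by ordering and
  monotonicity properties rather than numeric reproduction.

### Heat-balance core

The minute loop follows the standard's published program structure: an
equilibrium core temperature pulled toward `0.0036·Met + 36.6` °C with a
10-min time constant; mean skin temperature from the clothed/nude
regressions (blended between 0.2 and 0.6 clo) with a 3-min time constant;
clothing-surface temperature solved implicitly from the dry heat balance
(dynamic convective coefficient `max(2.38·|Tsk−Ta|^0.25, 3.5+5.2·var)` or
`8.7·var^0.6` above 1 m/s; radiation with effective radiating-area fraction
0.77 for standing posture); respiratory convective and evaporative losses
from `Met`, `Ta` and `Pa`; required evaporation closing the balance;
required sweat rate through the wettedness-dependent evaporative efficiency,
capped by the maximum sweat rate `(Met−32)·ADu` clipped to [250, 400] W/m²
(+25 % if acclimatized) and smoothed with a 10-min time constant; achieved
evaporation capped by maximum wettedness (0.85 unacclimatized); storage
partitioned between core and skin by a core-temperature-dependent weighting;
rectal temperature from the core-temperature recursion
`Tre += (2·Tcr − 1.962·Tre − 1.31)/9`. Initial state: rectal/core 36.8 °C,
skin 34.1 °C, zero sweat.

Duration limits are whole minutes at first crossing: rectal ≥ 38 °C
(`dlim_tre`), cumulative water loss ≥ 5 % (`dlim_loss95`) or 7.5 %
(`dlim_loss50`, 3 % when drinking is restricted) of body mass, each capped
at the exposure horizon. The maximum allowable time is
`min(dlim_tre, dlim_loss95)`.

Walking speed: when not measured it is estimated as `0.0052·(Met − 58)`,
capped at 0.7 m/s, and the relative air velocity equals the ambient air
speed. When a measured speed is supplied it drives the clothing corrections
*and* the relative air velocity through the omni-directional rule
`var = max(va, vw)` (capped at 3 m/s). The alternative — letting the
measured speed affect only the clothing corrections — is available via
`simulate(..., vw_affects_var=False)`; the default was chosen because it
reproduces the published protective-clothing duration limits exactly while
the alternative misses them by ~10 min.

Each minute the balance residual `storage − (M − W − Cres − Eres − C − R −
E)` is recorded; it is zero to machine precision whenever the required
evaporation is non-negative (all hot scenarios here), and the test suite
asserts closure to 1e−6 W/m² on every packaged scenario.

### Scenarios and evaluation

The nine packaged scenarios are climate-chamber treadmill exposures: one
light-clothing condition (0.48 clo, 30 °C), six normal-clothing conditions
(0.63–1.11 clo, 20–40 °C) and two cold-protective conditions (2.01 clo,
30/40 °C), all at va = 0.33 m/s, measured walking speed 1.25 m/s, 70 min.
Mean radiant temperature is set equal to air temperature (no radiant source
in a climate chamber); posture is standing, external work zero, subjects
unacclimatized with drinking allowed (80 kg/1.78 m; 77 kg/1.76 m for the
light-clothing group).

The comparison grids evaluate each algorithm over air speeds {0.5, 1, 3} m/s
× walking speeds {0.4, 0.8, 1.2} m/s with `var = max(va, vw)`, insulation
subsets {0.6, 0.8, 1.0} (NC), {1.5, 2.0} (SC), {0.2, 0.4} clo (LC), and a
single representative insulation per category (0.4/1/2 clo) for the
evaporative grid, whose static `Rt` is tied to the insulation through the
Lewis relation at a work-clothing permeability index of 0.38. Percent
differences are `100·(ISO9920 − ISO7933)/ISO7933`, the incumbent standard as
baseline, reported as absolute values in summaries.

Model fit is scored by rmsd and bias (measured − predicted) after dropping
the first 10 min; a fit is accepted when the rmsd is below the SD of the
observed data. For a single synthetic series that SD is taken as the SD of
the observed series over the exposure. Comparing rmsd against the
*generating* noise SD instead cannot give a high acceptance rate even for a
perfect model: the expected squared rmsd equals that SD squared, so rmsd
straddles the threshold and roughly 60 % of realisations fall below it.

### Synthetic observations

The exposure studies report only means and SDs, so observed series are
emulated as a model trajectory plus a constant offset plus stationary AR(1)
Gaussian noise (lag-1 autocorrelation 0.8 by default — minute-wise
physiological records are smooth — with the stationary SD set to the
reported experimental SDs, 0.19–0.41 °C for rectal temperature). Water-loss
series are additionally forced non-decreasing by a running maximum. This
emulates measurement noise around a single mean trajectory only; it carries
no inter-subject variability and no model misspecification, so a passing
evaluation demonstrates the pipeline, not field validity of the model.

## Known limitations

* The heat-balance core is the unacclimatized/acclimatized standing-work
  branch of the standard's program; posture effects, reflective clothing and
  directional walking are not modelled (radiating-area fraction and
  reflectivity are fixed constants).
* Cold-protective ISO 9920 corrections need the ensemble's air permeability;
  with the airtight default the predicted limits for those cells are lower
  bounds of a family of curves.
* Duration limits are whole-minute first crossings of a slowly moving
  trajectory; cells whose rectal temperature grazes 38 °C near the horizon
  are sensitive at the several-minute level to percent-level changes in the
  clothing inputs. One published normal-clothing cell (ISO 9920 with
  measured walking speed) differs from this implementation by 5 min for that
  reason; the other seven published cells agree within 1 min.
* Problem sizes: simulations are 70 one-minute steps; grids are 18–27
  points; synthetic-noise calibration uses 10⁴-sample series and 200-seed
  acceptance sweeps. The full test suite runs in a few seconds.
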