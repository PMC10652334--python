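# Methods

## Model structure and assumptions

The plant is discretized into four compartments in series — root, trunk,
branch, leaf — below a single-layer pot soil. Each plant compartment holds a
symplast water pool whose potential follows the two-parameter
pressure–volume model (osmotic component π₀/R, turgor component
−π₀ − ε(1−R) floored at zero) and an apoplast reserve that discharges in
proportion to the increase in PLC once cavitation begins. One
pressure–volume parameterization (the leaf's π₀, ε) is used for every
compartment's symplast, and one vulnerability curve is shared by leaf and
stem xylem: vulnerability segmentation is deliberately not modelled.

Fluxes between compartments are conductance × potential difference. The
axial chain realizes a whole-plant conductance `k_plant · LA` partitioned as
50% of resistance in the root segment, 12.5% each in trunk and branch, 25%
in the leaf; each link is scaled by the mean cavitation state of its end
compartments. There is no refilling: PLC is a running maximum per
compartment.

Atmospheric losses:

* canopy transpiration `gs · VPD/P_atm` over remaining leaf area, with
  stomata linear in relative turgor and a binary light gate (PAR ≥ 10
  µmol m⁻² s⁻¹) — the simplest continuous response consistent with
  turgor-mediated closure, which makes stomatal closure emerge at the
  derived turgor-loss point π₀/(1 + π₀/ε);
* residual (cuticular + leaky-stomata) loss `g_res(T) · VPD/P_atm` over the
  evaporating leaf surface, day and night. g_res is defined at 25 °C and
  responds to temperature with Q10a below the phase-transition temperature
  T_p and Q10b above it, continuous at T_p;
* bark loss at 2·g_res per unit bark surface (trunk + branch lateral
  cylinder areas).

**Residual-loss area basis.** Drought-box residual conductances for
broadleaf species are conventionally normalized by *double-sided* leaf area,
while conifer values use projected area. Canopy leaf areas are projected.
To conserve the measured flux, the simulator therefore applies residual leaf
loss over `g_res × leaf_surface_ratio × LA`, with `leaf_surface_ratio = 2`
for the broadleaf parameter sets (*P. nigra*, *Q. ilex*) and 1 for the
conifers. The ratio is an ordinary trait field and can be set per species.

**Leaf shedding.** For deciduous parameter sets the shed fraction
`PLF = 100/(1 + exp(rate (Ψ_leaf − ψ_half)))` (defaults 4 MPa⁻¹, −1.8 MPa)
is applied as a running maximum — a canopy, once shed, does not regrow
within a dry-down. Shedding reduces evaporating and transpiring area only;
the water content of shed leaves is not removed from the balance (the
simplification keeps the water budget closed and errs by at most the shed
leaves' symplast water, a few percent of plant storage).

## Soil

Campbell retention `Ψ = ψ_e · θ_eff^(−b)` on the relative-water-content
convention (water volume = pot volume × RWC/100; saturation 100%, field
capacity 37%, residual 9%), with ψ_e solved so that Ψ(field capacity) =
−0.033 MPa; b = 6 (sandy clay) by default; Ψ clipped at −50 MPa at residual.
Soil evaporation is zero (film-covered pot surface).

The soil–root interface follows the Campbell unsaturated-conductivity law
`k = k_sat · θ_eff^(2b+3)`. That exponent (15 at b = 6) spans ~8 orders of
magnitude between saturation and field capacity, so the *saturated* value is
a poor handle for choosing a default: instead the default k_sat is anchored
so the interface passes 50 mmol s⁻¹ MPa⁻¹ — an order of magnitude above
whole-plant conductance — at a soil potential of −1 MPa. The interface then
only limits uptake in genuinely dry soil, and predawn plant potentials track
soil potential until late in the dry-down, as observed in pot experiments.
`k_sat_soilroot` can be set explicitly to override the anchor.

**Initial condition.** Runs start at field capacity. The model has no
drainage flux, and under the bookkeeping convention above a "saturated"
100 L pot would hold 63 L of above-field-capacity water that, in a real
drained pot, leaves by gravity within hours; starting at saturation would
route that water through transpiration instead. `SimOptions.initial_rwc`
accepts any value up to saturation for users who want the undrained case.

## Numerics

Backward Euler on the four plant pools, solved simultaneously each sub-step
by damped Newton iteration; the Jacobian of the chain is tridiagonal and
each iteration is one Thomas solve. Leaf symplast time constants are tens of
seconds — far below the 600 s default step — so implicit stepping is
required for stability. Soil state and cavitation-scaled conductances are
frozen over a sub-step (they evolve on much slower scales); Newton steps are
clamped to half a pool's capacity and pools floored at 10⁻⁴ of capacity; a
sub-step that fails to converge in 80 iterations halves dt down to
`dt_min = 1 s` before aborting. Internal fluxes are evaluated once at the
converged state and applied antisymmetrically, so total water (soil + plant
+ undischarged apoplast + cumulative losses) is conserved to floating-point
rounding; every run verifies this balance (tolerance 10⁻³ of initial water
per simulated day; achieved ~10⁻¹⁴). Output is hourly regardless of internal
sub-stepping. The flat numerical core is JIT-compiled with numba when
available; the pure-Python fallback computes identically.

Halving the step changes the final-day mean leaf potential by well under
0.5%. Forcing is interpolated linearly between hourly climate records and
evaluated at the backward end of each sub-step.

## Metrics

* `t_close`: first time midday transpiration (total loss, the quantity a
  balance records, averaged 12:00–14:00) falls below 12% of its trajectory
  maximum — the P_gs88 convention applied to the trajectory itself, so the
  metric remains self-consistent when traits are perturbed. Crossings are
  linearly interpolated on the daily series.
* `t_cav` / `thf`: failure is the first crossing of leaf potential below the
  99%-PLC potential of the vulnerability curve; `thf = t_close + t_cav`.
  Runs cut short before failure carry flags rather than extrapolations.
* Predawn potential is the 05:00 sample; midday values average 12:00–14:00.

## Trait extraction

* **Midday transpiration from balance mass**: least-squares slope over all
  5-min samples in the 2 h midday window, normalized by leaf area — robust
  to 50 g quantization for fluxes ≥ 0.5 mmol m⁻² s⁻¹.
* **P_gs88**: Weibull `E = Emax·exp(−((−Ψ)/b)^c)` by multi-start nonlinear
  least squares (grid on b, c); the closure point is where the *fitted*
  curve reaches 0.12·Emax, `−b(−ln 0.12)^{1/c}`.
* **Pressure–volume**: classic 1/Ψ vs (1−RWC) analysis; the post-turgor-loss
  segment is chosen by maximizing tail linearity (r², ≥3 points), π₀ from
  its intercept, ε from the pre-segment turgor slope against the
  extrapolated osmotic line, TLP from π₀/(1+π₀/ε).
* **Residual conductance**: the post-closure phase of a drought-box mass
  series is the longest terminal window whose local slope stays within 10%
  of the terminal slope; g_res = slope / (VPD/P_atm) / evaporating area (the
  caller supplies the single- vs double-sided area convention).
* **Temperature response**: exhaustive two-segment fit of ln g_res vs 1/T(K)
  over interior breakpoints (≥2 points per side, minimum combined SSE); T_p
  from the intersection of the two Arrhenius lines; Q10a/Q10b from the
  ln g vs T(°C) slope *within each segment* (`Q10 = exp(10·slope)`), i.e.
  the Q10 of the g–temperature relationship on each side of T_p. This
  convention round-trips the Q10-form forward model exactly, which a fixed
  single-reference-temperature conversion of the Arrhenius slopes would not.
  Exactly-parallel segments (single-slope data) are flagged degenerate with
  T_p undefined.

## Synthetic experiments

`generate_observed_dataset` runs the simulator for a noise-free truth, then
emits (a) predawn/midday potentials every `psi_every_days` (default 3) with
homoscedastic Gaussian noise (default sd 0.15 MPa; an optional
heteroscedastic mode doubles the sd past stomatal closure, off by default),
(b) pot mass every 5 min as tare + remaining system water, quantized to the
50 g balance resolution, and (c) daily shed-leaf dry mass for deciduous
runs (80 g m⁻² leaf dry mass per area). Watering events, soil evaporation
and embolism imaging are not emulated; mass series are strictly
non-increasing. Everything is reproducible from the seed. Passing recovery
tests on these data therefore demonstrates estimator correctness under the
stated noise model — not robustness to instrument drift, weather gaps or
between-tree variability, which real campaigns add.

## Standardized comparisons and problem sizes

Species comparisons and sensitivity analyses standardize to a common canopy
of 2 m² and a 20 L pot under a constant synthetic summer day (15–32 °C,
30–80% RH antiphase, PAR peak 1800 µmol m⁻² s⁻¹, wind 1 m s⁻¹) — desk-scale
study conditions chosen once so a full dry-down lasts one to three weeks and
a 12-parameter Saltelli analysis (N = 128, i.e. 1792 simulations per
species) completes in seconds. Sensitivity runs use a 1800 s step and a
120-day horizon; runs that miss closure or failure are imputed by the
response median and counted (an error if >10% of the design).

The default sensitivity subset perturbs
{π₀, ε, gs_max, g_res, Q10a, Q10b, T_p, P50, slope, apoplastic fraction,
symplast volume per area, k_plant} by ±10% (uniform) around the species
values; both the subset and the bounds fraction are arguments.

## Sensitivity estimator

Scrambled Sobol' sequences (2k dimensions) provide the A/B sample matrices;
total-order indices use the Jansen estimator
`S_Ti = Σ(f(A) − f(AB_i))² / (2N·Var)` with the variance taken over the
pooled A and B evaluations, and percentile bootstrap CIs over sample rows.
The estimator is verified against the closed-form Ishigami indices
(0.5574, 0.4424, 0.2437 at a = 7, b = 0.1) and an additive two-factor model.

## Known limitations

* **Trait rankings reflect this model's structure.** In this
  implementation, the time to stomatal closure is governed first by the
  transpiration rate parameters (gs_max, k_plant) and only second by the
  osmotic potential: with Campbell b = 6 retention, little soil water sits
  behind the ±0.1·π₀ shift of the closure threshold, so π₀ acts mainly
  through the gs(Ψ) trajectory. Likewise Q10a ranks below P50 for the
  evergreen post-closure phase because the 15–32 °C standard day spends few
  hours far above the 25 °C g_res reference. Field parameterizations with
  measured soil retention, species wood-water reserves and hotter drought
  climates can reweight these rankings substantially; treat the shipped
  standardized conditions as a reproducible benchmark, not a field
  prediction.
* Single soil layer, no root growth, no rooting-depth variation, no
  drainage, no rain or rewatering, no recovery or refilling, no
  photosynthesis/carbon coupling, no ABA signalling.
* One PV parameterization and one vulnerability curve for the whole plant;
  no vulnerability segmentation between leaves and stems.
* The fractal branching constants (branch volume 0.5× and diameter 0.4× of
  the trunk, root volume 0.8×) and the conductance partition are declared
  defaults, not measurements.
* The 5-compartment topology is a deliberate simplification; its adequacy
  is judged by the property suite (mass balance, equilibrium, closed-form
  drainage, monotone cavitation), not by equivalence to any larger model.
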