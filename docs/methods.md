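# Methods

This note records the models implemented in `wheatphys`, the conventions
and defaults they use, what the synthetic-experiment generator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Forward photosynthesis model

Net assimilation follows the two-limitation FvCB scheme,
`A = min(Ac, Aj) − Rd`, with Rubisco-limited and RuBP-regeneration-limited
gross rates evaluated at the chloroplastic CO₂ mole fraction `Cc`.
Finite mesophyll conductance couples `Cc = Ci − A/gm`; substituting into
either limited rate yields a quadratic in A whose physical (smaller) root
is taken, computed in the cancellation-safe form `2c/(b + sqrt(b² − 4c))`
so that very large g_m converges smoothly to the infinite-g_m closed form
(relative agreement better than 1e−9 at g_m = 10⁹). Triose-phosphate
limitation is not modelled. At a tie `Ac = Aj` the point is reported
Rubisco-limited; the plain `min` rule is used with no hyperbolic
smoothing between limitations.

Electron transport is the smaller root of
`θJ² − (αQ + Jmax)J + αQJmax = 0` with θ = 0.85 and α = 0.24 mol e⁻ mol
photon⁻¹, the conventional defaults of A–C_i fitting tools; both are
configurable on `FvCBParameters`.

Rubisco kinetic constants are not identifiable from the data this
package targets, so the widely used in-vivo tobacco set is adopted:
Kc25 = 404.9 µbar, Ko25 = 278.4 mbar, Γ*25 = 42.75 µbar, O = 210 mbar,
with activation energies 79.43, 36.38 and 37.83 kJ mol⁻¹. All are
exposed on `KineticConstants`. Because the same constants drive both the
generator and the fitters, capacity-recovery checks are internally
consistent regardless of which kinetic set a field study actually used.

Unit conventions: 1 bar total pressure is assumed throughout, so
µmol mol⁻¹ and µbar are numerically equal; the Kelvin conversion uses
273 (25 °C ↔ 298 K) so that the `Tk − 298` Arrhenius pivot is exact at
the 25 °C reference everywhere.

## Temperature-response models and fitting

* **Arrhenius** (V_cmax, R_d, kinetics): `k25·exp[Ea(Tk−298)/(R·298·Tk)]`,
  Ea in kJ mol⁻¹. Fitted by nonlinear least squares; exact on its own
  noiseless forward curve.
* **Peaked Arrhenius** (J_max): the Arrhenius rise times a deactivation
  bracket controlled by H_d and ΔS. H_d is fixed at 200 kJ mol⁻¹ to
  avoid over-parameterisation; ΔS is bounded to [500, 800] J mol⁻¹ K⁻¹
  to prevent exchange with Ea. Starting values: k25 at the interpolated
  25 °C value, Ea = 40 kJ mol⁻¹, ΔS = 640 J mol⁻¹ K⁻¹. The optimum is
  reported from the closed form `Topt = Hd/(ΔS − R·ln[Ea/(Hd−Ea)])`,
  which a grid-search oracle (0.001 °C step) confirms to within 0.01 °C.
* **Q10** (R_d): fitted in log space, where the model is exactly linear,
  so the estimate is closed-form; a two-point series at 25/35 °C reduces
  to the plain ratio.
* **Parabola** (A_sat): `Aopt − b(T − Topt)²` is an exact
  re-parameterisation of quadratic regression, so the fit is the
  closed-form polynomial least-squares solution re-expressed at the
  vertex — no iteration, no local optima.
* **Quadratic** (g_m, g_s, C_i, J:V ratio): plain polynomial least
  squares; the vertex `−B/(2C)` is the reported optimum and is flagged
  undefined when |C| < 1e−12.

Replicates at a temperature enter the fits as individual points (no
pre-averaging). Standard errors are asymptotic, from the Jacobian at the
optimum (Gauss–Newton approximation); the interval-coverage test uses
t-quantiles at the small residual degrees of freedom of a five-point
series.

## A–C_i estimation

`fit_aci` is a joint two-parameter least squares of (V_cmax, J_max) on
the `min(Ac, Aj) − Rd` surface with measured g_m and R_d held fixed —
not segmented per-limitation fitting. Start at V_cmax = 100,
J_max = 170 µmol m⁻² s⁻¹, with bounded restarts from ×0.5 and ×2 on
non-convergence; convergence tolerance 1e−8 on the cost change, at most
500 iterations per start. With temperature correction off (the default)
the capacities are reported at the curve's leaf temperature. Curves must
span both limitation regimes (points below 300 and above 600 µmol mol⁻¹)
for a well-posed fit; thinner curves fit with a warning. The default
(joint) fit method is recorded in the output metadata. The alternative
`fit_from_cc` route transforms each point to `Cc = Ci − A/gm` and fits
with infinite g_m thereafter; the two routes agree within 0.5% on
well-behaved finite-g_m data and are identical in the g_m → ∞ limit.

## Isotope-based mesophyll conductance

Observed discrimination comes from chamber draw-down,
`ε = Cref/(Cref − Csam)` and
`Δo = 1000ε(δsam − δref)/(1000 + δsam − ε(δsam − δref))`; a draw-down
below 0.1% of Cref triggers a conditioning warning, and equal
concentrations are an error. Permil quantities are carried in ‰ and
converted to fractional form only inside `(1 + a′)` terms.

The infinite-g_m prediction uses the ternary-corrected form
`Δi = (1/(1−t))·[a′ + ((1+t)b − a′)·Ci/Ca]` with
`t = (1 + a′)E/(2 g_ac^t)`; the respiratory component is zero under the
default e = 0 assumption, and `Δf = ((1+t)/(1−t))·f·Γ*/Ca`. Constants:
b = 27.3‰, f = 11.6‰, a = 4.4‰, a_b = 2.9‰, ai = 1.8‰ (dissolution 1.1 +
aqueous diffusion 0.7). When boundary-layer conductance is not measured,
a′ defaults to a = 4.4‰ (the large-boundary-layer-conductance limit); a
weighted a′ can be supplied through `DiscriminationConstants` when C_s
is known. Setting t = 0 and e = 0 reduces the estimator exactly to the
classical simple form, which a test asserts to 1e−12.

`predict_delta_obs` is the exact algebraic inverse of the estimator and
exists for simulation and round-trip testing; composition recovers g_m
to 1e−10 relative over randomised physical leaf states.

## Synthetic experiment generator

The generator emulates a factorial glasshouse design: 2 cultivars
(Scout, Yitpi) × 2 growth CO₂ (450/650 µmol mol⁻¹) × 4 heat-stress
regimes (Control, HS1 at 38.1 °C daytime, HS2 at 33.5 °C, HS1+2) ×
5 harvests (T0–T4) × 10 plants per cell by default, with HS1-only cells
absent at final harvest. It produces gas-exchange records (growth-CO₂
and common-400 measurements at 25 and 35 °C), A–C_i curves at the
8-step CO₂ ladder (50…1800 µmol mol⁻¹, 25 °C, PPFD 1500), isotope
observations at five leaf temperatures, a per-plant trait table and a
temperature-response campaign.

Design choices:

* **Effects are multiplicative and exact in expectation.** Each
  calibrated treatment effect (e.g. +21% assimilation at growth CO₂
  under eCO₂, −12% at common CO₂, +64%/+50% grain number, −18% Yitpi
  grain protein, cultivar trait ratios) is applied as a multiplier to a
  deterministic baseline, with mean-preserving lognormal noise
  (default CV 10% for traits, 5% for gas exchange — positive-valued
  measurements with roughly constant CV). A zero-noise run therefore
  reproduces every configured effect exactly, and large-cohort runs
  recover them to sampling error. The single-point assimilation
  baseline is computed by the forward FvCB model at the cultivar's
  parameter set (C_i/C_a = 0.7, PPFD 1500), but the eCO₂ stimulation and
  downregulation multipliers are imposed on that baseline rather than
  left to emerge from the model — this keeps the generator's configured
  effects and the downstream estimators exactly commensurable. The
  capacity downregulation (V_cmax × 0.86/0.85, J_max unchanged) does act
  mechanistically in the A–C_i curve generator, where fitting recovers it.
* **Measurement vs plant noise.** A plant-level lognormal factor (the
  configured CV) scales a plant's whole response; instrument noise at
  20% of that CV sits on top. Draws violating C_i < C_a or net A above
  the plant's gross FvCB potential are rejected and redrawn (bounded at
  100 retries).
* **Isotope encoding.** The generator computes the true discrimination
  for the plant's g_m (the cultivar quadratic g_m(T) profile pinned to
  g_m(25 °C), times the plant factor) and encodes it into
  (Cref, Csam, δref, δsam) with a fixed 20 µmol mol⁻¹ chamber draw-down
  and δref = −8‰, making the whole table round-trippable by the
  estimator.
* **Seeding.** One master seed; each stage draws from its own stream
  keyed by a stable label, so adding a stage never shifts another
  stage's draws, and identical configs give byte-identical tables.
* **Free baselines.** Absolute trait magnitudes (e.g. grams per plant
  at each harvest) are plausible glasshouse values chosen once and
  documented in `calibration.py` as non-reported defaults; they are
  validated only as generator properties, never against published
  values. Effects reported only as significance statements without a
  magnitude default to multiplier 1 and are marked unquantified in the
  calibration file.

What the generator does **not** emulate: chamber/bench blocking (the
design is treated as fully randomised), phenology and crop duration,
leaf energy balance, soil water, within-leaf gradients, instrument
drift, and any mechanistic link between leaf photosynthesis and biomass
(trait effects are calibrated, not grown). Passing tests therefore show
that the estimators are correct and calibrated on data satisfying the
models' own assumptions — not that those assumptions hold in any real
glasshouse.

## Treatment-effect analysis

Percent changes are ratios of cell means with an expanded-percentile
bootstrap interval: the percentile quantiles are widened by the t-based
small-sample factor (replacing z with t_{α/2,n−1}·√(n/(n−1))), the
standard correction for the narrowness of plain percentile intervals at
glasshouse cell sizes (n ≈ 10); empirical coverage at nominal 95% sits
near 95–96% where the plain percentile method gives ≈ 92%.

The ANOVA is a full-factorial OLS decomposition with sequential (type I)
sums of squares; on the generator's balanced designs all SS types
coincide and terms are order-invariant, which a test asserts. Empty
cells raise an error naming the cell. α = 0.05 throughout, with the
conventional star mapping (*, **, *** at 0.05, 0.01, 0.001). Welch
variance is not needed for the balanced contrasts reported; pairwise
mean ranking uses the Tukey studentized-range criterion with a compact
letter display built from maximal runs of the sorted means (exact for
equal cell sizes, harmonic-mean n for mild imbalance).

A note on interaction power: the heat-stress × eCO₂ "cancellation"
of the yield gain is mostly a two-way CO₂ × HS signal, detected with
power well above 0.8 at 10 plants per cell. Its three-way component —
the difference between the cultivars' cancelled gains (×1.64 vs ×1.50)
— is an order of magnitude smaller and only becomes reliably detectable
at cohort sizes around 150 per cell; the power test checks each term at
a size where its configured effect is detectable.

## Problem sizes and numerical tolerances

Validation runs use: five-temperature series for every temperature fit;
8-point A–C_i curves; 200 noisy curves (2% CV) for recovery statistics;
500 replicates for Ea bias/coverage; 1000 random leaf states for the
isotope round trip; 2000 null simulations (3 plants per cell, final
harvest only) for ANOVA type-I calibration; 1000 replicates (B = 999)
for bootstrap coverage; and 1000 plants per cell at 10% CV for percent-
effect recovery (tolerance ±2 percentage points, dominated by sampling
error of the cell means). Self-consistency of every fitter on its own
noiseless forward model is asserted at 1e−6 relative or tighter;
closed-form fits (quadratic, parabola, Q10) at 1e−9.

## Known limitations

* The two FvCB capacities are fitted with g_m and R_d fixed; co-fitting
  g_m or R_d from the curve, TPU limitation, Bayesian fitting and C₄
  photosynthesis are out of scope.
* The g_m estimator assumes e = 0; respiratory fractionation, ¹⁸O
  discrimination and laser calibration/drift corrections are not
  modelled.
* Temperature acclimation (optima shifting with growth temperature) is
  not modelled; the temperature campaign reflects a single growth
  environment.
* Standard errors are asymptotic and can be optimistic for the
  three-parameter peaked fit on five points.
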