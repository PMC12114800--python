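# Methods

`dissoflow` models intrinsic dissolution of compacted pure-drug discs in a
laminar flow channel. This note records the models implemented, the
assumptions behind them, the tunable parameters, and the numerical and
design choices made where several defensible options existed.

## Dissolution-layer model

Dissolution of a low-porosity compact under forced convection is treated in
the Nernst–Brunner picture: a thin near-surface layer of thickness *h*
across which diffusion limits mass transfer, with saturation concentration
*c*_s at the solid surface and the bulk effectively at zero. At a running
length *x* along the tablet the dissolution boundary layer is

    h(x) = (D · c_s / IDR) · (1 / BNF_e) · (x / 1000 mm)^0.378   [m → reported in µm]

where *D* is the drug's diffusion coefficient in water (m² s⁻¹), *IDR* the
intrinsic dissolution rate (kg m⁻² s⁻¹), and *BNF*_e a dimensionless
boundary-layer normalization factor that removes the dependence on sample
area/diameter. The model assumes a flat, constant surface; erosion,
swelling and topography are measured (see topography metrics) but not fed
back into *h*.

Because `D·c_s/IDR` carries all substance-specific physics, the normalized
rate *y* = IDR/(c_s·D) collapses onto a substance-independent master curve
in the channel Reynolds number,

    IDR / (c_s · D) = A · Re^m ,

and the corresponding layer curve is h = a·Re^(−b) with
a = (x/1000)^0.378 / (BNF_e·A) and b = m. Three uses follow:

* **Master-curve fitting** (`fit_master_curve`): log-log OLS of *y* on Re,
  pooling temperatures (temperature enters through Re, via ν(T), and
  through D(T)). Log-log OLS is the default because the curve is linear on
  log axes and multiplicative noise becomes additive there; a nonlinear
  least-squares cross-check exists in the tests only.
* **Solubility back-fitting** (`fit_solubility`): for one substance and
  temperature, minimize Σᵢ (IDRᵢ/(c·D) − A·Reᵢ^m)² over *c*. With
  kᵢ = IDRᵢ/D and gᵢ = A·Reᵢ^m the minimizer is closed-form,
  c = Σkᵢ² / Σkᵢgᵢ. Residuals are taken on the normalized-rate scale (not
  on *h*); the alternative residual space would weight low-Re points more
  heavily and is not the default.
* **BNF_e calibration** (`calibrate_bnf`): given a fitted master curve and
  a fitted layer curve, BNF_e = (x/1000)^0.378 / (A·a). Only the
  prefactors enter; an exponent mismatch |m − b| > 0.05 raises a warning
  and is never averaged away. With the reference pair A = 2.125 m⁻¹,
  a = 471.8 µm at x = 8 mm this gives BNF_e ≈ 160.8. The master-curve
  prefactor unit is recorded explicitly (`m^-1` default); under the
  alternative `mm^-1` reading BNF_e ≈ 0.16, and the calibration result
  carries the unit tag so the two conventions cannot be mixed silently.

**Mechanistic reading.** The layer-curve exponent *b* is compared against
reference values: b = 0.5 (two-dimensional Blasius boundary layer, purely
diffusion-limited), b ≈ 0.39 (three-dimensional boundary-layer
configuration), and b → 0 (rate nearly independent of convection,
indicating surface-reaction influence). `mechanism_report` flags
b < 0.2 — halfway to the 3D reference — as surface-reaction-influenced,
a deliberately qualitative flag: real substances cannot in general be
assigned cleanly to either class, so no hard classification is emitted.
Model evaluation below Re = 100 warns: the power law is least consistent
with experiment in that regime.

## Substance properties

* **Water properties** (`water_properties`): dynamic viscosity from a
  three-parameter Vogel correlation η = A·exp(B/(T−C)) with
  A = 0.02939 mPa·s, B = 507.88 K, C = 149.3 K; density from the Kell
  (1975) polynomial. Both reproduce standard reference-table values within
  0.5% over 20–60 °C (unit-tested at 20/25/37/50 °C); ν = η/ρ.
* **Van der Waals radius** (`vdw_radius_from_composition`):
  Zhao–Abraham–Zissimos atomic increments (C 20.58, H 7.24, N 15.60,
  O 14.71, S/P 24.43, F 13.31, Cl 22.45, Br 26.52, I 32.52 Å³) with
  −5.92 Å³ per bond, −14.7 per aromatic ring, −3.8 per non-aromatic ring;
  the volume maps to the sphere-equivalent radius r = (3V/4π)^{1/3}. An
  explicit radius on the `Substance` overrides the scheme.
* **Diffusivity** (`diffusion_coefficient`): modified Stokes–Einstein
  D = k_B·T / (n_f·6π·η·R_vdW). The numerical factor n_f defaults to 1.0
  (classical limit) and is configurable; published modified variants place
  a factor of this kind multiplicatively in the denominator, and keeping
  it as a single scalar isolates that choice in one parameter.

All internal units are SI; °C, nm, mm and mL are accepted at the
boundaries and converted on ingest.

## Hydrodynamics

Re = ū·H/ν with H the **full** channel height (5 mm) and ū the
cross-section **mean** velocity; 0.12 m s⁻¹ at 37 °C gives Re ≈ 862
(≈ 850 after rounding ν). The laminar profile is plane Poiseuille,
u(y) = 1.5·ū·(2s − s²), s = y/half-height. The Blasius similarity
equation f‴ + ½ f f″ = 0 is solved by shooting (bracketing secant on
f″(0), RK45 integration to η = 10, tolerance 1e−8 on f′(∞) − 1), giving
f″(0) ≈ 0.332 and η₉₉ ≈ 4.91, hence δ₉₉ = η₉₉·√(νx/U) ∝ Re_x^(−1/2).

## Channel transport solver

A desk-scale counterpart of a full CFD study of the channel: since wall
blowing velocities are of order IDR/ρ ≈ 10⁻⁷ m s⁻¹, the drug does not
perturb the momentum field, and only steady scalar transport is solved on
the half channel (symmetry at the centerline):

    ∂(u w)/∂x = D (∂²w/∂x² + ∂²w/∂y²),

with u(y) Poiseuille, w = 0 at the inlet, convective outflow, zero wall
flux except over the tablet strip x ∈ [0, 8] mm where the diffusive flux
equals IDR/ρ (the tablet as a scalar source, not a velocity inlet).

Numerics: cell-centered finite volumes on a grid uniform in x
(default 400 cells over 26 mm) and geometrically stretched in y
(default 120 cells, first wall spacing 0.5 µm — sub-micron resolution is
required because the layer-edge criterion probes the near-wall profile).
Advection uses the hybrid central/upwind face coefficients (upwinding
engages at cell Péclet > 2; the flow is axis-aligned, so upwinding causes
no cross-stream false diffusion). The sparse system is solved directly;
the scaled residual (~1e−14) and the global drug mass balance (closes to
machine precision by construction of the conservative scheme) are recorded
on the returned field. The default grid is far coarser than an industrial
CFD mesh; `grid_convergence_study` quantifies the residual discretization
error instead (the Richardson order estimate is reported but is sensitive
to the mix of first-order x error and layer-edge interpolation error, so
the level-to-level change, not the order, is the acceptance quantity).

**Layer extraction.** The concentration layer δ_c(x) is the wall distance
where the wall-to-bulk deficit reaches 99%:
w(y₉₉) − w_bulk = 0.01·(w_wall − w_bulk), with w_bulk taken at the
symmetry plane and w_wall from the flux-consistent extrapolation; the
convention is recorded on every output because the reference value in the
99% criterion admits more than one reading. In near-wall shear the solver
reproduces the Lévêque similarity δ_c ∝ x^{1/3} (the analytic oracle used
for verification). The displacement layer δ_disp(x) is the height of the
streamline released 0.1 µm above the wall at the leading edge and lifted
by uniform wall blowing v_w = IDR/ρ (divergence-free by construction);
near the wall it follows y(x) = √(y₀² + 2 v_w x / γ̇). Only this
kinematic-blowing interpretation of the displacement layer is implemented.

## Synthetic data

`generate_idr_dataset` draws IDR = c_s(T)·D(T)·A·Re^m·ε with
ε ~ lognormal(0, σ). Defaults define the simulated study: eight
small-molecule substances, temperatures 25/37/50 °C, 8 log-spaced Re in
[25, 1000], 4 replicates (768 experiments), A = 2.125 m⁻¹, m = 0.3,
σ = 0.05. The noise law is multiplicative lognormal because dissolution
replicate scatter is proportional to the rate; σ = 5% is a realistic
replicate CV for channel IDR measurements. The per-substance solubility
tables are synthetic: plausible literature-scale aqueous solubilities
spanning ~3 orders of magnitude and increasing with temperature. An
`exponent_override` per substance emulates a surface-reaction-influenced
compound (weak Re dependence) for exercising the mechanism report; its
parameters are user choices, not measured values. Generators are pure
functions of (spec, seed); a seed is mandatory for any stochastic call.

What the generator does **not** emulate: temperature-dependent
heteroscedasticity, Re-dependent mechanism crossover (except via the
explicit override), surface evolution feeding back on IDR, and closed-loop
channel kinetics. Passing recovery tests therefore demonstrates the
correctness and statistical calibration of the fitting chain under the
assumed noise model, not the model's adequacy for any particular real
substance.

A note on recovery statistics: at σ = 0.05 with n = 32 points the log-log
OLS exponent is recovered within ±0.02 in ≈99% of repetitions, but the
prefactor is an extrapolation of the fit to Re = 1 (far outside the
design range) with SE(ln A) ≈ 0.038, so a 5% prefactor band holds in only
~80% of repetitions; the Monte-Carlo test asserts the 2-standard-error
band instead, and single-seed checks use the 5% tolerance directly.

## Experiment I/O

IDR from a closed-loop run is (V/A)·slope of the OLS line on the
concentration–time window. The default window skips the first 60 s
(equilibration of the channel and measurement loop); the full closed-loop
kinetics/delay correction used with such apparatus is out of scope, so the
window is exposed as configuration. Negative slopes are rejected as data
quality errors; windows with fewer than 3 points are rejected.
`mg min⁻¹ cm⁻² ` is accepted on disk (×1.667e−4 to SI). Topography
metrics compare per-state line profiles (≈300 points over 10 mm) after
linear resampling to a common grid; the leading-edge change averages
t2 − t1 over the first 0.5 mm of the tablet (a point value at the edge is
noise-sensitive), with negative = erosion and positive = swelling.

## Problem sizes

Defaults are sized for a workstation: the transport solver uses
400×120 cells (~1 s per solve, direct sparse factorization), the
convergence study up to 480×160, Monte-Carlo recovery 200 repetitions of
32-point fits. All stochastic defaults and seeds are stated in the test
suite and the acceptance script; identical seeds give bit-identical
outputs.

## Known limitations

* No momentum solve: the velocity field is prescribed Poiseuille; entrance
  effects, topography-induced flow disturbance and 3D secondary flows are
  absent.
* The layer model extrapolates poorly below Re ≈ 100 (warned, not blocked).
* Solubility temperature lookup is exact-key; no interpolation between
  measured temperatures.
* The structure→radius increment scheme ignores conformation and treats
  hydration only through the numerical factor n_f.
* The displacement layer is a kinematic construction; whether a
  commercial-solver displacement layer reflects blowing, meshing or
  momentum displacement is not resolved here.
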