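# Methods

`semisolid` implements the physicochemical characterization workflow for
semi-solid dosage forms (drug-loaded ointments and creams): spreadability,
rotational rheology, texture profile analysis (TPA) and in-vitro release
kinetics.  Raw instrument exports for this kind of bench study are rarely
deposited, so the package pairs every analysis stage with a synthetic
generator that produces instrument-realistic records from known ground
truth; correctness is then established by parameter recovery (round-trip)
rather than by re-reading archived traces.

## Spreadability

The parallel-plate test places an ointment aliquot under a glass plate
(298.0 g by default) and adds weights stepwise from 20 to 500 g, reading the
spread diameter at each step.  Diameters convert to areas as pi*(d/2)^2,
areas are averaged over replicates per load, and the spreading curve is
summarized by ordinary least squares of

    area [cm^2] = a * ln(load [g]) + b

where *load* is the **total** applied mass (plate + weights).  This abscissa
convention is a deliberate choice: integrating typical published fit
equations over [298, 798] g reproduces their reported curve areas to better
than 1%, while an added-mass abscissa does not.

The area under the spreading curve (AUC) is the closed-form integral
`a*(x ln x - x) + b*x` over the load range ([298, 798] g by default); a
trapezoid-on-raw-data variant (`auc_trapezoid`) exists because instrument
software usually integrates numerically.  The spreadability index

    i(S) = AUC_test / AUC_reference

compares formulations: i(S) > 1 spreads better than the reference base.
Reporting rounds a, b to 3 decimals, AUC to 1, i(S) to 3.

Fitting on per-load replicate means is the default (bench reports publish
n = 5 means); per-replicate fits are available by constructing
`LogSpreadModel` directly on unaveraged data.

## Rheology

Step viscosities at 300/700/1100 1/s and two temperatures (25 °C storage,
32 °C skin) are summarized as mean ± SD (n ≥ 2 per cell enforced; missing
cells stay missing).  A strictly decreasing mean across rates flags shear
thinning.

The yield-stress flow fit offers two variants:

* `linear` (default): tau = tau_y + eta*gamma, fitted by OLS on the
  ascending branch.  This is mathematically the **Bingham plastic** law, but
  it is the form most bench reports print when they cite Casson; fidelity to
  that practice is why it is the default.
* `sqrt`: the conventional **Casson** law sqrt(tau) = sqrt(tau_y) +
  sqrt(eta*gamma), fitted by OLS on square-root axes.

Negative intercepts clip to tau_y = 0 in both variants.

Thixotropy is quantified as the area between the ascending and descending
flow curves on the rate–stress plane: the descending branch is linearly
interpolated onto the ascending branch's rate grid over the shared rate
interval and the difference is integrated by the trapezoid rule.  The axes
choice (stress–rate, not stress–time) matches how hysteresis loops are drawn
on rheograms; with a smooth loop the result is stable to < 0.5% under 5x
resampling.  Positive area = thixotropic, negative = anti-thixotropic,
|area| below the noise floor = effectively reversible.  Pre-shear (100 1/s,
15 s) is treated as metadata: the generator applies it, the fits ignore it.

## Texture profile analysis

A cylindrical probe descends 10 mm at 5 mm/s, retracts at 0.1 mm/s, pauses,
and compresses again; the force–time trace is segmented at the 0.01 N
trigger threshold with a 3-sample debounce, and each positive-force episode
is extended to its zero-force shoulders.  Exactly two episodes are required.
Extracted parameters:

* hardness — peak force of episode 1 [N];
* cohesiveness — A2/A1 on force–**time** areas (the standard definition);
* elasticity — D2/D1, with travel D = descent speed x rise time of each
  compression (direct displacement channels, if logged, take precedence);
* adhesion force — the global force minimum (≤ 0) [N];
* adhesiveness — work of the negative detachment lobe after episode 1,
  |∫F dx| with dx = ascent speed x dt, reported in mJ (N·mm).  Converting
  the time integral through the ascent speed reconciles the force–time trace
  with the work unit conventionally reported.

Tensile strength F/A and Young's modulus (F/A)/(Δl/l) are plain formulas;
the probe cross-section A is a required input because instrument writeups
frequently omit the cylinder diameter — the examples use 1e-4 m^2 as a
placeholder only.

The TPA generator builds a piecewise-linear trace realizing a prescribed
parameter set exactly: symmetric rise/fall for episode 1, a triangular
detachment lobe whose duration is set by the prescribed work and minimum
force, and a second episode that is a time-scaled (by elasticity) copy with
peak `cohesiveness/elasticity * hardness`.  Sampling injects the breakpoints
into the uniform grid, so trapezoid integrals of the noiseless trace are
exact and `extract(generate(theta)) = theta` holds to machine precision;
with uniform-only sampling the error is bounded by one sample interval.
A profile whose implied second peak would sit at the trigger threshold, or
whose adhesiveness/adhesion-force pair is inconsistent (work without a
negative force or vice versa), is rejected.

## In-vitro release

The experiment loads 1.0 g of ointment into an enhancer cell with a 3.8 cm^2
orifice under a dialysis membrane, stirred in 50 mL of water at 32 °C;
3 mL aliquots are taken at 15, 30, 60, 90, 120, 150 min and replaced with
fresh medium.  Analysis chain:

1. **Calibration** — OLS of absorbance on concentration; the bundled default
   line is y = 0.5831x − 0.0169 at 276.5 nm.  Inversion floors negative
   concentrations at zero with a warning; a non-positive slope flags the
   curve unusable.
2. **Mass balance** — Q_n = (C_n·V + Σ_{i<n} C_i·V_s)/A.  The experiment
   descriptions in this field never print this correction; the replacement
   mass balance is adopted because it *exactly* inverts the stated sampling
   procedure (property-tested against an independent forward simulation, and
   invariant to the aliquot volume).
3. **Kinetics** — five models: zero-order Q = k0·t (through origin),
   first-order Q = q_inf(1 − e^(−k1 t)), Higuchi Q = kH·sqrt(t) fitted
   through the origin over 15–150 min (an intercept option exists for
   burst/lag), Korsmeyer–Peppas log–log fit restricted to fractional release
   ≤ 0.6 (standard practice), and Weibull Q/q_inf = 1 − exp(−(t/tau_d)^beta)
   via bounded nonlinear least squares seeded from the linearized form.
   q_inf defaults to dose/area (release approaches completion within the
   run); a profile-based max(Q) is equally valid input.  R^2 is
   1 − SS_res/SS_tot in all cases; `compare_models` ranks the five fits and
   tolerates per-model precondition failures (recorded, not raised).
   Replicate rate estimates are compared across formulations with Welch
   t-tests (the "Weibull method" significance machinery of proprietary
   dissolution kits is not reproducible from its descriptions; Welch tests
   on replicate rates are the documented substitution).

The release generator forward-simulates the vessel: the kinetic law gives
cumulative release, withdrawal removes dissolved drug, replacement dilutes,
and the pre-withdrawal concentration maps to absorbance plus photometric
noise drawn **uniform** on ±0.005 A — the instrument-specification semantics
of an accuracy bound, not a Gaussian SD.  `cap_at_dose` (default on)
saturates release at dose/area with a warning.  Recovery checks run with the
cap off: they validate the measurement chain (vessel, withdrawal,
calibration) against the pure kinetic law, and a capped profile is by
construction no longer that law.  Notably, with the bundled study rates the
cap engages within the sampling window (e.g. a 0.41 mg/cm^2/min^0.5 process
exhausts 15 mg/3.8 cm^2 near 93 min), so capped refits are biased low — that
is physics, not a defect, and the completion-time consistency check covers
it.

## Statistics

Means are arithmetic; SDs use n−1.  The two-sample test defaults to Welch
(group variances in bench tables differ visibly); `pooled=True` restores
classic Student.  Zero-variance groups are handled in the limit (equal means
→ t = 0, p = 1; different → p = 0).  Pairwise tests carry no
multiple-testing correction, and the report header says so.

## What the synthetic world does and does not establish

The generators emulate: log-law spreading with area-level Gaussian noise
(SD 0.5 cm^2 default — diameter readings to ~0.5 mm at typical spread
sizes), a first-order structural-kinetics thixotropy model
(dλ/dt = −k_b·γ·λ + k_r(1−λ), stress scaled by λ_floor + (1−λ_floor)λ with
λ_floor = 0.2 so stress never collapses to zero), exact piecewise-linear TPA
traces, and the full vessel/withdrawal/photometric chain.  They do **not**
emulate membrane transport (release follows the phenomenological laws, not
diffusion through the 12–14 kDa cellulose membrane), solvent evaporation
during spreading, viscoelastic moduli, or operator effects.  A green
round-trip therefore establishes that the analysis inverts the stated
measurement model — not that the measurement model captures every behaviour
of a real ointment on a real instrument.

Default sample sizes follow the emulated study design: n = 5 replicates for
spreadability/viscosity/TPA, n = 6 sampling times for release, 26 load steps
(plate + 20–500 g in 20 g increments), ramp 100→1100→100 1/s.

## Numerical notes and limitations

* All linear fits are exact OLS (statsmodels); no iterative tolerance is
  involved.  Nonlinear fits (first-order, Weibull) use scipy `curve_fit`
  with linearized starting values and positivity bounds.
* Hysteresis integration truncates to the overlapping rate interval;
  non-overlapping phases are an error, not zero.
* The AUC antiderivative takes x·ln x → 0 at x = 0, so a zero lower load
  bound is legal.
* Degenerate inputs fail loudly and specifically: non-positive diameters
  name the row, schema violations name the column, segmentation errors name
  the episode count found.
* Published AUC–concentration and spreadability–viscosity correlations from
  bench studies are generally computed on raw replicate data; recomputing
  them from rounded summary tables gives different values (the package
  computes them via `pearson_r` but makes no claim of matching any printed
  coefficient).
* Absolute viscosity, pH and texture magnitudes in the bundled defaults are
  a stated world for integration testing, not measurements.
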