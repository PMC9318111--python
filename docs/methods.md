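# Methods

This note documents the models implemented in `findose`, their
assumptions, the parameters that matter, the synthetic-data generator,
and the numerical and design choices made where the underlying procedure
left them open.

## 1. Parameter estimation from infinite-dose profiles

Under an infinite dose (donor applied in large excess, ≈500 µL/cm², donor
covered to prevent evaporation) the cumulative amount permeated through a
slab membrane approaches the straight line *Q*(*t*) = Flux·(*t* −
*T*<sub>lag</sub>).  `fit_steady_state` fits an ordinary least-squares
line over a chosen window of sampling points; Flux is the slope,
*T*<sub>lag</sub> the x-intercept, and the classical lag-time relations
give

- *Kp* = Flux / *C*<sub>v</sub> (cm/h),
- *D* = *L*²/(6·*T*<sub>lag</sub>) (cm²/h),
- *K* = 6·*T*<sub>lag</sub>·*Kp*/*L* (dimensionless),

with the identity *Kp* = *K·D*/*L* holding exactly for every fitted
bundle (asserted to 10⁻¹² relative in the tests).

**Window policy.** Sampling is every 2 h to 8 h.  Skin-like membranes are
linear from the first sample, so the default window is all points ≥ 2 h;
Strat-M shows a curved 2 h point and defaults to ≥ 4 h.  Both are
overridable per profile, because window choice is ultimately a judgement
about visual linearity.

**Withdrawal correction.** Each sampling removes a 500 µL aliquot from
the 8.0 mL receiver and replaces it with fresh solvent — 6.25 % of the
receiver per sample, which is not negligible.  When raw receiver
concentrations are supplied, the mass-balance correction
*Q*<sub>n</sub> = (*C*<sub>n</sub>·*V*<sub>rec</sub> + Σ<sub>i&lt;n</sub>
*C*<sub>i</sub>·*V*<sub>aliq</sub>)/*A* restores the cumulative amount.
Whether a given published profile was already corrected is often unclear,
so the correction is a toggle (`apply_withdrawal_correction`).

**Anomalies.** A non-positive fitted slope raises an error (no
steady-state flux).  A *negative* lag time — common on noisy data — is
retained as computed and flagged with a warning rather than clamped to
zero: silently clamping would hide a bad fit, whereas a propagated
negative *T*<sub>lag</sub> makes the anomaly visible in *D* (reported as
NaN, since *L*²/(6*T*<sub>lag</sub>) is undefined) and *K*.  Replicates
(typically *n* = 3–4 cells) are estimated independently and aggregated as
mean ± standard error.

**Units** are fixed internally: hours, cm, µg, mL (≡ cm³).

## 2. Two-phase finite-dose absorption model

Assumptions, in order of importance:

1. **First-order clearance with the infinite-dose *Kp*.**  Transport
   through the SC is described by Fick's first law with the permeability
   coefficient measured at steady state; no explicit depth-resolved
   diffusion (no second-law PDE), hence no parameters for the viable
   epidermis/dermis are needed — which is what makes the model usable
   with Strat-M-derived parameters, as the synthetic membrane cannot be
   split into layers.
2. **Constant solvent volume during phase 1.**  *V* is held at its
   initial value until *T*<sub>eva</sub> even though evaporation shrinks
   it continuously; the concentration increase this neglects makes the
   phase-1 clearance an underestimate late in phase 1.  Documented
   limitation, kept for closed-form tractability.
3. **Instantaneous equilibrium split at *T*<sub>eva</sub>.**  The
   remaining chemical partitions between SC (fraction
   *V*<sub>SC</sub>*K*/(*V* + *V*<sub>SC</sub>*K*)) and surface residue.
4. **The surface residue is inert after *T*<sub>eva</sub>** — dried-down
   chemical does not redissolve or keep penetrating.

Two printed-model inconsistencies are implemented as printed and noted
rather than "fixed": the phase-1 pooled concentration *M*/(*V* +
*V*<sub>SC</sub>) ignores *K* while the split at *T*<sub>eva</sub> uses
K-weighted volumes (thermodynamically inconsistent); and the phase-2
clearance applies *Kp* (which already embeds *K*) directly to the SC
concentration *M*<sub>SC</sub>/*V*<sub>SC</sub>.  Changing either would
change the model being implemented.

**Constants** (defaults of `FiniteDoseConfig`): *A* = 1.0 cm², *V* = 0.01
cm³ (10 µL dose), *V*<sub>SC</sub> = 0.002 cm³, *T*<sub>eva</sub> = 1.5 h,
*t*<sub>end</sub> = 24 h, *M*₀ = 0.01·*C*<sub>v</sub> µg.  The 24 h
horizon is an experiment duration, not a model constant, so
*t*<sub>end</sub> is configurable and the phase-2 formulas use it in
place of the literal 24.

**Outputs.**  `predict_absorption` returns the full mass budget: *M*₁,
*M*₂, SC content at *t*<sub>end</sub>, surface residue, total and ratio.
Mass conservation *M*₁ + *M*₂ + *M*<sub>SC</sub>(*t*<sub>end</sub>) +
residue = *M*₀ is provable from the closed forms and asserted to 10⁻⁹
relative in tests.

**Numerics.**  All decay exponents are non-negative; `exp(−x)` underflows
gracefully, and an explicit guard returns 0.0 for *x* > 700 (the correct
limit — *Kp·A·(t*<sub>end</sub>−*T*<sub>eva</sub>)/*V*<sub>SC</sub>
exceeds 50 for realistic inputs, and the SC depot genuinely empties).

**ODE oracle.**  `ode_oracle` integrates the two linear rate equations
with a fixed-step classical 4th-order Runge–Kutta scheme (default 10 000
steps per phase) and applies the same partition split at
*T*<sub>eva</sub>.  Fixed-step integration was chosen over an adaptive
solver because the system is linear and non-stiff and determinism
matters for byte-identical test runs.  The oracle shares no code with the
closed forms and is the independent check: agreement is < 10⁻⁶ relative
across the reference parameter rows and a (Kp, K, T<sub>eva</sub>) grid
spanning Kp ∈ [10⁻⁵, 5·10⁻²] cm/h, K ∈ [10⁻³, 5], T<sub>eva</sub> ∈
{0, 0.5, 1.5, 6, 24} h (measured ≈10⁻¹² with 2 000 steps).

## 3. Evaporation time

The applied solution is weighed every 0.25 h until the weight stops
changing.  The estimator defines **T<sub>eva</sub> as the earliest
sampled time from which every subsequent consecutive change is at most a
threshold**, default 1 % of the initial weight, sustained to the end of
the series.  The threshold is relative, so the estimate is invariant to
scaling the weights, and loosening it can only move the estimate earlier.
A series whose final pair still exceeds the threshold raises
"evaporation incomplete".  The 1 % default reproduces the 1.5 h
switch time on synthetic curves mimicking 10-µL aqueous doses; the
criterion itself is a design choice, as only the qualitative statement
"the change of weight was negligibly minimal" constrains it.

## 4. Synthetic-data generator

The generator defines the study conditions under which the package is
tested.

**Infinite-dose profiles** use the exact slab-diffusion series solution

&nbsp;&nbsp;*Q*(*t*) = *K·L·C*<sub>v</sub>·(*D·t*/*L*² − 1/6 −
(2/π²)·Σ<sub>n≥1</sub> ((−1)ⁿ/*n*²)·e^(−*D·n*²π²*t*/*L*²)),
&nbsp;&nbsp;*D* = *Kp·L*/*K*,

truncated when a term falls below 10⁻¹² (cap 200 terms).  Its large-*t*
tangent has slope *Kp·C*<sub>v</sub> and x-intercept *L*²/(6*D*), so
feeding a noiseless profile back through the estimator is a genuine
round-trip test of the lag-time method, not a fit to its own asymptote.
Recovery accuracy is limited by how much of the transient remains in the
sampling window: with sampling at 2–8 h, parameters are recoverable to
2 % (Kp) / 5 % (K, D) only when *T*<sub>lag</sub> ≲ 1 h; for longer lag
times steady state is simply not reached within the experiment and no
estimator could recover the parameters from those samples.

**Evaporation curves** decline linearly from *w*₀ at *t* = 0 to a
residual plateau (default 1 % of *w*₀) reached exactly at the true
*T*<sub>eva</sub>, then stay flat; the series runs 1 h past the plateau
onset so the estimator can verify it is sustained.

**Observed finite-dose ratios** are the ODE-oracle ratio (independent of
the closed forms being evaluated) perturbed by noise and clipped to
[0, 1].

**Noise** is multiplicative Gaussian, *x*·(1 + σ·*z*), clipped at zero:
amounts are positive and replicate scatter in permeation data scales
roughly with the mean.  Default σ = 0 (noiseless); the evaluation tests
use σ = 0.15, loosely calibrated to the standard errors of *n* = 3–4
replicate Franz cells.  A fixed seed gives byte-identical bundles;
different seeds change only the noise, never the structure.

What the generator does **not** emulate: inter-skin biological
variability structure, metabolism (e.g. ester hydrolysis of
methylparaben), tape-stripping recovery losses, formulation effects, or
correlated errors between replicates.  Passing tests therefore show the
estimator and model are self-consistent under idealized measurement
noise, not that real skin data will meet the same tolerances.

## 5. Evaluation layer

`pearson_with_p` reports the sample Pearson *r* with a two-sided *p*
from *t* = *r*·√((*n*−2)/(1−*r*²)), df = *n*−2 (delegated to
`scipy.stats.pearsonr`, which implements exactly this test; *p* is
reported as 0 in the degenerate |*r*| = 1 case).  The slope of the
predicted–observed relationship is computed by least squares
**constrained through the origin** by default, because on ratio axes a
slope of 1 is then exactly the 1:1 line; the intercept form is available
via `slope_through_origin=False`.  Factor-2 agreement counts a pair as
within when max(pred/obs, obs/pred) ≤ 2 — a point exactly on the dashed
factor-2 guide line counts as within.

## 6. Reference workflow and applicability domain

`reproduce_study` predicts absorption ratios for all seven reference
chemicals from porcine-skin parameters and for CAF, ISMN, BA (pH 3.0)
and MP from Strat-M parameters.  Strat-M under-represents the
appendageal (follicular) route, so its parameters are only applied
within −0.2 ≤ Log *K*<sub>ow</sub> ≤ 2.0; chemicals outside the domain
(KA, LID, BA pH 7.0) are excluded from the reproduction table with an
explicit warning, never silently dropped.  Reports embed all constants
and SHA-256 checksums of the packaged tables; timestamps are off by
default so repeated runs are byte-identical.

The packaged chemical table reproduces its source verbatim, including a
molecular-weight discrepancy for sodium benzoate (122.12 at pH 3.0 vs
121.12 at pH 7.0) that is deliberately left unresolved.

## 7. Problem sizes and known limitations

- Oracle-agreement and mass-conservation checks run on 139 parameter
  combinations with 2 000 RK4 steps per phase; the acceptance script
  completes in seconds on one CPU.
- Parameter recovery runs the 3×3×2 (Kp, K, L) grid filtered to
  *T*<sub>lag</sub> ≤ 1 h (5 combinations; see §4 for why the rest are
  unrecoverable from a 2–8 h window).
- The synthetic evaluation study uses 7 chemicals spanning Kp from 10⁻⁴
  to 2·10⁻² cm/h with σ = 0.15 observation noise.
- The model ignores solvent-volume shrinkage during phase 1, chemical
  precipitation kinetics, formulation components (polyols, surfactants),
  multi-dose regimens, and depth-resolved (second-law) transport in the
  viable layers; headline correlations reported for real finite-dose
  measurements cannot be recomputed here because those measurements are
  not tabulated anywhere machine-readable.
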