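# Methods

## Scope

`mipdsim` implements the computational pipeline of model-informed precision
dosing (MIPD) as used in therapeutic drug monitoring (TDM) of vancomycin
and amikacin in critically ill children, together with the evaluation layer
that asks whether Bayesian assimilation of measured concentrations improves
predictive accuracy. Because no patient-level dataset ships with the
package, a synthetic-cohort module generates virtual patients with the
statistical structure the analysis assumes; every empirical number the
package reports is computed at run time from those simulations.

## Structural and statistical model

Both drugs are modelled with linear IV-infusion kinetics: one compartment
(CL, V) for vancomycin, two compartments (CL, V1, V2, Q) for amikacin. The
disposition is represented internally as a sum of exponentials (the
two-compartment macro constants α, β are derived from the micro constants
k10 = CL/V1, k12 = Q/V1, k21 = Q/V2), so a single superposition engine
serves both structures. Closed forms rather than matrix exponentials or ODE
integration keep multi-dose prediction exact and fast; an independent
LSODA integration oracle in the test suite guards the algebra to a relative
error below 1e-6.

Individual parameters are `P_i = TVP · f(cov) · exp(η_P)` with log-normal
interindividual variability (IIV) on CL and V (vancomycin) or CL
(amikacin). Covariate effects are multiplicative: allometric weight scaling
(exponent 0.75 on clearances, 1.0 on volumes), clearance inversely related
to serum creatinine through a power term, and a mild power-law age term on
vancomycin clearance. Residual error is combined additive + proportional.

MAP estimation minimizes −2 log posterior,
`Σ[(c_obs−c_pred)²/σ² + ln σ²] + ηᵀΩ⁻¹η`, with BFGS from η = 0
(finite-difference gradients, objective tolerance 1e-8). The `ln σ²` term
is retained because the variance depends on the prediction through the
proportional component; implementations that drop it solve a slightly
different problem, so the choice is exposed as a flag. With no usable
observations the prior mode η = 0 is returned exactly, and a fit whose
objective exceeds the start point is replaced by the start point and
flagged unconverged. Full posterior sampling and credible intervals are out
of scope; the MAP mode is what routine TDM platforms compute.

Observations below the assay's lower limit of quantification (LOQ, default
0.5 mg/L) are flagged. Three policies exist for MAP fitting: `exclude`
(the library default, conservative pharmacometric practice), `loq_half`
(M5-style imputation), and `as_reported` (assimilate the recorded value,
zeros included). The study simulator defaults to `as_reported` because
that is how platform-based TDM treats the laboratory record — and because
excluding censored troughs assimilates only the upper tail of assay noise,
which demonstrably biases clearance estimates downward for a drug whose
true troughs sit below the LOQ.

## Default model parameters (synthetic)

The shipped typical values, IIV magnitudes and residual errors are
**synthetic defaults**, not estimates of any published model:
vancomycin CL 5 L/h, V 49 L at 70 kg with ω²(CL) = 0.16, ω²(V) = 0.09
(40%/30% CV) and σ_add 1.0 mg/L, σ_prop 0.15; amikacin CL 5.5 L/h,
V1 16 L, V2 30 L, Q 2 L/h at 70 kg with ω²(CL) = 0.09 and σ_add 0.5 mg/L,
σ_prop 0.15. They were chosen once so that the simulated cohort reproduces
the magnitudes this kind of pediatric TDM data exhibits — vancomycin
troughs around 8–15 mg/L with population-prior median absolute prediction
errors of several mg/L, amikacin 15 mg/kg peaks near 50 mg/L with
model-predicted troughs around 0.7 mg/L (often below the assay LOQ), and
first-trough a priori errors of roughly 40–50% for vancomycin. All values
are configuration: `model_from_dict` builds a `StructuralModel` from a
plain dictionary, and nothing in the code depends on the defaults.

## Exposure metrics and dose selection

At steady state AUC24 is the exact linear-PK identity (daily dose)/CL. The
within-interval profile — Cmax at end of infusion (a post-distribution
offset is available for two-compartment peaks), trough immediately
pre-dose, %fT>MIC by bracketed Brent root-finding — comes from the
closed-form geometric accumulation of the single-dose exponential terms.
MIC defaults to 1 mg/L as a standardization convention, explicitly not a
clinical breakpoint.

`recommend_dose` enumerates a candidate grid (vancomycin intervals
{4, 6, 8, 12, 24} h, amikacin {24, 36, 48} h; 1 h infusions; 10 mg dose
increments above 100 mg, 1 mg below) under safety caps (vancomycin
≤ 80 mg/kg/day and ≤ 4 g/day, amikacin ≤ 30 mg/kg/day — placeholders, not
clinical limits). Ranking among candidates is: feasibility of the hard
criteria, then a relative-deficiency score (for the infeasible case), then
smallest daily dose, then proximity to the advisory trough band, then the
longer interval. The advisory band deserves a note: a pure AUC criterion
makes every interval equivalent at equal daily dose, and breaking that tie
by interval length alone selects once-daily vancomycin with troughs near
zero. Letting the advisory band rank — but never veto — candidates keeps
minimal-daily-dose optimality intact while selecting clinically sensible
intervals; a config switch can make the band a hard constraint instead.

The standard-of-care comparator (`soc_adjust`) is the trough-driven rule:
below the target band the dose scales by band-midpoint/observed-trough
(factor capped at 3 for near-zero troughs), above it the dose scales down
by the same rule, and a trough exceeding twice the upper bound also steps
the interval up to the next candidate. For ceiling-only targets
(aminoglycoside trough < 5 mg/L) values under the ceiling leave the
regimen unchanged.

## The virtual cohort

`CohortConfig` defaults encode the emulated study population: n = 41,
age drawn from a log-normal calibrated so the median after truncation to
1–216 months equals 38.6 months with IQR 81.7 months; 56.1% female; 23/41
on vancomycin; 12/41 in the MIPD arm; a second TDM sample in 15/41. Weight
follows the transparent pediatric approximation (age_years + 4) × 2 kg
with 15% log-normal scatter — a documented toy, not a growth standard.
Serum creatinine is an age-dependent log-normal (median 0.20 + 0.02 ×
age_years mg/dL, 25% log-SD). Initial regimens are weight-based
conventions: vancomycin 15 mg/kg q6h, amikacin 15 mg/kg q24h, 1 h
infusions.

Each patient's protocol: true η drawn from Ω; first trough sampled 0.25 h
before the 4th vancomycin / 3rd amikacin dose with combined-error noise
(values below the LOQ truncated at zero and flagged); a priori and a
posteriori predictions at that time; then a group-specific adjustment —
MIPD patients receive the grid-optimized dose at η_MAP, standard-of-care
patients the proportional trough rule. Patients with a second sample have
it drawn before the adjusted-phase dose nearest hour 96 (day 4, the middle
of a typical day-3–5 window), with predictions compared a priori versus
using parameters updated with the first sample only. Randomness is
stream-split per patient from the master seed, so any patient is
reproducible independently of cohort size.

## What the simulation does and does not show

Passing tests demonstrate internal correctness (closed forms, estimator,
optimizer, metrics) and the qualitative behavior of Bayesian updating
under the generator's assumptions: the model that fits the data is the
model that generated them, covariates are error-free, sampling times are
exact, and adherence is perfect. Real TDM data adds model misspecification,
charted-time error and assay artifacts, so real-world accuracy gains will
generally be smaller than the simulated ones. One robust negative finding
from the simulation is worth stating: when a drug's true troughs sit below
the assay LOQ (amikacin on extended intervals), a single trough carries
almost no recoverable information, and cohort-level medians that pool two
error scales (near-zero amikacin errors with mg/L-scale vancomycin errors)
can move against both per-drug trends — a Simpson-type artifact of the
median on bimodal mixtures that evaluation designs should avoid by
stratifying on drug.

## Numerical choices

Two-compartment macro constants use the numerically safe discriminant
form; `expm1` avoids cancellation in infusion terms; steady-state
accumulation is the exact geometric series per exponential term. The MAP
start point is always the prior mode; grid searches break ties toward the
first minimum; %fT>MIC refines crossings with Brent's method on a 256-point
bracket grid. Degenerate inputs (all-zero residual error, singular Ω,
overlapping infusions, zero-amount doses, proportional-only error at zero
prediction) are rejected with named errors rather than propagated.

## Problem sizes

Default verification sizes — 10 random parameter sets for the ODE
cross-check, 200 virtual patients for recovery experiments, 20 master
seeds × 100 patients for directional cohort claims, n = 41 for the worked
study — were chosen as the smallest sizes at which the Monte-Carlo
statements are stable, keeping the full suite comfortably desk-scale.
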