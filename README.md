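# mipdsim

Model-informed precision dosing (MIPD), simulated end to end: population
pharmacokinetic forecasting, MAP Bayesian updating from sparse therapeutic
drug monitoring (TDM) samples, exposure-target dose optimization, and paired
a priori / a posteriori prediction-error evaluation — exercised on a
synthetic virtual-patient pediatric ICU cohort so the whole analysis runs
with no external data.

**Everything here is a research simulation.** The shipped population-model
parameters are synthetic defaults for testing; nothing this package prints
is clinical dosing advice.

## Who this is for

Pharmacometricians and methodologists who want a transparent, tested
reference implementation of the computational core of Bayesian TDM
platforms: how a trough concentration updates individual clearance, how an
AUC- or Cmax-targeted dose is chosen under safety caps, and how much a
single measured level actually improves predictive accuracy in a
trough-driven monitoring protocol.

## The model

Drug kinetics follow linear one-compartment (vancomycin-style: CL, V) or
two-compartment (aminoglycoside-style: CL, V1, V2, Q) IV-infusion models,
solved in closed form as sums of exponentials and superposed over arbitrary
dosing histories. Individual parameters follow the nonlinear mixed-effects
convention

    P_i = TVP · f(covariates) · exp(η_P),    η ~ N(0, Ω)

with allometric weight scaling, serum-creatinine and age terms on
clearance. Measured concentrations carry combined residual error,
σ² = σ_add² + (σ_prop · c_pred)². Given observations, the individual
deviations η are estimated at the posterior mode by minimizing

    Σ_i [ (c_obs,i − c_pred,i(η))² / σ_i² + ln σ_i² ] + ηᵀ Ω⁻¹ η

(the ln σ² term is kept: it matters when the variance depends on the
prediction). "A priori" predictions use η = 0 (covariates and dosing only);
"a posteriori" predictions use η_MAP. Exposure metrics (steady-state AUC24,
Cmax, trough, %fT>MIC) feed a deterministic grid search for the smallest
feasible daily dose meeting AUC/MIC ≥ 400 (vancomycin) or Cmax/MIC ≥ 8 with
trough < 5 mg/L (amikacin) under pediatric safety caps. Predictive accuracy
is summarized by MAE, MdAE and MdE over paired within-patient comparisons.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```bash
mipdsim run-study --out results/demo --seed 1 --n 41
```

simulates a 41-patient two-arm cohort (MIPD vs trough-guided standard of
care, vancomycin and amikacin), performs the MAP fits and dose adjustments,
and prints the total-cohort rows of the error summary:

```
 timepoint   prediction stratum level  n      mae     mdae       mde
         1     a_priori   total   all 41  2.90500  1.47910  0.044400
         1 a_posteriori   total   all 41  0.38960  0.23340 -0.092700
         2     a_priori   total   all 15  4.86100  2.22380 -0.018300
         2 a_posteriori   total   all 15  2.28050  1.21480  0.654700
```

Reading: at the first trough (n = 41) assimilating that same concentration
cuts the median absolute prediction error from 1.48 to 0.23 mg/L; at the
second trough (n = 15 patients with a second sample) predictions using
parameters updated with the *first* sample still halve both MAE and MdAE
relative to the population prior, while the signed median error (MdE) stays
near zero — updating sharpens precision without introducing gross bias. The
run directory also holds the cohort CSVs (`patients.csv`, `doses.csv`,
`levels.csv` plus a JSON schema), per-patient model-fit categories
(good / intermediate / poor) and the MIPD arm's dose recommendations.

Other subcommands: `simulate` (cohort only), `forecast` (per-patient
a priori / a posteriori concentration-time profile), `optimize` (dose
recommendations for an existing cohort), `evaluate` (error summary from a
prediction-pairs CSV).

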