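"""Virtual pediatric-ICU cohort generation and the study-shaped simulation.

The generator emulates the statistical structure an MIPD evaluation
assumes: a skewed pediatric age distribution (log-normal calibrated to a
median of 38.6 months with an IQR of 81.7 months), weight derived from
age by the transparent ``(age_years + 4) * 2`` kg approximation with
multiplicative scatter, an age-dependent serum creatinine, log-normal
interindividual variability on the PK parameters per model, and
combined additive + proportional measurement noise on trough samples
drawn at steady state (before the 4th vancomycin dose, before the 3rd
amikacin dose).

``run_study_simulation`` plays out the whole protocol per patient:
weight-based initial dosing, a first trough, a priori and a posteriori
predictions at that time, a group-specific adjustment (MIPD: model-based
dose optimization on the MAP parameters; SoC: proportional trough-driven
adjustment), and — for a configurable fraction of patients — a second
trough with predictions from parameters updated with the first sample
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy import stats as _stats

from .defaults import default_constraints, default_models, default_target
from .evaluation import PredictionPair, classify_fit, paired_evaluation
from .exposure import DoseConstraints, TargetSpec, recommend_dose, soc_adjust
from .forecasting import MapResult, Observation, map_fit, predict
from .models import (
    PatientCovariates,
    Regimen,
    StructuralModel,
    individualize,
    predict_concentration,
)

__all__ = [
    "SamplingPolicy",
    "CohortConfig",
    "VirtualPatient",
    "StudyResult",
    "sample_covariates",
    "simulate_tdm",
    "run_study_simulation",
    "round_dose",
]


def round_dose(dose_mg: float) -> float:
    """Round a dose to a practical order increment: 1 mg below 100 mg,
    10 mg above."""
    if dose_mg < 100.0:
        return max(1.0, round(dose_mg))
    return round(dose_mg / 10.0) * 10.0


@dataclass(frozen=True)
class SamplingPolicy:
    """Trough sampling rule: draw immediately before the given 1-based
    dose index, ``pre_dose_offset_h`` hours before that infusion starts."""

    trough_before_dose: int
    pre_dose_offset_h: float = 0.25

    def __post_init__(self) -> None:
        if self.trough_before_dose < 2:
            raise ValueError("trough_before_dose must be >= 2 (steady-state sampling)")
        if self.pre_dose_offset_h <= 0:
            raise ValueError("pre_dose_offset_h must be > 0")

    def sample_time(self, regimen: Regimen) -> float:
        idx = self.trough_before_dose - 1
        if idx >= len(regimen.events):
            raise ValueError(
                f"policy samples before dose {self.trough_before_dose} but the "
                f"regimen has only {len(regimen.events)} doses"
            )
        return regimen.events[idx].start_time_h - self.pre_dose_offset_h


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition configuration for the virtual cohort.

    Demographic anchors default to the evaluated cohort: n = 41, median
    (IQR) age 38.6 (81.7) months, 56.1% female, 23/41 on vancomycin,
    12/41 managed by MIPD, and a second TDM sample in 15/41.  Initial
    regimens are standard weight-based pediatric conventions
    (non-clinical simulation defaults).
    """

    n: int = 41
    seed: int = 12345
    vancomycin_fraction: float = 23 / 41
    mipd_fraction: float = 12 / 41
    second_sample_fraction: float = 15 / 41
    female_fraction: float = 0.561
    age_median_months: float = 38.6
    age_iqr_months: float = 81.7
    age_bounds_months: tuple[float, float] = (1.0, 216.0)
    weight_log_sd: float = 0.15
    scr_median_intercept_mg_dl: float = 0.20
    scr_median_slope_per_year: float = 0.02
    scr_log_sd: float = 0.25
    initial_mg_per_kg: dict = field(
        default_factory=lambda: {"vancomycin": 15.0, "amikacin": 15.0}
    )
    initial_interval_h: dict = field(
        default_factory=lambda: {"vancomycin": 6.0, "amikacin": 24.0}
    )
    infusion_duration_h: float = 1.0
    first_trough_dose: dict = field(
        default_factory=lambda: {"vancomycin": 4, "amikacin": 3}
    )
    #: the second TDM trough is drawn before the adjusted-phase dose whose
    #: start lies nearest this time (typically day 3-5 of therapy; day 4
    #: by default)
    second_sample_target_h: float = 96.0
    pre_dose_offset_h: float = 0.25
    #: assay lower limit of quantification; draws below it are flagged
    loq_mg_L: dict = field(
        default_factory=lambda: {"vancomycin": 0.5, "amikacin": 0.5}
    )
    #: how MAP fits treat below-LOQ observations; the study emulation
    #: assimilates reported values at face value (zeros included), the way
    #: TDM platforms take the laboratory record as-is
    blq_policy: str = "as_reported"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name in (
            "vancomycin_fraction",
            "mipd_fraction",
            "second_sample_fraction",
            "female_fraction",
        ):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        if self.age_median_months <= 0 or self.age_iqr_months <= 0:
            raise ValueError("age median and IQR must be > 0")

    @property
    def age_log_sd(self) -> float:
        """Log-scale SD of the age distribution implied by the configured
        median and IQR: for a log-normal, IQR = 2 * median * sinh(z * s)
        with z the 0.75 normal quantile."""
        z = _stats.norm.ppf(0.75)
        return math.asinh(self.age_iqr_months / (2.0 * self.age_median_months)) / z


@dataclass(frozen=True)
class VirtualPatient:
    id: str
    covariates: PatientCovariates
    true_eta: np.ndarray
    drug: str
    group: str
    regimen: Regimen
    observations: tuple[Observation, ...] = ()


@dataclass(frozen=True)
class StudyResult:
    """Everything the simulated study produces."""

    patients: list[VirtualPatient]
    pairs: list[PredictionPair]
    summary: pd.DataFrame
    fit_categories: pd.DataFrame
    recommendations: pd.DataFrame
    map_results: dict[str, MapResult]
    config: CohortConfig


@lru_cache(maxsize=32)
def _age_log_location(median: float, log_sd: float, lo: float, hi: float) -> float:
    """Log-scale location of the truncated log-normal age distribution,
    solved so the median AFTER truncation to [lo, hi] months equals the
    configured cohort median."""

    def truncated_median(mu: float) -> float:
        a = (math.log(lo) - mu) / log_sd
        b = (math.log(hi) - mu) / log_sd
        pa, pb = _stats.norm.cdf(a), _stats.norm.cdf(b)
        return math.exp(mu + log_sd * _stats.norm.ppf((pa + pb) / 2.0))

    target = math.log(median)
    return float(
        _opt.brentq(lambda mu: truncated_median(mu) - median, target - 3.0, target + 3.0)
    )


def _sample_one_covariates(config: CohortConfig, rng: np.random.Generator) -> PatientCovariates:
    lo, hi = config.age_bounds_months
    s = config.age_log_sd
    mu = _age_log_location(config.age_median_months, s, lo, hi)
    # inverse-CDF draw from the truncated log-normal
    pa = _stats.norm.cdf((math.log(lo) - mu) / s)
    pb = _stats.norm.cdf((math.log(hi) - mu) / s)
    u = pa + (pb - pa) * rng.random()
    age = float(np.exp(mu + s * _stats.norm.ppf(u)))
    age_years = age / 12.0
    weight = (age_years + 4.0) * 2.0 * float(
        np.exp(config.weight_log_sd * rng.standard_normal())
    )
    scr_median = (
        config.scr_median_intercept_mg_dl + config.scr_median_slope_per_year * age_years
    )
    scr = scr_median * float(np.exp(config.scr_log_sd * rng.standard_normal()))
    sex = "female" if rng.random() < config.female_fraction else "male"
    height = 50.0 + 6.0 * age_years  # crude linear stature curve, cm
    return PatientCovariates(
        age_months=age, weight_kg=weight, scr_mg_dl=scr, sex=sex, height_cm=height
    )


def sample_covariates(config: CohortConfig) -> list[PatientCovariates]:
    """Draw ``config.n`` covariate sets from the configured distributions."""
    rng = np.random.default_rng(config.seed)
    return [_sample_one_covariates(config, rng) for _ in range(config.n)]


def _noisy_observation(
    model: StructuralModel,
    true_params,
    regimen: Regimen,
    time_h: float,
    rng: np.random.Generator,
    loq_mg_L: float = 0.0,
) -> Observation:
    true_conc = float(predict_concentration(true_params, model, regimen, np.array([time_h]))[0])
    sd = float(np.sqrt(model.residual_error.variance(np.array([true_conc]))[0]))
    value = true_conc + sd * float(rng.standard_normal())
    # the assay reports anything below its quantification limit as BLQ
    # (kept in the record, truncated at zero, flagged)
    below_loq = value < loq_mg_L
    return Observation(
        time_h=time_h,
        concentration_mg_L=max(value, 0.0),
        drug=model.drug,
        below_loq=below_loq,
    )


def simulate_tdm(
    patient: VirtualPatient,
    model: StructuralModel,
    policy: SamplingPolicy,
    rng: np.random.Generator,
    loq_mg_L: float = 0.0,
) -> list[Observation]:
    """Draw trough observations for a patient under a sampling policy.

    The observed value is the model prediction at the patient's true eta
    perturbed by the residual-error model; draws below the assay
    quantification limit (and any negative draw) are truncated at zero
    concentration-floor and flagged ``below_loq``.
    """
    t = policy.sample_time(patient.regimen)
    true_params = individualize(model, patient.covariates, patient.true_eta)
    return [_noisy_observation(model, true_params, patient.regimen, t, rng, loq_mg_L)]


def _simulate_patient(
    pid: str,
    config: CohortConfig,
    models: dict[str, StructuralModel],
    targets: dict[str, TargetSpec],
    constraints: dict[str, DoseConstraints],
    rng: np.random.Generator,
):
    cov = _sample_one_covariates(config, rng)
    drug = "vancomycin" if rng.random() < config.vancomycin_fraction else "amikacin"
    group = "MIPD" if rng.random() < config.mipd_fraction else "SoC"
    has_second = rng.random() < config.second_sample_fraction
    model = models[drug]
    target = targets[drug]
    # true individual deviations
    if model.n_eta:
        chol = np.linalg.cholesky(model.omega)
        true_eta = chol @ rng.standard_normal(model.n_eta)
    else:
        true_eta = np.zeros(0)
    true_params = individualize(model, cov, true_eta)

    # phase 1: weight-based empiric regimen up to the first trough
    interval1 = config.initial_interval_h[drug]
    dose1 = round_dose(config.initial_mg_per_kg[drug] * cov.weight_kg)
    n_phase1 = config.first_trough_dose[drug] - 1
    phase1 = Regimen.from_schedule(
        dose1, interval1, config.infusion_duration_h, n_phase1, drug
    )
    t1 = n_phase1 * interval1 - config.pre_dose_offset_h
    obs1 = _noisy_observation(
        model, true_params, phase1, t1, rng, config.loq_mg_L[drug]
    )

    # predictions at the first sample time
    apriori1 = float(predict(model, cov, phase1, [t1], mode="a_priori")[0])
    fit = map_fit(
        model, cov, phase1, [obs1],
        blq_policy=config.blq_policy, loq_mg_L=config.loq_mg_L[drug],
    )
    apost1 = float(
        predict_concentration(fit.params, model, phase1, np.array([t1]))[0]
    )

    # group-specific adjustment at the next scheduled dose
    t_adjust = n_phase1 * interval1
    if group == "MIPD":
        rec = recommend_dose(model, cov, fit.eta_map, target, constraints[drug])
        dose2, interval2 = rec.dose_mg, rec.interval_h
    else:
        rec = None
        dose2, interval2 = soc_adjust(
            dose1, interval1, obs1.concentration_mg_L, target,
            intervals_h=constraints[drug].intervals_h,
        )

    # run the adjusted regimen past the second-sample window (~day 3-5)
    n_phase2 = max(
        2, int(np.ceil((config.second_sample_target_h - t_adjust) / interval2)) + 2
    )
    phase2 = Regimen.from_schedule(
        dose2, interval2, config.infusion_duration_h, n_phase2, drug,
        first_dose_time_h=t_adjust,
    )
    full_regimen = phase1.extended(phase2)

    pairs = [
        PredictionPair(
            patient_id=pid,
            timepoint_index=1,
            observed=obs1.concentration_mg_L,
            predicted_a_priori=apriori1,
            predicted_a_posteriori=apost1,
            group=group,
            drug=drug,
        )
    ]
    observations = [obs1]
    if has_second:
        # trough before the adjusted dose closest to the target day, with
        # at least one adjusted dose already given
        starts = np.array([e.start_time_h for e in phase2.events[1:]])
        nearest = int(np.argmin(np.abs(starts - config.second_sample_target_h)))
        t2 = starts[nearest] - config.pre_dose_offset_h
        obs2 = _noisy_observation(
            model, true_params, full_regimen, t2, rng, config.loq_mg_L[drug]
        )
        apriori2 = float(predict(model, cov, full_regimen, [t2], mode="a_priori")[0])
        # a posteriori at the 2nd sample: parameters updated with the 1st only
        fit2 = map_fit(
            model, cov, full_regimen, [obs1],
            blq_policy=config.blq_policy, loq_mg_L=config.loq_mg_L[drug],
        )
        apost2 = float(
            predict_concentration(fit2.params, model, full_regimen, np.array([t2]))[0]
        )
        pairs.append(
            PredictionPair(
                patient_id=pid,
                timepoint_index=2,
                observed=obs2.concentration_mg_L,
                predicted_a_priori=apriori2,
                predicted_a_posteriori=apost2,
                group=group,
                drug=drug,
            )
        )
        observations.append(obs2)

    patient = VirtualPatient(
        id=pid,
        covariates=cov,
        true_eta=true_eta,
        drug=drug,
        group=group,
        regimen=full_regimen,
        observations=tuple(observations),
    )
    return patient, pairs, fit, rec


def run_study_simulation(
    config: CohortConfig | None = None,
    models: dict[str, StructuralModel] | None = None,
    targets: dict[str, TargetSpec] | None = None,
    constraints: dict[str, DoseConstraints] | None = None,
) -> StudyResult:
    """Simulate the full two-arm TDM study on a virtual cohort.

    Per-patient randomness is stream-split from the master seed, so any
    patient's trajectory is reproducible independently of cohort size.
    """
    config = config or CohortConfig()
    models = models or default_models()
    targets = targets or {d: default_target(d) for d in models}
    constraints = constraints or {d: default_constraints(d) for d in models}

    streams = np.random.SeedSequence(config.seed).spawn(config.n)
    patients: list[VirtualPatient] = []
    pairs: list[PredictionPair] = []
    map_results: dict[str, MapResult] = {}
    rec_rows = []
    fit_rows = []
    for i, stream in enumerate(streams):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(stream)
        patient, patient_pairs, fit, rec = _simulate_patient(
            pid, config, models, targets, constraints, rng
        )
        patients.append(patient)
        pairs.extend(patient_pairs)
        map_results[pid] = fit
        if rec is not None:
            rec_rows.append(
                {
                    "patient_id": pid,
                    "drug": patient.drug,
                    "dose_mg": rec.dose_mg,
                    "interval_h": rec.interval_h,
                    "daily_dose_mg": rec.daily_dose_mg,
                    "feasible": rec.feasible,
                    "capped": rec.capped,
                    "pred_auc24": rec.predicted.auc24,
                    "pred_cmax": rec.predicted.cmax,
                    "pred_trough": rec.predicted.trough,
                }
            )
        for p in patient_pairs:
            for mode, predicted in (
                ("a_priori", p.predicted_a_priori),
                ("a_posteriori", p.predicted_a_posteriori),
            ):
                cat = classify_fit(p.observed, predicted)
                fit_rows.append(
                    {
                        "patient_id": p.patient_id,
                        "timepoint": p.timepoint_index,
                        "prediction": mode,
                        "group": p.group,
                        "drug": p.drug,
                        "label": cat.label,
                        "relative_error": cat.relative_error,
                    }
                )
    summary = paired_evaluation(pairs)
    return StudyResult(
        patients=patients,
        pairs=pairs,
        summary=summary,
        fit_categories=pd.DataFrame(fit_rows),
        recommendations=pd.DataFrame(rec_rows),
        map_results=map_results,
        config=config,
    )
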