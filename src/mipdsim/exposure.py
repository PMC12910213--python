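"""Steady-state exposure metrics and PK/PD-target dose optimization.

Exposure indices follow the usual antibacterial conventions: AUC24/MIC
(vancomycin efficacy), Cmax/MIC (aminoglycoside efficacy), the trough
concentration (safety for both), and %fT>MIC.  For a linear model at
steady state AUC24 is the analytic identity (daily dose)/CL; the interval
profile (Cmax, trough, MIC crossings) comes from the closed-form
steady-state solution obtained by geometric accumulation of the
single-dose exponential terms.

Dose selection is a deterministic grid search over candidate
(dose, interval) pairs under pediatric safety caps, returning the smallest
feasible daily dose (ties broken toward the longer interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _opt

from .models import (
    IndividualParameters,
    PatientCovariates,
    StructuralModel,
    disposition_terms,
    individualize,
)

__all__ = [
    "ExposureMetrics",
    "TargetSpec",
    "DoseConstraints",
    "DoseRecommendation",
    "steady_state_profile",
    "steady_state_metrics",
    "recommend_dose",
    "soc_adjust",
]


@dataclass(frozen=True)
class ExposureMetrics:
    auc24: float
    cmax: float
    trough: float
    mic: float
    ft_above_mic_pct: float

    @property
    def auc_over_mic(self) -> float:
        return self.auc24 / self.mic

    @property
    def cmax_over_mic(self) -> float:
        return self.cmax / self.mic

    def __post_init__(self) -> None:
        for name in ("auc24", "cmax", "trough"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mic <= 0:
            raise ValueError("mic must be > 0")
        if not 0.0 <= self.ft_above_mic_pct <= 100.0:
            raise ValueError("ft_above_mic_pct must be within [0, 100]")


@dataclass(frozen=True)
class TargetSpec:
    """PK/PD target definition.

    The trough band can act as a hard feasibility constraint or (default)
    as an advisory monitoring range that does not veto candidates, the
    role trough targets play when AUC-guided dosing is prioritized.
    """

    drug: str
    mic_mg_L: float = 1.0
    auc_over_mic_min: float | None = None
    trough_band_mg_L: tuple[float, float] | None = None
    trough_band_hard: bool = False
    cmax_over_mic_min: float | None = None
    trough_max_mg_L: float | None = None

    def __post_init__(self) -> None:
        if self.mic_mg_L <= 0:
            raise ValueError("mic_mg_L must be > 0")
        criteria = (
            self.auc_over_mic_min,
            self.trough_band_mg_L,
            self.cmax_over_mic_min,
            self.trough_max_mg_L,
        )
        if all(c is None for c in criteria):
            raise ValueError("a TargetSpec needs at least one criterion")
        if self.trough_band_mg_L is not None:
            lo, hi = self.trough_band_mg_L
            if not lo < hi:
                raise ValueError("trough band must satisfy low < high")

    def is_met(self, m: ExposureMetrics) -> bool:
        """Whether all active hard criteria are satisfied."""
        if self.auc_over_mic_min is not None and m.auc_over_mic < self.auc_over_mic_min:
            return False
        if self.cmax_over_mic_min is not None and m.cmax_over_mic < self.cmax_over_mic_min:
            return False
        if self.trough_max_mg_L is not None and m.trough >= self.trough_max_mg_L:
            return False
        if self.trough_band_hard and self.trough_band_mg_L is not None:
            lo, hi = self.trough_band_mg_L
            if not lo <= m.trough <= hi:
                return False
        return True

    def deficiency(self, m: ExposureMetrics) -> float:
        """Relative shortfall score used to rank infeasible candidates
        (0 when every hard criterion is met)."""
        score = 0.0
        if self.auc_over_mic_min is not None:
            score += max(0.0, (self.auc_over_mic_min - m.auc_over_mic) / self.auc_over_mic_min)
        if self.cmax_over_mic_min is not None:
            score += max(0.0, (self.cmax_over_mic_min - m.cmax_over_mic) / self.cmax_over_mic_min)
        if self.trough_max_mg_L is not None:
            score += max(0.0, (m.trough - self.trough_max_mg_L) / self.trough_max_mg_L)
        if self.trough_band_hard and self.trough_band_mg_L is not None:
            lo, hi = self.trough_band_mg_L
            score += max(0.0, (lo - m.trough) / lo) + max(0.0, (m.trough - hi) / hi)
        return score

    def advisory_deficiency(self, m: ExposureMetrics) -> float:
        """Relative distance from the advisory trough band (zero inside
        the band, or when the band is absent or acting as a hard
        constraint).  Used to prefer among otherwise-equivalent
        candidates without vetoing any."""
        if self.trough_band_mg_L is None or self.trough_band_hard:
            return 0.0
        lo, hi = self.trough_band_mg_L
        return max(0.0, (lo - m.trough) / lo) + max(0.0, (m.trough - hi) / hi)


@dataclass(frozen=True)
class DoseConstraints:
    """Candidate grids and safety caps for the dose search.

    The caps are configuration placeholders for simulation, not clinical
    dosing limits.
    """

    intervals_h: tuple[float, ...]
    max_mg_per_kg_day: float
    max_mg_day: float = float("inf")
    infusion_duration_h: float = 1.0
    dose_increment_mg: float = 10.0
    dose_increment_small_mg: float = 1.0
    small_dose_threshold_mg: float = 100.0

    def __post_init__(self) -> None:
        if not self.intervals_h:
            raise ValueError("the candidate interval set must be non-empty")
        if self.max_mg_per_kg_day <= 0:
            raise ValueError("max_mg_per_kg_day must be > 0")

    def candidate_doses(self, max_dose_mg: float) -> np.ndarray:
        """Doses from the increment grid up to ``max_dose_mg``: 1 mg steps
        below 100 mg, 10 mg steps above."""
        if max_dose_mg < self.dose_increment_small_mg:
            return np.array([])
        small = np.arange(
            self.dose_increment_small_mg,
            min(self.small_dose_threshold_mg, max_dose_mg) + 1e-9,
            self.dose_increment_small_mg,
        )
        if max_dose_mg < self.small_dose_threshold_mg:
            return small
        large = np.arange(
            self.small_dose_threshold_mg,
            max_dose_mg + 1e-9,
            self.dose_increment_mg,
        )
        return np.unique(np.concatenate([small, large]))


@dataclass(frozen=True)
class DoseRecommendation:
    dose_mg: float
    interval_h: float
    infusion_duration_h: float
    predicted: ExposureMetrics
    feasible: bool
    capped: bool

    @property
    def daily_dose_mg(self) -> float:
        return self.dose_mg * 24.0 / self.interval_h


def steady_state_profile(
    params: IndividualParameters,
    model: StructuralModel,
    dose_mg: float,
    interval_h: float,
    infusion_duration_h: float,
):
    """Return a vectorized function c_ss(t) for t in [0, interval_h].

    With the single-dose solution written as a sum of exponential terms,
    the steady-state profile is the single-dose profile plus the geometric
    accumulation of all earlier doses:
    ``sum_j C_j exp(-lam_j (t - T)) * r_j / (1 - r_j)``, ``r_j =
    exp(-lam_j * tau)``, where C_j is the end-of-infusion amplitude of
    term j.
    """
    if interval_h <= 0:
        raise ValueError("interval_h must be > 0")
    if interval_h <= infusion_duration_h:
        raise ValueError("interval_h must exceed infusion_duration_h")
    lambdas, coeffs = disposition_terms(params.values, model.structure)
    r0 = dose_mg / infusion_duration_h
    dur = infusion_duration_h
    scale = coeffs * r0 / lambdas  # per-term plateau amplitude
    end_amp = scale * -np.expm1(-lambdas * dur)  # end-of-infusion amplitude
    r = np.exp(-lambdas * interval_h)
    accum = end_amp * r / (1.0 - r)

    def profile(t):
        t = np.asarray(t, dtype=float)
        tt = t[..., None]
        current = (
            scale * -np.expm1(-lambdas * np.minimum(tt, dur))
        ) * np.exp(-lambdas * np.maximum(tt - dur, 0.0))
        past = accum * np.exp(-lambdas * (tt - dur))
        return np.maximum((current + past).sum(axis=-1), 0.0)

    return profile


def steady_state_metrics(
    params: IndividualParameters,
    model: StructuralModel,
    dose_mg: float,
    interval_h: float,
    infusion_duration_h: float,
    mic: float = 1.0,
    cmax_offset_h: float = 0.0,
) -> ExposureMetrics:
    """Exposure metrics over one steady-state dosing interval.

    AUC24 uses the linear-PK identity (daily dose)/CL.  Cmax is taken at
    the end of the infusion (plus ``cmax_offset_h`` for a post-distribution
    peak convention); the trough is the concentration immediately before
    the next dose.  %fT>MIC is measured by bracketed root finding on the
    interval profile.
    """
    if dose_mg <= 0:
        raise ValueError("dose_mg must be > 0")
    if interval_h <= 0:
        raise ValueError("interval_h must be > 0")
    cl = params.values["CL"]
    auc24 = dose_mg * (24.0 / interval_h) / cl
    profile = steady_state_profile(params, model, dose_mg, interval_h, infusion_duration_h)
    cmax = float(profile(min(infusion_duration_h + cmax_offset_h, interval_h)))
    trough = float(profile(interval_h))
    ft = _fraction_above(profile, interval_h, mic)
    return ExposureMetrics(
        auc24=auc24, cmax=cmax, trough=trough, mic=mic, ft_above_mic_pct=ft
    )


def _fraction_above(profile, interval_h: float, mic: float, n_grid: int = 256) -> float:
    """Percent of the interval with concentration above MIC, via a coarse
    grid to bracket crossings and Brent refinement on each bracket."""
    grid = np.linspace(0.0, interval_h, n_grid + 1)
    vals = profile(grid) - mic
    above = vals > 0
    if above.all():
        return 100.0
    if not above.any():
        return 0.0
    crossings = []
    for i in range(n_grid):
        if above[i] != above[i + 1]:
            root = _opt.brentq(lambda t: float(profile(t)) - mic, grid[i], grid[i + 1])
            crossings.append(root)
    edges = [0.0] + sorted(crossings) + [interval_h]
    time_above = 0.0
    for lo, hi in zip(edges, edges[1:]):
        mid = (lo + hi) / 2.0
        if profile(mid) > mic:
            time_above += hi - lo
    return 100.0 * time_above / interval_h


def recommend_dose(
    model: StructuralModel,
    cov: PatientCovariates,
    eta: np.ndarray,
    target: TargetSpec,
    constraints: DoseConstraints,
) -> DoseRecommendation:
    """Grid search for the smallest feasible daily dose under safety caps.

    All (dose, interval) candidates within the caps are evaluated at
    steady state with the individualized parameters.  Among feasible
    candidates the smallest daily dose wins; equal daily doses are then
    ranked by proximity to the advisory trough band (so a band that does
    not veto feasibility still steers the choice toward a sensible
    interval), and finally by the longer interval.  If nothing is
    feasible, the candidate minimizing the target's deficiency score is
    returned with ``feasible=False``.  ``capped=True`` marks an
    infeasible recommendation whose daily dose sits at the safety cap.
    """
    params = individualize(model, cov, np.asarray(eta, dtype=float))
    daily_cap = min(constraints.max_mg_per_kg_day * cov.weight_kg, constraints.max_mg_day)
    best = None  # (key, candidate)
    any_candidate = False
    for interval in sorted(constraints.intervals_h):
        if interval <= constraints.infusion_duration_h:
            continue
        dose_cap = daily_cap * interval / 24.0
        for dose in constraints.candidate_doses(dose_cap):
            any_candidate = True
            m = steady_state_metrics(
                params, model, float(dose), interval, constraints.infusion_duration_h,
                mic=target.mic_mg_L,
            )
            feasible = target.is_met(m)
            daily = float(dose) * 24.0 / interval
            # feasible candidates sort before infeasible ones; then by hard
            # deficiency (0 when feasible), daily dose, advisory-band
            # proximity, and longer interval
            key = (
                not feasible,
                target.deficiency(m),
                daily,
                target.advisory_deficiency(m),
                -interval,
            )
            if best is None or key < best[0]:
                best = (key, (float(dose), interval, m, feasible, dose_cap))
    if not any_candidate:
        raise ValueError("empty candidate grid: caps admit no dose")
    dose, interval, metrics, feasible, dose_cap = best[1]
    increment = (
        constraints.dose_increment_small_mg
        if dose_cap < constraints.small_dose_threshold_mg
        else constraints.dose_increment_mg
    )
    capped = dose > dose_cap - increment  # the cap truncated the grid here
    return DoseRecommendation(
        dose_mg=dose,
        interval_h=interval,
        infusion_duration_h=constraints.infusion_duration_h,
        predicted=metrics,
        feasible=feasible,
        capped=capped and not feasible,
    )


def soc_adjust(
    dose_mg: float,
    interval_h: float,
    trough_obs: float,
    target: TargetSpec,
    intervals_h: tuple[float, ...] = (4.0, 6.0, 8.0, 12.0, 24.0, 36.0, 48.0),
    dose_increment_mg: float = 1.0,
    max_scale_factor: float = 3.0,
) -> tuple[float, float]:
    """Trough-driven proportional dose adjustment (the comparator arm).

    Below the target band the total daily dose is scaled up by
    (band midpoint / observed trough); supratherapeutic troughs scale the
    dose down by the same rule, and a trough above twice the upper bound
    additionally extends the interval to the next candidate.  A zero or
    near-zero trough caps the scaling factor at ``max_scale_factor``.
    For a ceiling-only target (e.g. aminoglycoside trough < max) the dose
    is left unchanged below the ceiling and scaled toward half the ceiling
    above it.
    """
    if trough_obs < 0:
        raise ValueError("trough_obs must be >= 0")
    if target.trough_band_mg_L is not None:
        lo, hi = target.trough_band_mg_L
    elif target.trough_max_mg_L is not None:
        lo, hi = 0.0, target.trough_max_mg_L
    else:
        raise ValueError("soc_adjust needs a trough band or trough ceiling")
    mid = (lo + hi) / 2.0
    in_range = (lo <= trough_obs <= hi) if lo > 0 else (trough_obs < hi)
    if in_range:
        return dose_mg, interval_h
    factor = mid / trough_obs if trough_obs > 0 else max_scale_factor
    factor = min(factor, max_scale_factor)
    new_dose = max(
        dose_increment_mg,
        round(dose_mg * factor / dose_increment_mg) * dose_increment_mg,
    )
    new_interval = interval_h
    if trough_obs > 2.0 * hi:
        longer = [i for i in sorted(intervals_h) if i > interval_h]
        if longer:
            new_interval = longer[0]
    return new_dose, new_interval
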