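"""Population-pharmacokinetic model definitions and concentration prediction.

The structural models supported are the two workhorses of intravenous
antibiotic therapy: a one-compartment model (clearance CL, volume V) and a
two-compartment model (CL, central volume V1, peripheral volume V2,
intercompartmental clearance Q).  Both are linear, so an arbitrary
multi-infusion dosing history is handled by superposition of closed-form
single-infusion solutions.  Every disposition model is represented
internally as a sum of exponentials, which makes the one- and
two-compartment code paths identical apart from the macro-constant
decomposition.

Individual parameters follow the standard nonlinear mixed-effects
convention: ``P_i = TVP * f(covariates) * exp(eta_P)`` where ``TVP`` is the
population typical value, ``f`` the covariate model, and ``eta_P`` a
log-scale random effect with covariance ``omega`` for the parameters that
carry interindividual variability (IIV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatientCovariates",
    "DoseEvent",
    "Regimen",
    "CovariateEffect",
    "ResidualErrorSpec",
    "StructuralModel",
    "IndividualParameters",
    "individualize",
    "predict_concentration",
    "disposition_terms",
]

DRUGS = ("vancomycin", "amikacin")
STRUCTURES = ("one_compartment_iv_infusion", "two_compartment_iv_infusion")
COVARIATE_FORMS = ("allometric_power", "proportional", "power", "inverse")

#: attribute looked up on PatientCovariates for each covariate name
_COVARIATE_ATTR = {
    "weight": "weight_kg",
    "age": "age_months",
    "scr": "scr_mg_dl",
    "height": "height_cm",
}


@dataclass(frozen=True)
class PatientCovariates:
    """Demographic and renal covariates consumed by the covariate models.

    Units: age in months, weight in kg, height in cm, serum creatinine
    (SCr) in mg/dL.
    """

    age_months: float
    weight_kg: float
    scr_mg_dl: float
    sex: str
    height_cm: float | None = None

    def __post_init__(self) -> None:
        for name in ("age_months", "weight_kg", "scr_mg_dl"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"covariate {name!r} must be finite and > 0, got {value}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.height_cm is not None and self.height_cm <= 0:
            raise ValueError(f"covariate 'height_cm' must be > 0, got {self.height_cm}")


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion: ``amount_mg`` given over
    ``infusion_duration_h`` starting at ``start_time_h`` (hours from the
    regimen origin).  Bolus dosing is not modelled; both drugs are infused.
    """

    start_time_h: float
    amount_mg: float
    infusion_duration_h: float
    drug: str

    def __post_init__(self) -> None:
        if self.start_time_h < 0:
            raise ValueError(f"start_time_h must be >= 0, got {self.start_time_h}")
        if self.amount_mg <= 0:
            raise ValueError(f"amount_mg must be > 0, got {self.amount_mg}")
        if self.infusion_duration_h <= 0:
            raise ValueError(f"infusion_duration_h must be > 0, got {self.infusion_duration_h}")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")

    @property
    def end_time_h(self) -> float:
        return self.start_time_h + self.infusion_duration_h

    @property
    def rate_mg_h(self) -> float:
        return self.amount_mg / self.infusion_duration_h


@dataclass(frozen=True)
class Regimen:
    """An ordered dosing history.  The time origin is the start of the
    first infusion; consecutive infusions must not overlap.
    """

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        if not events:
            raise ValueError("a regimen needs at least one dose event")
        starts = [e.start_time_h for e in events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("dose events must be sorted by start_time_h")
        for a, b in zip(events, events[1:]):
            if b.start_time_h < a.end_time_h:
                raise ValueError(
                    f"overlapping infusions: dose at t={a.start_time_h} h runs to "
                    f"{a.end_time_h} h but next dose starts at {b.start_time_h} h"
                )

    @classmethod
    def from_schedule(
        cls,
        dose_mg: float,
        interval_h: float,
        infusion_duration_h: float,
        n_doses: int,
        drug: str,
        first_dose_time_h: float = 0.0,
    ) -> "Regimen":
        """Build a uniform ``dose_mg`` every ``interval_h`` regimen."""
        if n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if interval_h <= infusion_duration_h:
            raise ValueError("interval_h must exceed infusion_duration_h")
        events = tuple(
            DoseEvent(first_dose_time_h + i * interval_h, dose_mg, infusion_duration_h, drug)
            for i in range(n_doses)
        )
        return cls(events)

    @property
    def drug(self) -> str:
        return self.events[0].drug

    @property
    def last_event_end_h(self) -> float:
        return max(e.end_time_h for e in self.events)

    def extended(self, other: "Regimen") -> "Regimen":
        """Concatenate a follow-on regimen (e.g. after a dose adjustment)."""
        return Regimen(self.events + other.events)


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate effect on one PK parameter.

    Forms (``x`` the covariate value, ``r`` the reference, ``e`` the
    exponent or slope):

    - ``allometric_power`` / ``power``: ``(x / r) ** e``
    - ``proportional``: ``1 + e * (x - r)``
    - ``inverse``: ``(x / r) ** (-e)`` (e.g. clearance falling with SCr)
    """

    parameter: str
    covariate: str
    form: str
    reference_value: float
    exponent_or_slope: float

    def __post_init__(self) -> None:
        if self.form not in COVARIATE_FORMS:
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.reference_value <= 0:
            raise ValueError("reference_value must be > 0")
        if self.covariate not in _COVARIATE_ATTR:
            raise ValueError(f"unknown covariate {self.covariate!r}")

    def multiplier(self, cov: PatientCovariates) -> float:
        value = getattr(cov, _COVARIATE_ATTR[self.covariate])
        if value is None:
            raise ValueError(f"covariate {self.covariate!r} missing for this patient")
        ratio = value / self.reference_value
        if self.form in ("allometric_power", "power"):
            out = ratio ** self.exponent_or_slope
        elif self.form == "inverse":
            out = ratio ** (-self.exponent_or_slope)
        else:  # proportional
            out = 1.0 + self.exponent_or_slope * (value - self.reference_value)
        if out <= 0:
            raise ValueError(
                f"covariate effect on {self.parameter!r} produced a non-positive "
                f"multiplier ({out}) for {self.covariate}={value}"
            )
        return out


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Combined residual-error model: var = sigma_add^2 + (sigma_prop*pred)^2."""

    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual sigmas must be >= 0")
        if self.sigma_add + self.sigma_prop == 0:
            raise ValueError("a degenerate all-zero residual-error model is rejected")

    def variance(self, predicted: np.ndarray) -> np.ndarray:
        return self.sigma_add**2 + (self.sigma_prop * np.asarray(predicted)) ** 2


_STRUCTURE_PARAMS = {
    "one_compartment_iv_infusion": ("CL", "V"),
    "two_compartment_iv_infusion": ("CL", "V1", "V2", "Q"),
}


@dataclass(frozen=True)
class StructuralModel:
    """A population-PK model: structure, typical values, covariate effects,
    IIV covariance and residual error.

    ``iiv_parameters`` names the parameters carrying a random effect; its
    order defines the eta/omega indexing.
    """

    structure: str
    typical_values: dict[str, float]
    covariate_effects: tuple[CovariateEffect, ...]
    iiv_parameters: tuple[str, ...]
    omega: np.ndarray
    residual_error: ResidualErrorSpec
    drug: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        required = _STRUCTURE_PARAMS[self.structure]
        missing = set(required) - set(self.typical_values)
        if missing:
            raise ValueError(f"missing typical values for {sorted(missing)}")
        for p, v in self.typical_values.items():
            if v <= 0:
                raise ValueError(f"typical value {p} must be > 0, got {v}")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        object.__setattr__(self, "iiv_parameters", tuple(self.iiv_parameters))
        omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        object.__setattr__(self, "omega", omega)
        k = len(self.iiv_parameters)
        if omega.shape != (k, k):
            raise ValueError(f"omega must be {k}x{k} for {k} IIV parameters, got {omega.shape}")
        if k:
            if not np.allclose(omega, omega.T):
                raise ValueError("omega must be symmetric")
            eigs = np.linalg.eigvalsh(omega)
            if np.any(eigs < -1e-12):
                raise ValueError("omega must be positive semi-definite")
        unknown = set(self.iiv_parameters) - set(required)
        if unknown:
            raise ValueError(f"IIV on unknown parameters {sorted(unknown)}")
        for eff in self.covariate_effects:
            if eff.parameter not in required:
                raise ValueError(f"covariate effect targets unknown parameter {eff.parameter!r}")

    @property
    def n_eta(self) -> int:
        return len(self.iiv_parameters)

    def omega_inverse(self) -> np.ndarray:
        if self.n_eta == 0:
            return np.zeros((0, 0))
        try:
            return np.linalg.inv(self.omega)
        except np.linalg.LinAlgError as exc:
            raise ValueError("omega is singular; MAP estimation is undefined") from exc


@dataclass(frozen=True)
class IndividualParameters:
    """Individualized PK parameters produced by :func:`individualize`."""

    eta: np.ndarray
    values: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))
        for p, v in self.values.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"individualized {p} must be finite and > 0, got {v}")


def individualize(
    model: StructuralModel, cov: PatientCovariates, eta: np.ndarray
) -> IndividualParameters:
    """Apply the covariate model and log-normal random effects.

    ``P_i = TVP * prod(covariate multipliers) * exp(eta_P)`` for parameters
    with IIV, and the same without the exponential term otherwise.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    if eta.shape != (model.n_eta,):
        raise ValueError(
            f"eta has length {eta.shape[0]} but model carries IIV on {model.n_eta} parameters"
        )
    values: dict[str, float] = {}
    eta_index = {p: i for i, p in enumerate(model.iiv_parameters)}
    for param, tv in model.typical_values.items():
        mult = 1.0
        for eff in model.covariate_effects:
            if eff.parameter == param:
                mult *= eff.multiplier(cov)
        value = tv * mult
        if param in eta_index:
            value *= float(np.exp(eta[eta_index[param]]))
        values[param] = value
    return IndividualParameters(eta=eta, values=values)


def disposition_terms(values: dict[str, float], structure: str) -> tuple[np.ndarray, np.ndarray]:
    """Decompose the disposition model into a sum of exponentials.

    Returns ``(lambdas, coeffs)`` such that the concentration after a unit
    IV bolus is ``sum_j coeffs[j] * exp(-lambdas[j] * t)``.  For the
    two-compartment model these are the macro (hybrid) rate constants
    alpha/beta obtained from the micro constants k10 = CL/V1, k12 = Q/V1,
    k21 = Q/V2.
    """
    if structure == "one_compartment_iv_infusion":
        cl, v = values["CL"], values["V"]
        return np.array([cl / v]), np.array([1.0 / v])
    if structure == "two_compartment_iv_infusion":
        cl, v1, v2, q = values["CL"], values["V1"], values["V2"], values["Q"]
        k10 = cl / v1
        k12 = q / v1
        k21 = q / v2
        s = k10 + k12 + k21
        # alpha*beta = k10*k21; discriminant is >= (k10-k21)^2 >= 0
        disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = (s + disc) / 2.0
        beta = (s - disc) / 2.0
        a = (alpha - k21) / (v1 * (alpha - beta))
        b = (k21 - beta) / (v1 * (alpha - beta))
        return np.array([alpha, beta]), np.array([a, b])
    raise ValueError(f"unknown structure {structure!r}")


def predict_concentration(
    params: IndividualParameters,
    model: StructuralModel,
    regimen: Regimen,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form concentration (mg/L) at ``times`` (h from regimen origin).

    Single-infusion solution per exponential term (rate R0, duration T):
    during the infusion ``c(t) = (c_j R0 / lam_j)(1 - exp(-lam_j t))`` and
    afterwards the end-of-infusion value decays as ``exp(-lam_j (t - T))``.
    Multi-dose histories are superposed; linearity makes this exact.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("prediction times must be >= 0 (hours from regimen origin)")
    lambdas, coeffs = disposition_terms(params.values, model.structure)
    conc = np.zeros_like(times, dtype=float)
    for event in regimen.events:
        tau = times - event.start_time_h
        active = tau > 0
        if not np.any(active):
            continue
        t = tau[active]
        r0 = event.rate_mg_h
        dur = event.infusion_duration_h
        contrib = np.zeros_like(t)
        for lam, c in zip(lambdas, coeffs):
            scale = c * r0 / lam
            during = scale * -np.expm1(-lam * np.minimum(t, dur))
            decay = np.exp(-lam * np.maximum(t - dur, 0.0))
            contrib += during * decay
        conc[active] += contrib
    return np.maximum(conc, 0.0)
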