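"""Shared fixtures: reference patients, small structural models, and an
independent ODE-integration oracle for the closed-form kinetics."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mipdsim import (
    CovariateEffect,
    PatientCovariates,
    Regimen,
    ResidualErrorSpec,
    StructuralModel,
)


@pytest.fixture
def ref_covariates() -> PatientCovariates:
    """Covariates equal to the default models' reference values."""
    return PatientCovariates(
        age_months=38.6, weight_kg=70.0, scr_mg_dl=0.5, sex="female", height_cm=120.0
    )


@pytest.fixture
def child_covariates() -> PatientCovariates:
    return PatientCovariates(
        age_months=36.0, weight_kg=14.0, scr_mg_dl=0.3, sex="male", height_cm=95.0
    )


def make_one_compartment(
    cl: float = 5.0,
    v: float = 20.0,
    iiv: tuple[str, ...] = (),
    omega=None,
    sigma_add: float = 1.0,
    sigma_prop: float = 0.0,
) -> StructuralModel:
    k = len(iiv)
    return StructuralModel(
        structure="one_compartment_iv_infusion",
        drug="vancomycin",
        typical_values={"CL": cl, "V": v},
        covariate_effects=(),
        iiv_parameters=iiv,
        omega=np.eye(k) * 0.09 if omega is None else omega,
        residual_error=ResidualErrorSpec(sigma_add=sigma_add, sigma_prop=sigma_prop),
    )


def make_two_compartment(
    cl: float = 5.0, v1: float = 15.0, v2: float = 25.0, q: float = 2.0
) -> StructuralModel:
    return StructuralModel(
        structure="two_compartment_iv_infusion",
        drug="amikacin",
        typical_values={"CL": cl, "V1": v1, "V2": v2, "Q": q},
        covariate_effects=(),
        iiv_parameters=("CL",),
        omega=np.array([[0.09]]),
        residual_error=ResidualErrorSpec(sigma_add=0.5, sigma_prop=0.1),
    )


@pytest.fixture
def simple_model() -> StructuralModel:
    """One-compartment, CL 5 L/h, V 20 L, additive-only error, no IIV."""
    return make_one_compartment()


def ode_concentrations(
    values: dict[str, float], structure: str, regimen: Regimen, times: np.ndarray
) -> np.ndarray:
    """Numerically integrate the compartment ODEs piecewise between
    infusion start/stop discontinuities at tight tolerance.

    Entirely independent of the closed-form superposition path: amounts
    are propagated through scipy's LSODA on the micro-constant ODE system.
    """
    times = np.asarray(times, dtype=float)
    if structure == "one_compartment_iv_infusion":
        cl, v = values["CL"], values["V"]

        def rhs(t, y, rate):
            return [rate - (cl / v) * y[0]]

        n_state, volume = 1, v
    else:
        cl, v1, v2, q = values["CL"], values["V1"], values["V2"], values["Q"]
        k10, k12, k21 = cl / v1, q / v1, q / v2

        def rhs(t, y, rate):
            a1, a2 = y
            return [rate - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

        n_state, volume = 2, v1

    breaks = sorted(
        {0.0, float(np.max(times)) + 1e-9}
        | {e.start_time_h for e in regimen.events}
        | {e.end_time_h for e in regimen.events}
    )
    result = np.zeros_like(times)
    y = np.zeros(n_state)
    for t0, t1 in zip(breaks, breaks[1:]):
        rate = sum(
            e.rate_mg_h
            for e in regimen.events
            if e.start_time_h <= t0 + 1e-12 < e.end_time_h
        )
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            args=(rate,),
            method="LSODA",
            rtol=1e-11,
            atol=1e-13,
            dense_output=True,
        )
        inside = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
        if np.any(inside):
            result[inside] = sol.sol(times[inside])[0] / volume
        y = sol.y[:, -1]
    return result
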