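"""Default model, target and grid configurations.

The numeric population values below are SYNTHETIC defaults for testing and
simulation.  They reproduce the published skeleton of the two pediatric
reference models — a one-compartment vancomycin model with IIV on CL and V
and weight/age/SCr covariates, and a two-compartment amikacin model with
IIV on CL and weight as the sole covariate — but the magnitudes are
plausible round numbers, not the estimates of any fitted model, and must
not be used to dose patients.  Everything here can be overridden from a
YAML/JSON config (see :mod:`mipdsim.io`).
"""

from __future__ import annotations

import numpy as np

from .exposure import DoseConstraints, TargetSpec
from .models import CovariateEffect, ResidualErrorSpec, StructuralModel

__all__ = [
    "default_vancomycin_model",
    "default_amikacin_model",
    "default_models",
    "default_target",
    "default_constraints",
    "model_from_dict",
    "model_to_dict",
]

#: reference covariates the typical values are anchored to: a 70 kg subject
#: with SCr 0.5 mg/dL (a typical pediatric baseline) at the cohort median age.
REF_WEIGHT_KG = 70.0
REF_SCR_MG_DL = 0.5
REF_AGE_MONTHS = 38.6


def default_vancomycin_model() -> StructuralModel:
    """One-compartment vancomycin model (synthetic defaults).

    Allometric weight scaling (0.75 on CL, 1.0 on V), clearance falling
    with serum creatinine via an inverse power term, and a mild power-law
    age maturation on CL.  IIV on CL and V; combined residual error.
    """
    return StructuralModel(
        name="vancomycin-1cmt-synthetic-default",
        structure="one_compartment_iv_infusion",
        drug="vancomycin",
        typical_values={"CL": 5.0, "V": 49.0},
        covariate_effects=(
            CovariateEffect("CL", "weight", "allometric_power", REF_WEIGHT_KG, 0.75),
            CovariateEffect("V", "weight", "allometric_power", REF_WEIGHT_KG, 1.0),
            CovariateEffect("CL", "scr", "inverse", REF_SCR_MG_DL, 0.4),
            CovariateEffect("CL", "age", "power", REF_AGE_MONTHS, 0.12),
        ),
        iiv_parameters=("CL", "V"),
        omega=np.diag([0.16, 0.09]),  # 40% / 30% CV on the log scale
        residual_error=ResidualErrorSpec(sigma_add=1.0, sigma_prop=0.15),
    )


def default_amikacin_model() -> StructuralModel:
    """Two-compartment amikacin model (synthetic defaults).

    Weight is the only covariate (allometric on clearances, linear on
    volumes); IIV on CL only; combined residual error.  The peripheral
    compartment is sized so a typical patient on 15 mg/kg q24h shows
    peaks near 50 mg/L and model-predicted troughs around 0.7 mg/L —
    the concentration scales this kind of pediatric TDM data exhibits.
    """
    return StructuralModel(
        name="amikacin-2cmt-synthetic-default",
        structure="two_compartment_iv_infusion",
        drug="amikacin",
        typical_values={"CL": 5.5, "V1": 16.0, "V2": 30.0, "Q": 2.0},
        covariate_effects=(
            CovariateEffect("CL", "weight", "allometric_power", REF_WEIGHT_KG, 0.75),
            CovariateEffect("Q", "weight", "allometric_power", REF_WEIGHT_KG, 0.75),
            CovariateEffect("V1", "weight", "allometric_power", REF_WEIGHT_KG, 1.0),
            CovariateEffect("V2", "weight", "allometric_power", REF_WEIGHT_KG, 1.0),
        ),
        iiv_parameters=("CL",),
        omega=np.array([[0.09]]),
        residual_error=ResidualErrorSpec(sigma_add=0.5, sigma_prop=0.15),
    )


def default_models() -> dict[str, StructuralModel]:
    return {
        "vancomycin": default_vancomycin_model(),
        "amikacin": default_amikacin_model(),
    }


def default_target(drug: str) -> TargetSpec:
    """Exposure targets: vancomycin AUC24/MIC >= 400 with an advisory
    10-15 mg/L trough band; amikacin Cmax/MIC >= 8 with trough < 5 mg/L.
    MIC defaults to 1 mg/L as a standardization convention, not a clinical
    breakpoint.
    """
    if drug == "vancomycin":
        return TargetSpec(
            drug="vancomycin",
            auc_over_mic_min=400.0,
            trough_band_mg_L=(10.0, 15.0),
            trough_band_hard=False,
            mic_mg_L=1.0,
        )
    if drug == "amikacin":
        return TargetSpec(
            drug="amikacin",
            cmax_over_mic_min=8.0,
            trough_max_mg_L=5.0,
            mic_mg_L=1.0,
        )
    raise ValueError(f"unknown drug {drug!r}")


def default_constraints(drug: str) -> DoseConstraints:
    """Candidate grids and safety caps (non-clinical placeholders)."""
    if drug == "vancomycin":
        return DoseConstraints(
            intervals_h=(4.0, 6.0, 8.0, 12.0, 24.0),
            max_mg_per_kg_day=80.0,
            max_mg_day=4000.0,
            infusion_duration_h=1.0,
        )
    if drug == "amikacin":
        return DoseConstraints(
            intervals_h=(24.0, 36.0, 48.0),
            max_mg_per_kg_day=30.0,
            max_mg_day=float("inf"),
            infusion_duration_h=1.0,
        )
    raise ValueError(f"unknown drug {drug!r}")


def model_to_dict(model: StructuralModel) -> dict:
    """Serialize a StructuralModel to a plain dict (YAML/JSON friendly)."""
    return {
        "name": model.name,
        "structure": model.structure,
        "drug": model.drug,
        "typical_values": dict(model.typical_values),
        "covariate_effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "form": e.form,
                "reference_value": e.reference_value,
                "exponent_or_slope": e.exponent_or_slope,
            }
            for e in model.covariate_effects
        ],
        "iiv_parameters": list(model.iiv_parameters),
        "omega": np.asarray(model.omega).tolist(),
        "residual_error": {
            "sigma_add": model.residual_error.sigma_add,
            "sigma_prop": model.residual_error.sigma_prop,
        },
    }


def model_from_dict(data: dict) -> StructuralModel:
    """Inverse of :func:`model_to_dict`; validates on construction."""
    return StructuralModel(
        name=data.get("name", ""),
        structure=data["structure"],
        drug=data["drug"],
        typical_values=dict(data["typical_values"]),
        covariate_effects=tuple(
            CovariateEffect(
                parameter=e["parameter"],
                covariate=e["covariate"],
                form=e["form"],
                reference_value=float(e["reference_value"]),
                exponent_or_slope=float(e["exponent_or_slope"]),
            )
            for e in data.get("covariate_effects", ())
        ),
        iiv_parameters=tuple(data.get("iiv_parameters", ())),
        omega=np.asarray(data["omega"], dtype=float),
        residual_error=ResidualErrorSpec(**data["residual_error"]),
    )
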