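"""Prediction-error metrics, model-fit classification and paired summaries.

The predictive-performance layer works on paired within-patient
comparisons: for each observed concentration, the population (a priori)
prediction and the Bayesian-updated (a posteriori) prediction at the SAME
timepoint.  Errors are summarized with the mean absolute error (MAE), the
median absolute error (MdAE, robust to outliers and therefore the primary
summary), and the signed median error (MdE, a bias indicator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionPair",
    "ErrorSummary",
    "FitCategory",
    "error_metrics",
    "classify_fit",
    "paired_evaluation",
    "bootstrap_ci",
]

GROUPS = ("MIPD", "SoC")


@dataclass(frozen=True)
class PredictionPair:
    """Observed concentration with its a priori and a posteriori
    predictions at the same timepoint (1 = first TDM sample, 2 = second)."""

    patient_id: str
    timepoint_index: int
    observed: float
    predicted_a_priori: float
    predicted_a_posteriori: float
    group: str
    drug: str

    def __post_init__(self) -> None:
        if self.timepoint_index not in (1, 2):
            raise ValueError("timepoint_index must be 1 or 2")
        if not np.isfinite(self.observed):
            raise ValueError("observed concentration must be finite")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class ErrorSummary:
    n: int
    mae: float
    mdae: float
    mde: float


@dataclass(frozen=True)
class FitCategory:
    label: str
    relative_error: float


def error_metrics(pairs: list[tuple[float, float]]) -> ErrorSummary:
    """MAE / MdAE / MdE over (predicted, observed) pairs.

    MAE = mean |p - o|;  MdAE = median |p - o|;  MdE = median (p - o).
    The median of an even count is the midpoint of the two central order
    statistics.
    """
    if not pairs:
        raise ValueError("error_metrics requires at least one pair")
    err = np.array([p - o for p, o in pairs], dtype=float)
    return ErrorSummary(
        n=len(err),
        mae=float(np.mean(np.abs(err))),
        mdae=float(np.median(np.abs(err))),
        mde=float(np.median(err)),
    )


def classify_fit(
    observed: float,
    predicted: float,
    thresholds: tuple[float, float] = (0.20, 0.50),
) -> FitCategory:
    """Classify agreement between an observed and fitted concentration.

    The relative error |predicted - observed| / observed maps to ``good``
    (<= t1), ``intermediate`` (<= t2) or ``poor``.  The default 20% / 50%
    cutoffs are this package's configuration, not a published standard.
    An observed value of zero falls back to the absolute difference
    against the same thresholds in mg/L.
    """
    if observed < 0 or predicted < 0:
        raise ValueError("concentrations must be >= 0")
    t1, t2 = thresholds
    if not 0 < t1 < t2:
        raise ValueError("thresholds must satisfy 0 < t1 < t2")
    if observed > 0:
        rel = abs(predicted - observed) / observed
    else:
        rel = abs(predicted - observed)
    if rel <= t1:
        label = "good"
    elif rel <= t2:
        label = "intermediate"
    else:
        label = "poor"
    return FitCategory(label=label, relative_error=float(rel))


_STRATA = ("total", "group", "drug")


def paired_evaluation(
    pairs: list[PredictionPair],
    strata: tuple[str, ...] = _STRATA,
) -> pd.DataFrame:
    """Error summaries per timepoint x prediction mode x stratum.

    Emits one row per (timepoint, a priori / a posteriori, stratum) with
    n, MAE, MdAE and MdE — the layout of a predictive-performance table.
    Strata may be ``total``, ``group`` (MIPD vs SoC) and ``drug``.
    """
    if not pairs:
        raise ValueError("paired_evaluation requires at least one pair")
    unknown = set(strata) - set(_STRATA)
    if unknown:
        raise ValueError(f"unknown strata {sorted(unknown)}")
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "timepoint": [p.timepoint_index for p in pairs],
            "observed": [p.observed for p in pairs],
            "a_priori": [p.predicted_a_priori for p in pairs],
            "a_posteriori": [p.predicted_a_posteriori for p in pairs],
            "group": [p.group for p in pairs],
            "drug": [p.drug for p in pairs],
        }
    )
    rows = []
    for timepoint, tp_df in df.groupby("timepoint"):
        for mode, col in (("a_priori", "a_priori"), ("a_posteriori", "a_posteriori")):
            for stratum_key in strata:
                if stratum_key == "total":
                    groups = [("all", tp_df)]
                else:
                    groups = list(tp_df.groupby(stratum_key))
                for label, sub in groups:
                    summary = error_metrics(list(zip(sub[col], sub["observed"])))
                    rows.append(
                        {
                            "timepoint": timepoint,
                            "prediction": mode,
                            "stratum": stratum_key,
                            "level": label,
                            "n": summary.n,
                            "mae": summary.mae,
                            "mdae": summary.mdae,
                            "mde": summary.mde,
                        }
                    )
    return pd.DataFrame(rows)


def bootstrap_ci(
    pairs: list[tuple[float, float]],
    metric: str = "mdae",
    n_resamples: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for one error metric
    (exploratory; never a pass/fail criterion)."""
    if metric not in ("mae", "mdae", "mde"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    err = np.array([p - o for p, o in pairs], dtype=float)
    idx = rng.integers(0, len(err), size=(n_resamples, len(err)))
    samples = err[idx]
    if metric == "mae":
        stats = np.mean(np.abs(samples), axis=1)
    elif metric == "mdae":
        stats = np.median(np.abs(samples), axis=1)
    else:
        stats = np.median(samples, axis=1)
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
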