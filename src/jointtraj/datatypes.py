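"""Shared containers for cohorts, fitted models, and predictions.

Cohorts travel through the package as two tidy :class:`pandas.DataFrame`
tables — a long visit table (one row per biomarker measurement) and a
patient table (one row per subject, with the observed event time, event
type, and baseline covariates).  The record dataclasses below document the
row schemas and offer converters for users who prefer typed records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Allowed values of the ``event_type`` column.
EVENT_TYPES = ("vte", "death", "censored")

#: Column schema of the long visit table.
VISIT_COLUMNS = ("patient_id", "time_days", "ddimer_ugml")

#: Mandatory columns of the patient table (covariates follow).
PATIENT_COLUMNS = ("patient_id", "event_time_days", "event_type")

DAYS_PER_MONTH = 30.0


@dataclass(frozen=True)
class VisitRecord:
    """One biomarker measurement: D-dimer (µg/mL) at a time since baseline."""

    patient_id: str
    time_days: float
    ddimer_ugml: float


@dataclass(frozen=True)
class PatientRecord:
    """One subject: observed time, event type, and baseline covariates."""

    patient_id: str
    event_time_days: float
    event_type: str
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(
                f"event_type must be one of {EVENT_TYPES}, got {self.event_type!r}"
            )


def visits_to_frame(records: Iterable[VisitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.patient_id, r.time_days, r.ddimer_ugml) for r in records],
        columns=list(VISIT_COLUMNS),
    )


def patients_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "event_time_days": r.event_time_days,
            "event_type": r.event_type,
        }
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_visits(df: pd.DataFrame) -> list[VisitRecord]:
    return [
        VisitRecord(str(t.patient_id), float(t.time_days), float(t.ddimer_ugml))
        for t in df.itertuples()
    ]


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    covnames = [c for c in df.columns if c not in PATIENT_COLUMNS]
    return [
        PatientRecord(
            str(row["patient_id"]),
            float(row["event_time_days"]),
            str(row["event_type"]),
            {c: row[c] for c in covnames},
        )
        for _, row in df.iterrows()
    ]


@dataclass
class AnalysisDataset:
    """Model-ready dataset produced by :func:`jointtraj.preprocessing.build_dataset`.

    ``visits`` carries a ``time`` column in ``time_unit`` units and a
    ``log2_ddimer`` column; ``patients`` carries ``event_time`` in the same
    unit.  ``exclusions`` lists (patient_id, reason) pairs removed during
    preprocessing.
    """

    visits: pd.DataFrame
    patients: pd.DataFrame
    time_unit: str = "days"
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def values_on_scale(self, scale: str) -> np.ndarray:
        """Return the biomarker column on a modeling scale.

        ``original_ugml`` returns raw µg/mL, ``log2`` the per-doubling scale,
        ``natural_log`` the natural-log scale.
        """
        if scale == "original_ugml":
            return self.visits["ddimer_ugml"].to_numpy(float)
        if scale == "log2":
            return self.visits["log2_ddimer"].to_numpy(float)
        if scale == "natural_log":
            return self.visits["log2_ddimer"].to_numpy(float) * np.log(2.0)
        raise ValueError(f"unknown scale {scale!r}")


@dataclass
class LongitudinalFit:
    """ML fit of the random-intercept-and-slope linear mixed model."""

    fixed_effects: dict[str, tuple[float, float]]
    D_hat: np.ndarray
    sigma2_hat: float
    loglik: float
    aic: float
    scale: str
    time_unit: str
    n_subjects: int
    n_obs: int
    cov_fixed: pd.DataFrame | None = None
    group_by_event: bool = False
    groups: tuple[str, ...] = ()
    converged: bool = True

    @property
    def k_params(self) -> int:
        # fixed effects + 3 free entries of D + residual variance
        return len(self.fixed_effects) + 4


@dataclass
class IncidenceCurve:
    """Cumulative incidence (or 1-KM) curve with a pointwise 95% band."""

    times: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    method: str  # "one_minus_km" | "aalen_johansen"
    cause: str

    def at(self, t: float) -> float:
        """Step-function value of the curve at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.estimate[idx])

    def band_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (0.0, 0.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "estimate": self.estimate,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
            }
        )


@dataclass
class WeibullPHFit:
    """ML fit of the Weibull proportional-hazards model h(t)=lam*p*t^(p-1)*exp(x'b)."""

    shape: float
    scale: float
    shape_se: float
    scale_se: float
    coefficients: dict[str, tuple[float, float]]  # name -> (log-HR, SE)
    loglik: float
    aic: float
    n_subjects: int
    n_events: int
    time_unit: str = "days"
    converged: bool = True

    def hazard_ratios(self) -> dict[str, tuple[float, float, float]]:
        """HR with Wald 95% CI per covariate."""
        out = {}
        for name, (b, se) in self.coefficients.items():
            out[name] = (
                float(np.exp(b)),
                float(np.exp(b - 1.96 * se)),
                float(np.exp(b + 1.96 * se)),
            )
        return out


@dataclass
class DynamicPrediction:
    """Conditional VTE-risk curve beyond a landmark time for one subject."""

    patient_id: str
    landmark: float
    horizons: np.ndarray
    risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_mc_draws: int
    time_unit: str = "days"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "horizon": self.horizons,
                "risk": self.risk,
                "lo": self.ci_lower,
                "hi": self.ci_upper,
            }
        )
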