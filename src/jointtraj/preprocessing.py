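"""Build the analysis dataset from raw visit and patient tables.

Three rules are applied, in order: (1) any patient with a D-dimer
measurement above ``ddimer_cap`` (default 40 µg/mL — extreme values of this
magnitude destabilize the joint-model likelihood) is excluded entirely, and
logged; (2) measurements below ``lod_floor`` (default 0.1 µg/mL) are floored
before the log transform so the log2 column is always finite; (3) time is
optionally rescaled from days to 30-day months — the only place in the
package where the unit conversion happens.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    DAYS_PER_MONTH,
    EVENT_TYPES,
    AnalysisDataset,
)

__all__ = ["build_dataset", "read_visits_csv", "read_patients_csv"]


def read_visits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"patient_id", "time_days", "ddimer_ugml"} - set(df.columns)
    if missing:
        raise ValueError(f"visit table missing columns {sorted(missing)}")
    return df


def read_patients_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = {"patient_id", "event_time_days", "event_type"} - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing columns {sorted(missing)}")
    return df


def build_dataset(
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    ddimer_cap: float = 40.0,
    lod_floor: float = 0.1,
    time_unit: str = "days",
) -> AnalysisDataset:
    """Validate, filter, and transform raw tables into an AnalysisDataset.

    Parameters
    ----------
    visits, patients
        Long visit table (patient_id, time_days, ddimer_ugml) and patient
        table (patient_id, event_time_days, event_type, covariates...).
    ddimer_cap
        Patients with *any* measurement above this value (µg/mL) are removed
        (per patient, not per visit) and recorded in ``exclusions``.
    lod_floor
        Values below this limit are floored before the log2 transform.
    time_unit
        "days" keeps raw times; "months" rescales both visit times and
        event times by 1/30.

    Raises
    ------
    ValueError
        On empty tables, orphan visits, negative times or D-dimer values,
        or invalid event types.
    """
    if len(visits) == 0 or len(patients) == 0:
        raise ValueError("visit and patient tables must be non-empty")
    if time_unit not in ("days", "months"):
        raise ValueError("time_unit must be 'days' or 'months'")

    visits = visits.copy()
    patients = patients.copy()

    bad_types = set(patients["event_type"]) - set(EVENT_TYPES)
    if bad_types:
        raise ValueError(f"invalid event types {sorted(bad_types)}")
    if (patients["event_time_days"] < 0).any() or (visits["time_days"] < 0).any():
        raise ValueError("times must be non-negative")
    if (visits["ddimer_ugml"] < 0).any():
        bad = visits.loc[visits["ddimer_ugml"] < 0, "patient_id"].tolist()
        raise ValueError(f"negative D-dimer values for patients {bad}")
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids {dup}")

    known = set(patients["patient_id"])
    orphans = sorted(set(visits["patient_id"]) - known)
    if orphans:
        raise ValueError(f"orphan visits for unknown patients {orphans}")

    over_cap = visits.loc[visits["ddimer_ugml"] > ddimer_cap, "patient_id"]
    excluded_ids = sorted(set(over_cap))
    exclusions = [(pid, f"D-dimer > {ddimer_cap:g} ug/mL") for pid in excluded_ids]
    if excluded_ids:
        visits = visits[~visits["patient_id"].isin(excluded_ids)]
        patients = patients[~patients["patient_id"].isin(excluded_ids)]
        if len(patients) == 0:
            raise ValueError("all patients excluded by the D-dimer cap")

    floored = np.maximum(visits["ddimer_ugml"].to_numpy(float), lod_floor)
    visits["log2_ddimer"] = np.log2(floored)

    divisor = DAYS_PER_MONTH if time_unit == "months" else 1.0
    visits["time"] = visits["time_days"].to_numpy(float) / divisor
    patients["event_time"] = patients["event_time_days"].to_numpy(float) / divisor

    visits = visits.sort_values(["patient_id", "time"], kind="stable").reset_index(
        drop=True
    )
    patients = patients.reset_index(drop=True)

    return AnalysisDataset(
        visits=visits,
        patients=patients,
        time_unit=time_unit,
        exclusions=exclusions,
    )
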