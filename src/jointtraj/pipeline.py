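"""End-to-end reproducible pipeline.

``run_pipeline`` chains the stages — simulate (or ingest) -> preprocess ->
mixed model (per-group slope table) -> incidence curves -> joint model
(association table per scale) -> dynamic predictions — writing tidy CSVs
and JSON fit records.  Every output file carries a header comment with the
config hash and root seed; all randomness descends from the root seed via
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._numutils import spawn_seeds
from .datatypes import DAYS_PER_MONTH
from .jointmodel import JointModelSpec, fit_joint_model
from .longitudinal import fit_lmm, group_slope, percent_change_per_month, slope_contrast
from .preprocessing import build_dataset, read_patients_csv, read_visits_csv
from .simulate import CohortParams, paper_like_params, simulate_cohort, write_cohort
from .survival import aalen_johansen, kaplan_meier

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("jointtraj")

ALL_STAGES = ("simulate", "preprocess", "lmm", "incidence", "joint_model", "predict")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: str = "jointtraj_run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # input: either CSV paths or simulation parameters
    visits_csv: str | None = None
    patients_csv: str | None = None
    sim_params: dict = field(default_factory=dict)
    # preprocessing
    ddimer_cap: float = 40.0
    lod_floor: float = 0.1
    time_unit: str = "months"
    # models
    lmm_scale: str = "original_ugml"
    jm_scales: tuple[str, ...] = ("log2", "original_ugml")
    jm_quadrature_nodes: int = 9
    # prediction
    predict_patients: tuple[str, ...] = ()
    landmark: float | None = None
    horizon_months: float = 6.0
    n_mc_draws: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {ALL_STAGES}")
        if (self.visits_csv is None) != (self.patients_csv is None):
            raise ValueError("provide both visits_csv and patients_csv, or neither")
        if self.time_unit not in ("days", "months"):
            raise ValueError("time_unit must be 'days' or 'months'")

    def canonical_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @property
    def config_hash(self) -> str:
        # identifies the analysis, not the destination directory
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return hashlib.sha256(yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("stages", "jm_scales", "predict_patients"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.config_hash, "seed": cfg.seed, "result": obj}
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of in-memory results.

    Any stage failure aborts with the stage name in the exception while
    upstream outputs remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.canonical_yaml())
    seeds = spawn_seeds(config.seed, 8)
    results: dict = {}
    stage = "setup"
    try:
        # --- simulate / ingest ---
        stage = "simulate"
        if config.visits_csv is not None:
            visits = read_visits_csv(config.visits_csv)
            patients = read_patients_csv(config.patients_csv)
        else:
            params = paper_like_params(seed=seeds[0])
            if config.sim_params:
                params = CohortParams(**{**params.__dict__, **config.sim_params,
                                         "seed": seeds[0]})
            patients, visits = simulate_cohort(params)
            if "simulate" in config.stages:
                write_cohort(out / "cohort", patients, visits, params)
        results["patients_raw"], results["visits_raw"] = patients, visits

        # --- preprocess ---
        stage = "preprocess"
        data = build_dataset(
            visits, patients,
            ddimer_cap=config.ddimer_cap, lod_floor=config.lod_floor,
            time_unit=config.time_unit,
        )
        results["dataset"] = data
        if data.exclusions:
            _write_csv(pd.DataFrame(data.exclusions, columns=["patient_id", "reason"]),
                       out / "exclusions.csv", config)

        # --- per-group trajectory slopes ---
        if "lmm" in config.stages:
            stage = "lmm"
            fit_orig = fit_lmm(data, scale="original_ugml", group_by_event=True,
                               time_unit="months")
            fit_log = fit_lmm(data, scale="natural_log", group_by_event=True,
                              time_unit="months")
            pct = percent_change_per_month(fit_log)
            diff, diff_ci, diff_p = slope_contrast(fit_orig)
            rows = []
            for grp in ("no_vte", "vte"):
                s, se = group_slope(fit_orig, grp)
                rows.append((grp, "ugml_per_month", s, s - 1.96 * se, s + 1.96 * se))
                pc, (lo, hi) = pct[grp]
                rows.append((grp, "pct_per_month", pc, lo, hi))
            rows.append(("difference", "ugml_per_month", diff, diff_ci[0], diff_ci[1]))
            slopes = pd.DataFrame(rows, columns=["group", "quantity", "estimate", "lo", "hi"])
            _write_csv(slopes, out / "trajectory_slopes.csv", config)
            results["slopes"] = slopes
            results["lmm_fits"] = {"original_ugml": fit_orig, "natural_log": fit_log}

        # --- incidence curves ---
        if "incidence" in config.stages:
            stage = "incidence"
            km = kaplan_meier(data)
            cif_vte, cif_death = aalen_johansen(data)
            _write_csv(km.to_frame(), out / "one_minus_km.csv", config)
            _write_csv(cif_vte.to_frame(), out / "cif_vte.csv", config)
            _write_csv(cif_death.to_frame(), out / "cif_death.csv", config)
            results["km"], results["cif_vte"], results["cif_death"] = km, cif_vte, cif_death

        # --- joint models ---
        if "joint_model" in config.stages:
            stage = "joint_model"
            jm_fits = {}
            assoc_rows = []
            for scale in config.jm_scales:
                spec = JointModelSpec(scale=scale,
                                      quadrature_nodes=config.jm_quadrature_nodes)
                fit = fit_joint_model(data, spec)
                jm_fits[scale] = fit
                hr, lo, hi = fit.hazard_ratio
                unit = "per doubling" if scale == "log2" else "per 1 ug/mL"
                assoc_rows.append((scale, unit, fit.params.alpha, fit.ses["alpha"],
                                   hr, lo, hi, fit.alpha_pvalue(), fit.aic,
                                   fit.converged))
                _write_json(
                    {
                        "scale": scale,
                        "alpha": fit.params.alpha,
                        "alpha_se": fit.ses["alpha"],
                        "hazard_ratio": hr,
                        "loglik": fit.loglik,
                        "aic": fit.aic,
                        "converged": fit.converged,
                        "coefficients": fit.coefficient_table().to_dict("records"),
                    },
                    out / f"joint_model_{scale}.json", config,
                )
            assoc = pd.DataFrame(
                assoc_rows,
                columns=["scale", "unit", "alpha", "alpha_se", "hr", "hr_lo", "hr_hi",
                         "p", "aic", "converged"],
            )
            _write_csv(assoc, out / "association_table.csv", config)
            results["joint_fits"], results["association"] = jm_fits, assoc

        # --- dynamic predictions ---
        if "predict" in config.stages and "joint_model" in config.stages:
            stage = "predict"
            from .prediction import predict_risk

            fit = results["joint_fits"][config.jm_scales[0]]
            horizon = config.horizon_months * (
                1.0 if config.time_unit == "months" else DAYS_PER_MONTH
            )
            pids = config.predict_patients or tuple(data.patients["patient_id"].head(2))
            pred_rows = []
            for k, pid in enumerate(pids):
                hist = data.visits[data.visits["patient_id"] == pid]
                if len(hist) == 0:
                    continue
                pat = data.patients.set_index("patient_id").loc[pid]
                s = config.landmark if config.landmark is not None else float(hist["time"].max())
                cols = set(fit.spec.longitudinal_covariates) | set(fit.spec.survival_covariates)
                cov = {c: pat[c] for c in cols}
                grid = np.linspace(s, s + horizon, 13)
                pred = predict_risk(
                    fit, hist[hist["time"] <= s], cov, landmark=s, horizons=grid,
                    n_mc_draws=config.n_mc_draws, seed=seeds[2 + k], force=True,
                    patient_id=pid,
                )
                dfp = pred.to_frame()
                dfp.insert(0, "patient_id", pid)
                pred_rows.append(dfp)
            if pred_rows:
                preds = pd.concat(pred_rows, ignore_index=True)
                _write_csv(preds, out / "dynamic_predictions.csv", config)
                results["predictions"] = preds

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run.log").write_text(
        f"config_hash={config.config_hash}\nseed={config.seed}\n"
        f"stages={','.join(config.stages)}\n"
    )
    return results
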