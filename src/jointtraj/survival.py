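"""Baseline time-to-event machinery.

Three estimators:

* :func:`kaplan_meier` — the product-limit estimator for one cause,
  treating competing events as right-censoring, returned as 1 - S(t)
  (the naive incidence, upwardly biased when competing deaths exist);
* :func:`aalen_johansen` — nonparametric cumulative incidence functions
  for both causes, CIF_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j with S the
  all-cause Kaplan-Meier;
* :func:`fit_weibull_ph` — maximum-likelihood Weibull proportional-hazards
  regression, h(t) = lam * p * t**(p-1) * exp(x'beta).

Tie policy everywhere: events precede censorings at equal times, and
same-time events of different causes are handled in a single risk-set
update.  Pointwise 95% bands use the log(-log) transform.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._numutils import fd_hessian
from .datatypes import AnalysisDataset, IncidenceCurve, WeibullPHFit

__all__ = ["kaplan_meier", "aalen_johansen", "fit_weibull_ph"]

_Z95 = 1.959963984540054


def _extract_survival_table(patients) -> tuple[pd.DataFrame, str]:
    """Accept a patient DataFrame or AnalysisDataset; return (table, time col)."""
    if isinstance(patients, AnalysisDataset):
        return patients.patients, "event_time"
    df = patients
    col = "event_time_days" if "event_time_days" in df.columns else "event_time"
    return df, col


def _risk_table(times, cause_codes):
    """Unique event times with risk-set sizes and per-cause event counts.

    cause_codes: 0 = censored, 1 = cause of interest, 2 = competing cause.
    Events precede censorings at tied times (censored subjects at t remain
    in the risk set for events at t).
    """
    utimes = np.unique(times[cause_codes > 0])
    times_sorted = np.sort(times)
    n = times.size
    # risk set at t: subjects with observed time >= t
    n_at_risk = n - np.searchsorted(times_sorted, utimes, side="left")

    def _counts(cause_times):
        cs = np.sort(cause_times)
        return (
            np.searchsorted(cs, utimes, side="right")
            - np.searchsorted(cs, utimes, side="left")
        ).astype(float)

    d1 = _counts(times[cause_codes == 1])
    d2 = _counts(times[cause_codes == 2])
    return utimes, n_at_risk.astype(float), d1, d2


def _loglog_band(est, se, is_incidence: bool):
    """95% band on the log(-log) scale for a probability-valued estimate."""
    lo = np.zeros_like(est)
    hi = np.zeros_like(est)
    inner = (est > 0) & (est < 1) & (se > 0)
    F = est[inner]
    theta_se = se[inner] / np.abs(F * np.log(F))
    lo[inner] = F ** np.exp(_Z95 * theta_se)
    hi[inner] = F ** np.exp(-_Z95 * theta_se)
    lo[~inner] = est[~inner]
    hi[~inner] = est[~inner]
    return lo, hi


def kaplan_meier(patients, cause: str = "vte") -> IncidenceCurve:
    """1 - Kaplan-Meier incidence for ``cause``, other causes censored.

    Pointwise 95% band: Greenwood variance mapped through the log(-log)
    transform of survival.
    """
    df, tcol = _extract_survival_table(patients)
    times = df[tcol].to_numpy(float)
    codes = np.where(df["event_type"].to_numpy() == cause, 1, 0)
    if codes.sum() == 0:
        warnings.warn(f"no {cause!r} events observed; returning a flat zero curve")
        t_end = times.max() if times.size else 0.0
        z = np.zeros(1)
        return IncidenceCurve(np.array([t_end]), z, z.copy(), z.copy(), "one_minus_km", cause)

    ut, n_risk, d, _ = _risk_table(times, codes)
    keep = d > 0
    ut, n_risk, d = ut[keep], n_risk[keep], d[keep]
    S = np.cumprod(1.0 - d / n_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(n_risk > d, d / (n_risk * (n_risk - d)), 0.0)
    greenwood = S**2 * np.cumsum(incr)
    est = 1.0 - S
    lo, hi = _loglog_band(est, np.sqrt(greenwood), is_incidence=True)
    return IncidenceCurve(ut, est, lo, hi, "one_minus_km", cause)


def aalen_johansen(patients) -> tuple[IncidenceCurve, IncidenceCurve]:
    """Aalen-Johansen cumulative incidence for VTE and competing death.

    Returns ``(cif_vte, cif_death)``.  Pointwise variance follows the
    Marubini-Valsecchi counting-process estimator, with the 95% band on the
    log(-log CIF) scale.
    """
    df, tcol = _extract_survival_table(patients)
    times = df[tcol].to_numpy(float)
    etypes = df["event_type"].to_numpy()
    codes = np.where(etypes == "vte", 1, np.where(etypes == "death", 2, 0))
    if (codes > 0).sum() == 0:
        warnings.warn("no events observed; returning flat zero curves")
        t_end = times.max() if times.size else 0.0
        z = np.zeros(1)
        mk = lambda c: IncidenceCurve(np.array([t_end]), z.copy(), z.copy(), z.copy(), "aalen_johansen", c)
        return mk("vte"), mk("death")

    ut, n_risk, d1, d2 = _risk_table(times, codes)
    d_all = d1 + d2
    S = np.cumprod(1.0 - d_all / n_risk)          # all-cause KM at t_j
    S_prev = np.concatenate([[1.0], S[:-1]])      # S(t_j-)

    curves = []
    for dk, cause in ((d1, "vte"), (d2, "death")):
        F = np.cumsum(S_prev * dk / n_risk)
        var = _aj_variance(F, S_prev, n_risk, dk, d_all)
        lo, hi = _loglog_band(F, np.sqrt(np.maximum(var, 0.0)), is_incidence=True)
        curves.append(IncidenceCurve(ut, F, lo, hi, "aalen_johansen", cause))
    return curves[0], curves[1]


def _aj_variance(F, S_prev, n_risk, dk, d_all):
    """Pointwise variance of the Aalen-Johansen CIF (Marubini-Valsecchi)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_risk - d_all > 0, d_all / (n_risk * (n_risk - d_all)), 0.0)
    c = S_prev**2 * (n_risk - dk) / n_risk * dk / n_risk**2
    g = S_prev * dk / n_risk**2
    # var_j = sum_{l<=j} (F_j - F_l)^2 a_l + sum c_l - 2 sum (F_j - F_l) g_l,
    # expanded into cumulative sums so the whole curve is O(J)
    A, B, C = np.cumsum(a), np.cumsum(F * a), np.cumsum(F**2 * a)
    G, Gf = np.cumsum(g), np.cumsum(F * g)
    Csum = np.cumsum(c)
    var = F**2 * A - 2.0 * F * B + C + Csum - 2.0 * (F * G - Gf)
    return var


# ---------------------------------------------------------------------------
# Weibull proportional hazards regression
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    None: lambda x: x,
    "identity": lambda x: x,
    "per5": lambda x: x / 5.0,
    "per10": lambda x: x / 10.0,
    "log2": np.log2,
    "ln": np.log,
}


def _design(df: pd.DataFrame, covariates: Sequence[str], transforms: Mapping[str, str]):
    cols = []
    names = []
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not in patient table")
        tr = transforms.get(name)
        if tr not in _TRANSFORMS:
            raise ValueError(f"unknown transform {tr!r} for {name!r}")
        x = _TRANSFORMS[tr](df[name].to_numpy(float))
        cols.append(x)
        names.append(name if tr in (None, "identity") else f"{name}:{tr}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def weibull_ph_loglik(theta, t, delta, X, fix_shape=None):
    """Log-likelihood of the Weibull PH model.

    ``theta`` = (log lam, log p, beta...) — or (log lam, beta...) when the
    shape is fixed.  Exposed so the optimum can be validated against direct
    evaluation.
    """
    theta = np.asarray(theta, float)
    if fix_shape is None:
        loglam, logp = theta[0], theta[1]
        beta = theta[2:]
        p = np.exp(logp)
    else:
        loglam = theta[0]
        beta = theta[1:]
        p = float(fix_shape)
        logp = np.log(p)
    lam = np.exp(loglam)
    xb = X @ beta if X.shape[1] else np.zeros_like(t)
    logt = np.log(t)
    loghaz = loglam + logp + (p - 1.0) * logt + xb
    cumhaz = lam * t**p * np.exp(xb)
    return float(np.sum(delta * loghaz) - np.sum(cumhaz))


def fit_weibull_ph(
    patients,
    covariates: Sequence[str] = (),
    transforms: Mapping[str, str] | None = None,
    cause: str = "vte",
    fix_shape: float | None = None,
) -> WeibullPHFit:
    """ML Weibull proportional-hazards regression for time to ``cause``.

    Competing events are treated as right-censoring.  ``transforms`` maps a
    covariate name to one of {per5, per10, log2, ln} (e.g. per-5-unit BMI or
    per-doubling D-dimer effects).  ``fix_shape=1`` gives exponential
    regression, whose no-covariate MLE is events / total follow-up time.

    Subjects with missing covariate values are dropped (with a warning).
    """
    transforms = dict(transforms or {})
    df, tcol = _extract_survival_table(patients)
    df = df.copy()
    if covariates:
        before = len(df)
        df = df.dropna(subset=list(covariates))
        if len(df) < before:
            warnings.warn(f"dropped {before - len(df)} subjects with missing covariates")
    t = np.maximum(df[tcol].to_numpy(float), 1e-10)
    delta = (df["event_type"].to_numpy() == cause).astype(float)
    if delta.sum() == 0:
        raise ValueError("no events of the requested cause; cannot fit")
    X, names = _design(df, covariates, transforms)
    # center covariates for optimization stability; intercept absorbed in lam
    xbar = X.mean(axis=0) if X.shape[1] else np.zeros(0)
    Xc = X - xbar

    # moment-style start: exponential rate, shape 1
    rate0 = delta.sum() / t.sum()
    if fix_shape is None:
        x0 = np.concatenate([[np.log(rate0), 0.0], np.zeros(X.shape[1])])
    else:
        x0 = np.concatenate([[np.log(rate0)], np.zeros(X.shape[1])])

    def nll(theta):
        val = weibull_ph_loglik(theta, t, delta, Xc, fix_shape=fix_shape)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    if np.any(np.abs(theta) > 50):
        raise RuntimeError(
            "Weibull PH fit diverged (possible separation / monotone likelihood); "
            f"parameters: {theta}"
        )

    H = fd_hessian(lambda th: -nll(th), theta)
    try:
        vcov = np.linalg.inv(-H)
        ses = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.full(theta.size, np.nan)

    if fix_shape is None:
        loglam_c, logp = theta[0], theta[1]
        beta = theta[2:]
        beta_se = ses[2:]
        p = float(np.exp(logp))
        p_se = p * ses[1]
    else:
        loglam_c = theta[0]
        beta = theta[1:]
        beta_se = ses[1:]
        p = float(fix_shape)
        p_se = 0.0
    # undo covariate centering: lam = lam_c * exp(-xbar'beta)
    lam = float(np.exp(loglam_c - xbar @ beta))
    lam_se = lam * ses[0]  # SE on the centered log-scale, delta method

    loglik = -res.fun
    k = theta.size
    return WeibullPHFit(
        shape=p,
        scale=lam,
        shape_se=float(p_se),
        scale_se=float(lam_se),
        coefficients={n: (float(b), float(s)) for n, b, s in zip(names, beta, beta_se)},
        loglik=float(loglik),
        aic=float(2 * k - 2 * loglik),
        n_subjects=len(df),
        n_events=int(delta.sum()),
        time_unit="days" if tcol == "event_time_days" else "dataset",
        converged=bool(res.success or np.linalg.norm(res.jac if hasattr(res, "jac") else 0) < 1e-3),
    )
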