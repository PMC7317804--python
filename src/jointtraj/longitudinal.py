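"""Random-intercept-and-slope linear mixed model for biomarker trajectories.

The model for subject i at visit time t_ij is

    y_ij = (beta0 + b0_i) + (beta1 + b1_i) * t_ij + x_i' gamma + eps_ij,

with (b0_i, b1_i) ~ N(0, D) (unstructured 2x2 covariance) and
eps_ij ~ N(0, sigma^2).  Fitting is by maximum likelihood — not REML — so
AIC comparisons across fixed-effect structures are valid.

With ``group_by_event=True`` the fixed effects gain an event-group main
effect and a group x time interaction, giving each prospective event group
its own mean slope.  This grouping conditions on the future (it is a
descriptive summary of trajectories, as in a table of per-group slopes);
the joint model, not this fit, is the inferential product.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .datatypes import DAYS_PER_MONTH, AnalysisDataset, LongitudinalFit

__all__ = ["fit_lmm", "slope_contrast", "percent_change_per_month", "lmm_loglik_oracle"]

_LOG_SCALES = ("log2", "natural_log")
VTE_GROUP = "vte"
NO_VTE_GROUP = "no_vte"


def _long_table(data, scale: str) -> tuple[pd.DataFrame, str, int]:
    """Normalize input to (long df with value/time/patient_id[/group], unit)."""
    if isinstance(data, AnalysisDataset):
        df = data.visits[["patient_id", "time"]].copy()
        df["value"] = data.values_on_scale(scale)
        ev = data.patients.set_index("patient_id")["event_type"]
        df["group"] = np.where(
            df["patient_id"].map(ev).to_numpy() == "vte", VTE_GROUP, NO_VTE_GROUP
        )
        return df, data.time_unit
    df = data.copy()
    if "value" not in df.columns:
        raise ValueError("plain-DataFrame input needs a 'value' column")
    if "time" in df.columns:
        unit = "dataset"
    elif "time_days" in df.columns:
        df["time"] = df["time_days"]
        unit = "days"
    else:
        raise ValueError("need a 'time' or 'time_days' column")
    if "group" not in df.columns and "event_type" in df.columns:
        df["group"] = np.where(df["event_type"] == "vte", VTE_GROUP, NO_VTE_GROUP)
    return df, unit


def fit_lmm(
    data,
    scale: str = "log2",
    group_by_event: bool = False,
    covariates: tuple[str, ...] = (),
    time_unit: str | None = None,
    poly_degree: int = 1,
) -> LongitudinalFit:
    """ML fit of the random-intercept-and-slope model.

    Parameters
    ----------
    data
        An :class:`AnalysisDataset`, or a long DataFrame with columns
        ``patient_id``, ``time`` (or ``time_days``) and ``value`` (already on
        the desired scale — the ``scale`` argument is then only recorded).
    scale
        Biomarker scale: ``original_ugml``, ``log2`` or ``natural_log``.
    group_by_event
        Add a prospective-event-group main effect and group x time
        interaction so each group gets its own slope.
    covariates
        Extra time-constant fixed effects (columns of the patient table,
        broadcast to visits).
    time_unit
        Override: rescale the time axis before fitting; ``"months"`` divides
        day-valued times by 30.
    poly_degree
        Add time**2 ... time**poly_degree fixed effects (used for the
        linear-vs-polynomial AIC sensitivity check); random effects stay
        intercept + linear slope.

    Returns a :class:`LongitudinalFit` (ML estimates, unstructured D, AIC).
    """
    df, unit = _long_table(data, scale)
    if isinstance(data, AnalysisDataset) and covariates:
        pat = data.patients.set_index("patient_id")
        for c in covariates:
            df[c] = df["patient_id"].map(pat[c]).astype(float)

    if time_unit == "months" and unit == "days":
        df = df.assign(time=df["time"] / DAYS_PER_MONTH)
        unit = "months"
    elif time_unit is not None and time_unit != unit:
        unit = time_unit

    if df["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if np.var(df["time"].to_numpy(float)) <= 0:
        raise ValueError("time variance must be > 0")

    names = ["intercept", "time"]
    cols = [np.ones(len(df)), df["time"].to_numpy(float)]
    for degree in range(2, poly_degree + 1):
        cols.append(df["time"].to_numpy(float) ** degree)
        names.append(f"time^{degree}")
    groups_present: tuple[str, ...] = ()
    if group_by_event:
        if "group" not in df.columns:
            raise ValueError("event grouping requested but no event info available")
        gv = (df["group"].to_numpy() == VTE_GROUP).astype(float)
        cols += [gv, gv * df["time"].to_numpy(float)]
        names += ["group_vte", "group_vte:time"]
        groups_present = (NO_VTE_GROUP, VTE_GROUP)
    for c in covariates:
        cols.append(df[c].to_numpy(float))
        names.append(c)

    X = np.column_stack(cols)
    exog_re = np.column_stack([np.ones(len(df)), df["time"].to_numpy(float)])
    model = sm.MixedLM(
        df["value"].to_numpy(float), X, groups=df["patient_id"].to_numpy(), exog_re=exog_re
    )
    res, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=2000)
            except Exception:
                continue
            if res is None or cand.llf > res.llf + 1e-8:
                res, converged = cand, bool(cand.converged)
            if converged:
                break
    if res is None:
        raise RuntimeError("mixed-model fit failed under all optimizers")
    if not converged:
        warnings.warn("mixed-model fit did not flag convergence; inspect results")

    # statsmodels reports cov_re already on the data scale
    D_hat = np.asarray(res.cov_re.values if hasattr(res.cov_re, "values") else res.cov_re, float)
    sigma2 = float(res.scale)
    eig = np.linalg.eigvalsh(D_hat)
    if np.min(eig) < 1e-10:
        warnings.warn("random-effect covariance is singular (boundary fit)")

    k = X.shape[1] + 4
    llf = float(res.llf)
    fe = {
        n: (float(b), float(s))
        for n, b, s in zip(names, res.fe_params, res.bse_fe)
    }
    cov_fixed = pd.DataFrame(
        np.asarray(res.cov_params())[: X.shape[1], : X.shape[1]], index=names, columns=names
    )
    return LongitudinalFit(
        fixed_effects=fe,
        D_hat=D_hat,
        sigma2_hat=sigma2,
        loglik=llf,
        aic=float(2 * k - 2 * llf),
        scale=scale,
        time_unit=unit,
        n_subjects=int(df["patient_id"].nunique()),
        n_obs=len(df),
        cov_fixed=cov_fixed,
        group_by_event=group_by_event,
        groups=groups_present,
        converged=converged,
    )


def _slope_terms(fit: LongitudinalFit, group: str) -> dict[str, float]:
    """Linear combination of fixed effects giving the group's slope."""
    if not fit.group_by_event:
        if group is not None and group not in (None, "all"):
            raise ValueError("fit has no event grouping; only group='all' available")
        return {"time": 1.0}
    if group == NO_VTE_GROUP:
        return {"time": 1.0}
    if group == VTE_GROUP:
        return {"time": 1.0, "group_vte:time": 1.0}
    raise ValueError(f"unknown group {group!r}; fit has {fit.groups}")


def _combo(fit: LongitudinalFit, terms: dict[str, float]) -> tuple[float, float]:
    est = sum(w * fit.fixed_effects[n][0] for n, w in terms.items())
    if fit.cov_fixed is None:
        raise ValueError("fit carries no fixed-effect covariance")
    names = list(terms)
    w = np.array([terms[n] for n in names])
    V = fit.cov_fixed.loc[names, names].to_numpy()
    return float(est), float(np.sqrt(w @ V @ w))


def group_slope(fit: LongitudinalFit, group: str = "all") -> tuple[float, float]:
    """(estimate, SE) of a group's mean slope, per unit of the fit's time axis."""
    return _combo(fit, _slope_terms(fit, group))


def slope_contrast(
    fit: LongitudinalFit, group_a: str = VTE_GROUP, group_b: str = NO_VTE_GROUP
) -> tuple[float, tuple[float, float], float]:
    """Wald contrast of two group slopes: (estimate, 95% CI, p-value)."""
    ta = _slope_terms(fit, group_a)
    tb = _slope_terms(fit, group_b)
    terms = dict(ta)
    for n, w in tb.items():
        terms[n] = terms.get(n, 0.0) - w
    terms = {n: w for n, w in terms.items() if w != 0.0}
    if not terms:
        return 0.0, (0.0, 0.0), 1.0
    est, se = _combo(fit, terms)
    z = est / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return est, (est - 1.96 * se, est + 1.96 * se), p


def _per_month_factor(fit: LongitudinalFit) -> float:
    if fit.time_unit == "months":
        return 1.0
    if fit.time_unit == "days":
        return DAYS_PER_MONTH
    raise ValueError(
        f"cannot convert time unit {fit.time_unit!r} to months; refit with "
        "time_unit='months' or 'days'"
    )


def percent_change_per_month(fit: LongitudinalFit) -> dict[str, tuple[float, tuple[float, float]]]:
    """Per-group relative biomarker change, %/30-day month.

    Requires a log-scale fit; the slope per month s maps to
    100*(exp(s)-1) on the natural-log scale and 100*(2**s - 1) on log2.
    CI endpoints are transformed the same way.
    """
    if fit.scale not in _LOG_SCALES:
        raise ValueError("percent change requires a log2 or natural_log scale fit")
    f = _per_month_factor(fit)
    base = np.log(2.0) if fit.scale == "log2" else 1.0
    groups = fit.groups if fit.group_by_event else ("all",)
    out = {}
    for g in groups:
        est, se = group_slope(fit, g)
        s, s_se = est * f * base, se * f * base
        pct = 100.0 * (np.exp(s) - 1.0)
        lo = 100.0 * (np.exp(s - 1.96 * s_se) - 1.0)
        hi = 100.0 * (np.exp(s + 1.96 * s_se) - 1.0)
        out[g] = (float(pct), (float(lo), float(hi)))
    return out


def lmm_loglik_oracle(df: pd.DataFrame, beta: np.ndarray, X_cols, D: np.ndarray, sigma2: float) -> float:
    """Brute-force marginal log-likelihood of the mixed model.

    Evaluates, subject by subject, the multivariate-normal density of the
    stacked observations with covariance Z D Z' + sigma^2 I.  Independent of
    the fitting code path; used to validate fitted log-likelihoods.
    """
    total = 0.0
    for _, g in df.groupby("patient_id", sort=False):
        t = g["time"].to_numpy(float)
        y = g["value"].to_numpy(float)
        X = np.column_stack([np.asarray(c(g), float) for c in X_cols])
        Z = np.column_stack([np.ones(t.size), t])
        V = Z @ D @ Z.T + sigma2 * np.eye(t.size)
        r = y - X @ beta
        total += stats.multivariate_normal.logpdf(r, mean=np.zeros(t.size), cov=V)
    return float(total)
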