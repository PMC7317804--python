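"""Joint-model likelihood and estimation: quadrature oracles, invariances,
null/parameter recovery, adjustment, and AIC comparison semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import jointtraj as jt
from jointtraj._numutils import spawn_seeds
from jointtraj.jointmodel import (
    JointModelParams,
    JointModelSpec,
    joint_loglikelihood,
)
from jointtraj.simulate import NO_DEATH_WEIBULL_SCALE

FAST_SPEC = JointModelSpec(scale="log2", quadrature_nodes=5)


def _small_cohort(seed, n=120, alpha=1.0225, **kw):
    kw.setdefault("weibull_scale", NO_DEATH_WEIBULL_SCALE)
    params = jt.paper_like_params(seed=seed).with_(
        n_subjects=n, alpha=alpha, death_hazard=0.0, **kw,
    )
    pats, vis = jt.simulate_cohort(params)
    return params, jt.build_dataset(vis, pats, time_unit="months")


def _params_from_standalone(data):
    lf = jt.fit_lmm(data, scale="log2")
    wf = jt.fit_weibull_ph(data)
    return (
        JointModelParams(
            beta=np.array([lf.fixed_effects["intercept"][0], lf.fixed_effects["time"][0]]),
            D=lf.D_hat, sigma2=lf.sigma2_hat, lam=wf.scale, shape=wf.shape,
            gamma_S=np.zeros(0), alpha=0.0,
        ),
        lf,
        wf,
    )


def _mc_subject_loglik(row_visits, T, delta, p, rng, n_draws=100_000):
    """Monte-Carlo marginal log-likelihood for one subject: plain sampling of
    b ~ N(0, D) and averaging the conditional density.  Fully independent of
    the quadrature code path (direct formulas, trapezoid-free)."""
    y = row_visits["y"].to_numpy()
    tv = row_visits["t"].to_numpy()
    grid = np.linspace(1e-9, T, 1500)
    chunks = []
    for _ in range(n_draws // 10_000):
        b = rng.multivariate_normal([0, 0], p.D, size=10_000)
        mu = p.beta[0] + p.beta[1] * tv[None, :] + b[:, :1] + b[:, 1:] * tv[None, :]
        ll_long = stats.norm.logpdf(y[None, :], mu, np.sqrt(p.sigma2)).sum(axis=1)
        # cumulative hazard by high-resolution trapezoid on [0, T]
        level = p.beta[0] + p.beta[1] * grid[None, :] + b[:, :1] + b[:, 1:] * grid[None, :]
        haz = p.lam * p.shape * grid[None, :] ** (p.shape - 1) * np.exp(p.alpha * level)
        ll_surv = -np.trapezoid(haz, grid, axis=1)
        if delta:
            m_T = p.beta[0] + p.beta[1] * T + b[:, 0] + b[:, 1] * T
            ll_surv += np.log(p.lam * p.shape * T ** (p.shape - 1)) + p.alpha * m_T
        chunks.append(ll_long + ll_surv)
    w = np.concatenate(chunks)
    wmax = w.max()
    mean_lik = np.exp(w - wmax).mean()
    se_rel = np.exp(w - wmax).std(ddof=1) / (mean_lik * np.sqrt(n_draws))
    return wmax + np.log(mean_lik), se_rel


def test_separability_identity_when_association_is_zero():
    """With alpha=0 and no shared covariates the joint log-likelihood is the
    sum of the standalone mixed-model and Weibull log-likelihoods."""
    _, data = _small_cohort(21, n=150)
    p, lf, wf = _params_from_standalone(data)
    jll = joint_loglikelihood(p, data, JointModelSpec(scale="log2"))
    assert abs(jll - (lf.loglik + wf.loglik)) < 1e-6


def test_quadrature_matches_monte_carlo_oracle_on_toy_data():
    _, data = _small_cohort(22, n=5, alpha=0.9)
    p = JointModelParams(
        beta=np.array([0.0, 0.05]), D=np.array([[1.2, 0.02], [0.02, 0.05]]),
        sigma2=0.2, lam=0.006, shape=1.1, gamma_S=np.zeros(0), alpha=0.9,
    )
    spec = JointModelSpec(scale="log2")
    jll = joint_loglikelihood(p, data, spec)

    rng = np.random.default_rng(2024)
    total, total_var = 0.0, 0.0
    vis = data.visits
    for _, pat in data.patients.iterrows():
        sub = vis[vis["patient_id"] == pat["patient_id"]]
        row = pd.DataFrame({"y": sub["log2_ddimer"].to_numpy(), "t": sub["time"].to_numpy()})
        ll, se_rel = _mc_subject_loglik(
            row, float(pat["event_time"]), pat["event_type"] == "vte", p, rng
        )
        total += ll
        total_var += se_rel**2
    assert abs(jll - total) < 3 * np.sqrt(total_var)


def test_quadrature_refinement_is_converged():
    _, data = _small_cohort(23, n=40)
    p, _, _ = _params_from_standalone(data)
    p.alpha = 0.8
    ll9 = joint_loglikelihood(p, data, JointModelSpec(scale="log2", quadrature_nodes=9))
    ll15 = joint_loglikelihood(p, data, JointModelSpec(scale="log2", quadrature_nodes=15))
    assert abs(ll9 - ll15) < 1e-4


def test_time_unit_invariance():
    """Refitting with time in days instead of months rescales slope, slope
    variance and the Weibull scale consistently and leaves alpha unchanged."""
    params = jt.paper_like_params(seed=24).with_(n_subjects=150)
    pats, vis = jt.simulate_cohort(params)
    dm = jt.build_dataset(vis, pats, time_unit="months")
    dd = jt.build_dataset(vis, pats, time_unit="days")
    fm = jt.fit_joint_model(dm, JointModelSpec(scale="log2"))
    fd = jt.fit_joint_model(dd, JointModelSpec(scale="log2"))
    assert abs(fm.params.alpha - fd.params.alpha) < 1e-4
    assert fm.params.beta[1] == pytest.approx(fd.params.beta[1] * 30.0, rel=1e-4)
    # loglik identity: the event-time density Jacobian is 30 per event
    assert fm.loglik == pytest.approx(
        fd.loglik + fd.n_events * np.log(30.0), abs=1e-3
    )


def test_log_base_link_between_scales():
    """alpha on the log2 scale equals ln(2) times alpha on the natural-log
    scale (per-doubling vs per-e-fold parameterization)."""
    _, data = _small_cohort(25, n=150)
    f2 = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
    fe = jt.fit_joint_model(data, JointModelSpec(scale="natural_log"))
    assert abs(f2.params.alpha - fe.params.alpha * np.log(2.0)) < 1e-4


def test_null_association_recovery():
    """Cohorts simulated with alpha=0: the Wald interval alpha-hat +/- 2 SE
    should cover 0 in at least 90% of 50 replicates."""
    hits = 0
    for seed in spawn_seeds(31, 50):
        _, data = _small_cohort(seed, n=100, alpha=0.0, weibull_scale=5.6e-4)
        fit = jt.fit_joint_model(data, FAST_SPEC)
        a, se = fit.alpha
        hits += abs(a) <= 2 * se
    assert hits >= 45


def test_parameter_recovery_wald_coverage_pooled():
    """Pooled 95% Wald coverage of the main generating parameters across
    replicate fits stays near nominal."""
    truths = {"beta0": np.log2(0.97), "beta1": 0.0, "alpha": 1.0225}
    covered, total = 0, 0
    for seed in spawn_seeds(32, 12):
        _, data = _small_cohort(seed, n=250)
        fit = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
        ests = {
            "beta0": (fit.params.beta[0], fit.ses["beta:intercept"]),
            "beta1": (fit.params.beta[1], fit.ses["beta:time"]),
            "alpha": (fit.params.alpha, fit.ses["alpha"]),
        }
        for k, (e, s) in ests.items():
            covered += abs(e - truths[k]) <= 1.96 * s
            total += 1
    assert covered / total >= 0.80


class TestAdjustedFit:
    def test_null_covariate_leaves_alpha_unchanged(self):
        _, data = _small_cohort(33, n=150)
        base = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
        adj = jt.adjusted_fit(data, covariates=("age",),
                              spec=JointModelSpec(scale="log2"))
        a0, se0 = base.alpha
        a1, _ = adj.alpha
        assert abs(a1 - a0) <= 2 * se0

    def test_confounder_adjustment_reduces_bias(self):
        """A binary covariate pushing both the trajectory level and the hazard
        biases the crude alpha upward; adjusting for it shrinks the bias on
        average across replicates."""
        crude_err, adj_err = [], []
        gamma = {"metastatic": 0.8}
        for seed in spawn_seeds(34, 50):
            params = jt.paper_like_params(seed=seed).with_(
                n_subjects=80, alpha=0.7, death_hazard=0.0,
                weibull_scale=2.5e-4, gamma_L=gamma, gamma_S=gamma,
            )
            pats, vis = jt.simulate_cohort(params)
            data = jt.build_dataset(vis, pats, time_unit="months")
            crude = jt.fit_joint_model(data, FAST_SPEC)
            adj = jt.fit_joint_model(
                data,
                JointModelSpec(scale="log2", quadrature_nodes=5,
                               longitudinal_covariates=("metastatic",),
                               survival_covariates=("metastatic",)),
            )
            crude_err.append(crude.params.alpha - 0.7)
            adj_err.append(adj.params.alpha - 0.7)
        assert abs(np.mean(adj_err)) <= abs(np.mean(crude_err)) + 1e-9

    def test_association_interaction_returns_per_stratum_alpha(self):
        _, data = _small_cohort(35, n=150)
        fit = jt.adjusted_fit(
            data, covariates=(), spec=FAST_SPEC, association_interaction="metastatic"
        )
        assert "alpha_inter" in fit.ses
        table = fit.coefficient_table()
        assert (table["term"] == "alpha x metastatic").any()
        # per-stratum alpha = alpha + alpha_inter * stratum
        a_non = fit.params.alpha
        a_met = fit.params.alpha + fit.params.alpha_inter
        assert np.isfinite(a_non) and np.isfinite(a_met)


def test_first_derivative_association_near_zero_when_absent():
    """Data generated with a pure current-value link: the extra slope
    association term should be statistically indistinguishable from zero."""
    _, data = _small_cohort(36, n=150)
    spec = JointModelSpec(scale="log2", quadrature_nodes=5,
                          association=("current_value", "first_derivative"))
    fit = jt.fit_joint_model(data, spec)
    a_d, se_d = fit.params.alpha_deriv, fit.ses["alpha_deriv"]
    assert abs(a_d) <= 3 * se_d


class TestCompareFits:
    def test_single_fit_zero_delta(self, joint_fit_medium):
        _, _, fit = joint_fit_medium
        table = jt.compare_fits([fit])
        assert table["delta_aic"].iloc[0] == 0.0

    def test_mixed_scales_refused(self, joint_fit_medium):
        _, data, fit = joint_fit_medium
        f_orig = jt.fit_lmm(data, scale="original_ugml")
        f_log = jt.fit_lmm(data, scale="log2")
        with pytest.raises(ValueError, match="scales"):
            jt.compare_fits([f_orig, f_log])

    def test_nested_aic_agrees_with_likelihood_ratio(self):
        """For nested fits differing by one parameter, AIC prefers the larger
        model exactly when 2*(loglik gain) > 2."""
        df = jt.simulate_linear_trajectories(120, 1.8, 1.0, 0.0157, 0.003, 0.8, seed=40)
        lin = jt.fit_lmm(df, scale="original_ugml", time_unit="months")
        quad = jt.fit_lmm(df, scale="original_ugml", time_unit="months", poly_degree=2)
        lr = 2 * (quad.loglik - lin.loglik)
        table = jt.compare_fits([lin, quad], labels=["linear", "quadratic"])
        best = table.iloc[0]["model"]
        assert best == ("quadratic" if lr > 2 else "linear")

    def test_log2_scale_preferred_on_right_skewed_cohort(self, joint_fit_medium):
        """Fitting the same right-skewed cohort on the raw and log2 scales:
        the log2 fit has the (much) lower AIC, as the likelihoods are not
        comparable without the log-transform Jacobian; compare_fits refuses
        unless explicitly overridden, and then shows the direction."""
        _, data, fit_log2 = joint_fit_medium
        fit_orig = jt.fit_joint_model(data, JointModelSpec(scale="original_ugml"))
        table = jt.compare_fits([fit_log2, fit_orig], labels=["log2", "original"],
                                allow_scale_mix=True)
        assert table.iloc[0]["model"] == "log2"


def test_nonfinite_likelihood_names_subject():
    _, data = _small_cohort(41, n=10)
    p, _, _ = _params_from_standalone(data)
    p.alpha = 400.0  # absurd association -> overflowing hazard
    with pytest.raises(ValueError):
        joint_loglikelihood(p, data, JointModelSpec(scale="log2"))
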