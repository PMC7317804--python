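"""Dynamic individualized risk prediction: empirical-Bayes modes, conditional
risk curves, closed-form oracle at zero association, monotonicity."""

import numpy as np
import pandas as pd
import pytest

import jointtraj as jt
from jointtraj.jointmodel import JointModelParams, JointModelSpec, fit_at_params


def _true_params(alpha=1.0225, shape=1.0, lam=0.0042):
    # months time unit; lam per month (0.14e-3/day * 30)
    return JointModelParams(
        beta=np.array([np.log2(0.97), 0.0]),
        D=np.array([[1.2**2, 0.0], [0.0, 0.09**2]]),
        sigma2=0.16, lam=lam, shape=shape, gamma_S=np.zeros(0), alpha=alpha,
    )


@pytest.fixture(scope="module")
def truth_fit():
    return fit_at_params(_true_params(), JointModelSpec(scale="log2"))


def _history(times, log2_values):
    return pd.DataFrame({"time": times, "log2_ddimer": log2_values})


class TestEmpiricalBayesModes:
    def test_zero_noise_limit_recovers_true_effects(self):
        b_true = np.array([0.8, -0.05])
        p = _true_params()
        p.sigma2 = 1e-8
        fit = fit_at_params(p, JointModelSpec(scale="log2"))
        t = np.arange(7) * 1.0
        y = p.beta[0] + b_true[0] + (p.beta[1] + b_true[1]) * t
        b_hat, _ = jt.empirical_bayes_modes(fit, _history(t, y), landmark=6.0)
        np.testing.assert_allclose(b_hat, b_true, atol=0.01)

    def test_matches_grid_search_oracle(self, truth_fit):
        """The Newton mode agrees with an exhaustive 200x200 lattice search of
        the conditional log-density written out independently here."""
        p = _true_params()
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.2, 0.7, 1.1, 1.6])
        s = 3.0
        b_hat, _ = jt.empirical_bayes_modes(truth_fit, _history(t, y), landmark=s)

        b0g = np.linspace(b_hat[0] - 1.0, b_hat[0] + 1.0, 200)
        b1g = np.linspace(b_hat[1] - 0.5, b_hat[1] + 0.5, 200)
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        ll = np.zeros_like(B0)
        for ti, yi in zip(t, y):
            mu = p.beta[0] + p.beta[1] * ti + B0 + B1 * ti
            ll += -0.5 * (yi - mu) ** 2 / p.sigma2
        # survival-to-s term: H(b0, b1) = exp(alpha*b0) * C(b1) with C by
        # trapezoid over the landmark window (one 1-D integral per b1 value)
        grid = np.linspace(1e-9, s, 2000)
        base = p.lam * p.shape * grid ** (p.shape - 1) * np.exp(
            p.alpha * (p.beta[0] + p.beta[1] * grid)
        )
        C = np.trapezoid(
            base[None, :] * np.exp(p.alpha * b1g[:, None] * grid[None, :]),
            grid, axis=1,
        )
        ll -= np.exp(p.alpha * B0) * C[None, :]
        Dinv = np.linalg.inv(p.D)
        ll -= 0.5 * (Dinv[0, 0] * B0**2 + 2 * Dinv[0, 1] * B0 * B1 + Dinv[1, 1] * B1**2)
        idx = np.unravel_index(np.argmax(ll), ll.shape)
        res0 = b0g[1] - b0g[0]
        res1 = b1g[1] - b1g[0]
        assert abs(b0g[idx[0]] - b_hat[0]) <= res0
        assert abs(b1g[idx[1]] - b_hat[1]) <= res1

    def test_survival_term_pulls_slope_down_when_alpha_positive(self, truth_fit):
        """Surviving event-free to the landmark is evidence against a steep
        latent rise, so the conditional slope mode sits below the pure
        mixed-model (longitudinal-only) mode."""
        p = _true_params()
        t = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 0.6, 1.3, 1.9])
        b_full, _ = jt.empirical_bayes_modes(truth_fit, _history(t, y), landmark=3.0)
        # LMM-only mode in closed form: (Z'Z/s2 + Dinv)^-1 Z'r/s2
        Z = np.column_stack([np.ones(t.size), t])
        r = y - (p.beta[0] + p.beta[1] * t)
        A = Z.T @ Z / p.sigma2 + np.linalg.inv(p.D)
        b_lmm = np.linalg.solve(A, Z.T @ r / p.sigma2)
        assert b_full[1] < b_lmm[1]

    def test_no_visits_returns_prior_mode_with_warning(self, truth_fit):
        with pytest.warns(UserWarning, match="no visits"):
            b_hat, _ = jt.empirical_bayes_modes(
                truth_fit, _history([], []), landmark=2.0
            )
        # prior mode tilted only by the survival term; stays near zero
        assert np.all(np.abs(b_hat) < 0.5)


class TestPredictRisk:
    def test_risk_zero_at_landmark_and_monotone(self, joint_fit_medium):
        _, data, fit = joint_fit_medium
        pid = data.visits["patient_id"].iloc[0]
        hist = data.visits[data.visits["patient_id"] == pid]
        s = float(hist["time"].max())
        hz = np.array([s, s + 1, s + 3, s + 6])
        pred = jt.predict_risk(fit, hist, {}, landmark=s, horizons=hz,
                               n_mc_draws=200, seed=1)
        assert pred.risk[0] == 0.0
        assert np.all(np.diff(pred.risk) >= -1e-12)
        assert np.all((pred.risk >= 0) & (pred.risk <= 1))
        assert np.all(pred.ci_lower <= pred.risk) and np.all(pred.risk <= pred.ci_upper)

    def test_alpha_zero_equals_marginal_weibull_conditional_risk(self):
        """With no association the trajectory is irrelevant and the risk is
        the closed-form conditional Weibull probability."""
        p = _true_params(alpha=0.0, shape=1.3, lam=0.003)
        fit = fit_at_params(p, JointModelSpec(scale="log2"))
        hist = _history([0.0, 1.0, 2.0], [0.5, 2.0, 3.5])
        s, u = 2.0, np.array([4.0, 8.0])
        pred = jt.predict_risk(fit, hist, {}, landmark=s, horizons=u,
                               n_mc_draws=100, seed=3,
                               include_param_uncertainty=False)
        closed = 1.0 - np.exp(-p.lam * (u**p.shape - s**p.shape))
        np.testing.assert_allclose(pred.risk, closed, atol=1e-10)
        np.testing.assert_allclose(pred.ci_upper - pred.ci_lower, 0.0, atol=1e-10)

    def test_rising_history_riskier_than_flat(self, joint_fit_medium):
        _, _, fit = joint_fit_medium
        s = 3.0
        t = [0.0, 1.0, 2.0, 3.0]
        flat = _history(t, [0.0, 0.0, 0.0, 0.0])
        rising = _history(t, [-1.0, 0.5, 1.8, 3.0])
        hz = np.array([s + 6.0])
        r_flat = jt.predict_risk(fit, flat, {}, landmark=s, horizons=hz,
                                 n_mc_draws=300, seed=4).risk[0]
        r_rise = jt.predict_risk(fit, rising, {}, landmark=s, horizons=hz,
                                 n_mc_draws=300, seed=4).risk[0]
        assert r_rise > r_flat
        # magnitudes in the regimes the study's worked examples report
        assert r_flat < 0.10
        assert r_rise > 0.20

    def test_doubling_every_value_raises_risk(self, joint_fit_medium):
        _, _, fit = joint_fit_medium
        t = [0.0, 1.0, 2.0]
        base = _history(t, [0.0, 0.3, 0.6])
        doubled = _history(t, [1.0, 1.3, 1.6])  # +1 on log2 = one doubling
        hz = np.array([8.0])
        r0 = jt.predict_risk(fit, base, {}, landmark=2.0, horizons=hz,
                             n_mc_draws=300, seed=5).risk[0]
        r1 = jt.predict_risk(fit, doubled, {}, landmark=2.0, horizons=hz,
                             n_mc_draws=300, seed=5).risk[0]
        assert r1 > r0

    def test_longer_history_narrows_band(self, joint_fit_medium):
        """More visits from the same latent trajectory shrink the MC band."""
        _, _, fit = joint_fit_medium
        rng = np.random.default_rng(6)
        t_full = np.arange(7) * 1.0
        y_full = 0.3 + 0.15 * t_full + rng.normal(0, 0.4, 7)
        s = 6.0
        hz = np.array([s + 3.0, s + 6.0])
        widths = []
        for k in (2, 7):
            hist = _history(t_full[:k], y_full[:k])
            pred = jt.predict_risk(fit, hist, {}, landmark=s, horizons=hz,
                                   n_mc_draws=400, seed=7)
            widths.append(np.mean(pred.ci_upper - pred.ci_lower))
        assert widths[1] < widths[0]

    def test_metropolis_sampler_agrees_with_normal_approximation(self, joint_fit_medium):
        _, _, fit = joint_fit_medium
        hist = _history([0.0, 1.0, 2.0], [0.5, 0.8, 1.2])
        hz = np.array([8.0])
        kw = dict(landmark=2.0, horizons=hz, n_mc_draws=150, seed=8,
                  include_param_uncertainty=False)
        r_norm = jt.predict_risk(fit, hist, {}, sampler="normal", **kw).risk[0]
        r_mh = jt.predict_risk(fit, hist, {}, sampler="metropolis", **kw).risk[0]
        assert abs(r_norm - r_mh) < 0.05

    def test_bad_horizons_rejected(self, joint_fit_medium):
        _, _, fit = joint_fit_medium
        hist = _history([0.0, 1.0], [0.5, 0.8])
        with pytest.raises(ValueError):
            jt.predict_risk(fit, hist, {}, landmark=1.0, horizons=[0.5],
                            n_mc_draws=10, seed=9)
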