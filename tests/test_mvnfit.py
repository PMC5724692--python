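import numpy as np
import pytest
from scipy.stats import multivariate_normal

from augbin.cohort import ScenarioConfig, generate_dataset, table1_preset
from augbin.mvnfit import fit_model, fit_mvn, fit_newlesion, unvech, vech


def complete_config(T=2, n=60):
    """No new lesions (huge negative intercept), no growth truncation:
    every patient is observed through all T visits."""
    pre = table1_preset(T).config
    return ScenarioConfig(
        T=T, n=n, mean=pre.mean, Sigma=pre.Sigma, alpha=-30.0, gamma=0.0,
        growth_truncation=False,
    )


def iterated_gls(ds, T, tol=1e-10):
    """Independent complete-data ML oracle: iterate GLS for (beta, omega)
    with Sigma the ML residual covariance."""
    Y = np.stack([p.y for p in ds.patients])
    z0 = np.array([p.z0 for p in ds.patients])
    n = len(z0)
    X = np.zeros((n, T, T + 1))
    for t in range(T):
        X[:, t, t] = 1.0
    X[:, :, T] = z0[:, None]
    Sigma = np.eye(T)
    coef = np.zeros(T + 1)
    for _ in range(500):
        W = np.linalg.inv(Sigma)
        A = np.einsum("ntj,tk,nks->js", X, W, X)
        b = np.einsum("ntj,tk,nk->j", X, W, Y)
        new = np.linalg.solve(A, b)
        resid = Y - np.einsum("ntj,j->nt", X, new)
        Sigma_new = resid.T @ resid / n
        if np.max(np.abs(new - coef)) < tol and np.max(np.abs(Sigma_new - Sigma)) < tol:
            coef, Sigma = new, Sigma_new
            break
        coef, Sigma = new, Sigma_new
    return coef[:T], coef[T], Sigma


class TestMvnBlock:
    def test_complete_data_matches_gls_oracle(self):
        ds = generate_dataset(complete_config(), seed=101)
        assert all(p.F == 2 for p in ds.patients)
        mean, Sigma, _, ll, conv = fit_mvn(ds, 2)
        beta_o, omega_o, Sigma_o = iterated_gls(ds, 2)
        assert conv
        np.testing.assert_allclose(mean.beta, beta_o, atol=1e-5)
        assert mean.omega == pytest.approx(omega_o, abs=1e-5)
        np.testing.assert_allclose(Sigma, Sigma_o, atol=1e-5)

    def test_t1_reduces_to_ols(self):
        ds = generate_dataset(complete_config(), seed=102)
        mean, Sigma, _, _, _ = fit_mvn(ds, 1)
        y = np.array([p.y[0] for p in ds.patients])
        z0 = np.array([p.z0 for p in ds.patients])
        X = np.column_stack([np.ones(len(y)), z0])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        assert mean.beta[0] == pytest.approx(coef[0], abs=1e-6)
        assert mean.omega == pytest.approx(coef[1], abs=1e-6)
        assert Sigma[0, 0] == pytest.approx(resid @ resid / len(y), abs=1e-6)

    def test_loglik_value(self, t2_dataset, t2_fit):
        """Reported log likelihood equals the sum of per-patient normal
        prefix densities plus the logistic contributions."""
        ll = 0.0
        for p in t2_dataset.patients:
            f = p.F
            mu = t2_fit.mean.beta[:f] + t2_fit.mean.omega * p.z0
            ll += multivariate_normal.logpdf(
                p.y[:f], mean=mu, cov=t2_fit.Sigma[:f, :f]
            )
            for t in range(1, f + 1):
                pi = float(t2_fit.nl.prob(t, p.z_prev(t)))
                d = 1 if p.X == t else 0
                ll += d * np.log(pi) + (1 - d) * np.log(1 - pi)
        assert t2_fit.loglik == pytest.approx(ll, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        cfg = table1_preset(2).config
        big = ScenarioConfig(
            T=2, n=4000, mean=cfg.mean, Sigma=cfg.Sigma, alpha=-1.5, gamma=0.0,
            growth_truncation=False,
        )
        ds = generate_dataset(big, seed=77)
        fit = fit_model(ds, 2)
        np.testing.assert_allclose(fit.mean.beta, cfg.mean, atol=0.08)
        assert abs(fit.mean.omega) < 0.12
        np.testing.assert_allclose(fit.Sigma, cfg.Sigma, atol=0.08)
        np.testing.assert_allclose(fit.nl.alpha, -1.5, atol=0.25)
        np.testing.assert_allclose(fit.nl.gamma, 0.0, atol=0.45)

    def test_vcov_positive_semidefinite(self, t2_fit):
        w = np.linalg.eigvalsh(0.5 * (t2_fit.vcov + t2_fit.vcov.T))
        assert w.min() > -1e-10

    def test_se_scales_with_n(self):
        small = generate_dataset(complete_config(n=50), seed=9)
        large = generate_dataset(complete_config(n=800), seed=9)
        _, _, v_s, _, _ = fit_mvn(small, 2)
        _, _, v_l, _, _ = fit_mvn(large, 2)
        ratio = np.sqrt(v_s[0, 0] / v_l[0, 0])
        assert ratio == pytest.approx(np.sqrt(800 / 50), rel=0.35)

    def test_no_complete_patient_rejected(self):
        ds = generate_dataset(complete_config(), seed=3)
        for p in ds.patients:  # truncate everyone to one visit
            p.y = p.y[:1]
            p.D = p.D[:1]
            p.F = 1
        with pytest.raises(ValueError):
            fit_mvn(ds, 2)


class TestNewLesionBlock:
    def test_matches_statsmodels(self, t2_dataset):
        import statsmodels.api as sm

        params, vc, ll, degen = fit_newlesion(t2_dataset, 1)
        assert not degen
        d = np.array([1 if p.X == 1 else 0 for p in t2_dataset.patients])
        z = np.array([p.z0 for p in t2_dataset.patients])
        X = np.column_stack([np.ones(len(d)), z])
        ref = sm.Logit(d, X).fit(disp=0)
        np.testing.assert_allclose(params, ref.params, atol=1e-6)
        np.testing.assert_allclose(vc, ref.cov_params(), atol=1e-6)

    def test_single_class_fallback(self, t2_dataset):
        from augbin.data import TrialDataset
        import copy

        clean = []
        for p in t2_dataset.patients:
            q = copy.copy(p)
            if q.X == 1:
                q = copy.copy(p)
                q.y, q.D, q.X, q.F = q.y[:1] * 0 - 0.1, np.zeros(1, int), None, 1
            clean.append(q)
        ds = TrialDataset(clean)
        params, vc, _, degen = fit_newlesion(ds, 1)
        assert degen
        # continuity-corrected intercept: logit(0.5/(n+1))
        from scipy.special import expit

        assert 0 < expit(params[0]) < 0.02
        assert vc[0, 0] > 0

    def test_theta_layout_round_trip(self, t2_fit):
        rebuilt = t2_fit.replace_theta(t2_fit.theta.copy())
        np.testing.assert_allclose(rebuilt.mean.beta, t2_fit.mean.beta)
        np.testing.assert_allclose(rebuilt.Sigma, t2_fit.Sigma)
        np.testing.assert_allclose(rebuilt.nl.alpha, t2_fit.nl.alpha)
        np.testing.assert_allclose(rebuilt.nl.gamma, t2_fit.nl.gamma)

    def test_vech_round_trip(self):
        M = np.array([[2.0, 0.3, 0.1], [0.3, 1.5, -0.2], [0.1, -0.2, 1.1]])
        np.testing.assert_array_equal(unvech(vech(M), 3), M)


class TestTwoArm:
    def test_eta_and_lambda_present(self, two_arm_fit):
        assert two_arm_fit.mean.eta is not None and len(two_arm_fit.mean.eta) == 2
        assert two_arm_fit.nl.lam is not None
        assert len(two_arm_fit.theta) == 2 + 1 + 2 + 3 + 3 * 2

    def test_null_arm_effects_small(self, two_arm_fit):
        se = np.sqrt(np.diag(two_arm_fit.vcov))[3:5]
        assert np.all(np.abs(two_arm_fit.mean.eta) < 4 * se)
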