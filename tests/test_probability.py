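import numpy as np
import pytest
from scipy.special import expit, ndtr

from augbin.cohort import generate_dataset, table1_preset
from augbin.data import LOG_PROGRESSION, LOG_RESPONSE, EndpointSpec, TrialDataset
from augbin.probability import (
    MaugEngine,
    build_regions,
    eaugbin_prob,
    maug_prob,
    mean_response,
    pi_estimates,
    response_probabilities,
)


class TestRegions:
    def test_fixed_time_region(self):
        spec = EndpointSpec("fixed_time", T=3)
        reg = build_regions(spec)
        assert len(reg.entries) == 1
        h, lower, upper = reg.entries[0]
        assert h == 3
        assert np.all(np.isneginf(lower))
        assert upper[-1] == LOG_RESPONSE and np.all(np.isposinf(upper[:-1]))

    def test_bor_regions_disjoint_probability(self, bor_fit, bor_dataset):
        """The BOR event is a disjoint union over the response visit, so the
        rectangle probabilities must sum to at most one."""
        eng = MaugEngine(bor_dataset, EndpointSpec("bor", T=4))
        rect = eng.rectangles(bor_fit)
        assert np.all(rect.sum(axis=1) <= 1.0 + 1e-6)

    def test_confirmed_has_one_fewer_entry(self):
        assert len(build_regions(EndpointSpec("bor", T=4)).entries) == 4
        assert len(build_regions(EndpointSpec("bor_confirmed", T=4)).entries) == 3


class TestMaug:
    def test_fixed_time_t2_closed_form(self, t2_dataset, t2_fit):
        """With c = +inf, the mAug probability for a fully observed patient
        is (1-pi_1)(1-pi_2) * Phi((log .7 - mu_2)/sigma_2), all terms
        hand-computable from the fitted parameters."""
        spec = EndpointSpec("fixed_time", T=2)
        p = next(q for q in t2_dataset.patients if q.F == 2)
        mu2 = t2_fit.mean.beta[1] + t2_fit.mean.omega * p.z0
        rect = ndtr((LOG_RESPONSE - mu2) / np.sqrt(t2_fit.Sigma[1, 1]))
        s1 = 1 - float(t2_fit.nl.prob(1, p.z0))
        s2 = 1 - float(t2_fit.nl.prob(2, p.z_prev(2)))
        want = s1 * s2 * rect
        got = maug_prob(p, t2_fit, spec, ds=t2_dataset)
        assert got == pytest.approx(want, abs=2e-9)

    def test_mean_matches_per_patient(self, t2_dataset, t2_fit):
        spec = EndpointSpec("fixed_time", T=2)
        mean, probs = mean_response(t2_dataset, t2_fit, spec, engine="maug")
        assert mean == pytest.approx(probs.mean())
        assert probs.shape == (t2_dataset.n,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_trimmed_average_arithmetic(self, bor_dataset, bor_fit):
        """Beyond a patient's follow-up + 1 the chain uses the trimmed
        average of model probabilities over patients still observed whose
        log ratio stayed inside the stable band — recomputed by hand."""
        spec = EndpointSpec("bor", T=4)
        eng = MaugEngine(bor_dataset, spec)
        pi = eng.pi_matrix(bor_fit)
        short = next(i for i, p in enumerate(bor_dataset.patients) if p.F <= 2)
        t = bor_dataset.patients[short].F + 2  # first trimmed visit (1-based)
        lo, hi = eng.regions.phi[t - 1]
        vals = []
        for q in bor_dataset.patients:
            if q.F + 1 >= t:  # z_{t-1} observed
                if t <= q.F and not (lo < q.y[t - 1] < hi):
                    continue  # y_t observed outside phi: trimmed out
                vals.append(float(bor_fit.nl.prob(t, q.z_prev(t))))
        assert pi[short, t - 1] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_provenance_flags(self, bor_dataset, bor_fit):
        spec = EndpointSpec("bor", T=4)
        p = next(q for q in bor_dataset.patients if q.F <= 2)
        est = pi_estimates(p, bor_fit, bor_dataset, spec)
        assert est.model_based[: p.F + 1].all()
        assert not est.model_based[p.F + 1 :].any()
        assert np.all((est.pi > 0) & (est.pi < 1))

    def test_confirmed_below_unconfirmed(self, bor_dataset, bor_fit):
        pc = response_probabilities(
            bor_dataset, bor_fit, EndpointSpec("bor_confirmed", T=4), engine="maug"
        )
        pu = response_probabilities(
            bor_dataset, bor_fit, EndpointSpec("bor", T=4), engine="maug"
        )
        assert np.all(pc <= pu + 1e-10)

    def test_arm_override(self, two_arm_dataset, two_arm_fit):
        spec = EndpointSpec("fixed_time", T=2)
        p0 = response_probabilities(two_arm_dataset, two_arm_fit, spec, arm=0)
        p1 = response_probabilities(two_arm_dataset, two_arm_fit, spec, arm=1)
        assert p0.shape == p1.shape == (two_arm_dataset.n,)
        # overriding the arm changes probabilities through eta/lambda
        assert not np.allclose(p0, p1)


class TestEaugbin:
    def test_matches_maug_when_gamma_zero(self, t2_dataset, t2_fit):
        """With all size effects zero the logistic factors leave the
        integrand, so the two engines compute the same number."""
        spec = EndpointSpec("fixed_time", T=2)
        theta = t2_fit.theta.copy()
        nm = t2_fit.n_mean + t2_fit.n_sigma
        theta[nm + 1] = 0.0  # gamma_1
        theta[nm + 3] = 0.0  # gamma_2
        flat = t2_fit.replace_theta(theta)
        pm = response_probabilities(t2_dataset, flat, spec, engine="maug")
        pe = response_probabilities(
            t2_dataset, flat, spec, engine="eaugbin", n_qmc=8192
        )
        np.testing.assert_allclose(pe, pm, atol=2e-4)

    def test_bor_matches_maug_when_gamma_zero(self, bor_dataset, bor_fit):
        spec = EndpointSpec("bor", T=4)
        theta = bor_fit.theta.copy()
        nm = bor_fit.n_mean + bor_fit.n_sigma
        for t in range(4):
            theta[nm + 2 * t + 1] = 0.0
        flat = bor_fit.replace_theta(theta)
        # eAugbin integrates latent trajectories; mAug plugs in observed
        # sizes.  They coincide only when the size effect vanishes AND the
        # chain is fully model-based, so compare patients with F >= T - 1.
        full = [i for i, p in enumerate(bor_dataset.patients) if p.F >= 3]
        pm = response_probabilities(bor_dataset, flat, spec, engine="maug")
        pe = response_probabilities(bor_dataset, flat, spec, engine="eaugbin", n_qmc=8192)
        np.testing.assert_allclose(pe[full], pm[full], atol=2e-4)

    def test_against_simulation_oracle(self, t2_dataset, t2_fit):
        """eAugbin per-patient probability vs direct simulation from the
        fitted model (latent sizes feeding the new-lesion chain)."""
        spec = EndpointSpec("fixed_time", T=2)
        rng = np.random.default_rng(2024)
        n_mc = 200_000
        for p in list(t2_dataset.patients)[:3]:
            mu = t2_fit.mean.beta + t2_fit.mean.omega * p.z0
            L = np.linalg.cholesky(t2_fit.Sigma)
            Y = mu + rng.standard_normal((n_mc, 2)) @ L.T
            pi1 = float(t2_fit.nl.prob(1, p.z0))
            z1 = p.z0 * np.exp(Y[:, 0])
            pi2 = t2_fit.nl.prob(2, z1)
            no_nl = (rng.uniform(size=n_mc) > pi1) & (rng.uniform(size=n_mc) > pi2)
            hit = no_nl & (Y[:, 1] < LOG_RESPONSE)
            mc = hit.mean()
            se = np.sqrt(mc * (1 - mc) / n_mc)
            got = eaugbin_prob(p, t2_fit, spec, tol=1e-5)
            assert abs(got - mc) < 4 * se + 1e-4

    def test_adaptive_refinement_converges(self, t2_dataset, t2_fit):
        spec = EndpointSpec("fixed_time", T=2)
        p = t2_dataset.patients[0]
        a = eaugbin_prob(p, t2_fit, spec, tol=1e-3)
        b = eaugbin_prob(p, t2_fit, spec, tol=1e-5)
        assert a == pytest.approx(b, abs=2e-3)

    def test_unknown_engine_rejected(self, t2_dataset, t2_fit):
        with pytest.raises(ValueError):
            response_probabilities(
                t2_dataset, t2_fit, EndpointSpec("fixed_time", T=2), engine="foo"
            )
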