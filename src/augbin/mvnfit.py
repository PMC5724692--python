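"""Maximum-likelihood fitting of the joint longitudinal model.

The log tumour size ratios ``(Y_1, ..., Y_T) | z0`` are multivariate normal
with per-visit intercepts, a baseline-size slope ``omega`` shared across
visits and, in randomised trials, per-visit arm effects; the covariance is
unstructured.  Follow-up truncation at progression produces a monotone
missingness pattern that is missing at random, so the observed-data
likelihood is the product over patients of the normal density of the
observed prefix.  It is maximised directly (with an analytic gradient,
the covariance parameterised through its Cholesky factor so it stays
positive-definite).  New-lesion progression is modelled by independent
per-visit logistic regressions on the previous tumour size (and arm),
fitted on the at-risk patients.

The full parameter vector theta concatenates, in order: the mean-model
parameters ``(beta_1..beta_T, omega[, eta_1..eta_T])``, the lower triangle
of Sigma row by row (diagonal included), and per visit ``(alpha_t,
gamma_t[, lambda_t])``.  Its estimated variance is block-diagonal across
the normal and logistic blocks — exact under the factorised likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import logit

from ._numdiff import central_hessian
from .data import TrialDataset

__all__ = ["MeanModel", "NewLesionModel", "FittedModel", "fit_mvn", "fit_newlesion", "fit_model"]

logger = logging.getLogger(__name__)


@dataclass
class MeanModel:
    beta: np.ndarray          # per-visit intercepts
    omega: float              # shared baseline-size slope
    eta: Optional[np.ndarray] = None  # per-visit arm effects (two-arm)

    def means(self, z0: np.ndarray, R: np.ndarray) -> np.ndarray:
        mu = self.beta[None, :] + self.omega * np.asarray(z0)[:, None]
        if self.eta is not None:
            mu = mu + np.asarray(R)[:, None] * self.eta[None, :]
        return mu


@dataclass
class NewLesionModel:
    alpha: np.ndarray
    gamma: np.ndarray
    lam: Optional[np.ndarray] = None  # per-visit arm effects
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def prob(self, t: int, z_prev, R=0) -> np.ndarray:
        """P(new-lesion progression at visit t | at risk), t 1-based."""
        from scipy.special import expit

        lp = self.alpha[t - 1] + self.gamma[t - 1] * np.asarray(z_prev, dtype=float)
        if self.lam is not None:
            lp = lp + self.lam[t - 1] * np.asarray(R)
        return expit(lp)


def _vech_indices(T: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(T) for j in range(i + 1)]


def vech(M: np.ndarray) -> np.ndarray:
    T = M.shape[0]
    return np.array([M[i, j] for i, j in _vech_indices(T)])


def unvech(v: np.ndarray, T: int) -> np.ndarray:
    M = np.zeros((T, T))
    for (i, j), val in zip(_vech_indices(T), v):
        M[i, j] = M[j, i] = val
    return M


@dataclass
class FittedModel:
    """theta-hat with its estimated variance and component views."""

    T: int
    arms: int
    mean: MeanModel
    Sigma: np.ndarray
    nl: NewLesionModel
    theta: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    n: int = 0

    @property
    def n_mean(self) -> int:
        return self.T + 1 + (self.T if self.arms == 2 else 0)

    @property
    def n_sigma(self) -> int:
        return self.T * (self.T + 1) // 2

    @property
    def nl_width(self) -> int:
        return 3 if self.arms == 2 else 2

    def replace_theta(self, theta: np.ndarray) -> "FittedModel":
        """Rebuild the component models from a (perturbed) theta vector."""
        T, arms = self.T, self.arms
        k = 0
        beta = theta[k : k + T]; k += T
        omega = float(theta[k]); k += 1
        eta = None
        if arms == 2:
            eta = theta[k : k + T]; k += T
        Sigma = unvech(theta[k : k + self.n_sigma], T); k += self.n_sigma
        w = self.nl_width
        nlp = theta[k:].reshape(T, w)
        nl = NewLesionModel(
            alpha=nlp[:, 0].copy(),
            gamma=nlp[:, 1].copy(),
            lam=nlp[:, 2].copy() if arms == 2 else None,
            degenerate=self.nl.degenerate,
        )
        return FittedModel(
            T=T, arms=arms, mean=MeanModel(beta.copy(), omega, None if eta is None else eta.copy()),
            Sigma=Sigma, nl=nl, theta=np.asarray(theta, float),
            vcov=self.vcov, loglik=self.loglik, converged=self.converged, n=self.n,
        )


# ---------------------------------------------------------------------------
# monotone-missing MVN block

def _group_data(ds: TrialDataset, T: int):
    """Group observed prefixes by length F for vectorised likelihoods."""
    groups: dict[int, list[int]] = {}
    z0 = np.array([p.z0 for p in ds.patients])
    R = ds.arms
    for i, p in enumerate(ds.patients):
        f = min(p.F, T)
        if f < 1:
            logger.warning("patient %s has no follow-up measurements; skipped", p.id)
            continue
        groups.setdefault(f, []).append(i)
    Y = {f: np.stack([ds.patients[i].y[:f] for i in idx]) for f, idx in groups.items()}
    return groups, Y, z0, R


def _chol_from_params(c: np.ndarray, T: int) -> np.ndarray:
    L = np.zeros((T, T))
    k = 0
    for i, j in _vech_indices(T):
        L[i, j] = np.exp(c[k]) if i == j else c[k]
        k += 1
    return L


def _chol_to_params(L: np.ndarray) -> np.ndarray:
    out = []
    for i, j in _vech_indices(L.shape[0]):
        out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def _mvn_loglik_and_grad(params, T, two_arm, groups, Y, z0, R):
    nm = T + 1 + (T if two_arm else 0)
    beta = params[:T]
    omega = params[T]
    eta = params[T + 1 : T + 1 + T] if two_arm else np.zeros(T)
    L = _chol_from_params(params[nm:], T)
    Sigma = L @ L.T

    ll = 0.0
    g_beta = np.zeros(T)
    g_omega = 0.0
    g_eta = np.zeros(T)
    G = np.zeros((T, T))  # d ll / d Sigma (full symmetric convention)
    for f, idx in groups.items():
        idx = np.asarray(idx)
        Sf = Sigma[:f, :f]
        cf = cho_factor(Sf, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        mu = beta[None, :f] + omega * z0[idx, None] + R[idx, None] * eta[None, :f]
        Rres = Y[f] - mu
        U = cho_solve(cf, Rres.T).T                     # Sigma_f^{-1} r_i
        quad = np.einsum("ij,ij->i", Rres, U)
        n_f = len(idx)
        ll += -0.5 * (n_f * (logdet + f * np.log(2 * np.pi)) + quad.sum())
        g_beta[:f] += U.sum(axis=0)
        g_omega += float(z0[idx] @ U.sum(axis=1))
        g_eta[:f] += R[idx] @ U
        # with U = Sigma^{-1} r:  Sigma^{-1} S Sigma^{-1} = sum_i u_i u_i'
        G[:f, :f] += 0.5 * (U.T @ U - n_f * cho_solve(cf, np.eye(f)))
    # chain rule to Cholesky parameters: dll/dL = 2 G L (lower triangle)
    GL = 2.0 * (G @ L)
    g_chol = []
    for i, j in _vech_indices(T):
        g = GL[i, j]
        if i == j:
            g *= L[i, i]  # log-diagonal parameterisation
        g_chol.append(g)
    grad = np.concatenate(
        [g_beta, [g_omega]] + ([g_eta] if two_arm else []) + [np.array(g_chol)]
    )
    return ll, grad


def _mvn_loglik_natural(q, T, two_arm, groups, Y, z0, R):
    """Log-likelihood as a function of the natural parameters
    (mean parameters, vech Sigma) — used for the variance Hessian."""
    nm = T + 1 + (T if two_arm else 0)
    beta = q[:T]
    omega = q[T]
    eta = q[T + 1 : T + 1 + T] if two_arm else np.zeros(T)
    Sigma = unvech(q[nm:], T)
    ll = 0.0
    for f, idx in groups.items():
        idx = np.asarray(idx)
        Sf = Sigma[:f, :f]
        cf = cho_factor(Sf, lower=True)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        mu = beta[None, :f] + omega * z0[idx, None] + R[idx, None] * eta[None, :f]
        Rres = Y[f] - mu
        quad = np.einsum("ij,ij->i", Rres, cho_solve(cf, Rres.T).T)
        ll += -0.5 * (len(idx) * (logdet + f * np.log(2 * np.pi)) + quad.sum())
    return ll


def _initial_values(T, two_arm, groups, Y, z0, R):
    """Available-case per-visit OLS for the mean; available-case residual
    covariance (ridge-repaired to positive-definite) for Sigma."""
    n_all = sum(len(v) for v in groups.values())
    resid = np.full((n_all, T), np.nan)
    beta0 = np.zeros(T)
    eta0 = np.zeros(T)
    slopes = []
    row = {f: np.asarray(idx) for f, idx in groups.items()}
    flat_idx = np.concatenate([row[f] for f in groups])
    pos_of = {int(i): p for p, i in enumerate(flat_idx)}
    for t in range(T):
        ys, zs, rs, who = [], [], [], []
        for f, idx in groups.items():
            if f >= t + 1:
                ys.append(Y[f][:, t]); zs.append(z0[np.asarray(idx)])
                rs.append(R[np.asarray(idx)]); who.extend(idx)
        yv = np.concatenate(ys); zv = np.concatenate(zs); rv = np.concatenate(rs)
        cols = [np.ones_like(zv), zv] + ([rv] if two_arm else [])
        Xd = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(Xd, yv, rcond=None)
        beta0[t] = coef[0]
        slopes.append(coef[1])
        if two_arm:
            eta0[t] = coef[2]
        res = yv - Xd @ coef
        for w, r_ in zip(who, res):
            resid[pos_of[int(w)], t] = r_
    omega0 = float(np.mean(slopes))
    C = np.zeros((T, T))
    for s in range(T):
        for t in range(s, T):
            ok = ~np.isnan(resid[:, s]) & ~np.isnan(resid[:, t])
            v = float(np.mean(resid[ok, s] * resid[ok, t])) if ok.sum() > 1 else (1.0 if s == t else 0.0)
            C[s, t] = C[t, s] = v
    # ensure positive-definite
    w, V = np.linalg.eigh(C)
    C = (V * np.maximum(w, 1e-3)) @ V.T
    return beta0, omega0, eta0, C


def fit_mvn(ds: TrialDataset, T: int):
    """Fit the multivariate-normal block by direct observed-data ML.

    Returns ``(MeanModel, Sigma, vcov_block, loglik, converged)`` where
    ``vcov_block`` covers the natural parameters (mean parameters followed
    by vech Sigma), obtained from the inverse numerical Hessian.
    """
    two_arm = ds.n_arms == 2
    groups, Y, z0, R = _group_data(ds, T)
    max_f = max(groups) if groups else 0
    if max_f < T:
        raise ValueError(f"no patient observed through visit {T}")
    per_visit = {t: sum(len(v) for f, v in groups.items() if f >= t) for t in range(1, T + 1)}
    if min(per_visit.values()) < 2:
        raise ValueError("fewer than 2 observations at some visit")

    beta0, omega0, eta0, C0 = _initial_values(T, two_arm, groups, Y, z0, R)
    c0 = _chol_to_params(np.linalg.cholesky(C0))
    x0 = np.concatenate([beta0, [omega0]] + ([eta0] if two_arm else []) + [c0])

    def negll(x):
        ll, g = _mvn_loglik_and_grad(x, T, two_arm, groups, Y, z0, R)
        return -ll, -g

    res = minimize(negll, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
    converged = bool(res.success)
    if not converged:
        logger.warning("MVN fit did not fully converge: %s", res.message)
    x = res.x
    nm = T + 1 + (T if two_arm else 0)
    L = _chol_from_params(x[nm:], T)
    Sigma = L @ L.T
    mean = MeanModel(
        beta=x[:T].copy(),
        omega=float(x[T]),
        eta=x[T + 1 : T + 1 + T].copy() if two_arm else None,
    )
    q_hat = np.concatenate([x[:nm], vech(Sigma)])
    H = central_hessian(
        lambda q: _mvn_loglik_natural(q, T, two_arm, groups, Y, z0, R),
        q_hat, rel_step=1e-5,
    )
    H = 0.5 * (H + H.T)
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-H)
        converged = False
    return mean, Sigma, vcov, float(-res.fun), converged


# ---------------------------------------------------------------------------
# new-lesion logistic block

def fit_newlesion(ds: TrialDataset, t: int):
    """Logistic model for new-lesion progression at visit ``t`` (1-based),
    fitted on the at-risk patients (no progression before ``t``).

    Returns ``(params, vcov, loglik, degenerate)`` with params
    ``(alpha_t, gamma_t[, lambda_t])``.  Risk sets with a single outcome
    class (or separation) fall back to a continuity-corrected
    intercept-only fit, flagged as degenerate.
    """
    two_arm = ds.n_arms == 2
    rows = [p for p in ds.patients if p.F >= t]
    if not rows:
        raise ValueError(f"empty risk set at visit {t}")
    d = np.array([1 if p.X == t else 0 for p in rows])
    z_prev = np.array([p.z_prev(t) for p in rows])
    R = np.array([0 if p.arm is None else p.arm for p in rows])
    k = 3 if two_arm else 2
    n = len(rows)

    def fallback():
        p_tilde = (d.sum() + 0.5) / (n + 1.0)
        params = np.zeros(k)
        params[0] = logit(p_tilde)
        vc = np.zeros((k, k))
        vc[0, 0] = 1.0 / (n * p_tilde * (1.0 - p_tilde))
        ll = float(d.sum() * np.log(p_tilde) + (n - d.sum()) * np.log(1 - p_tilde))
        return params, vc, ll, True

    if d.min() == d.max():
        logger.warning("visit %d risk set has a single outcome class", t)
        return fallback()
    X = np.column_stack([np.ones(n), z_prev] + ([R] if two_arm else []))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(d, X).fit(disp=0, maxiter=100)
        params = np.asarray(fit.params, float)
        vc = np.asarray(fit.cov_params(), float)
        if (not np.all(np.isfinite(params)) or not np.all(np.isfinite(vc))
                or np.max(np.abs(params)) > 20):
            raise ValueError("separation suspected")
        return params, vc, float(fit.llf), False
    except Exception as err:  # separation / non-convergence
        logger.warning("logistic fit at visit %d failed (%s); using "
                       "continuity-corrected intercept", t, err)
        return fallback()


# ---------------------------------------------------------------------------
# assembly

def fit_model(ds: TrialDataset, T: int) -> FittedModel:
    """Fit all blocks and assemble theta-hat with its block-diagonal
    estimated variance."""
    two_arm = ds.n_arms == 2
    mean, Sigma, vcov_mvn, ll_mvn, conv = fit_mvn(ds, T)
    w = 3 if two_arm else 2
    nl_params = np.zeros((T, w))
    nl_vcovs = []
    degen = np.zeros(T, dtype=bool)
    ll = ll_mvn
    for t in range(1, T + 1):
        params, vc, llt, dg = fit_newlesion(ds, t)
        nl_params[t - 1] = params
        nl_vcovs.append(vc)
        degen[t - 1] = dg
        ll += llt
    nl = NewLesionModel(
        alpha=nl_params[:, 0].copy(),
        gamma=nl_params[:, 1].copy(),
        lam=nl_params[:, 2].copy() if two_arm else None,
        degenerate=degen,
    )
    theta = np.concatenate(
        [mean.beta, [mean.omega]]
        + ([mean.eta] if two_arm else [])
        + [vech(Sigma), nl_params.ravel()]
    )
    dim = len(theta)
    vcov = np.zeros((dim, dim))
    nmvn = vcov_mvn.shape[0]
    vcov[:nmvn, :nmvn] = vcov_mvn
    off = nmvn
    for vc in nl_vcovs:
        vcov[off : off + w, off : off + w] = vc
        off += w
    return FittedModel(
        T=T, arms=2 if two_arm else 1, mean=mean, Sigma=Sigma, nl=nl,
        theta=theta, vcov=vcov, loglik=float(ll), converged=conv, n=ds.n,
    )
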