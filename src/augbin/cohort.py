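"""Synthetic trial cohorts: generative models for the simulation studies.

A cohort is generated as follows.  Baseline tumour size ``z0`` is uniform
on (0, 1) (the tumour scale is unit-free).  The vector of log tumour size
ratios over the ``T`` follow-up visits is multivariate normal; in two-arm
trials the per-visit means shift by an arm effect.  New-lesion progression
at visit ``t`` is Bernoulli with a logistic probability depending on the
tumour size at the previous visit (and, optionally, the arm), generated
sequentially while the patient remains progression-free.  Follow-up is
truncated at new-lesion progression, and — in scenarios where the trial
treats tumour growth as a stopping event (``growth_truncation``) — also at
the first log ratio reaching ``log 1.2``; later measurements are missing,
monotonically.  Fixed-time scenarios analysed with no intermediate
constraint (``c`` infinite) follow patients through visit ``T`` unless a
new lesion appears, so tumour growth alone does not censor the final
measurement there.

The covariance of the log ratios follows a Brownian-motion-type pattern,
``Cov(Y_s, Y_t) = Var(Y_min(s,t))`` with variances increasing to the
terminal value: early ratios are less variable and increments are
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, ndtr

from .data import (
    LOG_PROGRESSION,
    LOG_RESPONSE,
    EndpointSpec,
    PatientRecord,
    TrialDataset,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioPreset",
    "generate_dataset",
    "table1_preset",
    "bor_preset",
    "two_arm_preset",
    "preset_by_name",
    "preset_names",
    "true_probability",
]


@dataclass
class ScenarioConfig:
    """Complete generative specification for one simulated trial.

    ``mean`` is the control/base per-visit mean log-ratio vector.  In
    two-arm trials the mean for arm indicator R is
    ``mean + delta * tau_vec + psi`` with ``delta = +1`` for control
    (R = 0) and ``-1`` for experimental (R = 1): ``2 * tau_t`` is the arm
    difference at visit t and ``psi`` shifts both arms (control-treatment
    effectiveness).  ``alpha``, ``gamma``, ``lam`` parameterise the
    per-visit new-lesion logistic models
    ``logit P(D_t = 1) = alpha_t + gamma_t * z_{t-1} + lam_t * R``.
    ``growth_truncation`` controls whether follow-up stops at the first
    tumour-growth progression (log ratio >= log 1.2) in addition to
    new-lesion progression; fixed-time scenarios with no intermediate
    constraint set it to False.
    """

    T: int
    n: int
    mean: np.ndarray
    Sigma: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    arms: int = 1
    tau_vec: Optional[np.ndarray] = None
    psi: float = 0.0
    lam: Optional[np.ndarray] = None
    growth_truncation: bool = True

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.alpha = np.broadcast_to(
            np.asarray(self.alpha, dtype=float), (self.T,)
        ).copy()
        self.gamma = np.broadcast_to(
            np.asarray(self.gamma, dtype=float), (self.T,)
        ).copy()
        if self.lam is None:
            self.lam = np.zeros(self.T)
        self.lam = np.broadcast_to(np.asarray(self.lam, dtype=float), (self.T,)).copy()
        if self.tau_vec is None:
            self.tau_vec = np.zeros(self.T)
        self.tau_vec = np.broadcast_to(
            np.asarray(self.tau_vec, dtype=float), (self.T,)
        ).copy()
        if self.mean.shape != (self.T,) or self.Sigma.shape != (self.T, self.T):
            raise ValueError("mean/Sigma shapes inconsistent with T")
        try:
            np.linalg.cholesky(self.Sigma)
        except np.linalg.LinAlgError as err:
            raise ValueError("Sigma must be positive-definite") from err

    def arm_mean(self, R: int) -> np.ndarray:
        """Per-visit mean log ratios for arm indicator R (delta = 1 - 2R)."""
        delta = 1.0 - 2.0 * R
        return self.mean + delta * self.tau_vec + self.psi


@dataclass
class ScenarioPreset:
    name: str
    config: ScenarioConfig


def _brownian_cov(variances: Sequence[float]) -> np.ndarray:
    """Cov(Y_s, Y_t) = Var(Y_min(s,t)) for increasing per-visit variances."""
    v = np.asarray(variances, dtype=float)
    return np.minimum.outer(v, v)


def table1_preset(T: int, alpha: float = -1.5, gamma: float = 0.0) -> ScenarioPreset:
    """Single-arm fixed-time scenarios: 75 patients, means ramping to
    ``log 0.7`` at the final visit, Brownian-pattern covariance with
    terminal variance 1 (0.5 at T = 2)."""
    if T == 2:
        fracs, variances = (0.5, 1.0), (0.5, 1.0)
    elif T == 3:
        fracs, variances = (0.5, 0.75, 1.0), (0.5, 0.75, 1.0)
    elif T == 4:
        fracs, variances = (0.25, 0.5, 0.75, 1.0), (0.25, 0.5, 0.75, 1.0)
    else:
        raise ValueError("single-arm fixed-time presets support T in {2, 3, 4}")
    cfg = ScenarioConfig(
        T=T,
        n=75,
        mean=LOG_RESPONSE * np.asarray(fracs),
        Sigma=_brownian_cov(variances),
        alpha=alpha,
        gamma=gamma,
        growth_truncation=False,
    )
    return ScenarioPreset(f"table1-T{T}-a{alpha}-g{gamma}", cfg)


def bor_preset(T: int, alpha: float = -1.5, gamma: float = 0.0) -> ScenarioPreset:
    """Single-arm best-observed-response scenarios: means ``(t/T) log 0.7``,
    unit per-visit variances with Brownian-pattern correlation
    ``Cov(Y_s, Y_t) = min(s, t)/T``; 75 patients (150 at T = 7)."""
    if not 4 <= T <= 7:
        raise ValueError("BOR presets support T in 4..7")
    t = np.arange(1, T + 1)
    Sigma = np.minimum.outer(t, t) / T
    np.fill_diagonal(Sigma, 1.0)
    cfg = ScenarioConfig(
        T=T,
        n=150 if T == 7 else 75,
        mean=LOG_RESPONSE * t / T,
        Sigma=Sigma,
        alpha=alpha,
        gamma=gamma,
    )
    return ScenarioPreset(f"bor-T{T}-a{alpha}-g{gamma}", cfg)


def two_arm_preset(
    kind: str = "fixed",
    tau: float = 0.0,
    psi: float = 0.0,
    alpha: float = -1.5,
    gamma: float = 0.0,
    lam: float = 0.0,
) -> ScenarioPreset:
    """Randomised-trial scenarios, 75 patients per arm.

    ``fixed``: T = 2, per-visit mean ``log 0.7 + delta*tau + psi``,
    per-visit variance 0.5 (correlation 0.5 between visits).
    ``bor``: T = 4, means ``f*(log 0.7 + delta*tau)`` for
    ``f = .25, .5, .75, 1``, unit variances with Brownian correlation.
    """
    if kind == "fixed":
        T = 2
        mean = np.full(T, LOG_RESPONSE)
        Sigma = 0.5 * np.array([[1.0, 0.5], [0.5, 1.0]])
        tau_vec = np.full(T, tau)
    elif kind == "bor":
        T = 4
        f = np.arange(1, T + 1) / T
        mean = LOG_RESPONSE * f
        Sigma = np.minimum.outer(np.arange(1, T + 1), np.arange(1, T + 1)) / T
        np.fill_diagonal(Sigma, 1.0)
        tau_vec = tau * f
    else:
        raise ValueError("kind must be 'fixed' or 'bor'")
    cfg = ScenarioConfig(
        T=T,
        n=75,
        arms=2,
        mean=mean,
        Sigma=Sigma,
        alpha=alpha,
        gamma=gamma,
        lam=lam,
        tau_vec=tau_vec,
        psi=psi,
        growth_truncation=(kind != "fixed"),
    )
    return ScenarioPreset(f"two-arm-{kind}-tau{tau}-psi{psi}", cfg)


_PRESETS = {
    "table1-T2-a": lambda: table1_preset(2, -1.5, 0.0),
    "table1-T2-b": lambda: table1_preset(2, -2.5, 0.2),
    "table1-T3-a": lambda: table1_preset(3, -1.5, 0.0),
    "table1-T3-b": lambda: table1_preset(3, -2.5, 0.2),
    "table1-T4-a": lambda: table1_preset(4, -1.5, 0.0),
    "table1-T4-b": lambda: table1_preset(4, -2.5, 0.2),
    "bor-T4-a": lambda: bor_preset(4, -1.5, 0.0),
    "bor-T5-a": lambda: bor_preset(5, -1.5, 0.0),
    "bor-T6-a": lambda: bor_preset(6, -1.5, 0.0),
    "bor-T7-a": lambda: bor_preset(7, -1.5, 0.0),
    "bor-T4-b": lambda: bor_preset(4, -2.5, 0.2),
    "two-arm-fixed-null": lambda: two_arm_preset("fixed", tau=0.0),
    "two-arm-bor-null": lambda: two_arm_preset("bor", tau=0.0),
}


def preset_by_name(name: str) -> ScenarioPreset:
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def _simulate_latent(sc: ScenarioConfig, n: int, rng: np.random.Generator, R=None):
    """Draw latent (untruncated) trajectories: z0, full Y matrix, and the
    new-lesion progression time X (inf when none occurs through T)."""
    z0 = rng.uniform(size=n)
    if R is None:
        R = np.zeros(n, dtype=int)
    means = np.where(
        R[:, None] == 0, sc.arm_mean(0)[None, :], sc.arm_mean(1)[None, :]
    )
    L = np.linalg.cholesky(sc.Sigma)
    Y = means + rng.standard_normal(size=(n, sc.T)) @ L.T
    Z = z0[:, None] * np.exp(Y)
    # sequential new-lesion indicators; the visit-t covariate is z_{t-1}
    X = np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    for t in range(1, sc.T + 1):
        zprev = z0 if t == 1 else Z[:, t - 2]
        p = expit(sc.alpha[t - 1] + sc.gamma[t - 1] * zprev + sc.lam[t - 1] * R)
        d = rng.uniform(size=n) < p
        hit = alive & d
        X[hit] = t
        alive &= ~d
    return z0, Y, X, R


def generate_dataset(
    sc: ScenarioConfig, seed: int | np.random.Generator = 0
) -> TrialDataset:
    """Generate one trial dataset; deterministic given the seed.

    Records are truncated at ``F = min(X, G, T)`` where ``G`` is the first
    visit with ``y >= log 1.2`` — or at ``F = min(X, T)`` when the scenario
    does not treat tumour growth as a stopping event.  For two-arm
    configurations ``n`` patients are generated per arm.
    """
    rng = np.random.default_rng(seed)
    if sc.arms == 2:
        R = np.repeat([0, 1], sc.n)
    else:
        R = np.zeros(sc.n, dtype=int)
    z0, Y, X, R = _simulate_latent(sc, len(R), rng, R)
    growth = Y >= LOG_PROGRESSION
    G = np.where(growth.any(axis=1), growth.argmax(axis=1) + 1, np.inf)
    F = np.minimum(X, sc.T)
    if sc.growth_truncation:
        F = np.minimum(F, G)
    F = F.astype(int)
    patients = []
    for i in range(len(R)):
        f = F[i]
        D = np.zeros(f, dtype=int)
        xi = None
        if np.isfinite(X[i]) and X[i] <= f:
            xi = int(X[i])
            D[xi - 1] = 1
        gi = int(G[i]) if np.isfinite(G[i]) and G[i] <= f else None
        patients.append(
            PatientRecord(
                id=f"p{i:05d}",
                arm=int(R[i]) if sc.arms == 2 else None,
                z0=float(z0[i]),
                y=Y[i, :f].copy(),
                D=D,
                X=xi,
                G=gi,
                F=f,
            )
        )
    return TrialDataset(patients)


def _latent_response(Y: np.ndarray, X: np.ndarray, spec: EndpointSpec) -> np.ndarray:
    """Endpoint indicator evaluated on latent trajectories."""
    T = spec.T
    if spec.kind == "fixed_time":
        ok = (X > T) | np.isinf(X)
        ok &= Y[:, T - 1] < spec.c_T
        if math.isfinite(spec.c) and T > 1:
            ok &= np.all(Y[:, : T - 1] < spec.c, axis=1)
        return ok
    # BOR: first h with Y_h < log 0.7, all earlier in (log 0.7, log 1.2),
    # no new lesion through h (through h+1 with confirmation)
    resp = Y[:, :T] < spec.c_T
    stable = (Y[:, :T] > spec.c_T) & (Y[:, :T] < LOG_PROGRESSION)
    out = np.zeros(len(Y), dtype=bool)
    prior_stable = np.ones(len(Y), dtype=bool)
    for h in range(1, T + 1):
        hit = prior_stable & resp[:, h - 1] & (X > h)
        if spec.kind == "bor_confirmed":
            if h >= T:
                hit = np.zeros(len(Y), dtype=bool)
            else:
                hit = hit & resp[:, h] & (X > h + 1)
        out |= hit
        prior_stable &= stable[:, h - 1]
    return out


def true_probability(
    sc: ScenarioConfig,
    spec: EndpointSpec,
    n_mc: int = 1_000_000,
    seed: int = 0,
    R: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo truth for P(endpoint = 1) under the generative law.

    Returns the estimate and its binomial standard error.  The endpoint is
    evaluated on latent (untruncated) trajectories, matching the model-based
    estimand: the probability a patient would be a responder were they
    observed through all ``T`` visits.
    """
    rng = np.random.default_rng(seed)
    arm = np.full(n_mc, R, dtype=int)
    _, Y, X, _ = _simulate_latent(sc, n_mc, rng, arm)
    s = _latent_response(Y, X, spec)
    p = float(s.mean())
    return p, math.sqrt(p * (1.0 - p) / n_mc)
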