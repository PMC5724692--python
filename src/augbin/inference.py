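"""Delta-method confidence intervals and two-arm Wald tests.

Confidence intervals for the mean response probability are built on the
logit scale: with ``l(theta) = logit P(response | theta)``,
``var l(theta-hat) ~= (grad l)' var(theta-hat) (grad l)`` and the interval
``expit(l +- z * se)`` is guaranteed to stay inside (0, 1).  The gradient
is taken by central finite differences of the functional through the full
parameter vector (mean model, covariance, new-lesion models).

For randomised trials the arm difference ``m = P(response | R=1) -
P(response | R=0)`` — each term averaging over all patients of both arms
with the arm indicator overridden — is tested with a Wald statistic on the
identity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from ._numdiff import central_gradient
from .data import EndpointSpec, TrialDataset
from .mvnfit import FittedModel
from .probability import MaugEngine, mean_response

__all__ = ["ResponseEstimate", "ComparisonResult", "delta_ci", "response_ci", "difference_test"]


@dataclass
class ResponseEstimate:
    estimate: float
    logit_se: float
    ci: tuple[float, float]
    method: str
    endpoint: str
    n: int

    @property
    def width(self) -> float:
        return self.ci[1] - self.ci[0]

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci": list(self.ci),
            "logit_se": self.logit_se,
            "method": self.method,
            "endpoint": self.endpoint,
            "n": self.n,
        }


@dataclass
class ComparisonResult:
    difference: float
    se: float
    wald_z: float
    p_value: float
    estimates: tuple[float, float]  # (control, experimental)
    method: str = ""

    def to_dict(self) -> dict:
        return {
            "difference": self.difference,
            "se": self.se,
            "z": self.wald_z,
            "p": self.p_value,
            "estimate_control": self.estimates[0],
            "estimate_experimental": self.estimates[1],
            "method": self.method,
        }


def delta_ci(
    functional: Callable[[FittedModel], float],
    fit: FittedModel,
    level: float = 0.95,
    rel_step: float = 1e-4,
    method: str = "",
    endpoint: str = "",
    n: int = 0,
) -> ResponseEstimate:
    """Logit-scale delta-method CI for a probability functional of theta."""
    p0 = float(functional(fit))
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"estimate {p0} on the boundary; logit undefined")

    def l_of(theta: np.ndarray) -> float:
        return float(logit(functional(fit.replace_theta(theta))))

    g = central_gradient(l_of, fit.theta, rel_step=rel_step)
    var = float(g @ fit.vcov @ g)
    if var < 0:
        var = 0.0
    se = math.sqrt(var)
    z = norm.ppf(0.5 + level / 2.0)
    l0 = logit(p0)
    ci = (float(expit(l0 - z * se)), float(expit(l0 + z * se)))
    return ResponseEstimate(p0, se, ci, method, endpoint, n or fit.n)


def response_ci(
    ds: TrialDataset,
    fit: FittedModel,
    spec: EndpointSpec,
    engine: str = "maug",
    level: float = 0.95,
    **kwargs,
) -> ResponseEstimate:
    """CI for the mean response probability under the chosen engine."""
    if engine == "maug":
        eng = MaugEngine(ds, spec)
        functional = eng.mean
    else:
        # a fixed QMC point set keeps finite-difference gradients coherent
        kwargs.setdefault("n_qmc", 2048)
        functional = lambda f: mean_response(ds, f, spec, engine, **kwargs)[0]
    return delta_ci(
        functional,
        fit,
        level=level,
        method=engine,
        endpoint=spec.kind,
        n=ds.n,
    )


def difference_test(
    ds: TrialDataset,
    fit: FittedModel,
    spec: EndpointSpec,
    engine: str = "maug",
    rel_step: float = 1e-4,
    **kwargs,
) -> ComparisonResult:
    """Wald test of a zero arm difference in mean response probability."""
    if ds.n_arms != 2:
        raise ValueError("difference_test requires a two-arm dataset")

    if engine == "maug":
        eng0 = MaugEngine(ds, spec, arm=0)
        eng1 = MaugEngine(ds, spec, arm=1)

        def m_of_fit(f: FittedModel) -> tuple[float, float, float]:
            p1, p0 = eng1.mean(f), eng0.mean(f)
            return p1 - p0, p0, p1

    else:
        kwargs.setdefault("n_qmc", 2048)

        def m_of_fit(f: FittedModel) -> tuple[float, float, float]:
            p1 = mean_response(ds, f, spec, engine, arm=1, **kwargs)[0]
            p0 = mean_response(ds, f, spec, engine, arm=0, **kwargs)[0]
            return p1 - p0, p0, p1

    m0, p0, p1 = m_of_fit(fit)
    g = central_gradient(
        lambda th: m_of_fit(fit.replace_theta(th))[0], fit.theta, rel_step=rel_step
    )
    var = max(float(g @ fit.vcov @ g), 0.0)
    se = math.sqrt(var)
    z = m0 / se if se > 0 else math.inf * np.sign(m0)
    p = 2.0 * norm.sf(abs(z))
    return ComparisonResult(m0, se, float(z), float(p), (p0, p1), method=engine)
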