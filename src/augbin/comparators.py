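"""Comparator analyses: the plain binary method, Karrison's continuous
tumour-change test, and a permutation check of empirical test size.

The binary method dichotomises each patient's outcome (responder or not,
with early progressors counted as non-responders) and uses a Wilson score
interval in single-arm trials or a baseline-adjusted logistic regression
in randomised trials.  Karrison's approach analyses a continuous summary
of tumour change directly in a baseline-adjusted linear model.
"""

from __future__ import annotations

import math
from typing import Callable, Union

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .data import (
    LOG_PROGRESSION,
    EndpointSpec,
    PatientRecord,
    TrialDataset,
    classify_bor,
    classify_fixed_time,
)
from .inference import ComparisonResult, ResponseEstimate

__all__ = [
    "wilson_interval",
    "binary_estimate",
    "binary_arm_test",
    "karrison_outcome",
    "karrison_test",
    "permutation_type1",
]


def classify(p: PatientRecord, spec: EndpointSpec) -> int:
    if spec.kind == "fixed_time":
        return classify_fixed_time(p, spec)
    return classify_bor(p, spec)


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes out of range")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    # the exact Wilson bounds at the boundaries; guard against round-off
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def binary_estimate(
    ds: TrialDataset, spec: EndpointSpec, level: float = 0.95
) -> ResponseEstimate:
    """Binary (dichotomised) response-rate estimate with a Wilson CI."""
    s = sum(classify(p, spec) for p in ds.patients)
    n = ds.n
    ci = wilson_interval(s, n, level)
    phat = s / n
    p_adj = min(max(phat, 0.5 / n), 1 - 0.5 / n)  # boundary nudge for the logit se
    se = 1.0 / math.sqrt(n * p_adj * (1 - p_adj))
    return ResponseEstimate(phat, se, ci, "bin", spec.kind, n)


def binary_arm_test(ds: TrialDataset, spec: EndpointSpec) -> ComparisonResult:
    """Two-arm binary comparison: logistic regression of the response
    indicator on arm and baseline tumour size; Wald test of the arm term."""
    if ds.n_arms != 2:
        raise ValueError("binary_arm_test requires two arms")
    y = np.array([classify(p, spec) for p in ds.patients])
    if y.min() == y.max():
        raise RuntimeError("all outcomes identical; logistic model degenerate")
    R = ds.arms
    z0 = np.array([p.z0 for p in ds.patients])
    X = np.column_stack([np.ones(ds.n), R, z0])
    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    params = np.asarray(fit.params)
    if not np.all(np.isfinite(fit.bse)) or abs(params[1]) > 20:
        raise RuntimeError("separation in the binary comparison model")
    z = params[1] / fit.bse[1]
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    p0 = float(y[R == 0].mean())
    p1 = float(y[R == 1].mean())
    return ComparisonResult(p1 - p0, float(fit.bse[1]), float(z), float(p), (p0, p1), "bin")


def karrison_outcome(p: PatientRecord) -> float:
    """Continuous outcome for Karrison's test: the worst (highest) observed
    log ratio when the first follow-up observation is already a
    progression, otherwise the best (lowest) log ratio strictly before
    progression."""
    if p.F < 1:
        raise ValueError(f"patient {p.id} has no follow-up data")
    first_prog = (p.X == 1) or (p.G == 1)
    if first_prog:
        return float(p.y.max())
    prog = min(x for x in (p.X, p.G) if x is not None) if (p.X or p.G) else None
    upto = p.F if prog is None else min(p.F, prog - 1)
    return float(p.y[:upto].min())


def karrison_test(ds: TrialDataset) -> ComparisonResult:
    """Arm effect on the continuous tumour-change outcome, tested in a
    baseline-adjusted ordinary least squares model."""
    if ds.n_arms != 2:
        raise ValueError("karrison_test requires two arms")
    y = np.array([karrison_outcome(p) for p in ds.patients])
    R = ds.arms
    z0 = np.array([p.z0 for p in ds.patients])
    if np.var(y) == 0:
        raise ValueError("degenerate outcome variance")
    X = np.column_stack([np.ones(ds.n), R, z0])
    fit = sm.OLS(y, X).fit()
    m0 = float(y[R == 0].mean())
    m1 = float(y[R == 1].mean())
    return ComparisonResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.tvalues[1]),
        float(fit.pvalues[1]), (m0, m1), "karrison",
    )


def _relabel(ds: TrialDataset, arms: np.ndarray) -> TrialDataset:
    import copy

    out = []
    for p, a in zip(ds.patients, arms):
        q = copy.copy(p)
        q.arm = int(a)
        out.append(q)
    return TrialDataset(out)


def permutation_type1(
    ds: TrialDataset,
    analysis: Union[str, Callable[[TrialDataset], float]],
    n_perm: int = 1000,
    seed: int = 0,
    spec: EndpointSpec | None = None,
    alpha: float = 0.05,
) -> float:
    """Empirical size of a two-arm test under random relabelling.

    ``analysis`` is either a callable mapping a dataset to a two-sided
    p-value, or one of ``"bin"``/``"karrison"``.  Returns the fraction of
    label-shuffled replicates rejected at ``alpha``.
    """
    if isinstance(analysis, str):
        if analysis == "bin":
            if spec is None:
                raise ValueError("spec required for the binary analysis")
            analysis_fn = lambda d: binary_arm_test(d, spec).p_value
        elif analysis == "karrison":
            analysis_fn = lambda d: karrison_test(d).p_value
        else:
            raise ValueError(f"unknown analysis tag {analysis!r}")
    else:
        analysis_fn = analysis
    rng = np.random.default_rng(seed)
    base = ds.arms
    hits = 0
    valid = 0
    for _ in range(n_perm):
        arms = rng.permutation(base)
        try:
            pval = analysis_fn(_relabel(ds, arms))
        except RuntimeError:
            continue
        valid += 1
        hits += pval < alpha
    if valid == 0:
        raise RuntimeError("no permutation replicate produced a valid test")
    return hits / valid
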