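"""Simulation studies: operating characteristics and power curves.

Each replicate generates a fresh trial from a scenario preset, analyses it
with the requested methods and records the estimate, confidence interval
and (for randomised trials) the test decision.  Replicates are seeded
individually from the master seed, so results are bit-identical for any
worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ScenarioPreset, generate_dataset, true_probability, two_arm_preset
from .comparators import binary_arm_test, binary_estimate, karrison_test
from .data import EndpointSpec
from .inference import difference_test, response_ci
from .mvnfit import fit_model

__all__ = ["run_single_arm_study", "run_power_study", "sample_size_equivalent"]

logger = logging.getLogger(__name__)

EAUGBIN_GRADIENT_QMC = 2048


def _rep_seed(master: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, rep]))


def _single_arm_replicate(preset: ScenarioPreset, spec: EndpointSpec,
                          methods: Sequence[str], master_seed: int, rep: int):
    ds = generate_dataset(preset.config, seed=_rep_seed(master_seed, rep))
    out = {}
    try:
        if "bin" in methods:
            r = binary_estimate(ds, spec)
            out["bin"] = (r.estimate, *r.ci)
        model_methods = [m for m in methods if m in ("maug", "eaugbin")]
        if model_methods:
            fit = fit_model(ds, spec.T)
            for m in model_methods:
                kw = {"n_qmc": EAUGBIN_GRADIENT_QMC} if m == "eaugbin" else {}
                r = response_ci(ds, fit, spec, engine=m, **kw)
                out[m] = (r.estimate, *r.ci)
    except Exception as err:
        logger.warning("replicate %d failed: %s", rep, err)
        return rep, None
    return rep, out


def run_single_arm_study(
    preset: ScenarioPreset,
    spec: EndpointSpec,
    methods: Sequence[str] = ("bin", "eaugbin", "maug"),
    n_reps: int = 1000,
    seed: int = 0,
    workers: int = 1,
    truth: Optional[float] = None,
    n_mc_truth: int = 1_000_000,
) -> pd.DataFrame:
    """Estimate mean probability, coverage, CI width and width reduction
    versus the binary method over simulated replicates of a single-arm
    trial.  Replicates where any analysis fails are excluded (their rate
    is reported in the frame attrs); more than 10% failures aborts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    if truth is None:
        truth, _ = true_probability(preset.config, spec, n_mc=n_mc_truth, seed=seed)
    args = [(preset, spec, methods, seed, r) for r in range(n_reps)]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(_single_arm_replicate)(*a) for a in args
        )
    else:
        results = [_single_arm_replicate(*a) for a in args]
    results = sorted(results)
    ok = [r for _, r in results if r is not None]
    fail_rate = 1.0 - len(ok) / n_reps
    if fail_rate > 0.10:
        raise RuntimeError(f"{fail_rate:.0%} of replicates failed")

    rows = []
    widths = {m: np.array([r[m][2] - r[m][1] for r in ok]) for m in methods}
    for m in methods:
        est = np.array([r[m][0] for r in ok])
        lo = np.array([r[m][1] for r in ok])
        hi = np.array([r[m][2] for r in ok])
        cover = (lo <= truth) & (truth <= hi)
        row = {
            "method": m,
            "mean_estimate": est.mean(),
            "coverage": cover.mean(),
            "coverage_se": float(np.sqrt(cover.mean() * (1 - cover.mean()) / len(ok))),
            "mean_width": widths[m].mean(),
        }
        if m != "bin" and "bin" in methods:
            red = 1.0 - widths[m] / widths["bin"]
            row["width_reduction_pct"] = 100.0 * red.mean()
            row["width_reduction_se"] = 100.0 * red.std(ddof=1) / np.sqrt(len(ok))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs.update(
        truth=truth, n_reps=n_reps, n_ok=len(ok), failure_rate=fail_rate, seed=seed
    )
    return df


def _two_arm_replicate(preset: ScenarioPreset, spec: EndpointSpec,
                       methods: Sequence[str], master_seed: int, rep: int,
                       alpha: float):
    ds = generate_dataset(preset.config, seed=_rep_seed(master_seed, rep))
    out = {}
    fit = None
    for m in methods:
        try:
            if m == "bin":
                p = binary_arm_test(ds, spec).p_value
            elif m == "karrison":
                p = karrison_test(ds).p_value
            else:
                if fit is None:
                    fit = fit_model(ds, spec.T)
                kw = {"n_qmc": EAUGBIN_GRADIENT_QMC} if m == "eaugbin" else {}
                p = difference_test(ds, fit, spec, engine=m, **kw).p_value
            out[m] = bool(p < alpha)
        except Exception as err:
            logger.warning("replicate %d, method %s failed: %s", rep, m, err)
            out[m] = None
    return rep, out


def run_power_study(
    grid: Iterable[tuple[str, ScenarioPreset]],
    spec: EndpointSpec,
    methods: Sequence[str] = ("bin", "maug"),
    n_reps: int = 1000,
    seed: int = 0,
    workers: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection fraction at level ``alpha`` per (grid point, method).

    ``grid`` pairs a label (e.g. the tau value) with a two-arm preset; the
    null point doubles as an empirical type-I error estimate.
    """
    frames = []
    for label, preset in grid:
        args = [(preset, spec, methods, seed, r, alpha) for r in range(n_reps)]
        if workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=workers)(
                delayed(_two_arm_replicate)(*a) for a in args
            )
        else:
            results = [_two_arm_replicate(*a) for a in args]
        results = sorted(results)
        for m in methods:
            dec = [r[m] for _, r in results if r[m] is not None]
            rate = float(np.mean(dec)) if dec else np.nan
            frames.append(
                {
                    "grid": label,
                    "method": m,
                    "rejection_rate": rate,
                    "rejection_se": float(np.sqrt(rate * (1 - rate) / len(dec)))
                    if dec
                    else np.nan,
                    "n_valid": len(dec),
                }
            )
    df = pd.DataFrame(frames)
    df.attrs.update(n_reps=n_reps, seed=seed, alpha=alpha)
    return df


def tau_grid(kind: str, taus: Sequence[float], psi: float = 0.0,
             **preset_kwargs) -> list[tuple[float, ScenarioPreset]]:
    """Convenience: a power-study grid over the arm-difference parameter."""
    return [(t, two_arm_preset(kind, tau=t, psi=psi, **preset_kwargs)) for t in taus]


def sample_size_equivalent(width_reduction: float) -> float:
    """Extra sample size (percent) the binary method needs to match a CI
    width smaller by ``width_reduction`` (CI width scales as 1/sqrt(n)):
    ``(1/(1-r))^2 - 1``, in percent."""
    if not 0 <= width_reduction < 1:
        raise ValueError("width_reduction must be in [0, 1)")
    return 100.0 * ((1.0 / (1.0 - width_reduction)) ** 2 - 1.0)
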