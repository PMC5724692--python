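"""Trial data containers, CSV input/output, and binary endpoint classification.

Tumour burden is summarised per visit as the sum of longest diameters of
target lesions ("tumour size").  Patients are followed until progression or
a planned maximum of ``T`` post-baseline visits.  Progression occurs either
through new lesions appearing (a new-lesion progression, time ``X``) or
through a >=20% increase in tumour size relative to baseline (a
tumour-growth progression, time ``G``).  All modelling works on the log
tumour size ratio ``y_t = log(z_t / z_0)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOG_RESPONSE",
    "LOG_PROGRESSION",
    "PatientRecord",
    "EndpointSpec",
    "TrialDataset",
    "read_trial_csv",
    "write_trial_csv",
    "classify_fixed_time",
    "classify_bor",
]

logger = logging.getLogger(__name__)

#: log(0.7): at least 30% shrinkage from baseline (CR/PR boundary).
LOG_RESPONSE = math.log(0.7)
#: log(1.2): at least 20% growth from baseline (PD boundary).
LOG_PROGRESSION = math.log(1.2)

CSV_COLUMNS = ["patient_id", "arm", "visit", "tumour_size", "new_lesion"]


@dataclass
class PatientRecord:
    """One patient's observed trajectory up to their last follow-up visit.

    Attributes
    ----------
    id:
        Patient identifier (unique within a dataset).
    arm:
        Arm indicator R (0 control, 1 experimental), or ``None`` for a
        single-arm trial.
    z0:
        Baseline tumour size (positive).
    y:
        Log tumour size ratios ``y_t = log(z_t/z_0)`` for visits
        ``t = 1..F``.
    D:
        New-lesion progression indicators for visits ``1..F``;
        ``D[t-1] == 1`` exactly at ``t == X``.
    X:
        Visit of new-lesion progression, or ``None``.
    G:
        Visit of tumour-growth progression (first observed ``t`` with
        ``y_t >= log 1.2``), or ``None``.
    F:
        Last observed visit.  Always ``<= min(X, T)`` (no measurements
        after a new lesion); whether growth progression also ends
        follow-up (``F <= G``) depends on the trial's design.
    """

    id: str
    z0: float
    y: np.ndarray
    D: np.ndarray
    arm: Optional[int] = None
    X: Optional[int] = None
    G: Optional[int] = None
    F: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.D = np.asarray(self.D, dtype=int)
        if self.F == 0:
            self.F = len(self.y)
        if len(self.y) != self.F or len(self.D) != self.F:
            raise ValueError(
                f"patient {self.id}: y and D must have length F={self.F}"
            )
        if self.z0 <= 0:
            raise ValueError(f"patient {self.id}: non-positive baseline size")
        if self.X is not None and (self.X > self.F or self.D[self.X - 1] != 1):
            raise ValueError(f"patient {self.id}: inconsistent new-lesion time")

    @property
    def sizes(self) -> np.ndarray:
        """Observed tumour sizes z_1..z_F (baseline excluded)."""
        return self.z0 * np.exp(self.y)

    def z_prev(self, t: int) -> float:
        """Tumour size at visit t-1 (the covariate of the visit-t
        new-lesion model); ``t`` is 1-based."""
        if t == 1:
            return self.z0
        return float(self.z0 * math.exp(self.y[t - 2]))


@dataclass
class EndpointSpec:
    """Definition of the response endpoint being analysed.

    Parameters
    ----------
    kind:
        ``"fixed_time"`` (responder status at visit ``T``), ``"bor"``
        (best observed response before progression), or
        ``"bor_confirmed"`` (response at two consecutive visits).
    T:
        Maximum number of post-baseline visits.
    c_T:
        Response threshold on the log-ratio scale (default ``log 0.7``,
        i.e. at least 30% shrinkage).
    c:
        Intermediate progression threshold for the fixed-time endpoint.
        ``inf`` places no constraint on intermediate visits; ``log 1.2``
        additionally requires no tumour-growth progression before ``T``.
        Ignored for BOR endpoints, whose regions carry the log(0.7)/log(1.2)
        boundaries directly.
    """

    kind: Literal["fixed_time", "bor", "bor_confirmed"] = "fixed_time"
    T: int = 2
    c_T: float = LOG_RESPONSE
    c: float = math.inf

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.c_T > self.c:
            raise ValueError("c_T must not exceed c")
        if self.kind not in ("fixed_time", "bor", "bor_confirmed"):
            raise ValueError(f"unknown endpoint kind {self.kind!r}")


@dataclass
class TrialDataset:
    """A collection of patient records from a single- or two-arm trial."""

    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids")

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def n_arms(self) -> int:
        arms = {p.arm for p in self.patients}
        return 1 if arms == {None} else len(arms)

    @property
    def arms(self) -> np.ndarray:
        """Arm indicators as an array (0/1); zeros for a single-arm trial."""
        return np.array(
            [0 if p.arm is None else p.arm for p in self.patients], dtype=int
        )

    def subset(self, arm: int) -> "TrialDataset":
        return TrialDataset([p for p in self.patients if p.arm == arm])


def _assemble_patient(
    pid: str, group: pd.DataFrame, eps: Optional[float]
) -> PatientRecord:
    visits = group["visit"].to_numpy()
    if visits[0] != 0:
        raise ValueError(f"patient {pid}: missing baseline (visit 0)")
    if not np.array_equal(visits, np.arange(len(visits))):
        raise ValueError(f"patient {pid}: visits must be consecutive from 0")
    sizes = group["tumour_size"].to_numpy(dtype=float)
    if np.any(sizes < 0) or sizes[0] <= 0:
        raise ValueError(f"patient {pid}: non-positive tumour size")
    if np.any(sizes == 0):
        # Complete response: tumour size 0 has log ratio -inf; substitute an
        # extreme but finite value so the normal model remains usable.
        if eps is None:
            raise ValueError(f"patient {pid}: zero size with no positive sizes")
        logger.info(
            "patient %s: complete response (size 0) set to %g", pid, eps
        )
        sizes = np.where(sizes == 0, eps, sizes)
    z0 = sizes[0]
    y = np.log(sizes[1:] / z0)
    D = group["new_lesion"].to_numpy(dtype=int)[1:]
    if np.any((D != 0) & (D != 1)):
        raise ValueError(f"patient {pid}: new_lesion must be 0/1")

    X = int(np.argmax(D) + 1) if D.any() else None
    growth = y >= LOG_PROGRESSION
    G = int(np.argmax(growth) + 1) if growth.any() else None
    F = len(y)
    if X is not None and F > X:
        raise ValueError(
            f"patient {pid}: measurements recorded after the new lesion at visit {X}"
        )
    arm_vals = group["arm"].dropna().unique() if "arm" in group else []
    arm = int(arm_vals[0]) if len(arm_vals) else None
    return PatientRecord(id=str(pid), arm=arm, z0=z0, y=y, D=D, X=X, G=G, F=F)


def read_trial_csv(path) -> TrialDataset:
    """Read a long-format tumour-measurement table.

    Expected columns: ``patient_id, arm, visit, tumour_size, new_lesion``
    with visit 0 the baseline.  ``arm`` may be blank throughout for a
    single-arm trial.  Tumour-growth progression (``G``) is derived as the
    first visit with a size ratio >= 1.2; rows after a new-lesion
    progression are rejected (rows after growth progression are legal,
    since not every design stops follow-up there).
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "arm"]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if "arm" not in df.columns:
        df["arm"] = np.nan
    df = df.sort_values(["patient_id", "visit"], kind="stable")
    pos = df.loc[df["tumour_size"] > 0, "tumour_size"]
    eps = float(pos.min()) / 10.0 if len(pos) else None
    patients = [
        _assemble_patient(pid, g, eps) for pid, g in df.groupby("patient_id", sort=True)
    ]
    return TrialDataset(patients)


def write_trial_csv(ds: TrialDataset, path) -> None:
    """Write a dataset in the same long-format schema read_trial_csv expects."""
    rows = []
    for p in ds.patients:
        arm = "" if p.arm is None else p.arm
        rows.append((p.id, arm, 0, p.z0, 0))
        sizes = p.sizes
        for t in range(1, p.F + 1):
            rows.append((p.id, arm, t, sizes[t - 1], int(p.D[t - 1])))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def classify_fixed_time(p: PatientRecord, spec: EndpointSpec) -> int:
    """Observed binary responder status at the fixed visit ``spec.T``.

    A responder has no new-lesion progression through ``T``, log ratio at
    ``T`` strictly below ``c_T``, and (when ``c`` is finite) no
    tumour-growth progression before ``T``.  Patients unobserved at ``T``
    (progressed or dropped out earlier) count as non-responders under the
    binary analysis.
    """
    if spec.kind != "fixed_time":
        raise ValueError("spec.kind must be 'fixed_time'")
    T = spec.T
    if p.F < T:
        return 0
    if p.X is not None and p.X <= T:
        return 0
    if math.isfinite(spec.c) and np.any(p.y[: T - 1] >= spec.c):
        return 0
    return int(p.y[T - 1] < spec.c_T)


def classify_bor(p: PatientRecord, spec: EndpointSpec) -> int:
    """Observed best-overall-response indicator.

    Without confirmation: responder iff some observed visit ``t`` before any
    progression has ``y_t < log 0.7`` with all earlier visits in the
    stable-disease band ``(log 0.7, log 1.2)``.  With confirmation the
    response must hold at two consecutive visits before progression.
    """
    if spec.kind not in ("bor", "bor_confirmed"):
        raise ValueError("spec.kind must be 'bor' or 'bor_confirmed'")
    limit = min(p.F, (p.X - 1) if p.X is not None else p.F, spec.T)
    h = None
    for t in range(1, limit + 1):
        yt = p.y[t - 1]
        if yt < spec.c_T:
            h = t
            break
        if yt >= LOG_PROGRESSION:
            return 0  # tumour-growth progression before any response
    if h is None:
        return 0
    if spec.kind == "bor":
        return 1
    # confirmation: next visit must also be a response, before progression
    if h + 1 <= limit and p.y[h] < spec.c_T:
        return 1
    return 0
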