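import numpy as np

from augbin.data import LOG_PROGRESSION, PatientRecord


def make_patient(y, D=None, X=None, z0=1.0, pid="p1", arm=None):
    """Build a PatientRecord from a log-ratio trajectory, deriving the
    growth-progression time from the values."""
    y = np.asarray(y, dtype=float)
    if D is None:
        D = np.zeros(len(y), dtype=int)
        if X is not None:
            D[X - 1] = 1
    growth = y >= LOG_PROGRESSION
    G = int(np.argmax(growth) + 1) if growth.any() else None
    return PatientRecord(id=pid, z0=z0, y=y, D=D, X=X, G=G, F=len(y), arm=arm)
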