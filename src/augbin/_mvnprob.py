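"""Low-level multivariate-normal region probabilities, vectorised over means.

Two routes are provided:

* a sequential-conditioning quasi-Monte-Carlo transform (the Genz–Bretz
  construction: map the rectangle integral to the unit cube through the
  Cholesky factor, then average over a Sobol' point set), which handles
  arbitrary rectangles and also carries extra integrand factors for the
  extended augmented binary method;
* a tensor Gauss–Legendre path for regions whose leading coordinates are
  bounded intervals and whose final coordinate is a lower tail
  ``(-inf, u]`` — the shape of every best-observed-response region — where
  the last coordinate is integrated analytically through the conditional
  normal distribution.

Everything is vectorised over patients: all patients share the covariance
matrix and differ only in their mean vectors.
"""

from __future__ import annotations

import functools

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.linalg import cholesky, solve_triangular
from scipy.special import ndtr, ndtri

_TINY = 1e-14
_SOBOL_SEED = 987654321  # fixed: probability evaluations must be reproducible


@functools.lru_cache(maxsize=64)
def _sobol_points(dim: int, n: int) -> np.ndarray:
    from scipy.stats import qmc

    eng = qmc.Sobol(d=dim, scramble=True, seed=_SOBOL_SEED)
    return eng.random(n)


@functools.lru_cache(maxsize=32)
def _gl_nodes(m: int) -> tuple[np.ndarray, np.ndarray]:
    return leggauss(m)


def _phi_diff(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return ndtr(hi) - ndtr(lo)


def mvn_region_prob(
    means: np.ndarray,
    cov: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n_qmc: int = 512,
    gl_nodes: int = 10,
) -> np.ndarray:
    """P(lower < Y < upper) for Y ~ N(mean_i, cov), one value per mean row.

    Coordinates with ``(-inf, +inf)`` bounds are marginalised away exactly.
    The remaining rectangle is routed to a closed form (one dimension), the
    Gauss–Legendre conditional path (bounded leading coordinates, lower-tail
    last coordinate) or the general QMC transform.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    cov = np.asarray(cov, dtype=float)
    keep = ~(np.isneginf(lower) & np.isposinf(upper))
    if not keep.any():
        return np.ones(means.shape[0])
    means = means[:, keep]
    lower, upper = lower[keep], upper[keep]
    cov = cov[np.ix_(keep, keep)]
    d = lower.size

    if d == 1:
        s = np.sqrt(cov[0, 0])
        return _phi_diff((lower[0] - means[:, 0]) / s, (upper[0] - means[:, 0]) / s)

    bounded_head = bool(np.all(np.isfinite(lower[:-1]) & np.isfinite(upper[:-1])))
    tail_last = bool(np.isneginf(lower[-1]) and np.isfinite(upper[-1]))
    if bounded_head and tail_last:
        return _gl_cond_prob(means, cov, lower, upper, gl_nodes)
    pts = _sobol_points(max(d - 1, 1), n_qmc)
    return np.clip(_genz_transform(means, cov, lower, upper, pts), 0.0, 1.0)


def _gl_cond_prob(means, cov, lower, upper, m) -> np.ndarray:
    """Tensor Gauss–Legendre over the bounded leading box; the lower-tail
    last coordinate is integrated analytically through its conditional
    normal distribution given the leading block."""
    d = lower.size
    k = d - 1
    A = cov[:k, :k]
    b = np.linalg.solve(A, cov[:k, k])          # regression coefs of Y_d on head
    s_cond = np.sqrt(cov[k, k] - cov[:k, k] @ b)
    La = cholesky(A, lower=True)
    logdet = 2.0 * np.log(np.diag(La)).sum()

    x, w = _gl_nodes(m)
    half = 0.5 * (upper[:k] - lower[:k])
    mid = 0.5 * (upper[:k] + lower[:k])
    grids = np.meshgrid(*[mid[j] + half[j] * x for j in range(k)], indexing="ij")
    Y = np.stack([g.ravel() for g in grids], axis=1)          # (K, k)
    wgrids = np.meshgrid(*[half[j] * w for j in range(k)], indexing="ij")
    W = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)  # (K,)

    R = Y[None, :, :] - means[:, None, :k]                    # (n, K, k)
    Z = solve_triangular(La, R.reshape(-1, k).T, lower=True).T.reshape(R.shape)
    quad = np.einsum("nkj,nkj->nk", Z, Z)
    dens = np.exp(-0.5 * (quad + logdet + k * np.log(2.0 * np.pi)))  # (n, K)

    m_cond = means[:, None, k] + np.einsum("nkj,j->nk", R, b)  # (n, K)
    tail = ndtr((upper[k] - m_cond) / s_cond)
    return np.clip((dens * tail) @ W, 0.0, 1.0)


def _genz_transform(means, cov, lower, upper, pts, factor=None):
    """Sequential-conditioning QMC estimate of
    ``E[ prod_j factor(j, Y_j) ; lower < Y < upper ]``.

    ``pts`` is a (P, d-1) unit-cube point set.  ``factor(j, yj)`` — if
    given — is called for realised coordinates ``j = 0..d-2`` with ``yj``
    of shape (n, P) holding the actual coordinate values, and must return
    a multiplicative term of the same shape.  The last coordinate is never
    realised (its contribution enters only through the interval
    probability), so factors may depend on coordinates 0..d-2 only.
    """
    means = np.atleast_2d(means)
    n = means.shape[0]
    d = lower.size
    L = cholesky(cov, lower=True)
    P = pts.shape[0]

    a = lower[None, :] - means   # (n, d)
    b = upper[None, :] - means

    ystar = np.empty((d - 1, n, P)) if d > 1 else None
    f = np.ones((n, P))
    lo = hi = None
    for j in range(d):
        part = (
            np.einsum("k,knp->np", L[j, :j], ystar[:j]) if j > 0 else 0.0
        )
        with np.errstate(invalid="ignore"):
            lo = np.where(
                np.isneginf(a[:, j, None]), 0.0, ndtr((a[:, j, None] - part) / L[j, j])
            )
            hi = np.where(
                np.isposinf(b[:, j, None]), 1.0, ndtr((b[:, j, None] - part) / L[j, j])
            )
        f = f * (hi - lo)
        if j < d - 1:
            u = pts[:, j][None, :]
            q = np.clip(lo + u * (hi - lo), _TINY, 1.0 - _TINY)
            z = ndtri(q)
            ystar[j] = z
            if factor is not None:
                yj = means[:, j, None] + part + L[j, j] * z
                f = f * factor(j, yj)
    return f.mean(axis=1)


def weighted_region_integral(
    means: np.ndarray,
    cov: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    factor,
    n_qmc: int = 1024,
) -> np.ndarray:
    """Rectangle integral of the MVN density times per-coordinate factors.

    The workhorse of the extended augmented binary method: ``factor(j, yj)``
    supplies the no-new-lesion logistic term that depends on the realised
    log ratio at coordinate ``j`` (i.e. the tumour size entering the next
    visit's new-lesion model).  Factors may depend on coordinates up to
    ``d-2`` only; the factor tied to the baseline size is the caller's to
    apply outside.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    pts = _sobol_points(max(d - 1, 1), n_qmc)
    out = _genz_transform(means, np.asarray(cov, float), lower, upper, pts, factor=factor)
    return np.clip(out, 0.0, 1.0)
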