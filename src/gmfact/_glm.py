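"""Batched IRLS for many GLMs sharing one design matrix.

Initialization fits m column-wise GLMs (shared design X or U) and n
row-wise GLMs (shared design Z); AIRWLS performs one penalized Fisher
scoring step per row/column with shared designs [X, U] and [Z, V].  All of
these share the design across fits and differ only in response, weights,
offset and mask, so the normal matrices for every fit are formed in one
einsum and solved with a single batched ``np.linalg.solve``.

Results are independent of the order in which the fits are listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GMFNumericalError
from .families import FamilySpec

logger = logging.getLogger(__name__)

_RIDGE_JITTER = 1e-10


@dataclass
class ManyGLMResult:
    coef: np.ndarray          # (n_fits, k)
    converged: np.ndarray     # (n_fits,) bool
    n_fallback: int           # fits replaced by the OLS fallback
    n_iter: int


def _batched_wls(
    A: np.ndarray,
    Z: np.ndarray,
    W: np.ndarray,
    ridge: Optional[np.ndarray],
) -> np.ndarray:
    """Solve (A^T W_f A + diag(ridge)) b_f = A^T W_f z_f for every fit f.

    A: (n_obs, k); Z, W: (n_obs, n_fits).  Returns (n_fits, k).
    """
    k = A.shape[1]
    XtWX = np.einsum("oi,of,oj->fij", A, W, A, optimize=True)
    XtWz = np.einsum("oi,of,of->fi", A, W, Z, optimize=True)
    eye = np.eye(k)
    if ridge is not None:
        XtWX = XtWX + np.diag(ridge)
    XtWX = XtWX + _RIDGE_JITTER * eye
    try:
        return np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # rank-deficient fits: fall back to least-squares per fit
        out = np.empty((Z.shape[1], k))
        for f in range(Z.shape[1]):
            out[f] = np.linalg.lstsq(XtWX[f], XtWz[f], rcond=None)[0]
        return out


def ols_transformed(
    Y: np.ndarray,
    A: np.ndarray,
    family: FamilySpec,
    weights: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    offset: Optional[np.ndarray] = None,
    ridge: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Weighted least squares on the link-transformed response.

    The fast path of the structured initialization: counts use the started
    log transform log(y + 1/2).  Returns coefficients (n_fits, k).
    """
    Y = np.asarray(Y, dtype=float)
    n_obs, n_fits = Y.shape
    w = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
    if mask is not None:
        w = np.where(mask, w, 0.0)
        Y = np.where(mask, Y, 0.0)  # placeholder never weighted in
    z = family.init_transform(Y)
    if offset is not None:
        z = z - offset
    return _batched_wls(A, z, w, ridge)


def fit_glm_many(
    Y: np.ndarray,
    A: np.ndarray,
    family: FamilySpec,
    weights: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    offset: Optional[np.ndarray] = None,
    coef0: Optional[np.ndarray] = None,
    ridge: Optional[np.ndarray] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    fallback: bool = True,
) -> ManyGLMResult:
    """Fit n_fits GLMs sharing design ``A`` by vectorized Fisher scoring.

    Y, weights, mask, offset: (n_obs, n_fits); A: (n_obs, k).  ``ridge``
    (length k) adds a quadratic penalty on selected coefficients (the
    latent blocks in AIRWLS).  With ``max_iter=1`` and ``coef0`` this is a
    single penalized Fisher scoring step from ``coef0``.

    Fits that have not converged after ``max_iter`` iterations are replaced
    by the OLS-on-transformed-response fallback and counted.
    """
    Y = np.asarray(Y, dtype=float)
    n_obs, n_fits = Y.shape
    k = A.shape[1]
    if k == 0:
        return ManyGLMResult(np.zeros((n_fits, 0)), np.ones(n_fits, bool), 0, 0)
    w = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
    obs = np.ones(Y.shape, bool) if mask is None else np.asarray(mask, dtype=bool)
    w = np.where(obs, w, 0.0)
    y = np.where(obs, Y, 0.0)
    off = np.zeros_like(Y) if offset is None else np.asarray(offset, dtype=float)

    if coef0 is None:
        coef = ols_transformed(y, A, family, w, obs, off, ridge)
    else:
        coef = np.array(coef0, dtype=float, copy=True)

    converged = np.zeros(n_fits, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ coef.T + off
        mu, _ = family.mean_from_eta(eta)
        nu = family.variance(mu)
        dg = family.link.deriv(mu)
        Wk = w / (nu * dg**2)
        z = (eta - off) + (y - mu) * dg
        # masked entries already carry zero weight
        new = _batched_wls(A, z, Wk, ridge)
        if not np.all(np.isfinite(new)):
            bad = ~np.isfinite(new).all(axis=1)
            new[bad] = coef[bad]
            converged[bad] = False
        delta = np.max(
            np.abs(new - coef) / np.maximum(1.0, np.abs(coef)), axis=1
        )
        coef = new
        converged = delta < tol
        if converged.all():
            break

    n_fallback = 0
    if fallback and max_iter > 1 and not converged.all():
        stale = ~converged
        n_fallback = int(stale.sum())
        logger.info(
            "IRLS did not converge for %d of %d fits; using the OLS fallback",
            n_fallback,
            n_fits,
        )
        ols = ols_transformed(y, A, family, w, obs, off, ridge)
        coef[stale] = ols[stale]

    if not np.all(np.isfinite(coef)):
        raise GMFNumericalError("non-finite GLM coefficients in batched IRLS")
    return ManyGLMResult(coef, converged, n_fallback, it)
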