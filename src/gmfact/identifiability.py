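"""Projection onto the identifiability-constraint space.

The decomposition eta = X B^T + Gamma Z^T + U V^T is invariant under
(i) shifts of Gamma, U along the column space of X (and of V along Z),
and (ii) rotation/scaling/sign-flips of (U, V).  The projection makes the
decomposition unique without changing eta:

(A)  X^T Gamma = 0, X^T U = 0, Z^T V = 0 (components absorbed into the
     regression blocks);
(B1) U^T U = Sigma (decreasing positive diagonal), V^T V = I_d, first
     non-zero entry of each column of V positive (PCA convention);
(B2) U^T U = I_d, V^T V = Sigma, first non-zero entry of each column of
     U positive (spectral convention);
(B3) columns of U standardized (variance one after centering), V lower
     triangular with positive diagonal (factor-model convention; requires
     an intercept in X so that U is centered by constraint (A)).
"""

from __future__ import annotations

import numpy as np

from .core_model import GMFData, GMFParams
from .errors import GMFConfigError

#: threshold for the first-non-zero sign rule
_SIGN_EPS = 1e-12


def _first_nonzero_signs(M: np.ndarray) -> np.ndarray:
    """Sign of the first entry with |entry| > threshold in each column,
    ties broken by the lowest row index; +1 for all-zero columns."""
    d = M.shape[1]
    signs = np.ones(d)
    for k in range(d):
        nz = np.nonzero(np.abs(M[:, k]) > _SIGN_EPS)[0]
        if nz.size:
            signs[k] = np.sign(M[nz[0], k])
    return signs


def _absorb_covariates(data: GMFData, params: GMFParams) -> GMFParams:
    """Enforce (A) by least-squares absorption, leaving eta unchanged."""
    B = params.B.copy()
    Gamma = params.Gamma.copy()
    U = params.U.copy()
    V = params.V.copy()
    X, Z = data.X, data.Z
    if X.shape[1]:
        # Gamma = X A + Gamma_perp  =>  X A Z^T absorbed into X B^T
        A = np.linalg.lstsq(X, Gamma, rcond=None)[0]  # (p, q)
        B = B + Z @ A.T
        Gamma = Gamma - X @ A
        if U.shape[1]:
            C = np.linalg.lstsq(X, U, rcond=None)[0]  # (p, d)
            B = B + V @ C.T
            U = U - X @ C
    if Z.shape[1] and V.shape[1]:
        E = np.linalg.lstsq(Z, V, rcond=None)[0]  # (q, d)
        Gamma = Gamma + U @ E.T  # X^T U = 0 already, so (A) is preserved
        V = V - Z @ E
    return GMFParams(B, Gamma, U, V, params.phi)


def project_constraints(
    data: GMFData, params: GMFParams, parametrization: str = "B1"
) -> GMFParams:
    """Project parameters onto (A) + one of (B1)/(B2)/(B3).

    The fitted linear predictor is preserved to numerical precision; the
    projection is idempotent and invariant to rotations of (U, V).
    """
    if parametrization not in ("B1", "B2", "B3"):
        raise GMFConfigError(f"unknown parametrization '{parametrization}'")
    d = params.d
    if d > min(data.n, data.m):
        raise GMFConfigError("latent rank d exceeds min(n, m)")
    out = _absorb_covariates(data, params)
    if d == 0:
        return out

    # rank-d SVD of U V^T via the thin-QR trick
    Qu, Ru = np.linalg.qr(out.U)
    Qv, Rv = np.linalg.qr(out.V)
    P, s, Qt = np.linalg.svd(Ru @ Rv.T)
    left = Qu @ P          # (n, d) orthonormal
    right = Qv @ Qt.T      # (m, d) orthonormal

    if parametrization == "B1":
        signs = _first_nonzero_signs(right)
        U_new = (left * s) * signs
        V_new = right * signs
    elif parametrization == "B2":
        signs = _first_nonzero_signs(left)
        U_new = left * signs
        V_new = (right * s) * signs
    else:  # B3
        if not np.any(np.all(data.X == data.X[0:1], axis=0) & (data.X[0] != 0)):
            raise GMFConfigError(
                "parametrization B3 requires an intercept column in X "
                "(constraint (A) then centers U)"
            )
        keep = s > _SIGN_EPS
        if not np.all(keep):
            raise GMFConfigError(
                "parametrization B3 is undefined for rank-deficient U V^T"
            )
        n = data.n
        U_std = np.sqrt(n) * left              # (1/n) U^T U = I_d
        V_s = (right * s) / np.sqrt(n)
        # rotate so the top d x d block of V is lower triangular: with
        # V_s[:d].T = Q R (QR), the rotation O = Q gives V_s[:d] O = R^T.
        Qtop, _ = np.linalg.qr(V_s[:d, :].T)
        V_new = V_s @ Qtop
        U_new = U_std @ Qtop
        diag = np.sign(np.diag(V_new[:d, :]))
        diag[diag == 0] = 1.0
        V_new = V_new * diag
        U_new = U_new * diag

    return GMFParams(out.B, out.Gamma, U_new, V_new, out.phi)
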