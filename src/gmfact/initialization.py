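"""Structured starting values via the null-residual method.

The initialization proceeds in four stages: (1) m column-wise GLMs give
the column-effect coefficients B; (2) conditionally on the offsets
X b_j, n row-wise GLMs give the row effects Gamma; (3) the rank-d
truncated SVD of the deviance (or Pearson) residual matrix at the
regression-only fit supplies the latent factors, with U scaled by the
singular values; (4) m column-wise GLMs with U as design and the
regression offset give the loadings V.  A fast path replaces every GLM by
ordinary least squares on a link-transformed response (the started log
log(y + 1/2) for counts).

Masked entries are excluded from every regression and set to zero in the
residual matrix before the SVD ("as predicted by the null model").
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.sparse.linalg import svds

from ._glm import fit_glm_many, ols_transformed
from .core_model import GMFData, GMFParams, linear_predictor
from .errors import GMFConfigError
from .families import FamilySpec, estimate_dispersion

#: IRLS budget for the row/column GLM fits
_GLM_MAX_ITER = 50
_GLM_TOL = 1e-8


@dataclass
class InitConfig:
    method: str = "glm"            # "glm" | "ols"
    residual_type: str = "deviance"  # "deviance" | "pearson"
    d: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("glm", "ols"):
            raise GMFConfigError("init method must be 'glm' or 'ols'")
        if self.residual_type not in ("deviance", "pearson"):
            raise GMFConfigError("residual_type must be 'deviance' or 'pearson'")
        if self.d < 0:
            raise GMFConfigError("latent rank d must be nonnegative")


def _residual_matrix(
    data: GMFData, mu: np.ndarray, family: FamilySpec, residual_type: str
) -> np.ndarray:
    y_safe = np.where(data.mask, data.Y, mu)
    if residual_type == "pearson":
        r = (y_safe - mu) / np.sqrt(family.variance(mu))
    else:
        dev = family.unit_deviance(y_safe, mu)
        r = np.sign(y_safe - mu) * np.sqrt(np.maximum(dev, 0.0))
    r = r * np.sqrt(data.W)
    return np.where(data.mask, r, 0.0)


def _truncated_svd(R: np.ndarray, d: int, seed: int):
    n, m = R.shape
    if d >= min(n, m) or min(n, m) <= 100:
        L, s, Vt = np.linalg.svd(R, full_matrices=False)
        return L[:, :d], s[:d], Vt[:d]
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(n, m))
    L, s, Vt = svds(R, k=d, v0=v0)
    order = np.argsort(s)[::-1]
    return L[:, order], s[order], Vt[order]


def initialize(
    data: GMFData, config: InitConfig, family: FamilySpec
) -> GMFParams:
    """Structured initial parameters (B, Gamma, U, V, phi)."""
    if config.d > min(data.n, data.m):
        raise GMFConfigError("latent rank d exceeds min(n, m)")
    n, m, p, q, d = data.n, data.m, data.p, data.q, config.d
    use_glm = config.method == "glm"
    base_off = data.offset if data.offset is not None else np.zeros((n, m))

    # stage 1: column GLMs for B (design X shared across the m columns)
    if p:
        if use_glm:
            B = fit_glm_many(
                data.Y, data.X, family, data.W, data.mask, base_off,
                max_iter=_GLM_MAX_ITER, tol=_GLM_TOL,
            ).coef
        else:
            B = ols_transformed(data.Y, data.X, family, data.W, data.mask, base_off)
    else:
        B = np.zeros((m, 0))

    # stage 2: row GLMs for Gamma given offsets X b_j (design Z shared)
    off_rows = (data.X @ B.T + base_off).T  # (m, n)
    if q:
        if use_glm:
            Gamma = fit_glm_many(
                data.Y.T, data.Z, family, data.W.T, data.mask.T, off_rows,
                max_iter=_GLM_MAX_ITER, tol=_GLM_TOL,
            ).coef
        else:
            Gamma = ols_transformed(
                data.Y.T, data.Z, family, data.W.T, data.mask.T, off_rows
            )
    else:
        Gamma = np.zeros((n, 0))

    params0 = GMFParams(B, Gamma, np.zeros((n, d)), np.zeros((m, d)), 1.0)
    eta0 = linear_predictor(data, params0)
    mu0, _ = family.mean_from_eta(eta0)

    if d > 0:
        # stage 3: left singular vectors of the null-residual matrix,
        # scaled by the singular values so U carries magnitude (B1-style)
        R = _residual_matrix(data, mu0, family, config.residual_type)
        L, s, Vt = _truncated_svd(R, d, config.seed)
        U = L * s
        # stage 4: column GLMs with U as design and the regression offset
        off_v = eta0
        if use_glm:
            V = fit_glm_many(
                data.Y, U, family, data.W, data.mask, off_v,
                coef0=Vt.T.copy(), max_iter=_GLM_MAX_ITER, tol=_GLM_TOL,
            ).coef
        else:
            V = ols_transformed(data.Y, U, family, data.W, data.mask, off_v)
    else:
        U = np.zeros((n, 0))
        V = np.zeros((m, 0))

    phi = 1.0
    if family.dispersion_mode == "estimated":
        params1 = GMFParams(B, Gamma, U, V, 1.0)
        eta1 = linear_predictor(data, params1)
        mu1, _ = family.mean_from_eta(eta1)
        npar = min(params1.n_parameters(), data.n_obs - 1)
        phi = estimate_dispersion(data.Y, mu1, family, data.W, npar, data.mask)

    return GMFParams(B, Gamma, U, V, phi)
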