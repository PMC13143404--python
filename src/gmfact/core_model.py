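"""Data/parameter containers, linear predictor, objective and gradients.

The model for an n x m response matrix Y is

    g(mu_ij) = eta_ij = (X B^T + Gamma Z^T + U V^T)_ij (+ offset_ij),

with row covariates X (n x p), column covariates Z (m x q), column-effect
coefficients B (m x p), row-effect coefficients Gamma (n x q), latent
factors U (n x d) and loadings V (m x d).  Estimation minimizes the
penalized negative log-likelihood

    l_lambda = - sum_{(i,j) in Omega} log f(y_ij; theta_ij, phi)
               + (lambda/2) ||U||_F^2 + (lambda/2) ||V||_F^2,

where Omega is the set of observed entries.  The y-only constant
c(y, phi) is included so AIC/BIC are on the standard likelihood scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import GMFConfigError, GMFNumericalError
from .families import FamilySpec, eta_derivatives


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GMFData:
    """Observed matrix with covariates, weights and observation mask.

    ``X`` and ``Z`` default to a single intercept column; pass an
    ``(n, 0)`` / ``(m, 0)`` array for a covariate-free model.  ``mask``
    marks observed entries (Omega); masked cells of ``Y`` may hold any
    placeholder (including NaN) and are never read.  ``offset`` is a fixed
    additive term on the linear-predictor scale, excluded from penalties
    and updates.
    """

    Y: np.ndarray
    X: Optional[np.ndarray] = None
    Z: Optional[np.ndarray] = None
    W: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    offset: Optional[np.ndarray] = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise GMFConfigError("Y must be a 2-D matrix")
        n, m = self.Y.shape
        if self.X is None:
            self.X = np.ones((n, 1))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Z is None:
            self.Z = np.ones((m, 1))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.X.shape[0] != n or self.Z.shape[0] != m:
            raise GMFConfigError(
                f"covariate shapes {self.X.shape}, {self.Z.shape} do not "
                f"conform to Y {self.Y.shape}"
            )
        for name, A in (("X", self.X), ("Z", self.Z)):
            if A.shape[1] and np.linalg.matrix_rank(A) < A.shape[1]:
                raise GMFConfigError(f"{name} is not full column rank")
        if self.W is None:
            self.W = np.ones((n, m))
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, m) or np.any(self.W <= 0):
            raise GMFConfigError("W must be an n x m matrix of positive weights")
        if self.mask is None:
            self.mask = ~np.isnan(self.Y)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n, m):
            raise GMFConfigError("mask must match the shape of Y")
        if not self.mask.any():
            raise GMFConfigError("the observation set Omega is empty")
        if not np.all(np.isfinite(self.Y[self.mask])):
            raise GMFConfigError("observed entries of Y must be finite")
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape != (n, m):
                raise GMFConfigError("offset must match the shape of Y")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def with_mask(self, mask: np.ndarray) -> "GMFData":
        return GMFData(self.Y, self.X, self.Z, self.W, mask, self.offset)


@dataclass
class GMFParams:
    """Regression blocks B, Gamma, latent blocks U, V and dispersion phi."""

    B: np.ndarray
    Gamma: np.ndarray
    U: np.ndarray
    V: np.ndarray
    phi: float = 1.0

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        self.U = np.asarray(self.U, dtype=float).reshape(self.Gamma.shape[0], -1)
        self.V = np.asarray(self.V, dtype=float).reshape(self.B.shape[0], -1)
        if self.U.shape[1] != self.V.shape[1]:
            raise GMFConfigError("U and V must share the latent rank d")
        if self.phi <= 0:
            raise GMFConfigError("dispersion phi must be positive")

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def copy(self) -> "GMFParams":
        return GMFParams(
            self.B.copy(), self.Gamma.copy(), self.U.copy(), self.V.copy(), self.phi
        )

    @staticmethod
    def zeros(n: int, m: int, p: int, q: int, d: int, phi: float = 1.0) -> "GMFParams":
        return GMFParams(
            np.zeros((m, p)), np.zeros((n, q)), np.zeros((n, d)), np.zeros((m, d)), phi
        )

    def n_parameters(self, n_for_count: Optional[int] = None) -> int:
        """Total parameter count pm + qn + d(n+m) + 1."""
        n, m = self.Gamma.shape[0], self.B.shape[0]
        p, q, d = self.B.shape[1], self.Gamma.shape[1], self.d
        return p * m + q * n + d * (n + m) + 1


@dataclass
class FitConfig:
    """Hyperparameters shared by the three fitting algorithms.

    ``schedule`` is the learning-rate triple (k0, k1, tau) of
    rho_t = k0 / (1 + k0 k1 t)^tau with tau in (1/2, 1]; ``smoothing`` the
    exponential-averaging coefficients (alpha1, alpha2) in (0, 1];
    ``minibatch`` the (row-chunk, column-chunk) counts (R, S), derived from
    target chunk sizes of min(n, 1000) x min(m, 250) when omitted.
    """

    d: int = 2
    penalty: float = 1.0
    algorithm: str = "sgd"
    max_epochs: int = 500
    tol: float = 1e-5
    seed: int = 0
    schedule: Tuple[float, float, float] = (0.01, 0.01, 0.75)
    smoothing: Tuple[float, float] = (0.1, 0.01)
    minibatch: Optional[Tuple[int, int]] = None
    parametrization: str = "B1"
    fisher: bool = True
    step: Optional[float] = None  # newton/airwls initial step
    monitor_fraction: float = 0.1
    convergence_window: int = 3
    divergence_factor: float = 50.0
    hessian_floor: float = 1e-8

    def __post_init__(self):
        k0, k1, tau = self.schedule
        if not (0.5 < tau <= 1.0):
            raise GMFConfigError(
                "learning-rate exponent tau must lie in (1/2, 1] "
                "(Robbins-Monro conditions)"
            )
        if k0 <= 0 or k1 <= 0:
            raise GMFConfigError("learning-rate constants k0, k1 must be positive")
        a1, a2 = self.smoothing
        if not (0 < a1 <= 1 and 0 < a2 <= 1):
            raise GMFConfigError("smoothing coefficients must lie in (0, 1]")
        if self.d < 0:
            raise GMFConfigError("latent rank d must be nonnegative")
        if self.penalty < 0:
            raise GMFConfigError("penalty lambda must be nonnegative")
        if self.parametrization not in ("B1", "B2", "B3"):
            raise GMFConfigError("parametrization must be one of B1, B2, B3")
        if self.algorithm not in ("sgd", "newton", "airwls"):
            raise GMFConfigError("algorithm must be one of sgd, newton, airwls")


@dataclass
class FitResult:
    """Final parameters, objective trace and convergence diagnostics."""

    params: GMFParams
    trace: list
    converged: bool
    epochs_run: int
    clip_events: int
    manifest: dict

    @property
    def objective(self) -> float:
        return self.trace[-1] if self.trace else np.nan


@dataclass
class GradientBlocks:
    """Gradient and diagonal-curvature blocks of the penalized objective."""

    G_U: np.ndarray
    H_U: np.ndarray
    G_V: np.ndarray
    H_V: np.ndarray
    G_B: np.ndarray
    H_B: np.ndarray
    G_Gamma: np.ndarray
    H_Gamma: np.ndarray


# ---------------------------------------------------------------------------
# model surface
# ---------------------------------------------------------------------------

def linear_predictor(
    data: GMFData,
    params: GMFParams,
    rows: Optional[Sequence[int]] = None,
    cols: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """eta = X B^T + Gamma Z^T + U V^T (+ offset), restricted to a block.

    Computing a block touches only rows ``rows`` of X, Gamma, U and rows
    ``cols`` of B, Z, V.
    """
    X = data.X if rows is None else data.X[rows]
    G = params.Gamma if rows is None else params.Gamma[rows]
    U = params.U if rows is None else params.U[rows]
    B = params.B if cols is None else params.B[cols]
    Z = data.Z if cols is None else data.Z[cols]
    V = params.V if cols is None else params.V[cols]
    eta = X @ B.T + G @ Z.T + U @ V.T
    if data.offset is not None:
        off = data.offset
        if rows is not None:
            off = off[rows]
        if cols is not None:
            off = off[:, cols]
        eta = eta + off
    return eta


def predict_mean(data: GMFData, params: GMFParams, family: FamilySpec) -> np.ndarray:
    """Fitted means mu = g^{-1}(eta), clipped to the family domain."""
    mu, _ = family.mean_from_eta(linear_predictor(data, params))
    return mu


def penalized_objective(
    data: GMFData,
    params: GMFParams,
    penalty: float,
    family: FamilySpec,
    monitor: Optional[np.ndarray] = None,
) -> float:
    """Penalized negative log-likelihood over the observed set Omega.

    ``monitor`` optionally restricts the likelihood sum to a boolean
    subsample of Omega, rescaled by |Omega| / |monitor| so monitored and
    full objectives are on the same scale.
    """
    eta = linear_predictor(data, params)
    mu, _ = family.mean_from_eta(eta)
    mask = data.mask if monitor is None else (data.mask & monitor)
    y_safe = np.where(mask, data.Y, mu)
    ll = family.log_density(y_safe, mu, params.phi, data.W)
    total = float(ll[mask].sum())
    if monitor is not None:
        n_sub = int(mask.sum())
        if n_sub == 0:
            raise GMFConfigError("empty monitoring subsample")
        total *= data.n_obs / n_sub
    pen = 0.5 * penalty * (np.sum(params.U**2) + np.sum(params.V**2))
    obj = -total + pen
    if not np.isfinite(obj):
        raise GMFNumericalError(
            "non-finite penalized objective: the fit has diverged"
        )
    return obj


def full_gradients(
    data: GMFData,
    params: GMFParams,
    penalty: float,
    family: FamilySpec,
    fisher: bool = True,
) -> GradientBlocks:
    """Full-batch gradient and curvature blocks for U, V, B, Gamma.

    Masked entries are imputed with the current mean (y <- mu) before the
    derivative kernels are evaluated, which zeroes their score
    contribution while retaining their Fisher weight in the diagonal
    curvature; only U and V carry the ridge penalty.
    """
    eta = linear_predictor(data, params)
    mu, _ = family.mean_from_eta(eta)
    y_eff = np.where(data.mask, data.Y, mu)
    phi = family.effective_phi(params.phi)
    dD, d2D = eta_derivatives(y_eff, mu, family, phi, data.W, fisher=fisher)
    lam = penalty
    return GradientBlocks(
        G_U=dD @ params.V + lam * params.U,
        H_U=d2D @ (params.V * params.V) + lam,
        G_V=dD.T @ params.U + lam * params.V,
        H_V=d2D.T @ (params.U * params.U) + lam,
        G_B=dD.T @ data.X,
        H_B=d2D.T @ (data.X * data.X),
        G_Gamma=dD @ data.Z,
        H_Gamma=d2D @ (data.Z * data.Z),
    )


def total_deviance(
    data: GMFData, params: GMFParams, family: FamilySpec
) -> float:
    """Weighted total deviance over Omega at the fitted means."""
    from .families import deviance as _dev

    mu = predict_mean(data, params, family)
    y_safe = np.where(data.mask, data.Y, mu)
    dev = _dev(y_safe, mu, family, data.W)
    return float(dev[data.mask].sum())
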