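"""Exponential-dispersion families with links, variances and deviances.

A :class:`FamilySpec` bundles everything the estimation algorithms need to
know about one exponential-dispersion family EF(theta, phi): the link
``g`` with derivatives, the variance function ``nu(mu)`` with derivative,
the per-entry unit deviance ``D(y, mu)``, the log-density kernel, and the
dispersion convention.  The derivative kernels returned by
:func:`eta_derivatives` are the building blocks of every fitter: they are
the first and second derivatives of the penalized *negative* log-likelihood
with respect to the linear predictor eta, so that descent steps
``delta = -G/H`` are unambiguous.  All gradients in the package are
cross-checked against central finite differences of the objective.

Supported families: gaussian, poisson, binomial, gamma, negbin (NB2 with
fixed or estimated size), quasipoisson.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import special

from .errors import GMFConfigError, GMFDomainError

#: clipping bound for positive / unit-interval means, g^{-1}(eta) is kept
#: inside [MEAN_EPS, 1/MEAN_EPS] (or [MEAN_EPS, 1-MEAN_EPS] on (0,1)).
MEAN_EPS = 1e-10

#: lower truncation for dispersion estimates.
DISPERSION_FLOOR = 1e-8

_ETA_MAX = np.log(1.0 / MEAN_EPS)  # exp overflow guard on the log link


@dataclass(frozen=True)
class LinkFunction:
    """A smooth bijective link g with first and second derivatives."""

    name: str
    g: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    deriv: Callable[[np.ndarray], np.ndarray]
    deriv2: Callable[[np.ndarray], np.ndarray]


def _logit(mu):
    return np.log(mu) - np.log1p(-mu)


def _expit(eta):
    return special.expit(eta)


LINKS = {
    "identity": LinkFunction(
        "identity",
        g=lambda mu: np.asarray(mu, dtype=float),
        inverse=lambda eta: np.asarray(eta, dtype=float),
        deriv=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
        deriv2=lambda mu: np.zeros_like(np.asarray(mu, dtype=float)),
    ),
    "log": LinkFunction(
        "log",
        g=np.log,
        inverse=lambda eta: np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX)),
        deriv=lambda mu: 1.0 / mu,
        deriv2=lambda mu: -1.0 / mu**2,
    ),
    "logit": LinkFunction(
        "logit",
        g=_logit,
        inverse=_expit,
        deriv=lambda mu: 1.0 / (mu * (1.0 - mu)),
        deriv2=lambda mu: (2.0 * mu - 1.0) / (mu * (1.0 - mu)) ** 2,
    ),
    "inverse": LinkFunction(
        "inverse",
        g=lambda mu: 1.0 / mu,
        inverse=lambda eta: 1.0 / eta,
        deriv=lambda mu: -1.0 / mu**2,
        deriv2=lambda mu: 2.0 / mu**3,
    ),
}


@dataclass(frozen=True)
class FamilySpec:
    """One exponential-dispersion family: link, variance, deviance, density.

    ``mean_domain`` is the open interval of valid means; ``response_range``
    the closed set of valid responses.  ``aux`` carries the negative
    binomial size when applicable; ``aux_estimated`` marks it for
    method-of-moments re-estimation during fitting.
    """

    name: str
    link: LinkFunction
    variance: Callable[[np.ndarray], np.ndarray]
    variance_deriv: Callable[[np.ndarray], np.ndarray]
    unit_deviance: Callable[[np.ndarray, np.ndarray], np.ndarray]
    log_density: Callable[..., np.ndarray]
    dispersion_mode: str  # "fixed" | "estimated"
    mean_domain: Tuple[float, float]
    response_range: Tuple[float, float]
    init_transform: Callable[[np.ndarray], np.ndarray]
    canonical_link: str = "identity"
    aux: Optional[float] = None
    aux_estimated: bool = False
    link_warning: Optional[str] = None

    def effective_phi(self, phi: float) -> float:
        """Dispersion entering the likelihood: 1 for fixed-phi families."""
        return phi if self.dispersion_mode == "estimated" else 1.0

    def clip_mean(self, mu: np.ndarray) -> np.ndarray:
        lo, hi = self.mean_domain
        lo_c = lo + MEAN_EPS if np.isfinite(lo) else lo
        hi_c = hi - MEAN_EPS if np.isfinite(hi) else 1.0 / MEAN_EPS
        if not np.isfinite(lo):
            lo_c = -1.0 / MEAN_EPS
        return np.clip(mu, lo_c, hi_c)

    def mean_from_eta(self, eta: np.ndarray) -> Tuple[np.ndarray, int]:
        """Inverse link with domain clipping; returns (mu, #clipped)."""
        raw = self.link.inverse(eta)
        mu = self.clip_mean(raw)
        n_clip = int(np.sum(mu != raw))
        return mu, n_clip

    def check_response(self, y: np.ndarray, mask: Optional[np.ndarray] = None) -> None:
        lo, hi = self.response_range
        yv = y[mask] if mask is not None else y
        if yv.size and (np.nanmin(yv) < lo or np.nanmax(yv) > hi):
            raise GMFDomainError(
                f"responses outside the valid range [{lo}, {hi}] "
                f"for family '{self.name}'"
            )


# ---------------------------------------------------------------------------
# per-family kernels
# ---------------------------------------------------------------------------

def _gaussian_logdensity(y, mu, phi=1.0, w=1.0):
    return -0.5 * (w * (y - mu) ** 2 / phi + np.log(2.0 * np.pi * phi / w))


def _poisson_logdensity(y, mu, phi=1.0, w=1.0):
    return w * (special.xlogy(y, mu) - mu - special.gammaln(y + 1.0))


def _quasipoisson_logdensity(y, mu, phi=1.0, w=1.0):
    # quasi-likelihood kernel: the Poisson log-density scaled by 1/phi; an
    # exact c(y, phi) does not exist for quasi-families.
    return _poisson_logdensity(y, mu, 1.0, w) / phi


def _binomial_logdensity(y, mu, phi=1.0, w=1.0):
    return w * (special.xlogy(y, mu) + special.xlog1py(1.0 - y, -mu))


def _gamma_logdensity(y, mu, phi=1.0, w=1.0):
    k = w / phi  # shape; mean mu, variance mu^2/k
    return (
        special.xlogy(k, k / mu)
        - special.gammaln(k)
        + special.xlogy(k - 1.0, y)
        - k * y / mu
    )


def _make_negbin_logdensity(size):
    def _ld(y, mu, phi=1.0, w=1.0, r=size):
        return w * (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + special.xlogy(r, r / (r + mu))
            + special.xlogy(y, mu / (r + mu))
        )

    return _ld


def _gaussian_dev(y, mu):
    return (y - mu) ** 2


def _poisson_dev(y, mu):
    return 2.0 * (special.xlogy(y, y / mu) - (y - mu))


def _binomial_dev(y, mu):
    return 2.0 * (
        special.xlogy(y, y / mu) + special.xlogy(1.0 - y, (1.0 - y) / (1.0 - mu))
    )


def _gamma_dev(y, mu):
    return 2.0 * ((y - mu) / mu - np.log(y / mu))


def _make_negbin_dev(size):
    def _dev(y, mu, r=size):
        return 2.0 * (
            special.xlogy(y, y / mu) - special.xlogy(y + r, (y + r) / (mu + r))
        )

    return _dev


def _started_log(y):
    return np.log(np.asarray(y, dtype=float) + 0.5)


_FAMILY_TABLE = {
    "gaussian": dict(
        canonical_link="identity",
        variance=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
        variance_deriv=lambda mu: np.zeros_like(np.asarray(mu, dtype=float)),
        unit_deviance=_gaussian_dev,
        log_density=_gaussian_logdensity,
        dispersion_mode="estimated",
        mean_domain=(-np.inf, np.inf),
        response_range=(-np.inf, np.inf),
        init_transform=lambda y: np.asarray(y, dtype=float),
    ),
    "poisson": dict(
        canonical_link="log",
        variance=lambda mu: mu,
        variance_deriv=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
        unit_deviance=_poisson_dev,
        log_density=_poisson_logdensity,
        dispersion_mode="fixed",
        mean_domain=(0.0, np.inf),
        response_range=(0.0, np.inf),
        init_transform=_started_log,
    ),
    "quasipoisson": dict(
        canonical_link="log",
        variance=lambda mu: mu,
        variance_deriv=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
        unit_deviance=_poisson_dev,
        log_density=_quasipoisson_logdensity,
        dispersion_mode="estimated",
        mean_domain=(0.0, np.inf),
        response_range=(0.0, np.inf),
        init_transform=_started_log,
    ),
    "binomial": dict(
        canonical_link="logit",
        variance=lambda mu: mu * (1.0 - mu),
        variance_deriv=lambda mu: 1.0 - 2.0 * mu,
        unit_deviance=_binomial_dev,
        log_density=_binomial_logdensity,
        dispersion_mode="fixed",
        mean_domain=(0.0, 1.0),
        response_range=(0.0, 1.0),
        init_transform=lambda y: _logit((np.asarray(y, dtype=float) + 0.25) / 1.5),
    ),
    "gamma": dict(
        canonical_link="inverse",
        variance=lambda mu: mu**2,
        variance_deriv=lambda mu: 2.0 * mu,
        unit_deviance=_gamma_dev,
        log_density=_gamma_logdensity,
        dispersion_mode="estimated",
        mean_domain=(0.0, np.inf),
        response_range=(0.0, np.inf),
        init_transform=lambda y: np.log(np.maximum(np.asarray(y, dtype=float), 1e-8)),
    ),
}


def make_family(
    name: str, link: Optional[str] = None, aux: Optional[float] = None
) -> FamilySpec:
    """Build a :class:`FamilySpec` by name, with an optional non-canonical link.

    ``aux`` is the negative binomial size; omitting it for ``negbin`` marks
    the size for method-of-moments estimation during fitting.
    """
    name = name.lower()
    if name == "negbin":
        aux_estimated = aux is None
        size = float(aux) if aux is not None else 1.0
        if size <= 0:
            raise GMFConfigError("negative binomial size must be positive")
        table = dict(
            canonical_link="log",
            variance=lambda mu, r=size: mu + mu**2 / r,
            variance_deriv=lambda mu, r=size: 1.0 + 2.0 * mu / r,
            unit_deviance=_make_negbin_dev(size),
            log_density=_make_negbin_logdensity(size),
            dispersion_mode="fixed",
            mean_domain=(0.0, np.inf),
            response_range=(0.0, np.inf),
            init_transform=_started_log,
        )
    elif name in _FAMILY_TABLE:
        aux_estimated = False
        if aux is not None:
            raise GMFConfigError(f"family '{name}' takes no auxiliary parameter")
        table = dict(_FAMILY_TABLE[name])
    else:
        raise GMFConfigError(f"unknown family '{name}'")

    link_name = link or table["canonical_link"]
    if link_name not in LINKS:
        raise GMFConfigError(f"unknown link '{link_name}'")

    warning = None
    lo, hi = table["mean_domain"]
    if link_name == "identity" and lo >= 0.0 and name != "gaussian":
        warning = (
            f"identity link with the strictly positive mean domain of "
            f"'{name}': means are clipped at {MEAN_EPS}"
        )
    if link_name == "logit" and name != "binomial":
        raise GMFConfigError(f"logit link incompatible with family '{name}'")
    if link_name in ("log", "inverse", "sqrt") and not np.isfinite(hi) and lo < 0:
        pass

    return FamilySpec(
        name=name,
        link=LINKS[link_name],
        variance=table["variance"],
        variance_deriv=table["variance_deriv"],
        unit_deviance=table["unit_deviance"],
        log_density=table["log_density"],
        dispersion_mode=table["dispersion_mode"],
        mean_domain=table["mean_domain"],
        response_range=table["response_range"],
        init_transform=table["init_transform"],
        canonical_link=table["canonical_link"],
        aux=float(aux) if (name == "negbin" and aux is not None) else (1.0 if name == "negbin" else None),
        aux_estimated=aux_estimated,
        link_warning=warning,
    )


def deviance(
    y: np.ndarray,
    mu: np.ndarray,
    family: FamilySpec,
    weights: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Element-wise weighted unit deviances w * D(y, mu).

    Boundary responses (y = 0 under log-domain deviances, y in {0, 1} for
    the binomial) are handled through the x*log(x) -> 0 limit.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lo, hi = family.mean_domain
    if np.any(mu <= lo) or np.any(mu >= hi):
        bad = np.argwhere((mu <= lo) | (mu >= hi))
        raise GMFDomainError(
            f"mean outside the open domain ({lo}, {hi}) for family "
            f"'{family.name}' at entry {tuple(bad[0])}"
        )
    dev = family.unit_deviance(y, mu)
    if weights is not None:
        dev = np.asarray(weights, dtype=float) * dev
    return dev


def eta_derivatives(
    y: np.ndarray,
    mu: np.ndarray,
    family: FamilySpec,
    phi: float = 1.0,
    weights: Optional[np.ndarray] = None,
    fisher: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """First and second derivatives of the negative log-likelihood in eta.

    Returns ``(dD, d2D)`` with

        dD  = -w (y - mu) / (phi nu(mu) g'(mu)),
        d2D =  w alpha(mu) / (phi nu(mu) g'(mu)^2),

    where ``alpha(mu) = 1 + (y - mu){nu'(mu)/nu(mu) + g''(mu)/g'(mu)}`` is
    replaced by 1 when ``fisher`` is true (expected information), making
    d2D strictly positive.
    """
    if phi <= 0:
        raise GMFConfigError("dispersion phi must be positive")
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.ones_like(mu) if weights is None else np.asarray(weights, dtype=float)
    nu = family.variance(mu)
    dg = family.link.deriv(mu)
    if np.any(nu <= 0):
        raise GMFDomainError("nonpositive variance function value")
    if np.any(dg == 0):
        raise GMFDomainError("vanishing link derivative")
    dD = -w * (y - mu) / (phi * nu * dg)
    if fisher:
        alpha = 1.0
    else:
        alpha = 1.0 + (y - mu) * (
            family.variance_deriv(mu) / nu + family.link.deriv2(mu) / dg
        )
    d2D = w * alpha / (phi * nu * dg**2)
    return dD, d2D


def estimate_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    family: FamilySpec,
    weights: Optional[np.ndarray] = None,
    npar: int = 0,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Pearson method-of-moments dispersion estimate.

    phi_hat = sum_Omega w (y-mu)^2 / nu(mu) / (N_obs - npar), truncated below
    at :data:`DISPERSION_FLOOR`.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.ones_like(mu) if weights is None else np.asarray(weights, dtype=float)
    if mask is None:
        mask = np.ones(y.shape, dtype=bool)
    n_obs = int(mask.sum())
    denom = n_obs - npar
    if denom <= 0:
        raise GMFConfigError(
            f"dispersion denominator N_obs - npar = {denom} is not positive"
        )
    y_safe = np.where(mask, y, mu)
    pearson = w * (y_safe - mu) ** 2 / family.variance(mu)
    phi = float(pearson[mask].sum() / denom)
    return max(phi, DISPERSION_FLOOR)


def estimate_nb_size(
    y: np.ndarray,
    mu: np.ndarray,
    weights: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Method-of-moments negative binomial size from Pearson residuals.

    Solves sum w[(y-mu)^2 - mu] = (1/r) sum w mu^2 for r, clipped to
    [1e-2, 1e6]; falls back to 1e6 (near-Poisson) when the excess
    variance is nonpositive.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    w = np.ones_like(mu) if weights is None else np.asarray(weights, dtype=float)
    if mask is None:
        mask = np.ones(y.shape, dtype=bool)
    y_safe = np.where(mask, y, mu)
    excess = (w * ((y_safe - mu) ** 2 - mu))[mask].sum()
    scale = (w * mu**2)[mask].sum()
    if excess <= 0 or scale <= 0:
        return 1e6
    return float(np.clip(scale / excess, 1e-2, 1e6))
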