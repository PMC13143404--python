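"""Synthetic data generators for end-to-end testing.

Two generators:

* :func:`simulate_gmf` draws data exactly from the factor model
  g(mu) = X B^T + Gamma Z^T + U V^T with the chosen family — the
  well-specified case used for parameter-recovery and algorithm-agreement
  checks;
* :func:`simulate_scrna` emulates a single-cell RNA-seq count matrix with
  discrete cell types, batches with shifted expression levels and
  log-normal cell-specific library sizes, drawn from a negative binomial
  with log-link mean

      log mu_ij = log L_i + b_j + batch_{b(i), j} + type_{c(i), j}.

  The generator is deliberately *not* the factor model: the clustered
  mean structure is only approximately low-rank on the link scale, so
  every fitted model is misspecified, mimicking real benchmarking
  conditions.  Batch labels are exported as dummy covariates in X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core_model import GMFData, GMFParams, linear_predictor
from .errors import GMFConfigError
from .families import FamilySpec, make_family
from .identifiability import project_constraints


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    U: Optional[np.ndarray]
    V: Optional[np.ndarray]
    B: Optional[np.ndarray]
    Gamma: Optional[np.ndarray]
    eta: np.ndarray
    mu: np.ndarray
    family: str
    phi: float
    nb_size: Optional[float] = None
    cell_type: Optional[np.ndarray] = None
    batch: Optional[np.ndarray] = None
    library_size: Optional[np.ndarray] = None


def _draw_response(mu: np.ndarray, family: FamilySpec, phi: float, rng):
    if family.name == "gaussian":
        return rng.normal(mu, np.sqrt(phi))
    if family.name in ("poisson", "quasipoisson"):
        return rng.poisson(mu).astype(float)
    if family.name == "binomial":
        return rng.binomial(1, mu).astype(float)
    if family.name == "gamma":
        shape = 1.0 / phi
        return rng.gamma(shape, mu * phi)
    if family.name == "negbin":
        r = family.aux
        return rng.negative_binomial(r, r / (r + mu)).astype(float)
    raise GMFConfigError(f"cannot simulate from family '{family.name}'")


_INTERCEPT_LOC = {
    "gaussian": 0.0,
    "poisson": 1.0,
    "quasipoisson": 1.0,
    "negbin": 1.0,
    "gamma": 1.0,
    "binomial": 0.0,
}


def simulate_gmf(
    n: int,
    m: int,
    d: int,
    family: str = "poisson",
    snr: float = 1.0,
    seed: int = 0,
    phi: float = 1.0,
    aux: Optional[float] = None,
) -> Tuple[GMFData, SimulationTruth]:
    """Exact-model data: intercepts plus a rank-d latent factorization.

    U and V entries are independent Gaussians scaled so that the latent
    term u_i . v_j has standard deviation ``snr`` on the link scale
    (``snr=0`` gives a pure-intercept model).  The returned truth is
    projected onto parametrization B1.
    """
    if d > min(n, m):
        raise GMFConfigError("d exceeds min(n, m)")
    fam = make_family(family, aux=aux)
    rng = np.random.default_rng(seed)
    B = rng.normal(_INTERCEPT_LOC[family], 0.3, size=(m, 1))
    Gamma = rng.normal(0.0, 0.2, size=(n, 1))
    if d > 0 and snr > 0:
        scale = (snr**2 / d) ** 0.25
        U = rng.normal(0.0, scale, size=(n, d))
        V = rng.normal(0.0, scale, size=(m, d))
    else:
        U = np.zeros((n, d))
        V = np.zeros((m, d))
    params = GMFParams(B, Gamma, U, V, phi)
    X = np.ones((n, 1))
    Z = np.ones((m, 1))
    shell = GMFData(np.zeros((n, m)), X, Z)
    eta = linear_predictor(shell, params)
    mu, _ = fam.mean_from_eta(eta)
    Y = _draw_response(mu, fam, phi, rng)
    data = GMFData(Y, X, Z)
    if d > 0 and snr > 0:
        proj = project_constraints(data, params, "B1")
    else:
        proj = params  # degenerate latent block: nothing to rotate
    truth = SimulationTruth(
        U=proj.U, V=proj.V, B=proj.B, Gamma=proj.Gamma,
        eta=eta, mu=mu, family=family, phi=phi,
        nb_size=fam.aux if family == "negbin" else None,
    )
    return data, truth


def _even_labels(n: int, k: int, rng) -> np.ndarray:
    """Evenly allocated labels (remainders spread round-robin), shuffled."""
    base = np.tile(np.arange(k), n // k + 1)[:n]
    return rng.permutation(base)


def simulate_scrna(
    n: int = 2000,
    m: int = 200,
    n_types: int = 5,
    n_batches: int = 3,
    type_effect: float = 1.0,
    batch_effect: float = 0.3,
    libsize_sdlog: float = 0.4,
    nb_size: float = 2.0,
    marker_fraction: float = 0.1,
    marker_loc: float = 1.0,
    base_log_mean: float = 2.0,
    base_log_sd: float = 0.5,
    seed: int = 0,
    include_batch_covariates: bool = True,
) -> Tuple[GMFData, SimulationTruth]:
    """scRNA-seq-like negative binomial counts with types/batches/libsizes.

    Defaults: five evenly distributed, well-separated cell types; each
    type up-regulates a random ``marker_fraction`` = 10% of genes with
    log-scale effects N(``marker_loc`` = 1, ``type_effect``^2 = 1) —
    marker genes are predominantly over-expressed in their type, as in
    real cell-type signatures, which makes the five type profiles span a
    genuinely five-dimensional signal (zero-mean effects would collapse
    to four dimensions after centering).  Three batches shift all genes
    with sd 0.3, library sizes are log-normal(0, 0.4), counts are NB with
    size 2.  The baseline log-expression N(2, 0.5^2) mimics a
    most-variable-genes selection (moderately expressed genes).  Batch
    labels are exported as dummy covariates (intercept + n_batches - 1
    indicators) in X when ``include_batch_covariates``.
    """
    if nb_size <= 0:
        raise GMFConfigError("nb_size must be positive")
    rng = np.random.default_rng(seed)
    types = _even_labels(n, n_types, rng)
    batches = _even_labels(n, n_batches, rng)
    log_lib = rng.normal(0.0, libsize_sdlog, size=n)
    log_base = rng.normal(base_log_mean, base_log_sd, size=m)

    type_profiles = np.zeros((n_types, m))
    n_mark = max(1, int(round(marker_fraction * m)))
    for t in range(n_types):
        genes = rng.choice(m, size=n_mark, replace=False)
        loc = marker_loc if type_effect > 0 else 0.0
        type_profiles[t, genes] = rng.normal(loc, type_effect, size=n_mark)
    batch_profiles = rng.normal(0.0, batch_effect, size=(n_batches, m))

    eta = (
        log_lib[:, None]
        + log_base[None, :]
        + batch_profiles[batches]
        + type_profiles[types]
    )
    mu = np.exp(np.clip(eta, -30.0, 13.0))
    Y = rng.negative_binomial(nb_size, nb_size / (nb_size + mu)).astype(float)

    if include_batch_covariates and n_batches > 1:
        X = np.column_stack(
            [np.ones(n)] + [(batches == b).astype(float) for b in range(1, n_batches)]
        )
    else:
        X = np.ones((n, 1))
    data = GMFData(Y, X, np.ones((m, 1)))
    truth = SimulationTruth(
        U=None, V=None, B=None, Gamma=None,
        eta=eta, mu=mu, family="negbin", phi=1.0, nb_size=nb_size,
        cell_type=types, batch=batches, library_size=np.exp(log_lib),
    )
    return data, truth
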