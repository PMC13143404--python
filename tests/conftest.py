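"""Shared fixtures and oracles for the gmfact test suite."""

from __future__ import annotations

import numpy as np
import pytest

import gmfact as g
from gmfact.core_model import penalized_objective


#: family/link pairs shipped by the package (canonical links plus the
#: log-linked gamma commonly used for positive continuous data)
FAMILY_LINK_PAIRS = [
    ("gaussian", None, None),
    ("poisson", None, None),
    ("binomial", None, None),
    ("gamma", None, None),       # canonical inverse link
    ("gamma", "log", None),
    ("negbin", None, 10.0),
    ("quasipoisson", None, None),
]


def random_instance(
    family: str,
    link=None,
    aux=None,
    seed: int = 0,
    n: int = 20,
    m: int = 10,
    d: int = 2,
    p: int = 2,
    q: int = 1,
    masked: bool = True,
    phi: float = 1.0,
):
    """A small random (data, params, family) triple with valid domains.

    Latent and covariate scales are kept small so the linear predictor
    stays in the interior of each link's domain (the inverse link needs
    eta bounded away from zero).
    """
    rng = np.random.default_rng(seed)
    fam = g.make_family(family, link=link, aux=aux)
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p - 1)])
    Z = np.column_stack([np.ones(m)] + [rng.standard_normal(m) for _ in range(q - 1)])
    link_name = fam.link.name
    # the inverse link needs eta bounded well away from zero: mu = 1/eta is
    # hyper-sensitive there and even central differences lose accuracy
    sc = 0.08 if link_name == "inverse" else 0.2
    B = sc * rng.standard_normal((m, p))
    Gamma = sc * rng.standard_normal((n, q))
    U = (0.1 if link_name == "inverse" else 0.25) * rng.standard_normal((n, d))
    V = (0.1 if link_name == "inverse" else 0.25) * rng.standard_normal((m, d))
    if link_name == "inverse":
        B[:, 0] += 1.5
    elif family in ("poisson", "quasipoisson", "negbin"):
        B[:, 0] += 1.0
    params = g.GMFParams(B, Gamma, U, V, phi)
    shell = g.GMFData(np.zeros((n, m)), X, Z)
    eta = g.linear_predictor(shell, params)
    mu, _ = fam.mean_from_eta(eta)
    if family in ("poisson", "quasipoisson"):
        Y = rng.poisson(mu).astype(float)
    elif family == "negbin":
        r = fam.aux
        Y = rng.negative_binomial(r, r / (r + mu)).astype(float)
    elif family == "binomial":
        Y = rng.binomial(1, mu).astype(float)
    elif family == "gamma":
        Y = rng.gamma(2.0, mu / 2.0)
    else:
        Y = rng.normal(mu, 1.0)
    if masked:
        mask = rng.random((n, m)) > 0.1
        mask[0, :] = True  # keep every row/column observed somewhere
        mask[:, 0] = True
        Yp = Y.copy()
        Yp[~mask] = np.nan
        data = g.GMFData(Yp, X, Z, mask=mask)
    else:
        data = g.GMFData(Y, X, Z)
    return data, params, fam


def fd_block_gradients(data, params, lam, fam, h: float = 1e-4):
    """Central finite differences of the penalized objective in each block."""
    out = {}
    for attr in ("U", "V", "B", "Gamma"):
        M = getattr(params, attr)
        FD = np.zeros_like(M)
        for idx in np.ndindex(M.shape):
            for sgn in (+1.0, -1.0):
                P = params.copy()
                A = getattr(P, attr).copy()
                A[idx] += sgn * h
                setattr(P, attr, A)
                FD[idx] += sgn * penalized_objective(data, P, lam, fam)
        out[attr] = FD / (2.0 * h)
    return out


def rel_err(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.linalg.norm(a - b) / max(1.0, np.linalg.norm(b)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
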