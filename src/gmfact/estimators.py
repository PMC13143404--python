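"""The three fitting algorithms: AIRWLS, diagonal quasi-Newton, adaptive SGD.

All three minimize the penalized negative log-likelihood of
:mod:`gmfact.core_model`.

* :func:`fit_airwls` — alternated iterative re-weighted least squares:
  Fisher scoring applied column-wise to [B, V] (design [X, U]) and
  row-wise to [Gamma, U] (design [Z, V]), a ridge lambda on the latent
  coefficients only, with step-halving on objective increase.
* :func:`fit_newton` — diagonal quasi-Newton: global updates
  psi <- psi + rho * delta with delta = -G/H elementwise, H the diagonal
  of the (expected) Fisher information, damped line-halving.
* :func:`fit_sgd` — block-wise adaptive stochastic gradient descent:
  minibatch blocks B = I x J from random row/column partitions, unbiased
  rescaled gradients, exponential moving averages of gradient and
  curvature with bias factor alpha_t = (1 - alpha2^t)/(1 - alpha1^t),
  partial updates touching only rows I of U (with Gamma_I) and rows J of
  V (with B_J), and a Robbins-Monro learning-rate schedule
  rho_t = k0/(1 + k0 k1 t)^tau.

Convergence for the stochastic fitter is declared when the relative
change of the objective monitored on a fixed seeded subsample of Omega
(default 10%) stays below ``tol`` for 3 consecutive epochs; the
deterministic fitters monitor the full objective they already evaluate
for line search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._glm import fit_glm_many
from .core_model import (
    FitConfig,
    FitResult,
    GMFData,
    GMFParams,
    GradientBlocks,
    full_gradients,
    linear_predictor,
    penalized_objective,
)
from .errors import GMFConfigError, GMFNumericalError
from .families import FamilySpec, estimate_dispersion, estimate_nb_size, eta_derivatives, make_family
from .identifiability import project_constraints

logger = logging.getLogger(__name__)

_MAX_HALVINGS = 10


# ---------------------------------------------------------------------------
# schedule and partitions
# ---------------------------------------------------------------------------

def learning_rate(t: int, k0: float, k1: float, tau: float) -> float:
    """rho_t = k0 / (1 + k0 k1 t)^tau, positive and non-increasing in t."""
    if not (0.5 < tau <= 1.0):
        raise GMFConfigError(
            "tau must lie in (1/2, 1] for the Robbins-Monro conditions "
            "sum rho_t = inf and sum rho_t^2 < inf"
        )
    if k0 <= 0 or k1 <= 0:
        raise GMFConfigError("k0 and k1 must be positive")
    return k0 / (1.0 + k0 * k1 * t) ** tau


def minibatch_partition(
    n: int, m: int, R: int, S: int, seed: int
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    """Random exact partitions of {0..n-1} into R chunks and {0..m-1} into S.

    Chunk sizes differ by at most one; the partition is a deterministic
    function of the seed.
    """
    if not (1 <= R <= n and 1 <= S <= m):
        raise GMFConfigError(f"invalid chunk counts R={R} (n={n}), S={S} (m={m})")
    rng = np.random.default_rng(seed)
    rows = np.array_split(rng.permutation(n), R)
    cols = np.array_split(rng.permutation(m), S)
    return rows, cols


# ---------------------------------------------------------------------------
# minibatch gradients and the adaptive step
# ---------------------------------------------------------------------------

@dataclass
class SGDState:
    """Smoothed accumulators, iteration counter and minibatch partitions."""

    Gbar_U: np.ndarray
    Hbar_U: np.ndarray
    Gbar_V: np.ndarray
    Hbar_V: np.ndarray
    Gbar_B: np.ndarray
    Hbar_B: np.ndarray
    Gbar_Gamma: np.ndarray
    Hbar_Gamma: np.ndarray
    t: int
    row_partition: List[np.ndarray]
    col_partition: List[np.ndarray]
    rng: np.random.Generator

    @staticmethod
    def initialize(
        data: GMFData, d: int, R: int, S: int, seed: int
    ) -> "SGDState":
        n, m, p, q = data.n, data.m, data.p, data.q
        rows, cols = minibatch_partition(n, m, R, S, seed)
        return SGDState(
            Gbar_U=np.zeros((n, d)),
            Hbar_U=np.zeros((n, d)),
            Gbar_V=np.zeros((m, d)),
            Hbar_V=np.zeros((m, d)),
            Gbar_B=np.zeros((m, p)),
            Hbar_B=np.zeros((m, p)),
            Gbar_Gamma=np.zeros((n, q)),
            Hbar_Gamma=np.zeros((n, q)),
            t=0,
            row_partition=rows,
            col_partition=cols,
            rng=np.random.default_rng(seed + 1),
        )


def minibatch_gradients(
    data: GMFData,
    params: GMFParams,
    rows: np.ndarray,
    cols: np.ndarray,
    penalty: float,
    family: FamilySpec,
    fisher: bool = True,
) -> GradientBlocks:
    """Unbiased stochastic gradient/curvature blocks on the block I x J.

    The likelihood parts are rescaled by m/m*_J (U, Gamma blocks) and
    n/n*_I (V, B blocks); masked in-block entries are imputed with the
    current mean before the derivative kernels are evaluated.
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if rows.size == 0 or cols.size == 0:
        raise GMFConfigError("empty minibatch block")
    eta = linear_predictor(data, params, rows, cols)
    mu, _ = family.mean_from_eta(eta)
    Yb = data.Y[np.ix_(rows, cols)]
    Mb = data.mask[np.ix_(rows, cols)]
    y_eff = np.where(Mb, Yb, mu)
    Wb = data.W[np.ix_(rows, cols)]
    phi = family.effective_phi(params.phi)
    dD, d2D = eta_derivatives(y_eff, mu, family, phi, Wb, fisher=fisher)
    cu = data.m / cols.size  # m / m*_J
    cv = data.n / rows.size  # n / n*_I
    U_I = params.U[rows]
    V_J = params.V[cols]
    X_I = data.X[rows]
    Z_J = data.Z[cols]
    lam = penalty
    return GradientBlocks(
        G_U=cu * (dD @ V_J) + lam * U_I,
        H_U=cu * (d2D @ (V_J * V_J)) + lam,
        G_V=cv * (dD.T @ U_I) + lam * V_J,
        H_V=cv * (d2D.T @ (U_I * U_I)) + lam,
        G_B=cv * (dD.T @ X_I),
        H_B=cv * (d2D.T @ (X_I * X_I)),
        G_Gamma=cu * (dD @ Z_J),
        H_Gamma=cu * (d2D @ (Z_J * Z_J)),
    )


def _bias_factor(t: int, a1: float, a2: float) -> float:
    den = 1.0 - a1**t
    if den <= 0.0:
        return 1.0
    return (1.0 - a2**t) / den


def sgd_step(
    state: SGDState,
    grads: GradientBlocks,
    params: GMFParams,
    config: FitConfig,
    rows: np.ndarray,
    cols: np.ndarray,
) -> Tuple[SGDState, GMFParams]:
    """One adaptive update of (V_J, B_J) then (U_I, Gamma_I), in place.

    Smoothed accumulators are refreshed on the touched rows only; the
    update is theta <- theta + rho_t * delta with
    delta = -alpha_t (Gbar / max(Hbar, floor)).  Rows outside I union J
    are bitwise unchanged.
    """
    a1, a2 = config.smoothing
    k0, k1, tau = config.schedule
    state.t += 1
    t = state.t
    rho = learning_rate(t - 1, k0, k1, tau)
    alpha_t = _bias_factor(t, a1, a2)
    floor = config.hessian_floor

    def _update(Gbar, Hbar, Ghat, Hhat, block, idx):
        Gbar[idx] = (1.0 - a1) * Gbar[idx] + a1 * Ghat
        Hbar[idx] = (1.0 - a2) * Hbar[idx] + a2 * Hhat
        delta = -alpha_t * Gbar[idx] / np.maximum(Hbar[idx], floor)
        if not np.all(np.isfinite(delta)):
            raise GMFNumericalError(
                f"non-finite SGD update at iteration {t} on a "
                f"{len(rows)}x{len(cols)} block"
            )
        block[idx] = block[idx] + rho * delta

    # V-then-U order, both from the derivatives at the current iterate
    _update(state.Gbar_V, state.Hbar_V, grads.G_V, grads.H_V, params.V, cols)
    _update(state.Gbar_B, state.Hbar_B, grads.G_B, grads.H_B, params.B, cols)
    _update(state.Gbar_U, state.Hbar_U, grads.G_U, grads.H_U, params.U, rows)
    _update(
        state.Gbar_Gamma, state.Hbar_Gamma, grads.G_Gamma, grads.H_Gamma,
        params.Gamma, rows,
    )
    return state, params


# ---------------------------------------------------------------------------
# shared fitting scaffolding
# ---------------------------------------------------------------------------

def _default_chunks(data: GMFData, config: FitConfig) -> Tuple[int, int]:
    if config.minibatch is not None:
        return config.minibatch
    R = max(1, int(np.ceil(data.n / min(data.n, 1000))))
    S = max(1, int(np.ceil(data.m / min(data.m, 250))))
    return R, S


def _monitor_mask(data: GMFData, fraction: float, seed: int) -> Optional[np.ndarray]:
    """Fixed seeded subsample of Omega used to monitor convergence."""
    if fraction >= 1.0:
        return None
    rng = np.random.default_rng(seed + 101)
    obs = np.argwhere(data.mask)
    k = max(1, int(round(fraction * obs.shape[0])))
    pick = obs[rng.choice(obs.shape[0], size=k, replace=False)]
    monitor = np.zeros(data.mask.shape, dtype=bool)
    monitor[pick[:, 0], pick[:, 1]] = True
    return monitor


def _family_for_fit(data, params, family):
    """Re-estimate an unknown negative binomial size once per epoch."""
    if family.name == "negbin" and family.aux_estimated:
        from .core_model import predict_mean

        mu = predict_mean(data, params, family)
        size = estimate_nb_size(data.Y, mu, data.W, data.mask)
        new = make_family("negbin", link=family.link.name, aux=size)
        return FamilySpec(
            **{**new.__dict__, "aux_estimated": True}
        )
    return family


def _manifest(data, config, family, algorithm, extra=None):
    man = {
        "algorithm": algorithm,
        "family": family.name,
        "link": family.link.name,
        "aux": family.aux,
        "d": config.d,
        "penalty": config.penalty,
        "max_epochs": config.max_epochs,
        "tol": config.tol,
        "seed": config.seed,
        "schedule": list(config.schedule),
        "smoothing": list(config.smoothing),
        "parametrization": config.parametrization,
        "fisher": config.fisher,
        "n": data.n,
        "m": data.m,
        "p": data.p,
        "q": data.q,
        "n_obs": data.n_obs,
    }
    if family.link_warning:
        man["link_warning"] = family.link_warning
    if extra:
        man.update(extra)
    return man


def _finalize(data, params, config, family, trace, converged, epochs, clip, man):
    if family.dispersion_mode == "estimated":
        from .core_model import predict_mean

        mu = predict_mean(data, params, family)
        npar = min(params.n_parameters(), data.n_obs - 1)
        params.phi = estimate_dispersion(data.Y, mu, family, data.W, npar, data.mask)
    # full-batch objective at the pre-projection optimum: the projection
    # preserves eta but redistributes ||U||^2 + ||V||^2, so this is the
    # value the optimizer actually attained
    man["final_objective"] = penalized_objective(
        data, params, config.penalty, family
    )
    projected = project_constraints(data, params, config.parametrization)
    projected.phi = params.phi
    return FitResult(
        params=projected,
        trace=trace,
        converged=converged,
        epochs_run=epochs,
        clip_events=clip,
        manifest=man,
    )


def _count_clips(data, params, family) -> int:
    eta = linear_predictor(data, params)
    _, n_clip = family.mean_from_eta(eta)
    return n_clip


# ---------------------------------------------------------------------------
# adaptive SGD (Algorithm: block-wise partial updates)
# ---------------------------------------------------------------------------

def fit_sgd(
    data: GMFData,
    init: GMFParams,
    config: FitConfig,
    family: FamilySpec,
) -> FitResult:
    """Block-wise adaptive stochastic gradient descent.

    One epoch sweeps all S column chunks; for each, a row chunk is drawn
    (cycling without replacement, reshuffled every epoch) and the paired
    (V_J, B_J) / (U_I, Gamma_I) adaptive updates are applied.  The final
    estimate is projected onto the identifiability constraints.
    """
    params = init.copy()
    R, S = _default_chunks(data, config)
    state = SGDState.initialize(data, config.d, R, S, config.seed)
    monitor = _monitor_mask(data, config.monitor_fraction, config.seed)
    fam = _family_for_fit(data, params, family)
    if fam.dispersion_mode == "estimated":
        params.phi = max(params.phi, 1e-8)

    obj0 = penalized_objective(data, params, config.penalty, fam, monitor)
    trace = [obj0]
    best_bound = abs(obj0) * config.divergence_factor + 1.0
    streak = 0
    converged = False
    epochs = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs = epoch
        order = state.rng.permutation(R)
        pos = 0
        for J in state.col_partition:
            if pos >= R:
                order = state.rng.permutation(R)
                pos = 0
            I = state.row_partition[order[pos]]
            pos += 1
            grads = minibatch_gradients(
                data, params, I, J, config.penalty, fam, fisher=config.fisher
            )
            state, params = sgd_step(state, grads, params, config, I, J)

        if fam.dispersion_mode == "estimated":
            # smoothed stochastic dispersion update, exponential weight a2:
            # mean Pearson statistic on the monitoring subsample with the
            # full-data degrees-of-freedom correction
            from .core_model import predict_mean

            mu = predict_mean(data, params, fam)
            sub = data.mask if monitor is None else (data.mask & monitor)
            npar = min(params.n_parameters(), data.n_obs - 1)
            mean_pearson = estimate_dispersion(data.Y, mu, fam, data.W, 0, sub)
            phi_hat = mean_pearson * data.n_obs / (data.n_obs - npar)
            a2 = config.smoothing[1]
            params.phi = float(
                max((1.0 - a2) * params.phi + a2 * phi_hat, 1e-8)
            )
        fam = _family_for_fit(data, params, fam)

        obj = penalized_objective(data, params, config.penalty, fam, monitor)
        change = abs(obj - trace[-1]) / max(1.0, abs(trace[-1]))
        trace.append(obj)
        if not np.isfinite(obj) or obj > best_bound:
            raise GMFNumericalError(
                f"objective diverged at epoch {epoch}: {obj:.6g} "
                f"(initial {obj0:.6g}); trace={trace}"
            )
        streak = streak + 1 if change < config.tol else 0
        if streak >= config.convergence_window:
            converged = True
            break

    clip = _count_clips(data, params, fam)
    man = _manifest(
        data, config, fam, "sgd",
        {"R": R, "S": S, "monitor_fraction": config.monitor_fraction},
    )
    return _finalize(data, params, config, fam, trace, converged, epochs, clip, man)


# ---------------------------------------------------------------------------
# diagonal quasi-Newton
# ---------------------------------------------------------------------------

def _apply_newton_step(params, grads, rho, floor):
    out = params.copy()
    out.U = params.U + rho * (-grads.G_U / np.maximum(grads.H_U, floor))
    out.V = params.V + rho * (-grads.G_V / np.maximum(grads.H_V, floor))
    if params.B.size:
        out.B = params.B + rho * (-grads.G_B / np.maximum(grads.H_B, floor))
    if params.Gamma.size:
        out.Gamma = params.Gamma + rho * (
            -grads.G_Gamma / np.maximum(grads.H_Gamma, floor)
        )
    return out


def fit_newton(
    data: GMFData,
    init: GMFParams,
    config: FitConfig,
    family: FamilySpec,
) -> FitResult:
    """Global diagonal quasi-Newton with damped line-halving.

    psi <- psi + rho * delta, delta = -(G/H) elementwise with the diagonal
    expected-information curvature; rho starts at ``config.step`` (default
    0.1) and is halved (at most 10 times) whenever the penalized objective
    would increase, guaranteeing a monotone trace over accepted steps.
    """
    params = init.copy()
    fam = _family_for_fit(data, params, family)
    rho0 = config.step if config.step is not None else 0.1
    obj = penalized_objective(data, params, config.penalty, fam)
    trace = [obj]
    streak = 0
    converged = False
    epochs = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs = epoch
        grads = full_gradients(data, params, config.penalty, fam, config.fisher)
        rho = rho0
        accepted = False
        for _ in range(_MAX_HALVINGS + 1):
            trial = _apply_newton_step(params, grads, rho, config.hessian_floor)
            try:
                obj_new = penalized_objective(data, trial, config.penalty, fam)
            except GMFNumericalError:
                obj_new = np.inf
            if obj_new <= obj:
                accepted = True
                break
            rho *= 0.5
        if not accepted:
            logger.info("newton: no descent after %d halvings at epoch %d",
                        _MAX_HALVINGS, epoch)
            trace.append(obj)
            break
        params, prev = trial, obj
        obj = obj_new
        trace.append(obj)
        fam = _family_for_fit(data, params, fam)
        change = abs(obj - prev) / max(1.0, abs(prev))
        streak = streak + 1 if change < config.tol else 0
        if streak >= config.convergence_window:
            converged = True
            break

    clip = _count_clips(data, params, fam)
    man = _manifest(data, config, fam, "newton", {"step": rho0})
    return _finalize(data, params, config, fam, trace, converged, epochs, clip, man)


# ---------------------------------------------------------------------------
# alternated IRWLS
# ---------------------------------------------------------------------------

def _airwls_half_cycle(
    data, params, config, fam, obj, update_cols: bool
):
    """One damped Fisher-scoring update of [B, V] (columns) or [Gamma, U]."""
    lam = config.penalty
    d = params.d
    if update_cols:
        A = np.hstack([data.X, params.U])  # (n, p+d), shared across columns
        coef0 = np.hstack([params.B, params.V])  # (m, p+d)
        offset = params.Gamma @ data.Z.T
        if data.offset is not None:
            offset = offset + data.offset
        Y, W, M = data.Y, data.W, data.mask
        ridge = np.concatenate([np.zeros(data.p), np.full(d, lam)])
    else:
        A = np.hstack([data.Z, params.V])  # (m, q+d), shared across rows
        coef0 = np.hstack([params.Gamma, params.U])  # (n, q+d)
        offset = (data.X @ params.B.T).T  # (m, n)
        if data.offset is not None:
            offset = offset + data.offset.T
        Y, W, M = data.Y.T, data.W.T, data.mask.T
        ridge = np.concatenate([np.zeros(data.q), np.full(d, lam)])
    if A.shape[1] == 0:
        return params, obj, 1.0
    target = fit_glm_many(
        Y, A, fam, W, M, offset, coef0=coef0, ridge=ridge,
        max_iter=1, fallback=False,
    ).coef
    rho = config.step if config.step is not None else 1.0
    for _ in range(_MAX_HALVINGS + 1):
        coef = coef0 + rho * (target - coef0)
        trial = params.copy()
        if update_cols:
            trial.B = coef[:, : data.p]
            trial.V = coef[:, data.p :]
        else:
            trial.Gamma = coef[:, : data.q]
            trial.U = coef[:, data.q :]
        try:
            obj_new = penalized_objective(data, trial, config.penalty, fam)
        except GMFNumericalError:
            obj_new = np.inf
        if obj_new <= obj:
            return trial, obj_new, rho
        rho *= 0.5
    return params, obj, 0.0


def fit_airwls(
    data: GMFData,
    init: GMFParams,
    config: FitConfig,
    family: FamilySpec,
) -> FitResult:
    """Alternated iterative re-weighted least squares.

    Each outer cycle performs one penalized Fisher-scoring solve for every
    column ([B_j, v_j] against design [X, U]) and every row
    ([gamma_i, u_i] against design [Z, V]); the ridge lambda acts on the
    latent coefficients only.  Masked entries enter with weight zero.
    Steps are halved whenever the objective would increase.
    """
    params = init.copy()
    fam = _family_for_fit(data, params, family)
    obj = penalized_objective(data, params, config.penalty, fam)
    trace = [obj]
    streak = 0
    converged = False
    epochs = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs = epoch
        prev = obj
        params, obj, rho_v = _airwls_half_cycle(
            data, params, config, fam, obj, update_cols=True
        )
        params, obj, rho_u = _airwls_half_cycle(
            data, params, config, fam, obj, update_cols=False
        )
        trace.append(obj)
        fam = _family_for_fit(data, params, fam)
        if rho_v == 0.0 and rho_u == 0.0:
            logger.info("airwls: stalled at epoch %d", epoch)
            break
        change = abs(obj - prev) / max(1.0, abs(prev))
        streak = streak + 1 if change < config.tol else 0
        if streak >= config.convergence_window:
            converged = True
            break

    clip = _count_clips(data, params, fam)
    man = _manifest(data, config, fam, "airwls", {"step": config.step or 1.0})
    return _finalize(data, params, config, fam, trace, converged, epochs, clip, man)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_FITTERS = {"sgd": fit_sgd, "newton": fit_newton, "airwls": fit_airwls}


def fit(
    data: GMFData,
    config: FitConfig,
    family: FamilySpec,
    init: Optional[GMFParams] = None,
    init_config=None,
) -> FitResult:
    """Initialize (unless given) and fit with the configured algorithm."""
    from .initialization import InitConfig, initialize

    if init is None:
        icfg = init_config or InitConfig(d=config.d, seed=config.seed)
        if icfg.d != config.d:
            raise GMFConfigError("init rank does not match fit rank")
        init = initialize(data, icfg, family)
    return _FITTERS[config.algorithm](data, init, config, family)
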