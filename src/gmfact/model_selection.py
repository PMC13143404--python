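"""Rank selection: information criteria, entrywise-holdout CV, spectral rules.

Three complementary routes to the latent dimension d:

* :func:`information_criteria` — AIC/BIC with the full parameter count
  k = pm + qn + d(n+m) + 1;
* :func:`cv_rank_select` — repeated entrywise holdout: a fraction of the
  observed cells is masked, the model fit on the remainder (the fitter's
  native missing-value handling imputes them), and the out-of-sample
  relative deviance is averaged per entry over folds; ranks are processed
  ascending with warm starts;
* :func:`spectral_rank` — eigengap or elbow rule on the singular values of
  the null-residual matrix (the regression-only fit of the initialization
  module, OLS fast path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_model import FitConfig, FitResult, GMFData, GMFParams, predict_mean
from .errors import GMFConfigError
from .estimators import fit as _fit
from .evaluation_metrics import relative_deviance, train_mean
from .families import FamilySpec
from .initialization import InitConfig, _residual_matrix, _truncated_svd, initialize
from .core_model import linear_predictor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# holdout split
# ---------------------------------------------------------------------------

def holdout_mask(
    n: int,
    m: int,
    fraction: float,
    seed: int,
    base_mask: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform entrywise train/test split of the observed positions.

    Returns boolean (train, test) masks forming a disjoint exhaustive
    split of Omega; every row and column retains at least one training
    entry (offending test entries are resampled back into the train set).
    """
    if not (0.0 < fraction < 1.0):
        raise GMFConfigError("holdout fraction must lie in (0, 1)")
    base = np.ones((n, m), bool) if base_mask is None else np.asarray(base_mask, bool)
    rng = np.random.default_rng(seed)
    obs = np.argwhere(base)
    k = int(round(fraction * obs.shape[0]))
    if k == 0:
        raise GMFConfigError("holdout fraction too small: empty test set")
    pick = rng.choice(obs.shape[0], size=k, replace=False)
    test = np.zeros((n, m), bool)
    test[obs[pick, 0], obs[pick, 1]] = True
    train = base & ~test

    for _ in range(100):
        bad_rows = np.flatnonzero(base.any(axis=1) & ~train.any(axis=1))
        bad_cols = np.flatnonzero(base.any(axis=0) & ~train.any(axis=0))
        if bad_rows.size == 0 and bad_cols.size == 0:
            break
        for i in bad_rows:
            cand = np.flatnonzero(test[i])
            j = cand[rng.integers(cand.size)]
            test[i, j] = False
            train[i, j] = True
        for j in bad_cols:
            cand = np.flatnonzero(test[:, j])
            if cand.size == 0:
                continue
            i = cand[rng.integers(cand.size)]
            test[i, j] = False
            train[i, j] = True
    else:
        raise GMFConfigError(
            "holdout fraction too large: cannot retain one training entry "
            "per row and column"
        )
    if not test.any():
        raise GMFConfigError("holdout fraction too large for the retention rule")
    return train, test


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def information_criteria(fit_result: FitResult, data: GMFData, family: FamilySpec):
    """(AIC, BIC) with k = pm + qn + d(n+m) + 1 parameters.

    AIC = 2 negloglik + 2k; BIC = 2 negloglik + k log|Omega|, with the
    log-likelihood evaluated over the observed entries (penalty excluded).
    """
    params = fit_result.params
    mu = predict_mean(data, params, family)
    y_safe = np.where(data.mask, data.Y, mu)
    ll = family.log_density(y_safe, mu, params.phi, data.W)
    negll = -float(ll[data.mask].sum())
    k = params.n_parameters()
    aic = 2.0 * negll + 2.0 * k
    bic = 2.0 * negll + k * np.log(data.n_obs)
    return aic, bic


# ---------------------------------------------------------------------------
# cross-validated rank selection
# ---------------------------------------------------------------------------

@dataclass
class RankSelectionResult:
    """Per-rank criteria and the chosen rank per criterion."""

    grid: List[int]
    cv_deviance: np.ndarray          # (folds, ranks), NaN for failed cells
    mean_cv_deviance: np.ndarray     # (ranks,)
    aic: Optional[np.ndarray]
    bic: Optional[np.ndarray]
    best_rank_cv: int
    best_rank_aic: Optional[int]
    best_rank_bic: Optional[int]
    singular_values: np.ndarray
    n_failed: int = 0


def _pad_warm_start(params: GMFParams, d_new: int, rng) -> GMFParams:
    """Grow (U, V) to rank d_new; new columns get small seeded noise.

    A zero column pair is an exact stationary point of the penalized
    objective, so the pad uses sd 1e-2 Gaussian entries instead.
    """
    out = params.copy()
    add = d_new - out.d
    if add <= 0:
        return out
    n, m = out.U.shape[0], out.V.shape[0]
    out.U = np.hstack([out.U, 1e-2 * rng.standard_normal((n, add))])
    out.V = np.hstack([out.V, 1e-2 * rng.standard_normal((m, add))])
    return out


def cv_rank_select(
    data: GMFData,
    grid: Sequence[int],
    folds: int,
    config: FitConfig,
    family: FamilySpec,
    seed: int = 0,
    fraction: float = 0.3,
    compute_ic: bool = True,
) -> RankSelectionResult:
    """Rank selection by repeated entrywise holdout.

    ``folds`` independent uniform holdouts at ``fraction`` (not a
    partition of Omega) are drawn; for each fold and each rank of the
    ascending grid the model is fit on the training entries (warm-started
    from the previous rank) and scored by relative deviance on the
    held-out entries.  The test entries are masked before initialization
    and fitting, so they never leak into the estimate.
    """
    grid = sorted(int(d) for d in grid)
    if grid[0] < 0 or grid[-1] > min(data.n, data.m):
        raise GMFConfigError("rank grid outside [0, min(n, m)]")
    rng = np.random.default_rng(seed)
    cv = np.full((folds, len(grid)), np.nan)
    n_failed = 0

    for f in range(folds):
        train, test = holdout_mask(
            data.n, data.m, fraction, seed + 7 * f, base_mask=data.mask
        )
        fold_data = data.with_mask(train)
        ybar = train_mean(data.Y, train)
        warm = None
        for r, d in enumerate(grid):
            cfg = FitConfig(**{**config.__dict__, "d": d, "seed": seed + f})
            try:
                if warm is None:
                    res = _fit(fold_data, cfg, family)
                else:
                    init = _pad_warm_start(warm, d, rng)
                    res = _fit(fold_data, cfg, family, init=init)
                mu = predict_mean(fold_data, res.params, family)
                cv[f, r] = relative_deviance(
                    data.Y, mu, ybar, test, family, data.W
                )
                warm = res.params
                if not res.converged:
                    logger.warning(
                        "cv fold %d rank %d: not converged after %d epochs",
                        f, d, res.epochs_run,
                    )
            except Exception as exc:  # noqa: BLE001 - recorded, fold skipped
                n_failed += 1
                logger.warning("cv fold %d rank %d failed: %s", f, d, exc)

    mean_cv = np.nanmean(cv, axis=0)
    if np.all(np.isnan(mean_cv)):
        raise GMFConfigError("all cross-validation cells failed")
    best_cv = grid[int(np.nanargmin(mean_cv))]

    aic = bic = None
    best_aic = best_bic = None
    if compute_ic:
        aic = np.full(len(grid), np.nan)
        bic = np.full(len(grid), np.nan)
        warm = None
        for r, d in enumerate(grid):
            cfg = FitConfig(**{**config.__dict__, "d": d, "seed": seed})
            if warm is None:
                res = _fit(data, cfg, family)
            else:
                res = _fit(data, cfg, family, init=_pad_warm_start(warm, d, rng))
            aic[r], bic[r] = information_criteria(res, data, family)
            warm = res.params
        best_aic = grid[int(np.nanargmin(aic))]
        best_bic = grid[int(np.nanargmin(bic))]

    sv = _null_residual_singular_values(
        data, family, min(min(data.n, data.m) - 1, max(grid) + 5 if grid else 10),
        seed,
    )
    return RankSelectionResult(
        grid=grid,
        cv_deviance=cv,
        mean_cv_deviance=mean_cv,
        aic=aic,
        bic=bic,
        best_rank_cv=best_cv,
        best_rank_aic=best_aic,
        best_rank_bic=best_bic,
        singular_values=sv,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# spectral thresholding
# ---------------------------------------------------------------------------

def _null_residual_singular_values(
    data: GMFData, family: FamilySpec, dmax: int, seed: int
) -> np.ndarray:
    """Leading singular values of the regression-only residual matrix.

    The residuals are deviance residuals at the OLS-on-transformed-response
    null fit (the initialization module's fast path with d = 0).
    """
    icfg = InitConfig(method="ols", residual_type="deviance", d=0, seed=seed)
    params0 = initialize(data, icfg, family)
    eta0 = linear_predictor(data, params0)
    mu0, _ = family.mean_from_eta(eta0)
    R = _residual_matrix(data, mu0, family, "deviance")
    k = min(dmax + 1, min(data.n, data.m))
    _, s, _ = _truncated_svd(R, k, seed)
    return s


def spectral_rank(
    data: GMFData,
    family: FamilySpec,
    dmax: int,
    rule: str = "eigengap",
    seed: int = 0,
) -> Tuple[int, np.ndarray]:
    """Select the rank from the null-residual scree profile.

    ``eigengap`` returns argmax_k (sigma_k - sigma_{k+1}) for k <= dmax;
    ``elbow`` locates the knee of the (convex, decreasing) profile as the
    point of maximum distance below the chord joining the endpoints and
    returns the component just before it — the last one above the bend.
    """
    if dmax < 1:
        raise GMFConfigError("dmax must be at least 1")
    if dmax > min(data.n, data.m) - 1:
        raise GMFConfigError("dmax must be at most min(n, m) - 1")
    if rule not in ("eigengap", "elbow"):
        raise GMFConfigError("rule must be 'eigengap' or 'elbow'")
    s = _null_residual_singular_values(data, family, dmax, seed)
    if dmax == 1:
        logger.warning("degenerate spectral profile: dmax=1 forces rank 1")
        return 1, s
    if rule == "eigengap":
        gaps = s[:dmax] - s[1 : dmax + 1]
        return int(np.argmax(gaps)) + 1, s
    # elbow: signed distance below the chord from (1, s_1) to (dmax, s_dmax)
    ks = np.arange(1, dmax + 1, dtype=float)
    sv = s[:dmax]
    chord = sv[0] + (sv[-1] - sv[0]) * (ks - 1.0) / (dmax - 1.0)
    below = chord - sv
    knee = int(np.argmax(below)) + 1
    return max(1, knee - 1), s
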