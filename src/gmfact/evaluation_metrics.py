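"""Out-of-sample reconstruction metrics.

Both metrics compare the model's predictions on a held-out entry set V
against the constant train-mean predictor ybar_T: values below 1 mean the
model reconstructs the held-out entries better than the null predictor.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .errors import GMFConfigError
from .families import FamilySpec, deviance


def train_mean(Y: np.ndarray, train_mask: np.ndarray) -> float:
    """Empirical mean of the observed training entries."""
    if not train_mask.any():
        raise GMFConfigError("empty training set")
    return float(Y[train_mask].mean())


def relative_log_rmse(
    Y: np.ndarray,
    mu_hat: np.ndarray,
    ybar_train: float,
    test_mask: np.ndarray,
) -> float:
    """Relative logarithmic root mean squared error on the test set:

        sum_V [log(1+y) - log(1+mu_hat)]^2 / sum_V [log(1+y) - log(1+ybar_T)]^2.
    """
    if not test_mask.any():
        raise GMFConfigError("empty test set")
    y = Y[test_mask]
    mu = np.asarray(mu_hat)[test_mask]
    num = np.sum((np.log1p(y) - np.log1p(mu)) ** 2)
    den = np.sum((np.log1p(y) - np.log1p(ybar_train)) ** 2)
    if den <= 0:
        raise GMFConfigError(
            "undefined metric: test responses all equal the train mean"
        )
    return float(num / den)


def relative_deviance(
    Y: np.ndarray,
    mu_hat: np.ndarray,
    ybar_train: float,
    test_mask: np.ndarray,
    family: FamilySpec,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Relative deviance on the test set:

        sum_V D(y, mu_hat) / sum_V D(y, ybar_T),

    with the family's unit deviance D.
    """
    if not test_mask.any():
        raise GMFConfigError("empty test set")
    y = Y[test_mask]
    mu = np.asarray(mu_hat)[test_mask]
    w = None if weights is None else np.asarray(weights)[test_mask]
    ybar = family.clip_mean(np.full_like(y, ybar_train))
    num = np.sum(deviance(y, family.clip_mean(mu), family, w))
    den = np.sum(deviance(y, ybar, family, w))
    if den <= 0:
        raise GMFConfigError(
            "undefined metric: null deviance on the test set is zero"
        )
    return float(num / den)
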