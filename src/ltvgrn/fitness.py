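"""Multi-replicate mean-squared-error objective for model fitting.

The objective compares model-computed expression against the observed
series over every replicate, gene and predicted time point:

    MSE = (1 / (M * n * (T-1))) * sum_k sum_i sum_t e_{k,i}(t)^2

where the per-point error is relative, ``(X_cal - X_exp) / X_exp``
(Tominaga-style; requires strictly positive observations), or absolute,
``X_cal - X_exp``.  The first point of each series anchors the recursion
and is never scored, hence T-1 scored points per series.

``mse_population`` evaluates a whole population of flattened parameter
vectors at once; the differential-evolution driver calls it once per
generation, which keeps a full inference run in the seconds range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .ltv_core import ExpressionSeriesSet, LTVParameters, simulate_trajectory

__all__ = ["FitnessConfig", "mse", "mse_population"]

_MODES = ("free_run", "one_step")
_NORMALIZATIONS = ("relative", "absolute")


@dataclass(frozen=True)
class FitnessConfig:
    """Objective settings: trajectory mode and error normalization."""

    mode: str = "free_run"
    normalization: str = "relative"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.normalization not in _NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {_NORMALIZATIONS}")


def mse(params: LTVParameters, data: ExpressionSeriesSet, cfg: FitnessConfig = FitnessConfig()) -> float:
    """Mean squared (relative) error of the model against all replicates."""
    obs = data.as_array()  # (M, T, n)
    M, T, n = obs.shape
    if T < 2:
        raise ValueError("need at least two time points to score predictions")
    if cfg.normalization == "relative" and np.any(obs[:, 1:, :] <= 0):
        raise ValueError(
            "relative normalization requires positive observations; "
            "preprocess with normalize() to replace zeros"
        )
    total = 0.0
    for k in range(M):
        pred = simulate_trajectory(
            params, x0=obs[k, 0], T=T, mode=cfg.mode, observed=obs[k] if cfg.mode == "one_step" else None
        )
        diff = pred[1:] - obs[k, 1:]
        if cfg.normalization == "relative":
            diff = diff / obs[k, 1:]
        total += float(np.sum(diff**2))
    return total / (M * n * (T - 1))


def mse_population(
    thetas: np.ndarray,
    data: ExpressionSeriesSet,
    cfg: FitnessConfig = FitnessConfig(),
) -> np.ndarray:
    """Objective for P flattened parameter vectors at once.

    ``thetas`` is (P, D) with D = 3 n^2 + n in the LTVParameters flattening
    (alpha, beta, phi row-major, then omega).  Returns a length-P vector of
    objective values.  Matches :func:`mse` applied row by row.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    obs = data.as_array()  # (M, T, n)
    M, T, n = obs.shape
    P, D = thetas.shape
    nn = n * n
    if D != 3 * nn + n:
        raise ValueError(f"theta length {D} does not match n={n} (expected {3 * nn + n})")
    if cfg.normalization == "relative" and np.any(obs[:, 1:, :] <= 0):
        raise ValueError("relative normalization requires positive observations")

    alpha = thetas[:, :nn].reshape(P, n, n)
    beta = thetas[:, nn : 2 * nn].reshape(P, n, n)
    phi = thetas[:, 2 * nn : 3 * nn].reshape(P, n, n)
    omega = thetas[:, 3 * nn :]  # (P, n)

    # state for every (individual, replicate): (P, M, n)
    x = np.broadcast_to(obs[None, :, 0, :], (P, M, n)).copy()
    err = np.zeros(P)
    for t in range(T - 1):
        w = beta + alpha * np.sin(omega[:, :, None] * t + phi)  # (P, n, n)
        z = np.einsum("pij,pmj->pmi", w, x)
        pred = expit(z)
        diff = pred - obs[None, :, t + 1, :]
        if cfg.normalization == "relative":
            diff = diff / obs[None, :, t + 1, :]
        err += np.einsum("pmi,pmi->p", diff, diff)
        if cfg.mode == "one_step":
            x = np.broadcast_to(obs[None, :, t + 1, :], (P, M, n)).copy()
        else:
            x = pred
    return err / (M * n * (T - 1))
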