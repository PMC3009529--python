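"""Linear time-variant weight-matrix model of gene regulation.

A network of ``n`` genes is described by a time-varying weight matrix

    W_ij(t) = beta_ij + alpha_ij * sin(omega_i * t + phi_ij)

where ``beta_ij`` is the constant (linear) part of the influence of gene j
on gene i and the single sinusoid term absorbs the nonlinear part of the
interaction.  The angular frequency ``omega_i`` is shared by every input of
the regulated gene i; amplitude and phase are per pair.  Total regulatory
input to gene i at time t is ``Z_i(t) = sum_j W_ij(t) x_j(t)`` and the
response one sampling step later is the squashed input
``x_i(t+1) = sigma(Z_i(t))`` with the logistic function
``sigma(z) = 1 / (1 + exp(-z))``, so predicted expression always lies in
(0, 1).

Time ``t`` is the integer sampling index of the series (0, 1, 2, ...), not
wall-clock time: typical fitted ``omega`` magnitudes (~0.1-0.5 rad/step)
then give sub-period weight variation over a ~11-point series, which is the
regime the sinusoid correction is meant for.

A positive fitted ``W_ij`` is read as gene j inducing gene i, a negative
one as repression, and zero as no influence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "LTVParameters",
    "ExpressionSeriesSet",
    "Bounds",
    "weight_at",
    "weight_matrix_at",
    "regulatory_input",
    "squash",
    "predict_one_step",
    "simulate_trajectory",
    "static_weight_matrix",
]


@dataclass
class LTVParameters:
    """Full parameter set {alpha, beta, phi, omega} of the model.

    alpha, beta, phi are (n, n) arrays indexed [target i, regulator j];
    omega is length n, one angular frequency per regulated gene.
    """

    alpha: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    omega: np.ndarray
    gene_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.alpha.shape[0]
        if self.alpha.shape != (n, n) or self.beta.shape != (n, n) or self.phi.shape != (n, n):
            raise ValueError("alpha, beta, phi must all be n x n with the same n")
        if self.omega.shape != (n,):
            raise ValueError("omega must be a length-n vector (one frequency per regulated gene)")
        if n < 1:
            raise ValueError("need at least one gene")
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must equal n")

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to a length 3n^2 + n vector: alpha, beta, phi row-major, then omega."""
        return np.concatenate(
            [self.alpha.ravel(), self.beta.ravel(), self.phi.ravel(), self.omega]
        )

    @classmethod
    def from_vector(cls, theta: np.ndarray, n: int, gene_names: list[str] | None = None) -> "LTVParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (3 * n * n + n,):
            raise ValueError(f"expected vector of length {3 * n * n + n}, got {theta.shape}")
        nn = n * n
        return cls(
            alpha=theta[:nn].reshape(n, n),
            beta=theta[nn : 2 * nn].reshape(n, n),
            phi=theta[2 * nn : 3 * nn].reshape(n, n),
            omega=theta[3 * nn :],
            gene_names=gene_names,
        )


@dataclass
class ExpressionSeriesSet:
    """M replicate time-series, each T time points by n genes.

    ``series`` is a list of (T, n) arrays sharing the time grid and gene
    order.  Expression levels are non-negative; after :func:`~ltvgrn.simulators.normalize`
    every value lies in (0, 1].
    """

    series: list[np.ndarray]
    times: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.series = [np.asarray(s, dtype=float) for s in self.series]
        self.times = np.asarray(self.times, dtype=float)
        if not self.series:
            raise ValueError("need at least one replicate series")
        T, n = self.series[0].shape
        for k, s in enumerate(self.series):
            if s.shape != (T, n):
                raise ValueError(f"replicate {k} has shape {s.shape}, expected {(T, n)}")
        if self.times.shape != (T,):
            raise ValueError("times length must match the number of sampling points")
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match the number of genes")

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_times(self) -> int:
        return self.series[0].shape[0]

    @property
    def n_genes(self) -> int:
        return self.series[0].shape[1]

    def as_array(self) -> np.ndarray:
        """Stack replicates into an (M, T, n) array."""
        return np.stack(self.series, axis=0)


@dataclass(frozen=True)
class Bounds:
    """Search region per parameter class, as (lower, upper) pairs.

    Defaults are the benchmark settings: amplitude alpha in [-10, 10],
    linear weight beta in [-3, 3], phase phi and frequency omega in
    [-pi/2, pi/2] radians.
    """

    alpha: tuple[float, float] = (-10.0, 10.0)
    beta: tuple[float, float] = (-3.0, 3.0)
    phi: tuple[float, float] = (-np.pi / 2, np.pi / 2)
    omega: tuple[float, float] = (-np.pi / 2, np.pi / 2)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "phi", "omega"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} bounds must satisfy lower < upper, got ({lo}, {hi})")

    def lower_vector(self, n: int) -> np.ndarray:
        """Per-component lower bounds matching the flattening of LTVParameters."""
        nn = n * n
        return np.concatenate(
            [
                np.full(nn, self.alpha[0]),
                np.full(nn, self.beta[0]),
                np.full(nn, self.phi[0]),
                np.full(n, self.omega[0]),
            ]
        )

    def upper_vector(self, n: int) -> np.ndarray:
        nn = n * n
        return np.concatenate(
            [
                np.full(nn, self.alpha[1]),
                np.full(nn, self.beta[1]),
                np.full(nn, self.phi[1]),
                np.full(n, self.omega[1]),
            ]
        )


def weight_matrix_at(params: LTVParameters, t: float) -> np.ndarray:
    """Full (n, n) weight matrix W(t) = beta + alpha * sin(omega_i t + phi)."""
    return params.beta + params.alpha * np.sin(params.omega[:, None] * t + params.phi)


def weight_at(params: LTVParameters, i: int, j: int, t: float) -> float:
    """Time-varying weight W_ij(t) of regulator j on target i."""
    n = params.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"gene indices ({i}, {j}) out of range for n={n}")
    return float(params.beta[i, j] + params.alpha[i, j] * np.sin(params.omega[i] * t + params.phi[i, j]))


def regulatory_input(params: LTVParameters, x: np.ndarray, t: float) -> np.ndarray:
    """Total regulatory input Z(t) = W(t) x for a state vector x at time t."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise ValueError(f"state must have length n={params.n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite values")
    return weight_matrix_at(params, t) @ x


def squash(z, fn: Callable | None = None):
    """Squashing function mapping regulatory input into (0, 1).

    Defaults to the logistic sigmoid 1/(1 + exp(-z)); pass ``fn`` to use an
    alternative bounded monotone map.
    """
    if fn is not None:
        return fn(z)
    return expit(z)


def predict_one_step(params: LTVParameters, x_t: np.ndarray, t: float) -> np.ndarray:
    """Next-step expression x(t+1) = sigma(W(t) x(t))."""
    return squash(regulatory_input(params, x_t, t))


def simulate_trajectory(
    params: LTVParameters,
    x0: np.ndarray | None = None,
    T: int = 11,
    mode: str = "free_run",
    observed: np.ndarray | None = None,
) -> np.ndarray:
    """Roll the model forward for T sampling points.

    In ``free_run`` mode the model iterates on its own predictions from
    ``x0``.  In ``one_step`` (teacher-forcing) mode each prediction is made
    from the *observed* previous point, which requires the observed (T, n)
    series.  Row 0 is the anchor (x0 or the observed first row) in both
    modes; the time variable is the sampling index.
    """
    if T < 1:
        raise ValueError("T must be at least 1")
    if mode not in ("free_run", "one_step"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "one_step":
        if observed is None:
            raise ValueError("one_step mode requires the observed series")
        observed = np.asarray(observed, dtype=float)
        if observed.shape[0] < T:
            raise ValueError("observed series shorter than requested T")
        x0 = observed[0]
    if x0 is None:
        raise ValueError("free_run mode requires an initial state x0")
    x0 = np.asarray(x0, dtype=float)
    out = np.empty((T, params.n))
    out[0] = x0
    for t in range(T - 1):
        prev = observed[t] if mode == "one_step" else out[t]
        out[t + 1] = predict_one_step(params, prev, t)
    return out


def static_weight_matrix(params: LTVParameters, times: Sequence[float]) -> np.ndarray:
    """Static network summary: the time-average of W(t) over the sampling grid.

    Equals beta exactly when alpha is zero or when the grid spans whole
    sinusoid periods; for a single time point it is just W(t0).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times grid must be non-empty")
    # (T, n, n) stack of instantaneous weights, averaged over T
    w = params.beta[None, :, :] + params.alpha[None, :, :] * np.sin(
        params.omega[None, :, None] * times[:, None, None] + params.phi[None, :, :]
    )
    return w.mean(axis=0)
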