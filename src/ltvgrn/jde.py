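"""Self-adaptive differential evolution (jDE) in the DE/rand/1/bin scheme.

Each of the NP individuals carries, besides its D-dimensional parameter
vector, its own amplification factor F and crossover rate CR.  At every
generation, before the DE operators run, each individual resamples its
control parameters with small probabilities tau1 and tau2:

    F_new  = F_low + rand1 * F_upp   if rand2 < tau1 else F      (F in [0.1, 1.0])
    CR_new = rand3                   if rand4 < tau2 else CR     (CR in [0, 1])

so good control settings propagate together with good solutions.  Mutation
is DE/rand/1 (donor = x_r1 + F (x_r2 - x_r3) with r1, r2, r3 distinct and
different from the target), crossover is binomial with a forced index, out
of-bounds trial components are clamped to the boundary, and selection is
greedy (ties keep the trial, which lets the population drift across
plateaus).

``run`` drives the loop fully vectorised over the population: the
objective is called once per generation on an (NP, D) array.  All
stochastic draws come from one ``numpy.random.Generator`` seeded from the
config, in a fixed order per generation (control-parameter draws, mutation
indices, crossover mask, forced indices), so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "JdeConfig",
    "JdeResult",
    "initialize_population",
    "adapt_control",
    "mutate",
    "crossover",
    "repair_bounds",
    "select",
    "run",
]


@dataclass
class Individual:
    """One population member: parameter vector, own F and CR, cached fitness."""

    theta: np.ndarray
    F: float = 0.5
    CR: float = 0.9
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if not 0.1 <= self.F <= 1.0:
            raise ValueError("F must lie in [0.1, 1.0]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must lie in [0, 1]")


@dataclass(frozen=True)
class JdeConfig:
    NP: int = 200
    max_generations: int = 10_000
    tau1: float = 0.1
    tau2: float = 0.1
    F_low: float = 0.1
    F_upp: float = 0.9
    F_init: float = 0.5
    CR_init: float = 0.9
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.NP < 4:
            raise ValueError("NP must be at least 4 (mutation draws 3 distinct non-target members)")
        for name in ("tau1", "tau2", "CR_init"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class JdeResult:
    best: Individual
    history: pd.DataFrame = field(repr=False)
    population: np.ndarray = field(repr=False)
    fitnesses: np.ndarray = field(repr=False)


def initialize_population(
    lower: np.ndarray,
    upper: np.ndarray,
    cfg: JdeConfig,
    objective: Callable[[np.ndarray], np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """NP individuals uniform within the per-component bounds, F and CR at their initial values."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if cfg.NP < 4:
        raise ValueError("NP must be at least 4")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    thetas = lower + rng.uniform(size=(cfg.NP, lower.size)) * (upper - lower)
    fits = objective(thetas) if objective is not None else [None] * cfg.NP
    return [
        Individual(theta=thetas[i], F=cfg.F_init, CR=cfg.CR_init, fitness=None if fits[i] is None else float(fits[i]))
        for i in range(cfg.NP)
    ]


def adapt_control(
    F: float,
    CR: float,
    rands: tuple[float, float, float, float],
    cfg: JdeConfig = JdeConfig(),
) -> tuple[float, float]:
    """Self-adaptation rule for one individual's control parameters.

    ``rands`` are four uniform [0, 1) draws; applied *before* mutation so
    the new F and CR govern this generation's operators.
    """
    r1, r2, r3, r4 = rands
    F_new = cfg.F_low + r1 * cfg.F_upp if r2 < cfg.tau1 else F
    CR_new = r3 if r4 < cfg.tau2 else CR
    return F_new, CR_new


def mutate(thetas: np.ndarray, target_idx: int, F: float, rng: np.random.Generator) -> np.ndarray:
    """DE/rand/1 donor: x_r1 + F (x_r2 - x_r3), r1 r2 r3 distinct, != target."""
    NP = thetas.shape[0]
    if NP < 4:
        raise ValueError("mutation needs at least 4 population members")
    candidates = np.delete(np.arange(NP), target_idx)
    r1, r2, r3 = rng.choice(candidates, size=3, replace=False)
    return thetas[r1] + F * (thetas[r2] - thetas[r3])


def crossover(target: np.ndarray, donor: np.ndarray, CR: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover with one forced donor index j_rand."""
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if target.shape != donor.shape:
        raise ValueError("target and donor must have equal length")
    D = target.size
    mask = rng.uniform(size=D) < CR
    mask[rng.integers(D)] = True
    return np.where(mask, donor, target)


def repair_bounds(theta: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Clamp out-of-bounds components to the boundary value."""
    return np.clip(theta, lower, upper)


def select(target: Individual, trial: Individual) -> Individual:
    """Greedy minimising selection; ties keep the trial."""
    if target.fitness is None or trial.fitness is None:
        raise ValueError("both individuals must have evaluated fitness")
    return trial if trial.fitness <= target.fitness else target


def _distinct_triples(rng: np.random.Generator, NP: int) -> np.ndarray:
    """(NP, 3) mutation indices, rows distinct and different from the row index."""
    idx = rng.integers(0, NP, size=(NP, 3))
    target = np.arange(NP)
    while True:
        bad = (
            (idx[:, 0] == target)
            | (idx[:, 1] == target)
            | (idx[:, 2] == target)
            | (idx[:, 0] == idx[:, 1])
            | (idx[:, 0] == idx[:, 2])
            | (idx[:, 1] == idx[:, 2])
        )
        n_bad = int(bad.sum())
        if n_bad == 0:
            return idx
        idx[bad] = rng.integers(0, NP, size=(n_bad, 3))


def run(
    objective: Callable[[np.ndarray], np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    cfg: JdeConfig,
) -> JdeResult:
    """Full jDE minimisation loop.

    ``objective`` receives an (NP, D) array and returns NP values; it is
    called once for the initial population and once per generation on the
    trial vectors (one evaluation per trial, targets are never rescored).
    Returns the best individual plus a per-generation history of best/mean
    objective and mean control parameters.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    NP, D = cfg.NP, lower.size

    thetas = lower + rng.uniform(size=(NP, D)) * (upper - lower)
    F = np.full(NP, cfg.F_init)
    CR = np.full(NP, cfg.CR_init)
    fit = np.asarray(objective(thetas), dtype=float)

    rows = []
    for gen in range(cfg.max_generations):
        r = rng.uniform(size=(NP, 4))
        F_new = np.where(r[:, 1] < cfg.tau1, cfg.F_low + r[:, 0] * cfg.F_upp, F)
        CR_new = np.where(r[:, 3] < cfg.tau2, r[:, 2], CR)

        idx = _distinct_triples(rng, NP)
        donors = thetas[idx[:, 0]] + F_new[:, None] * (thetas[idx[:, 1]] - thetas[idx[:, 2]])

        mask = rng.uniform(size=(NP, D)) < CR_new[:, None]
        mask[np.arange(NP), rng.integers(0, D, size=NP)] = True
        trials = np.where(mask, donors, thetas)
        np.clip(trials, lower, upper, out=trials)

        trial_fit = np.asarray(objective(trials), dtype=float)
        better = trial_fit <= fit
        thetas[better] = trials[better]
        fit[better] = trial_fit[better]
        F[better] = F_new[better]
        CR[better] = CR_new[better]

        rows.append(
            (gen, float(fit.min()), float(fit.mean()), float(F.mean()), float(CR.mean()))
        )

    best_i = int(np.argmin(fit))
    best = Individual(theta=thetas[best_i].copy(), F=float(F[best_i]), CR=float(CR[best_i]), fitness=float(fit[best_i]))
    history = pd.DataFrame(rows, columns=["generation", "best_mse", "mean_mse", "mean_F", "mean_CR"])
    return JdeResult(best=best, history=history, population=thetas, fitnesses=fit)
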