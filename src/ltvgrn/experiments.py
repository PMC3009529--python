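"""End-to-end benchmark experiments: simulate, infer, consense, score.

Each named experiment reproduces one benchmark condition:

* ``noise-free`` — the 5-gene S-system network, 10 replicates of 11
  samples, no measurement noise;
* ``noise5`` / ``noise10`` — the same design with 5% / 10% multiplicative
  Gaussian noise;
* ``camp`` — the seven-component cAMP oscillator, 5 replicates of 10
  samples.

An experiment draws the dataset, runs R independent seeded jDE fits of the
linear time-variant model, reduces each fit to a static weight matrix
(time average over the sampling grid), scores each run's thresholded
network against the gold standard, and also forms the Z-score consensus
network across runs.  Sub-seeds for the dataset, the noise and every run
are derived deterministically from the experiment seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitness import FitnessConfig, mse_population
from .jde import JdeConfig, JdeResult, run as jde_run
from .ltv_core import Bounds, ExpressionSeriesSet, LTVParameters, static_weight_matrix
from .netextract import (
    ConsensusResult,
    GoldStandard,
    ScoreResult,
    camp_gold_standard,
    extract_network,
    gold_from_ssystem,
    sensitivity_specificity,
    zscore_consensus,
)
from .simulators import (
    OdeRunConfig,
    add_noise,
    five_gene_benchmark,
    generate_camp_dataset,
    generate_ssystem_dataset,
    normalize,
)

__all__ = ["ExperimentSettings", "ExperimentResult", "EXPERIMENTS", "make_dataset", "infer_dataset", "run_experiment"]

EXPERIMENTS = ("noise-free", "noise5", "noise10", "camp")


@dataclass(frozen=True)
class ExperimentSettings:
    """Scale and thresholds of one benchmark experiment."""

    name: str = "noise-free"
    runs: int = 10
    generations: int = 10_000
    NP: int = 200
    seed: int = 0
    z_threshold: float = 1.0
    magnitude_threshold: float = 0.5
    fitness_mode: str = "free_run"

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}")
        if self.runs < 1:
            raise ValueError("need at least one run")


@dataclass
class ExperimentResult:
    settings: ExperimentSettings
    data: ExpressionSeriesSet = field(repr=False)
    gold: GoldStandard = field(repr=False)
    run_params: list[LTVParameters] = field(repr=False)
    run_weights: list[np.ndarray] = field(repr=False)
    run_scores: list[ScoreResult]
    run_mse: list[float]
    consensus: ConsensusResult | None = field(repr=False)
    consensus_score: ScoreResult | None
    histories: list = field(repr=False, default_factory=list)

    @property
    def mean_sn(self) -> float:
        return float(np.mean([s.sn for s in self.run_scores]))

    @property
    def mean_sp(self) -> float:
        return float(np.mean([s.sp for s in self.run_scores]))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.run_mse))


def make_dataset(name: str, seed: int) -> tuple[ExpressionSeriesSet, GoldStandard, Bounds]:
    """Dataset, gold standard and search bounds for a named experiment.

    Synthetic S-system observations are normalized per gene to (0, 1]
    (after noise injection for the noisy conditions) so they live on the
    scale the squashing model emits.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, noise_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    if name in ("noise-free", "noise5", "noise10"):
        p = five_gene_benchmark()
        cfg = OdeRunConfig(t_end=0.5, n_points=11, step=1e-3, init_range=(0.05, 1.0), n_replicates=10, seed=data_seed)
        data = generate_ssystem_dataset(p, cfg)
        level = {"noise-free": 0.0, "noise5": 0.05, "noise10": 0.10}[name]
        if level > 0:
            data = add_noise(data, level, seed=noise_seed)
        data = normalize(data)
        gold = gold_from_ssystem(p)
        bounds = Bounds(alpha=(-10.0, 10.0), beta=(-3.0, 3.0))
    elif name == "camp":
        cfg = OdeRunConfig(t_end=9.0, n_points=10, step=1e-3, init_range=(0.1, 2.0), n_replicates=5, seed=data_seed)
        data = generate_camp_dataset(cfg=cfg)
        gold = camp_gold_standard()
        bounds = Bounds(alpha=(-5.0, 5.0), beta=(-3.0, 3.0))
    else:
        raise ValueError(f"unknown experiment {name!r}")
    return data, gold, bounds


def infer_dataset(
    data: ExpressionSeriesSet,
    bounds: Bounds,
    *,
    NP: int = 200,
    generations: int = 10_000,
    seed: int | None = None,
    fitness_mode: str = "free_run",
) -> tuple[LTVParameters, np.ndarray, JdeResult]:
    """One jDE fit of the model to a dataset.

    Returns the best-fit parameters, their static weight matrix over the
    sampling-index grid, and the full optimizer result.
    """
    n = data.n_genes
    cfg = FitnessConfig(mode=fitness_mode)
    objective = lambda thetas: mse_population(thetas, data, cfg)  # noqa: E731
    jcfg = JdeConfig(NP=NP, max_generations=generations, seed=seed)
    res = jde_run(objective, bounds.lower_vector(n), bounds.upper_vector(n), jcfg)
    params = LTVParameters.from_vector(res.best.theta, n, gene_names=list(data.gene_names))
    W = static_weight_matrix(params, np.arange(data.n_times))
    return params, W, res


def run_experiment(settings: ExperimentSettings) -> ExperimentResult:
    """Full pipeline for one named experiment at the configured scale."""
    data, gold, bounds = make_dataset(settings.name, settings.seed)
    ss = np.random.SeedSequence((settings.seed, 1))
    run_seeds = [int(s) % (2**31) for s in ss.generate_state(settings.runs)]

    run_params, run_weights, run_scores, run_mse, histories = [], [], [], [], []
    for rs in run_seeds:
        params, W, res = infer_dataset(
            data,
            bounds,
            NP=settings.NP,
            generations=settings.generations,
            seed=rs,
            fitness_mode=settings.fitness_mode,
        )
        run_params.append(params)
        run_weights.append(W)
        pred = extract_network(W, settings.magnitude_threshold, gene_names=list(data.gene_names))
        run_scores.append(sensitivity_specificity(pred, gold))
        run_mse.append(float(res.best.fitness))
        histories.append(res.history)

    consensus = None
    consensus_score = None
    if settings.runs >= 2:
        consensus = zscore_consensus(
            run_weights,
            z_threshold=settings.z_threshold,
            magnitude_threshold=settings.magnitude_threshold,
            gene_names=list(data.gene_names),
        )
        consensus_score = sensitivity_specificity(consensus.prediction(), gold)

    return ExperimentResult(
        settings=settings,
        data=data,
        gold=gold,
        run_params=run_params,
        run_weights=run_weights,
        run_scores=run_scores,
        run_mse=run_mse,
        consensus=consensus,
        consensus_score=consensus_score,
        histories=histories,
    )
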