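"""Synthetic benchmark generators: S-system networks, the Laub-Loomis cAMP
oscillator, measurement noise, and expression preprocessing.

These produce the study inputs that the inference pipeline is benchmarked
on; the S-system and the seven-component cAMP model are data generators
only, never fitted themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ltv_core import ExpressionSeriesSet

__all__ = [
    "SSystemParameters",
    "OdeRunConfig",
    "five_gene_benchmark",
    "ssystem_derivatives",
    "integrate",
    "generate_ssystem_dataset",
    "laub_loomis_derivatives",
    "camp_rate_constants",
    "CAMP_COMPONENTS",
    "generate_camp_dataset",
    "add_noise",
    "normalize",
]


@dataclass
class SSystemParameters:
    """Power-law (S-system) ODE parameters.

    dX_i/dt = rate_alpha_i * prod_j X_j^{g_ij} - rate_beta_i * prod_j X_j^{h_ij}

    g and h are the kinetic orders: the exponent g_ij (h_ij) quantifies the
    effect of component j on the production (degradation) of component i.
    """

    rate_alpha: np.ndarray
    rate_beta: np.ndarray
    g: np.ndarray
    h: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.rate_alpha = np.asarray(self.rate_alpha, dtype=float)
        self.rate_beta = np.asarray(self.rate_beta, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.rate_alpha.size
        if self.rate_beta.size != n or self.g.shape != (n, n) or self.h.shape != (n, n):
            raise ValueError("inconsistent S-system dimensions")
        if np.any(self.rate_alpha < 0) or np.any(self.rate_beta < 0):
            raise ValueError("rate constants must be non-negative")
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.rate_alpha.size


def five_gene_benchmark() -> SSystemParameters:
    """The classic 5-gene S-system benchmark network (Tominaga lineage).

    A cascade with one feedback loop: gene 3 activates gene 1 and gene 5
    represses it, gene 1 activates gene 2, gene 2 feeds gene 3 (activating
    production, repressing degradation), genes 3 and 5 regulate gene 4, and
    gene 4 activates gene 5; every gene degrades itself.
    """
    rate_alpha = [5.0, 10.0, 10.0, 8.0, 10.0]
    rate_beta = [10.0, 10.0, 10.0, 10.0, 10.0]
    g = [
        [0.0, 0.0, 1.0, 0.0, -1.0],
        [2.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, -1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 2.0, 0.0, -1.0],
        [0.0, 0.0, 0.0, 2.0, 0.0],
    ]
    h = [
        [2.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 2.0, 0.0, 0.0, 0.0],
        [0.0, -1.0, 2.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 2.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 2.0],
    ]
    return SSystemParameters(rate_alpha, rate_beta, g, h)


def ssystem_derivatives(p: SSystemParameters, x: np.ndarray) -> np.ndarray:
    """Right-hand side of the S-system ODE at a strictly positive state."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("S-system state must stay strictly positive (negative kinetic orders)")
    logx = np.log(x)
    prod_g = np.exp(p.g @ logx)
    prod_h = np.exp(p.h @ logx)
    return p.rate_alpha * prod_g - p.rate_beta * prod_h


@dataclass(frozen=True)
class OdeRunConfig:
    """Sampling design for a simulated experiment.

    ``t_end`` and ``n_points`` define the uniform output grid [0, t_end];
    ``step`` is the internal fixed RK4 step; ``init_range`` bounds the
    random initial state of each replicate; ``n_replicates`` is M.
    """

    t_end: float = 0.5
    n_points: int = 11
    step: float = 1e-3
    init_range: tuple[float, float] = (0.05, 1.0)
    n_replicates: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("need at least 2 sampling points")
        if self.step <= 0:
            raise ValueError("step must be positive")


def integrate(deriv_fn, x0: np.ndarray, cfg: OdeRunConfig) -> np.ndarray:
    """Classic fixed-step RK4 sampled at n_points uniform times in [0, t_end].

    The internal step is at most cfg.step (shrunk to divide each sampling
    interval evenly).  Raises if the state leaves the positive orthant or
    blows up, with the failing time in the message.
    """
    x = np.asarray(x0, dtype=float).copy()
    times = np.linspace(0.0, cfg.t_end, cfg.n_points)
    out = np.empty((cfg.n_points, x.size))
    out[0] = x
    for k in range(cfg.n_points - 1):
        t0, t1 = times[k], times[k + 1]
        n_sub = max(1, int(np.ceil((t1 - t0) / cfg.step)))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = deriv_fn(x)
            k2 = deriv_fn(x + 0.5 * h * k1)
            k3 = deriv_fn(x + 0.5 * h * k2)
            k4 = deriv_fn(x + h * k3)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 1e6):
                raise RuntimeError(f"integration diverged near t={t:.4g}")
        out[k + 1] = x
    return out


def generate_ssystem_dataset(
    p: SSystemParameters | None = None,
    cfg: OdeRunConfig = OdeRunConfig(),
    max_retries: int = 20,
) -> ExpressionSeriesSet:
    """M replicate time courses of the S-system from random initial states.

    Each replicate starts from an independent uniform draw in
    ``cfg.init_range`` per component; replicates whose integration fails
    are redrawn up to ``max_retries`` times.
    """
    if p is None:
        p = five_gene_benchmark()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    series = []
    for _ in range(cfg.n_replicates):
        for attempt in range(max_retries):
            x0 = rng.uniform(lo, hi, size=p.n)
            try:
                traj = integrate(lambda x: ssystem_derivatives(p, x), x0, cfg)
            except (RuntimeError, ValueError):
                continue
            series.append(traj)
            break
        else:
            raise RuntimeError(f"could not integrate a replicate in {max_retries} attempts")
    times = np.linspace(0.0, cfg.t_end, cfg.n_points)
    return ExpressionSeriesSet(series=series, times=times, gene_names=list(p.gene_names))


# ---------------------------------------------------------------------------
# Laub-Loomis cAMP oscillator (Dictyostelium discoideum aggregation)

CAMP_COMPONENTS = ["ACA", "PKA", "ERK2", "RegA", "cAMPi", "cAMPe", "CAR1"]


def camp_rate_constants() -> np.ndarray:
    """Rate constants k1..k14 of the seven-ODE cAMP oscillation model.

    Values from the Laub & Loomis circuit model of spontaneous cAMP
    oscillations during D. discoideum aggregation; with these constants the
    system settles onto a stable limit cycle with a period of roughly 7
    minutes.
    """
    return np.array(
        [2.0, 0.9, 2.5, 1.5, 0.6, 0.8, 1.0, 1.3, 0.3, 0.8, 0.7, 4.9, 23.0, 4.5]
    )


def laub_loomis_derivatives(state: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
    """Seven coupled ODEs of the cAMP oscillator.

    State order is [ACA, PKA, ERK2, RegA, cAMPi, cAMPe, CAR1].  Wiring:
    ligand-bound CAR1 activates ACA and ERK2; PKA inhibits both ACA and
    ERK2; internal cAMP activates PKA; ERK2 inhibits RegA (via its
    constitutive production being countered); ACA produces both internal
    and external cAMP; RegA hydrolyses internal cAMP; external cAMP binds
    and activates CAR1; every component also decays.
    """
    if k is None:
        k = camp_rate_constants()
    s = np.asarray(state, dtype=float)
    if s.shape != (7,):
        raise ValueError("state must have length 7: [ACA, PKA, ERK2, RegA, cAMPi, cAMPe, CAR1]")
    aca, pka, erk2, rega, campi, campe, car1 = s
    return np.array(
        [
            k[0] * car1 - k[1] * aca * pka,
            k[2] * campi - k[3] * pka,
            k[4] * car1 - k[5] * erk2 * pka,
            k[6] - k[7] * rega * erk2,
            k[8] * aca - k[9] * campi * rega,
            k[10] * aca - k[11] * campe,
            k[12] * campe - k[13] * car1,
        ]
    )


def generate_camp_dataset(
    k: np.ndarray | None = None,
    cfg: OdeRunConfig | None = None,
) -> ExpressionSeriesSet:
    """Replicate time courses of the cAMP oscillator, normalized to (0, 1].

    Default design: 5 replicates of 10 uniform samples over 9 minutes
    (about 1.3 oscillation periods), each replicate starting from an
    independent random positive state so the replicates sit at different
    phases/transients of the limit cycle.  Per-gene normalization against
    the maximum over all replicates maps values into (0, 1].
    """
    if k is None:
        k = camp_rate_constants()
    if cfg is None:
        cfg = OdeRunConfig(t_end=9.0, n_points=10, step=1e-3, init_range=(0.1, 2.0), n_replicates=5)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_range
    series = []
    for _ in range(cfg.n_replicates):
        x0 = rng.uniform(lo, hi, size=7)
        series.append(integrate(lambda x: laub_loomis_derivatives(x, k), x0, cfg))
    times = np.linspace(0.0, cfg.t_end, cfg.n_points)
    data = ExpressionSeriesSet(series=series, times=times, gene_names=list(CAMP_COMPONENTS))
    return normalize(data)


# ---------------------------------------------------------------------------
# Measurement noise and preprocessing


def add_noise(
    data: ExpressionSeriesSet,
    level: float,
    seed: int | None = None,
    model: str = "multiplicative",
    floor: float = 1e-6,
) -> ExpressionSeriesSet:
    """Corrupt expression values with Gaussian measurement noise.

    ``multiplicative`` (default): x' = x (1 + level * eps), i.e. relative
    noise with standard deviation ``level`` ("5% noise" -> level=0.05).
    ``additive``: x' = x + level * eps.  Outputs are clipped to a small
    positive floor; level 0 returns the data unchanged.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if model not in ("multiplicative", "additive"):
        raise ValueError("model must be 'multiplicative' or 'additive'")
    if level == 0:
        return ExpressionSeriesSet(
            series=[s.copy() for s in data.series], times=data.times.copy(), gene_names=list(data.gene_names)
        )
    rng = np.random.default_rng(seed)
    noisy = []
    for s in data.series:
        eps = rng.standard_normal(s.shape)
        out = s * (1.0 + level * eps) if model == "multiplicative" else s + level * eps
        noisy.append(np.maximum(out, floor))
    return ExpressionSeriesSet(series=noisy, times=data.times.copy(), gene_names=list(data.gene_names))


def normalize(data: ExpressionSeriesSet, zero_floor: float = 1e-4) -> ExpressionSeriesSet:
    """Scale each gene into (0, 1] and replace exact zeros.

    Every gene is divided by its maximum over all replicates and time
    points; exact zeros (which a relative-error objective cannot score)
    are then replaced by ``zero_floor``.  Idempotent apart from the zero
    replacement.
    """
    stacked = data.as_array()  # (M, T, n)
    gene_max = stacked.max(axis=(0, 1))
    if np.any(gene_max <= 0):
        bad = [data.gene_names[i] for i in np.nonzero(gene_max <= 0)[0]]
        raise ValueError(f"cannot normalize genes with non-positive maximum: {bad}")
    scaled = stacked / gene_max
    scaled[scaled == 0.0] = zero_floor
    return ExpressionSeriesSet(
        series=[scaled[m] for m in range(scaled.shape[0])],
        times=data.times.copy(),
        gene_names=list(data.gene_names),
    )
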