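"""From fitted weights to a discrete signed network, and its scoring.

A fitted static weight matrix is pruned by magnitude; networks from
repeated independent optimisation runs are combined by a Z-score
(mean/standard-deviation) consensus that keeps only regulations predicted
consistently across runs.  Predictions are scored against a gold-standard
edge set with sensitivity and specificity over all n^2 ordered gene pairs
(self-regulation included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .simulators import CAMP_COMPONENTS, SSystemParameters

__all__ = [
    "NetworkPrediction",
    "GoldStandard",
    "ConsensusResult",
    "ScoreResult",
    "extract_network",
    "zscore_consensus",
    "gold_from_ssystem",
    "camp_gold_standard",
    "sensitivity_specificity",
]


@dataclass
class NetworkPrediction:
    """Signed, weighted adjacency: weights[i, j] is the influence of gene j
    on gene i; 0 means no predicted edge."""

    weights: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return self.weights != 0.0

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.weights)

    def edges(self) -> list[tuple[str, str, str, float]]:
        """(regulator, target, sign, weight) tuples for every predicted edge."""
        out = []
        for i in range(self.n):
            for j in range(self.n):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.gene_names[j], self.gene_names[i], "+" if w > 0 else "-", float(w)))
        return out


@dataclass
class GoldStandard:
    """Reference edge set: adjacency[i, j] is True iff gene j regulates gene i."""

    adjacency: np.ndarray
    gene_names: list[str] | None = None
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if self.signs is not None:
            self.signs = np.asarray(self.signs)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


@dataclass
class ConsensusResult:
    """Per-pair statistics of fitted weights over R independent runs."""

    mean: np.ndarray
    std: np.ndarray
    z: np.ndarray
    retained: np.ndarray  # consensus weight matrix, 0 where dropped
    gene_names: list[str] | None = None

    def prediction(self) -> NetworkPrediction:
        return NetworkPrediction(weights=self.retained, gene_names=self.gene_names)


class ScoreResult(NamedTuple):
    sn: float
    sp: float
    tp: int
    fp: int
    tn: int
    fn: int


def extract_network(
    W: np.ndarray,
    magnitude_threshold: float = 0.5,
    gene_names: list[str] | None = None,
) -> NetworkPrediction:
    """Prune a static weight matrix: |W_ij| below the threshold becomes 0."""
    if magnitude_threshold < 0:
        raise ValueError("magnitude threshold must be non-negative")
    W = np.asarray(W, dtype=float)
    pruned = np.where(np.abs(W) >= magnitude_threshold, W, 0.0)
    return NetworkPrediction(weights=pruned, gene_names=gene_names)


def zscore_consensus(
    run_matrices: Sequence[np.ndarray],
    z_threshold: float = 1.0,
    magnitude_threshold: float = 0.5,
    gene_names: list[str] | None = None,
) -> ConsensusResult:
    """Consensus over R >= 2 runs: keep pair (i, j) iff |mean/std| >= z_threshold
    and |mean| >= magnitude_threshold.

    A pair with zero spread across runs is perfectly consistent: it is
    retained when its mean passes the magnitude test (infinite Z) and
    dropped when the mean is zero.
    """
    mats = [np.asarray(m, dtype=float) for m in run_matrices]
    if len(mats) < 2:
        raise ValueError("consensus needs at least 2 runs")
    stack = np.stack(mats, axis=0)
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(std > 0, mean / std, np.where(mean != 0, np.inf * np.sign(mean), 0.0))
    keep = (np.abs(z) >= z_threshold) & (np.abs(mean) >= magnitude_threshold)
    retained = np.where(keep, mean, 0.0)
    return ConsensusResult(mean=mean, std=std, z=z, retained=retained, gene_names=gene_names)


def gold_from_ssystem(p: SSystemParameters) -> GoldStandard:
    """Gold standard of an S-system: edge j->i iff g_ij != 0 or h_ij != 0.

    Self-degradation (h_ii != 0) counts as a self-edge, so the 5-gene
    benchmark yields 12 true edges among the 25 ordered pairs.
    """
    adj = (p.g != 0) | (p.h != 0)
    return GoldStandard(adjacency=adj, gene_names=list(p.gene_names))


# Wiring of the seven-component cAMP oscillation circuit
# (regulator, target, sign): CAR1 activates ACA and ERK2, PKA inhibits
# both; internal cAMP activates PKA; ERK2 inhibits RegA; ACA produces
# internal and external cAMP; RegA hydrolyses internal cAMP; external cAMP
# activates CAR1; each component decays (self-edges).
CAMP_GOLD_EDGES: list[tuple[str, str, str]] = [
    ("CAR1", "ACA", "+"),
    ("PKA", "ACA", "-"),
    ("cAMPi", "PKA", "+"),
    ("CAR1", "ERK2", "+"),
    ("PKA", "ERK2", "-"),
    ("ERK2", "RegA", "-"),
    ("ACA", "cAMPi", "+"),
    ("RegA", "cAMPi", "-"),
    ("ACA", "cAMPe", "+"),
    ("cAMPe", "CAR1", "+"),
    ("ACA", "ACA", "-"),
    ("PKA", "PKA", "-"),
    ("ERK2", "ERK2", "-"),
    ("RegA", "RegA", "-"),
    ("cAMPi", "cAMPi", "-"),
    ("cAMPe", "cAMPe", "-"),
    ("CAR1", "CAR1", "-"),
]


def camp_gold_standard() -> GoldStandard:
    """17-edge gold standard of the cAMP oscillator (10 cross + 7 self-decay)."""
    names = list(CAMP_COMPONENTS)
    idx = {g: i for i, g in enumerate(names)}
    adj = np.zeros((7, 7), dtype=bool)
    signs = np.zeros((7, 7), dtype=int)
    for reg, tgt, sign in CAMP_GOLD_EDGES:
        adj[idx[tgt], idx[reg]] = True
        signs[idx[tgt], idx[reg]] = 1 if sign == "+" else -1
    return GoldStandard(adjacency=adj, gene_names=names, signs=signs)


def sensitivity_specificity(pred: NetworkPrediction, gold: GoldStandard) -> ScoreResult:
    """Presence-only confusion counts over all n^2 ordered pairs.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP).  Edge sign is not scored here; it is
    available separately on the prediction.
    """
    if pred.n != gold.n:
        raise ValueError("prediction and gold standard sizes differ")
    if pred.gene_names != gold.gene_names:
        raise ValueError("gene orders differ between prediction and gold standard")
    p = pred.adjacency
    g = gold.adjacency
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    sn = tp / (tp + fn) if (tp + fn) else 1.0
    sp = tn / (tn + fp) if (tn + fp) else 1.0
    return ScoreResult(sn=sn, sp=sp, tp=tp, fp=fp, tn=tn, fn=fn)
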