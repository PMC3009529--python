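"""Tabular I/O: expression series, edge lists, consensus reports, run logs.

The canonical on-disk form of an expression dataset is a directory of
tab-delimited files, one per replicate, each with a mandatory leading
``time`` column followed by one column per gene (header row carries the
gene names).  Edge lists are TSV with columns regulator, target, sign,
weight.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ltv_core import ExpressionSeriesSet, LTVParameters
from .netextract import ConsensusResult, GoldStandard, NetworkPrediction

__all__ = [
    "RunConfig",
    "write_series_dir",
    "read_series_dir",
    "write_edge_list",
    "read_edge_list",
    "read_gold_standard",
    "write_consensus_report",
    "write_weight_matrix",
    "read_weight_matrix",
    "write_parameters",
    "read_parameters",
    "load_sos_table",
]


@dataclass
class RunConfig:
    """Settings of one inference invocation (serialized alongside outputs)."""

    series_dir: str | None = None
    alpha_bounds: tuple[float, float] = (-10.0, 10.0)
    beta_bounds: tuple[float, float] = (-3.0, 3.0)
    phi_bounds: tuple[float, float] = (-float(np.pi / 2), float(np.pi / 2))
    omega_bounds: tuple[float, float] = (-float(np.pi / 2), float(np.pi / 2))
    NP: int = 200
    generations: int = 10_000
    runs: int = 10
    fitness_mode: str = "free_run"
    z_threshold: float = 1.0
    magnitude_threshold: float = 0.5
    seed: int = 0
    outdir: str = "runs"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("alpha_bounds", "beta_bounds", "phi_bounds", "omega_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Expression series


def write_series_dir(data: ExpressionSeriesSet, path: str | Path, prefix: str = "replicate") -> list[Path]:
    """One TSV per replicate: ``time`` column then one column per gene."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for k, s in enumerate(data.series):
        df = pd.DataFrame(s, columns=data.gene_names)
        df.insert(0, "time", data.times)
        fname = path / f"{prefix}_{k:02d}.tsv"
        df.to_csv(fname, sep="\t", index=False, float_format="%.12g")
        written.append(fname)
    return written


def read_series_dir(path: str | Path) -> ExpressionSeriesSet:
    """Read a directory of replicate TSVs into an ExpressionSeriesSet.

    All files must share the header (``time`` + gene names) and row count;
    errors name the offending file.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix == ".tsv")
    if not files:
        raise FileNotFoundError(f"no .tsv replicate files in {path}")
    series, times, genes = [], None, None
    for f in files:
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"{f.name}: could not parse as TSV ({exc})") from exc
        if df.columns[0] != "time":
            raise ValueError(f"{f.name}: first column must be 'time', got {df.columns[0]!r}")
        cols = list(df.columns[1:])
        if genes is None:
            genes = cols
        elif cols != genes:
            raise ValueError(f"{f.name}: gene columns {cols} do not match {genes}")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            raise ValueError(f"{f.name}: non-numeric cells present")
        t = df["time"].to_numpy(dtype=float)
        if times is None:
            times = t
        elif t.shape != times.shape or not np.allclose(t, times):
            raise ValueError(f"{f.name}: time grid differs from the first replicate")
        series.append(df[genes].to_numpy(dtype=float))
    return ExpressionSeriesSet(series=series, times=times, gene_names=genes)


# ---------------------------------------------------------------------------
# Edge lists and matrices


def write_edge_list(pred: NetworkPrediction, path: str | Path) -> None:
    rows = pred.edges()
    df = pd.DataFrame(rows, columns=["regulator", "target", "sign", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    return df


def read_gold_standard(path: str | Path, gene_names: list[str]) -> GoldStandard:
    """Gold standard from a TSV edge list (regulator, target[, sign])."""
    df = read_edge_list(path)
    idx = {g: i for i, g in enumerate(gene_names)}
    n = len(gene_names)
    adj = np.zeros((n, n), dtype=bool)
    signs = np.zeros((n, n), dtype=int)
    for _, row in df.iterrows():
        reg, tgt = str(row["regulator"]), str(row["target"])
        if reg not in idx or tgt not in idx:
            raise ValueError(f"edge {reg}->{tgt} references unknown gene")
        adj[idx[tgt], idx[reg]] = True
        if "sign" in df.columns:
            signs[idx[tgt], idx[reg]] = 1 if str(row["sign"]) == "+" else -1
    return GoldStandard(adjacency=adj, gene_names=list(gene_names), signs=signs)


def write_weight_matrix(W: np.ndarray, gene_names: list[str], path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(W), index=gene_names, columns=gene_names)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_weight_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)


def write_consensus_report(res: ConsensusResult, path: str | Path) -> None:
    """Per-pair mean, std and Z across runs as a long-form TSV."""
    names = res.gene_names or [f"G{i + 1}" for i in range(res.mean.shape[0])]
    rows = []
    n = res.mean.shape[0]
    for i in range(n):
        for j in range(n):
            rows.append(
                (
                    names[j],
                    names[i],
                    res.mean[i, j],
                    res.std[i, j],
                    res.z[i, j],
                    int(res.retained[i, j] != 0),
                )
            )
    df = pd.DataFrame(rows, columns=["regulator", "target", "mean", "std", "z", "retained"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_parameters(params: LTVParameters, path: str | Path) -> None:
    payload = {
        "gene_names": params.gene_names,
        "alpha": params.alpha.tolist(),
        "beta": params.beta.tolist(),
        "phi": params.phi.tolist(),
        "omega": params.omega.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_parameters(path: str | Path) -> LTVParameters:
    payload = json.loads(Path(path).read_text())
    return LTVParameters(
        alpha=np.array(payload["alpha"]),
        beta=np.array(payload["beta"]),
        phi=np.array(payload["phi"]),
        omega=np.array(payload["omega"]),
        gene_names=list(payload["gene_names"]),
    )


# ---------------------------------------------------------------------------
# Real-microarray (wide-table) loader


def load_sos_table(
    path: str | Path,
    genes: list[str] | None = None,
    zero_floor: float = 1e-4,
    drop_all_zero_first_row: bool = True,
) -> ExpressionSeriesSet:
    """Load one wide expression table (time + one column per gene) and apply
    the standard microarray preprocessing: optional gene subset selection,
    dropping a leading all-zero row (identical initial concentrations carry
    no dynamic information), per-gene normalization to (0, 1] against the
    maximum, and replacement of exact zeros with a small positive value.

    Intended for expression-kinetics tables such as the E. coli SOS DNA
    repair measurements; no data ships with the package.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    if genes is not None:
        missing = [g for g in genes if g not in df.columns]
        if missing:
            raise ValueError(f"{path}: requested genes not present: {missing}")
        df = df[["time"] + list(genes)]
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    times = df["time"].to_numpy(dtype=float)
    if drop_all_zero_first_row and values.shape[0] > 1 and np.all(values[0] == 0):
        values = values[1:]
        times = times[1:]
    gene_names = list(df.columns[1:])
    gene_max = values.max(axis=0)
    if np.any(gene_max <= 0):
        bad = [gene_names[i] for i in np.nonzero(gene_max <= 0)[0]]
        raise ValueError(f"{path}: all-zero gene columns {bad}")
    values = values / gene_max
    values[values == 0.0] = zero_floor
    return ExpressionSeriesSet(series=[values], times=times, gene_names=gene_names)

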