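"""Synthetic RNA-seq fixtures: negative-binomial count matrices with planted
differentially expressed genes, plus a simple logFC / Welch-t / BH metrics
stand-in.

The simulator exists so that every figure builder is testable without
downloading an experiment.  It is deliberately non-canonical as a DE caller:
real analyses should import metrics from an established pipeline (edgeR,
DESeq2, limma, …); :func:`compute_metrics` merely produces the logFC / PValue
/ FDR columns such a pipeline would supply, using transparent arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ExpressionMatrix,
    MetricsTable,
    TreatmentPair,
    write_expression,
)
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_counts",
    "compute_metrics",
    "worked_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the negative-binomial simulation.

    ``baseline_mean`` is the median of the per-gene lognormal baseline-mean
    distribution (reads per gene); ``dispersion`` is the NB dispersion α with
    Var = μ + α·μ² (gene-shared); ``deg_log2fc`` is the planted log2 fold
    change between the first two treatments, applied symmetrically (±lfc/2 on
    each side), with half of the DEGs up- and half down-regulated.
    """

    n_genes: int = 1000
    treatments: tuple[str, ...] = ("A", "B")
    reps_per_treatment: int = 3
    baseline_mean: float = 50.0
    dispersion: float = 0.2
    deg_fraction: float = 0.1
    deg_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError(f"n_genes must be positive, got {self.n_genes}")
        if len(self.treatments) < 2:
            raise ConfigError("need at least 2 treatments")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigError(f"duplicate treatment names: {self.treatments}")
        if self.reps_per_treatment <= 0:
            raise ConfigError("reps_per_treatment must be positive")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("baseline_mean and dispersion must be positive")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ConfigError(f"deg_fraction must lie in [0,1], got {self.deg_fraction}")

    @property
    def n_deg(self) -> int:
        return int(round(self.deg_fraction * self.n_genes))


@dataclass(frozen=True)
class TruthTable:
    """Planted truth: which genes are DEGs and their true log2 fold change."""

    gene_ids: tuple[str, ...]
    is_deg: np.ndarray  # bool, per gene
    true_log2fc: np.ndarray  # float, 0 for non-DEGs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"is_deg": self.is_deg.astype(int), "true_log2fc": self.true_log2fc},
            index=list(self.gene_ids),
        )
        df.index.name = "ID"
        return df


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw a seeded NB count matrix with planted DEG structure.

    Identical config (including seed) ⇒ byte-identical output.  DEG means
    differ by a factor of ``2**deg_log2fc`` between the first two treatments;
    any further treatments sit at the baseline mean.
    """
    rng = np.random.default_rng(config.seed)
    g, t, r = config.n_genes, len(config.treatments), config.reps_per_treatment
    width = max(4, len(str(g)))
    gene_ids = tuple(f"gene{idx:0{width}d}" for idx in range(1, g + 1))

    base = config.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=g))
    deg_idx = rng.choice(g, size=config.n_deg, replace=False)
    signs = np.where(np.arange(config.n_deg) % 2 == 0, 1.0, -1.0)
    true_lfc = np.zeros(g)
    true_lfc[deg_idx] = signs * config.deg_log2fc
    is_deg = np.zeros(g, dtype=bool)
    is_deg[deg_idx] = True

    # mean per gene per treatment: the planted effect is split symmetrically
    # across the first two groups so the geometric-mean expression is preserved
    means = np.tile(base[:, None], (1, t))
    means[:, 0] = base * np.power(2.0, true_lfc / 2.0)
    means[:, 1] = base * np.power(2.0, -true_lfc / 2.0)

    size = 1.0 / config.dispersion  # NB shape: Var = mu + mu^2/size
    counts = np.empty((g, t * r), dtype=float)
    labels = []
    for ti, treatment in enumerate(config.treatments):
        mu = means[:, ti]
        p = size / (size + mu)
        for rep in range(1, r + 1):
            labels.append(f"{treatment}.{rep}")
            counts[:, ti * r + rep - 1] = rng.negative_binomial(size, p)
    matrix = ExpressionMatrix.from_arrays(gene_ids, counts, labels)
    return matrix, TruthTable(gene_ids, is_deg, true_lfc)


def compute_metrics(
    matrix: ExpressionMatrix,
    pair: TreatmentPair,
    pseudocount: float = 1.0,
) -> MetricsTable:
    """logFC, Welch-t PValue, and BH FDR for one treatment pair.

    logFC = log2((mean_first + c) / (mean_second + c)) with pseudocount c;
    PValue from a two-sample unequal-variance t-test on log2(count + c),
    present only when both groups have ≥ 2 replicates; FDR is the
    Benjamini–Hochberg step-up adjustment across all genes.  Genes with zero
    variance in both groups and equal means carry no evidence and get p = 1.
    """
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be positive, got {pseudocount}")
    design = matrix.design
    cols_first = design.columns_for(pair.first)
    cols_second = design.columns_for(pair.second)
    a = np.asarray(matrix.counts)[:, cols_first]
    b = np.asarray(matrix.counts)[:, cols_second]
    # difference of logs (not log of ratio) so swapping the pair negates
    # the fold change exactly, bit for bit
    logfc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(b.mean(axis=1) + pseudocount)
    data = {"logFC": logfc}
    if a.shape[1] >= 2 and b.shape[1] >= 2:
        la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        data["PValue"] = pvals
        data["FDR"] = stats.false_discovery_control(pvals, method="bh")
    frame = pd.DataFrame(data, index=list(matrix.gene_ids))
    return MetricsTable(pair, frame)


# ---------------------------------------------------------------------------
# Hand-checkable worked fixture
# ---------------------------------------------------------------------------

_FIXTURE_COUNTS = {
    #         A.1  A.2  B.1  B.2      pseudocount-1 logFC
    "w1": (6, 8, 2, 4),      # means 7 vs 3   -> log2(8/4)   = +1
    "w2": (2, 4, 6, 8),      # means 3 vs 7   -> log2(4/8)   = -1
    "w3": (5, 5, 5, 5),      # means 5 vs 5   -> log2(6/6)   =  0
    "w4": (14, 16, 2, 4),    # means 15 vs 3  -> log2(16/4)  = +2
    "w5": (2, 4, 14, 16),    # means 3 vs 15  -> log2(4/16)  = -2
    "w6": (126, 128, 14, 16),  # means 127 vs 15 -> log2(128/16) = +3
    "w7": (14, 16, 126, 128),  # means 15 vs 127 -> log2(16/128) = -3
    "w8": (30, 32, 0, 0),    # means 31 vs 0  -> log2(32/1)  = +5
}

_FIXTURE_LOGFC = {
    "w1": 1.0, "w2": -1.0, "w3": 0.0, "w4": 2.0,
    "w5": -2.0, "w6": 3.0, "w7": -3.0, "w8": 5.0,
}

# Illustrative significances, monotone in |logFC|; FDR is the exact BH
# step-up of these eight p-values (min over j >= rank of p_j * 8 / j).
_FIXTURE_PVALUE = {
    "w8": 0.001, "w6": 0.002, "w7": 0.004, "w4": 0.008,
    "w5": 0.02, "w1": 0.04, "w2": 0.2, "w3": 0.8,
}
_FIXTURE_FDR = {
    "w8": 0.008, "w6": 0.008, "w7": 0.004 * 8 / 3, "w4": 0.016,
    "w5": 0.032, "w1": 0.04 * 8 / 6, "w2": 0.2 * 8 / 7, "w3": 0.8,
}


def worked_fixture() -> tuple[ExpressionMatrix, MetricsTable]:
    """A deterministic 8-gene × (2 treatments × 2 replicates) fixture.

    Counts are hand-chosen so every pseudocount-1 log fold change is an exact
    small integer (see the table in the source); PValue/FDR are illustrative
    hand-set significances consistent under BH.  Used for exact-value tests
    and CLI examples.
    """
    gene_ids = list(_FIXTURE_COUNTS)
    counts = np.array([_FIXTURE_COUNTS[g] for g in gene_ids], dtype=float)
    matrix = ExpressionMatrix.from_arrays(gene_ids, counts, ["A.1", "A.2", "B.1", "B.2"])
    frame = pd.DataFrame(
        {
            "logFC": [_FIXTURE_LOGFC[g] for g in gene_ids],
            "PValue": [_FIXTURE_PVALUE[g] for g in gene_ids],
            "FDR": [_FIXTURE_FDR[g] for g in gene_ids],
        },
        index=gene_ids,
    )
    metrics = MetricsTable(TreatmentPair("A", "B"), frame)
    return matrix, metrics


def write_fixture(
    directory: str | Path,
    matrix: ExpressionMatrix,
    metrics_tables: Sequence[MetricsTable] = (),
    truth: TruthTable | None = None,
) -> list[Path]:
    """Write a matrix (+ optional metrics/truth) as the TSV dialect core_data reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = [write_expression(matrix, directory / "counts.tsv")]
    for table in metrics_tables:
        path = directory / f"metrics_{table.pair.first}_{table.pair.second}.tsv"
        table.frame.to_csv(path, sep="\t")
        written.append(path)
    if truth is not None:
        path = directory / "truth.tsv"
        truth.to_frame().to_csv(path, sep="\t")
        written.append(path)
    return written
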