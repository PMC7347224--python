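"""Count-matrix ingestion, sample design, metrics tables and gene subsets.

The central container is :class:`ExpressionMatrix`: a gene × sample table of
nonnegative read counts whose column labels encode the experimental design as
``TREATMENT.REPLICATE`` (split at the *last* dot, so treatment names may
themselves contain dots).  Per-contrast differential-expression statistics
(log2 fold change, p-value, FDR, plus anything else a DE pipeline emits) live
in a :class:`MetricsTable` bound to a :class:`TreatmentPair`, mirroring the
assay / rowData split of a SummarizedExperiment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DesignError,
    MalformedLabelError,
    UnknownIdError,
    ValidationError,
)

__all__ = [
    "SampleDesign",
    "TreatmentPair",
    "ExpressionMatrix",
    "MetricsTable",
    "GeneList",
    "parse_sample_labels",
    "load_expression",
    "write_expression",
    "load_metrics",
    "load_gene_list",
    "enumerate_pairs",
    "select_subset",
]

_SEPARATOR = "."

#: Columns whose values must lie in [0, 1] when present in a metrics table.
_UNIT_INTERVAL_METRICS = ("PValue", "FDR")


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass(frozen=True)
class TreatmentPair:
    """An unordered pair of treatment groups, stored in canonical design order."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValidationError(
                f"treatment pair must name two distinct groups, got {self.first!r} twice"
            )

    def swapped(self) -> "TreatmentPair":
        return TreatmentPair(self.second, self.first)

    def __str__(self) -> str:
        return f"{self.first}-{self.second}"


@dataclass(frozen=True)
class SampleDesign:
    """Treatment/replicate structure recovered from sample labels."""

    treatments: tuple[str, ...]
    replicates_of: Mapping[str, tuple[int, ...]]
    column_of: Mapping[tuple[str, int], int]

    def n_samples(self) -> int:
        return len(self.column_of)

    def columns_for(self, treatment: str) -> list[int]:
        """Column indices of a treatment's replicates, in replicate order."""
        if treatment not in self.replicates_of:
            raise UnknownIdError(
                f"unknown treatment {treatment!r}; available: {list(self.treatments)}"
            )
        return [self.column_of[(treatment, r)] for r in self.replicates_of[treatment]]

    def canonical_pair(self, first: str, second: str) -> TreatmentPair:
        """Order a pair by design order so each unordered pair has one form."""
        for t in (first, second):
            if t not in self.replicates_of:
                raise UnknownIdError(
                    f"unknown treatment {t!r}; available: {list(self.treatments)}"
                )
        order = {t: i for i, t in enumerate(self.treatments)}
        if order[first] <= order[second]:
            return TreatmentPair(first, second)
        return TreatmentPair(second, first)


def parse_sample_labels(labels: Sequence[str]) -> SampleDesign:
    """Parse ``TREATMENT.REPLICATE`` labels into a :class:`SampleDesign`.

    Labels are split at the last ``.``; the trailing field must be an integer
    replicate index (any unique integers are accepted — numbering need not
    start at 1 or be consecutive).
    """
    if len(labels) == 0:
        raise ValidationError("no sample labels given")
    seen: set[str] = set()
    treatments: list[str] = []
    replicates: dict[str, list[int]] = {}
    column_of: dict[tuple[str, int], int] = {}
    for col, label in enumerate(labels):
        if label in seen:
            raise ValidationError(f"duplicate sample label {label!r}")
        seen.add(label)
        treatment, sep, rep_text = label.rpartition(_SEPARATOR)
        if not sep or not treatment:
            raise MalformedLabelError(
                f"sample label {label!r} has no '{_SEPARATOR}' separator"
            )
        try:
            rep = int(rep_text)
        except ValueError:
            raise MalformedLabelError(
                f"sample label {label!r} has non-integer replicate {rep_text!r}"
            ) from None
        if treatment not in replicates:
            treatments.append(treatment)
            replicates[treatment] = []
        if rep in replicates[treatment]:
            raise MalformedLabelError(
                f"replicate {rep} repeated within treatment {treatment!r}"
            )
        replicates[treatment].append(rep)
        column_of[(treatment, rep)] = col
    if len(treatments) < 2:
        raise DesignError(
            f"need at least 2 treatment groups, found {len(treatments)}: {treatments}"
        )
    return SampleDesign(
        treatments=tuple(treatments),
        replicates_of={t: tuple(r) for t, r in replicates.items()},
        column_of=dict(column_of),
    )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample table of nonnegative read counts plus its sample design.

    Counts are accepted as nonnegative reals, not only integers, so
    normalized matrices (CPM and the like) are valid input.
    """

    gene_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_genes, n_samples), float64, read-only
    sample_labels: tuple[str, ...]
    design: SampleDesign = field(repr=False)

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        counts: np.ndarray,
        sample_labels: Sequence[str],
    ) -> "ExpressionMatrix":
        gene_ids = tuple(str(g) for g in gene_ids)
        sample_labels = tuple(str(s) for s in sample_labels)
        if len(gene_ids) == 0:
            raise ValidationError("expression matrix has no genes")
        if len(set(gene_ids)) != len(gene_ids):
            dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(gene_ids), len(sample_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_labels)} samples"
            )
        bad = ~np.isfinite(counts)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite count at gene {gene_ids[i]!r}, sample {sample_labels[j]!r}"
            )
        neg = counts < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative count {counts[i, j]} at gene {gene_ids[i]!r}, "
                f"sample {sample_labels[j]!r}"
            )
        design = parse_sample_labels(sample_labels)
        counts = counts.copy()
        counts.setflags(write=False)
        return cls(gene_ids, counts, sample_labels, design)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_labels)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._index[gene_id]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
            )
            return self.gene_index(gene_id)
        except KeyError:
            raise UnknownIdError(f"gene id {gene_id!r} not in expression matrix") from None

    def sample_index(self, label: str) -> int:
        try:
            return self.sample_labels.index(label)
        except ValueError:
            raise UnknownIdError(
                f"sample {label!r} not in matrix; samples: {list(self.sample_labels)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.asarray(self.counts), index=list(self.gene_ids),
            columns=list(self.sample_labels),
        )
        df.index.name = "ID"
        return df


def load_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited count table (first column = gene ids, header = samples).

    The delimiter is inferred from the extension (``.csv`` → comma, anything
    else → tab) unless given explicitly.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    gene_ids = [str(g) for g in df.index]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric count at gene {row!r}, sample {col!r}"
            )
        # astype(float) is correctly rounded; to_numeric's fast path is not
        values[:, j] = df[col].astype(float).to_numpy()
    return ExpressionMatrix.from_arrays(gene_ids, values, list(df.columns))


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> Path:
    """Write the matrix back to delimited text; exact round-trip with load."""
    sep = _infer_delimiter(path, delimiter)
    path = Path(path)
    # 17 significant digits round-trip any float64 exactly
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.17g")
    return path


class MetricsTable:
    """Per-gene DE metrics (logFC, PValue, FDR, …) for one treatment pair.

    Thin wrapper over a DataFrame indexed by gene id; validates uniqueness,
    finiteness, and that probability-like columns stay in [0, 1].
    """

    def __init__(self, pair: TreatmentPair, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in metrics table: {dupes[:5]}")
        for col in frame.columns:
            values = pd.to_numeric(frame[col], errors="coerce")
            if values.isna().any() and frame[col].notna().any():
                bad_gene = frame.index[values.isna().to_numpy().argmax()]
                raise ValidationError(
                    f"non-numeric metric {col!r} at gene {bad_gene!r}"
                )
            frame[col] = values.astype(float)
            if not np.isfinite(frame[col].to_numpy()).all():
                bad_gene = frame.index[~np.isfinite(frame[col].to_numpy())][0]
                raise ValidationError(f"non-finite {col!r} at gene {bad_gene!r}")
        for col in _UNIT_INTERVAL_METRICS:
            if col in frame.columns:
                vals = frame[col].to_numpy()
                if len(vals) and ((vals < 0) | (vals > 1)).any():
                    bad_gene = frame.index[(vals < 0) | (vals > 1)][0]
                    raise ValidationError(
                        f"{col} outside [0, 1] at gene {bad_gene!r}: "
                        f"{frame.loc[bad_gene, col]}"
                    )
        self.pair = pair
        self.frame = frame
        self.frame.index = self.frame.index.astype(str)
        self.frame.index.name = "ID"

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def metric_names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def values(self, metric: str) -> np.ndarray:
        if metric not in self.frame.columns:
            raise UnknownIdError(
                f"unknown metric {metric!r}; available: {list(self.frame.columns)}"
            )
        return self.frame[metric].to_numpy()

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.gene_ids) - set(matrix.gene_ids)
        if missing:
            raise ValidationError(
                f"metrics table names genes absent from the matrix: "
                f"{sorted(missing)[:5]}"
            )


def load_metrics(
    path: str | Path,
    pair: TreatmentPair,
    delimiter: str | None = None,
    matrix: ExpressionMatrix | None = None,
) -> MetricsTable:
    """Read a delimited metrics table (``ID`` column plus numeric metrics)."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    table = MetricsTable(pair, df)
    if matrix is not None:
        table.validate_against(matrix)
    return table


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene identifiers."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({g for g in self.ids if self.ids.count(g) > 1})
            raise ValidationError(f"duplicate ids in gene list: {dupes[:5]}")

    @classmethod
    def of(cls, ids: Iterable[str]) -> "GeneList":
        return cls(tuple(str(g) for g in ids))

    def resolve(self, matrix: ExpressionMatrix) -> tuple[int, ...]:
        """Row indices of every id; unresolvable ids are an error, not dropped."""
        missing = [g for g in self.ids if g not in set(matrix.gene_ids)]
        if missing:
            raise UnknownIdError(
                f"gene list ids not found in expression matrix: {missing[:5]}"
            )
        return tuple(matrix.gene_index(g) for g in self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def load_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list, one id per line; blank lines ignored."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return GeneList.of([ln for ln in lines if ln])


def enumerate_pairs(design: SampleDesign) -> list[TreatmentPair]:
    """All C(t, 2) unordered treatment pairs, in canonical design order."""
    return [
        TreatmentPair(a, b) for a, b in itertools.combinations(design.treatments, 2)
    ]


def select_subset(
    metrics: MetricsTable,
    variable: str,
    threshold: float,
    direction: str = "le",
) -> GeneList:
    """Threshold a metrics table into a gene subset (the DEG-overlay source).

    direction ``le`` keeps values ≤ threshold, ``ge`` keeps ≥, and ``abs_ge``
    compares the absolute value (the usual |logFC| filter).  Result preserves
    metrics row order.
    """
    values = metrics.values(variable)
    if direction == "le":
        keep = values <= threshold
    elif direction == "ge":
        keep = values >= threshold
    elif direction == "abs_ge":
        keep = np.abs(values) >= threshold
    else:
        raise ValidationError(
            f"direction must be one of 'le', 'ge', 'abs_ge'; got {direction!r}"
        )
    return GeneList.of(np.asarray(metrics.gene_ids)[keep])
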