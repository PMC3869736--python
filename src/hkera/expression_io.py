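"""Expression-matrix I/O and the per-tissue rank transform.

All downstream computation in this package consumes ranks, not intensities:
each tissue (column) is rank-transformed over the full gene universe of the
loaded matrix, with ties averaged. Rank 1 is the lowest intensity; the
orientation is an internal convention because the pairwise decomposition uses
only rank differences and their sign products.

Matrices travel as tab-separated text: one header row of tissue identifiers,
first column gene identifiers, nonnegative intensities. Gene lists are plain
text, one identifier per line, ``#`` comments and blank lines ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("hkera")

__all__ = [
    "ExpressionMatrix",
    "PresentCallMatrix",
    "RankMatrix",
    "GeneSet",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "read_present_calls",
    "write_present_calls",
    "read_gene_list",
    "write_gene_list",
    "rank_transform",
    "derive_present_calls",
]


class ValidationError(ValueError):
    """Raised when an input table or gene list violates its contract."""


def _check_axes(gene_ids: tuple[str, ...], tissue_ids: tuple[str, ...]) -> None:
    if len(set(gene_ids)) != len(gene_ids):
        dupes = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()].tolist()
        raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
    if len(set(tissue_ids)) != len(tissue_ids):
        dupes = pd.Index(tissue_ids)[pd.Index(tissue_ids).duplicated()].tolist()
        raise ValidationError(f"duplicate tissue identifiers: {dupes[:5]}")
    if len(gene_ids) < 2 or len(tissue_ids) < 2:
        raise ValidationError(
            f"matrix needs at least 2 genes and 2 tissues, got "
            f"{len(gene_ids)} x {len(tissue_ids)}"
        )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative intensity matrix, genes x tissues.

    Parameters
    ----------
    gene_ids, tissue_ids
        Ordered, unique identifiers for the rows and columns.
    values
        Finite, nonnegative float array of shape ``(n_genes, n_tissues)``.
    """

    gene_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_axes(self.gene_ids, self.tissue_ids)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match axes "
                f"({len(self.gene_ids)}, {len(self.tissue_ids)})"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if np.any(values < 0):
            raise ValidationError("expression values must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
            )
            return self._index[gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.tissue_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            tissue_ids=tuple(str(t) for t in frame.columns),
            values=frame.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class PresentCallMatrix:
    """Boolean present/absent detection calls on the same axes as an
    :class:`ExpressionMatrix`."""

    gene_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_axes(self.gene_ids, self.tissue_ids)
        values = np.asarray(self.values, dtype=bool)
        if values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValidationError(
                f"calls shape {values.shape} does not match axes"
            )
        object.__setattr__(self, "values", values)

    def matches_axes(self, expr: ExpressionMatrix) -> bool:
        return (
            self.gene_ids == expr.gene_ids and self.tissue_ids == expr.tissue_ids
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.where(self.values, "P", "A"),
            index=list(self.gene_ids),
            columns=list(self.tissue_ids),
        )


@dataclass(frozen=True)
class RankMatrix:
    """Within-tissue ranks of every gene, ties averaged, range [1, G].

    Every column is a permutation of 1..G after tie-averaging, so each
    column sums to G(G+1)/2 exactly.
    """

    gene_ids: tuple[str, ...]
    tissue_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _check_axes(self.gene_ids, self.tissue_ids)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValidationError("rank shape does not match axes")
        G = len(self.gene_ids)
        expected = G * (G + 1) / 2.0
        sums = values.sum(axis=0)
        if not np.allclose(sums, expected, rtol=0, atol=1e-6 * max(expected, 1.0)):
            raise ValidationError(
                "rank columns must each sum to G(G+1)/2; not a valid rank matrix"
            )
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except AttributeError:
            object.__setattr__(
                self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
            )
            return self._index[gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.tissue_ids)
        )


@dataclass(frozen=True)
class GeneSet:
    """Named, unordered collection of gene identifiers.

    Membership may include identifiers absent from a given matrix; such
    mismatches are resolved wherever the set is used.
    """

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))


# ---------------------------------------------------------------------------
# Table readers / writers


def _read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValidationError(
            f"{path}: missing values in rows {bad[:5]} (ragged or empty cells); "
            "missing data is rejected, not imputed"
        )
    return frame


def read_expression_table(
    path: str | Path, dialect: str = "tsv"
) -> ExpressionMatrix:
    """Read a genes x tissues intensity table.

    The file must have one header row of tissue identifiers and gene
    identifiers in the first column. Duplicate identifiers, negative or
    non-numeric values, and ragged rows are rejected.
    """
    frame = _read_table(path, dialect)
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression value: {exc}") from exc
    return ExpressionMatrix.from_frame(numeric)


def write_expression_table(
    expr: ExpressionMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_present_calls(path: str | Path, dialect: str = "tsv") -> PresentCallMatrix:
    """Read a present/absent call table (values ``P``/``A``) parallel to an
    expression table."""
    frame = _read_table(path, dialect)
    upper = frame.apply(lambda col: col.str.strip().str.upper())
    bad = ~upper.isin(["P", "A"])
    if bad.any().any():
        raise ValidationError(f"{path}: call values must be 'P' or 'A'")
    return PresentCallMatrix(
        gene_ids=tuple(str(g) for g in frame.index),
        tissue_ids=tuple(str(t) for t in frame.columns),
        values=(upper == "P").to_numpy(),
    )


def write_present_calls(
    calls: PresentCallMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    calls.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-identifier-per-line gene list.

    Blank lines and ``#`` comments are ignored; duplicates are collapsed
    with a logged warning. An effectively empty file is an error.
    """
    path = Path(path)
    seen: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        seen.append(token)
    if not seen:
        raise ValidationError(f"{path}: gene list contains no identifiers")
    members = frozenset(seen)
    if len(members) < len(seen):
        logger.warning(
            "%s: collapsed %d duplicate identifiers", path, len(seen) - len(members)
        )
    return GeneSet(name=name or path.stem, members=members)


def write_gene_list(genes: Iterable[str] | GeneSet, path: str | Path) -> None:
    members = sorted(set(genes))
    Path(path).write_text("\n".join(members) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Rank transform and surrogate calls


def rank_transform(expr: ExpressionMatrix) -> RankMatrix:
    """Rank every gene within each tissue, ascending, ties averaged.

    Rank 1 is the lowest intensity. Ranks are computed over the full gene
    universe of ``expr``: subsetting genes changes ranks, so pairwise
    computation always takes a full :class:`RankMatrix` plus gene
    identifiers, never pre-sliced rank vectors.
    """
    ranks = rankdata(expr.values, method="average", axis=0)
    return RankMatrix(
        gene_ids=expr.gene_ids, tissue_ids=expr.tissue_ids, values=ranks
    )


def derive_present_calls(
    expr: ExpressionMatrix, call_threshold: float = 100.0
) -> PresentCallMatrix:
    """Derive surrogate present calls by an intensity threshold.

    Detection p-values are rarely shipped with expression matrices; when no
    explicit call matrix is available, a gene is called present in a tissue
    iff its intensity is at least ``call_threshold``. The surrogate nature is
    logged.
    """
    if call_threshold < 0:
        raise ValueError("call_threshold must be >= 0")
    logger.info(
        "deriving surrogate present calls at intensity threshold %g "
        "(no detection p-values available)",
        call_threshold,
    )
    return PresentCallMatrix(
        gene_ids=expr.gene_ids,
        tissue_ids=expr.tissue_ids,
        values=expr.values >= call_threshold,
    )
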