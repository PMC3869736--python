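"""Per-gene 16-attribute feature vectors.

Each query gene is paired with every member of a fixed reference panel; the
arithmetic mean of each tensor component over those pairings is one
attribute. Because the eight R+ components are nonnegative and the eight R-
components nonpositive for every pair, the means preserve those signs.

Feature computation is embarrassingly parallel over queries and the result
is identical regardless of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import GeneSet, RankMatrix
from .rank_tensor import (
    COMPONENT_NAMES,
    N_COMPONENTS,
    TensorThresholds,
    _decompose_batch,
)

logger = logging.getLogger("hkera")

__all__ = [
    "ReferenceSet",
    "FeatureTable",
    "select_reference_set",
    "build_feature_vector",
    "build_feature_table",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered panel of reference genes each query is paired with."""

    members: tuple[str, ...]
    composition_label: str = "custom"  # HK-only | TS-only | mixed | custom
    name: str = "reference"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("reference set must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("reference set contains duplicate genes")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FeatureTable:
    """Per-gene 16-attribute vectors plus provenance metadata."""

    gene_ids: tuple[str, ...]
    attributes: np.ndarray = field(repr=False)  # (n_genes, 16)
    reference_name: str = "reference"
    thresholds_used: TensorThresholds = TensorThresholds()

    def __post_init__(self) -> None:
        attrs = np.asarray(self.attributes, dtype=float)
        if attrs.shape != (len(self.gene_ids), N_COMPONENTS):
            raise ValueError(
                f"attributes must be (n_genes, {N_COMPONENTS}), got {attrs.shape}"
            )
        object.__setattr__(self, "attributes", attrs)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.attributes, index=list(self.gene_ids), columns=list(COMPONENT_NAMES)
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read(cls, path: str | Path, **meta) -> "FeatureTable":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if list(frame.columns) != list(COMPONENT_NAMES):
            raise ValueError(f"{path}: expected columns {COMPONENT_NAMES}")
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            attributes=frame.to_numpy(dtype=float),
            **meta,
        )


def select_reference_set(
    pool: GeneSet,
    exclude: GeneSet,
    n: int = 50,
    seed: int = 0,
    composition_label: str = "custom",
    name: str | None = None,
) -> ReferenceSet:
    """Sample ``n`` reference genes uniformly without replacement from
    ``pool`` minus ``exclude``; deterministic for a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates = sorted(pool.members - exclude.members)
    if len(candidates) < n:
        raise ValueError(
            f"reference pool too small: need {n}, have {len(candidates)} "
            f"after excluding {len(pool.members & exclude.members)} genes "
            f"(short by {n - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return ReferenceSet(
        members=tuple(candidates[i] for i in sorted(chosen)),
        composition_label=composition_label,
        name=name or f"{pool.name}-ref{n}",
    )


def _feature_vector_idx(
    rank_values: np.ndarray,
    query_idx: int,
    ref_idx: np.ndarray,
    thresholds: TensorThresholds,
) -> np.ndarray:
    _, comps, _, _ = _decompose_batch(rank_values, query_idx, ref_idx, thresholds)
    return comps.mean(axis=0)


def build_feature_vector(
    query: str,
    ref: ReferenceSet,
    ranks: RankMatrix,
    thresholds: TensorThresholds = TensorThresholds(),
) -> np.ndarray:
    """16-attribute vector of one query gene: elementwise mean of the tensor
    components over all query-reference pairs.

    A query present in its own reference panel is dropped pairwise (its
    self-pair is an all-tie decomposition that would bias every attribute
    toward zero).
    """
    qi = ranks.gene_index(query)
    members = list(ref.members)
    if query in members:
        logger.warning("query %s found in reference set; dropped pairwise", query)
        members = [m for m in members if m != query]
    if not members:
        raise ValueError(f"no reference genes left for query {query!r}")
    ref_idx = np.array([ranks.gene_index(m) for m in members])
    return _feature_vector_idx(ranks.values, qi, ref_idx, thresholds)


def build_feature_table(
    queries,
    ref: ReferenceSet,
    ranks: RankMatrix,
    thresholds: TensorThresholds = TensorThresholds(),
) -> FeatureTable:
    """Feature vectors for a batch of queries, rows in query order.

    ``queries`` may be a GeneSet (iterated in sorted order) or any ordered
    iterable of gene identifiers. Per-query failures are collected and
    reported together with the offending gene ids.
    """
    query_list = list(queries)
    errors: list[str] = []
    rows = np.zeros((len(query_list), N_COMPONENTS))
    for i, q in enumerate(query_list):
        try:
            rows[i] = build_feature_vector(q, ref, ranks, thresholds)
        except (KeyError, ValueError) as exc:
            errors.append(f"{q}: {exc}")
    if errors:
        raise ValueError(
            f"feature computation failed for {len(errors)} queries: "
            + "; ".join(errors[:10])
        )
    return FeatureTable(
        gene_ids=tuple(query_list),
        attributes=rows,
        reference_name=ref.name,
        thresholds_used=thresholds,
    )
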