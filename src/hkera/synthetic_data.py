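"""Labeled synthetic transcriptomes with controllable rank structure.

The generator emulates the statistical skeleton of a genome-wide tissue
panel (by default 2,000 genes x 36 tissues, with class sizes proportioned
like a curated microarray compendium: 388 housekeeping-like, 734
tissue-specific-like, 878 middle-ranged):

* **HK genes** draw a gene-specific median level log-uniformly from
  ``base_level_range`` and multiply it by small log-normal tissue noise
  (sd ``hk_rank_noise_sd`` on the log scale), so the between-gene rank
  order is nearly constant across tissues — the rank-preservation property
  the classifier exploits. Level and rank stability are independently
  controllable: HK genes can be placed entirely below any intensity cutoff
  without touching their rank behavior.
* **TS genes** are expressed at ``ts_on_level`` in a small random subset of
  tissues (``ts_on_tissues``) and at ``ts_off_level`` elsewhere, with
  log-normal noise.
* **MR genes** (middle-ranged) reuse the HK construction with large noise
  (sd ``mr_noise_sd``), scrambling their rankings.

A single global seed drives a hierarchical RNG with one substream per gene,
so enlarging a class appends genes without perturbing existing ones.
Present calls are derived at ``call_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    GeneSet,
    PresentCallMatrix,
    derive_present_calls,
)
from .features import ReferenceSet

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "Benchmark",
    "generate_transcriptome",
    "make_benchmark",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic transcriptome."""

    n_tissues: int = 36
    n_hk: int = 388
    n_ts: int = 734
    n_mr: int = 878
    hk_rank_noise_sd: float = 0.05  # log-scale tissue noise for HK genes
    mr_noise_sd: float = 0.5  # log-scale noise for MR genes
    ts_on_tissues: int = 3  # tissues where a TS gene is "on"
    ts_on_level: float = 500.0
    ts_off_level: float = 10.0
    ts_noise_sd: float = 0.3  # log-scale noise around on/off levels
    base_level_range: tuple[float, float] = (50.0, 5000.0)  # log-uniform medians
    call_threshold: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hk, self.n_ts, self.n_mr) < 0:
            raise ValueError("class counts must be >= 0")
        if self.n_hk + self.n_ts + self.n_mr < 4:
            raise ValueError("need at least 4 genes in total")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.hk_rank_noise_sd < 0 or self.mr_noise_sd < 0 or self.ts_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0 < self.ts_on_tissues <= self.n_tissues):
            raise ValueError("ts_on_tissues must be in 1..n_tissues")
        lo, hi = self.base_level_range
        if not (0 < lo <= hi):
            raise ValueError("base_level_range must be a positive interval")
        if not (self.ts_on_level > self.ts_off_level > 0):
            raise ValueError("ts_on_level must exceed ts_off_level > 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth class (HK / TS / MR) of every generated gene."""

    classes: Mapping[str, str]

    def gene_set(self, cls: str) -> GeneSet:
        return GeneSet(
            name=cls, members=frozenset(g for g, c in self.classes.items() if c == cls)
        )

    def __getitem__(self, gene: str) -> str:
        return self.classes[gene]

    def write(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            sorted(self.classes.items()), columns=["gene_id", "class"]
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        return cls(classes=dict(zip(frame["gene_id"], frame["class"])))


def generate_transcriptome(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[ExpressionMatrix, PresentCallMatrix, SyntheticTruth]:
    """Generate one labeled transcriptome; deterministic for a fixed seed."""
    n_genes = spec.n_hk + spec.n_ts + spec.n_mr
    classes = ["HK"] * spec.n_hk + ["TS"] * spec.n_ts + ["MR"] * spec.n_mr
    width = len(str(n_genes))
    gene_ids = tuple(
        f"g{str(i + 1).zfill(width)}_{c}" for i, c in enumerate(classes)
    )

    log_lo, log_hi = np.log(spec.base_level_range[0]), np.log(spec.base_level_range[1])
    streams = np.random.SeedSequence(spec.seed).spawn(n_genes)
    values = np.empty((n_genes, spec.n_tissues))
    for i, (cls, ss) in enumerate(zip(classes, streams)):
        rng = np.random.default_rng(ss)
        if cls == "HK":
            base = np.exp(rng.uniform(log_lo, log_hi))
            values[i] = base * np.exp(
                rng.normal(0.0, spec.hk_rank_noise_sd, spec.n_tissues)
            )
        elif cls == "TS":
            on = rng.choice(spec.n_tissues, size=spec.ts_on_tissues, replace=False)
            level = np.full(spec.n_tissues, spec.ts_off_level)
            level[on] = spec.ts_on_level
            values[i] = level * np.exp(
                rng.normal(0.0, spec.ts_noise_sd, spec.n_tissues)
            )
        else:  # MR
            base = np.exp(rng.uniform(log_lo, log_hi))
            values[i] = base * np.exp(
                rng.normal(0.0, spec.mr_noise_sd, spec.n_tissues)
            )

    tissue_ids = tuple(f"tissue_{j + 1:02d}" for j in range(spec.n_tissues))
    expr = ExpressionMatrix(gene_ids=gene_ids, tissue_ids=tissue_ids, values=values)
    calls = derive_present_calls(expr, spec.call_threshold)
    truth = SyntheticTruth(classes=dict(zip(gene_ids, classes)))
    return expr, calls, truth


@dataclass(frozen=True)
class Benchmark:
    """A generated transcriptome plus the seeded gene selections needed to
    train and evaluate a classifier on it."""

    expression: ExpressionMatrix
    calls: PresentCallMatrix
    truth: SyntheticTruth
    labels: dict[str, str]  # the selected train/test genes -> HK/TS
    reference: ReferenceSet

    @property
    def labeled_genes(self) -> tuple[str, ...]:
        return tuple(self.labels)


def make_benchmark(
    spec: SyntheticSpec = SyntheticSpec(),
    n_train_per_class: int = 300,
    n_reference: int = 50,
    seed: int = 0,
    reference_composition: str = "TS-only",
) -> Benchmark:
    """Generate a transcriptome and select disjoint training/test genes and
    a reference panel.

    ``n_train_per_class`` genes are sampled from each of the HK and TS
    pools for cross-validated training/testing; the reference panel is then
    drawn from the remaining pool genes (``reference_composition``:
    "TS-only", "HK-only", or "mixed"). All selections are seeded and
    reproducible.
    """
    expr, calls, truth = generate_transcriptome(spec)
    rng = np.random.default_rng(seed)

    pools = {
        "HK": sorted(truth.gene_set("HK").members),
        "TS": sorted(truth.gene_set("TS").members),
    }
    labels: dict[str, str] = {}
    chosen: dict[str, set[str]] = {}
    for cls in ("HK", "TS"):
        pool = pools[cls]
        if len(pool) < n_train_per_class:
            raise ValueError(
                f"{cls} pool has {len(pool)} genes, need {n_train_per_class}"
            )
        pick = rng.choice(len(pool), size=n_train_per_class, replace=False)
        chosen[cls] = {pool[i] for i in pick}
        for g in sorted(chosen[cls]):
            labels[g] = cls

    def draw(cls: str, n: int) -> list[str]:
        remaining = sorted(set(pools[cls]) - chosen[cls])
        if len(remaining) < n:
            raise ValueError(
                f"{cls} pool too small for a {n}-gene reference after "
                f"excluding training genes (short by {n - len(remaining)})"
            )
        pick = rng.choice(len(remaining), size=n, replace=False)
        return [remaining[i] for i in sorted(pick)]

    if reference_composition == "TS-only":
        members = draw("TS", n_reference)
    elif reference_composition == "HK-only":
        members = draw("HK", n_reference)
    elif reference_composition == "mixed":
        half = n_reference // 2
        members = draw("HK", half) + draw("TS", n_reference - half)
    else:
        raise ValueError(
            f"reference_composition must be TS-only, HK-only or mixed, "
            f"got {reference_composition!r}"
        )
    reference = ReferenceSet(
        members=tuple(members),
        composition_label=reference_composition,
        name=f"{reference_composition}-{n_reference}",
    )
    return Benchmark(
        expression=expr, calls=calls, truth=truth, labels=labels, reference=reference
    )
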