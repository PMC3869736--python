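"""Performance measures, ROC curves, and cross-coverage analysis.

Predictions are evaluated against a benchmark HK gene set and a TS gene
set. Genes present in both truth sets are excluded before counting
(benchmark sets curated by different groups overlap slightly), then

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    recall      = TP / (TP + FN)           (sensitivity)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)

all reported in percent. ROC curves sweep the continuous score over all
distinct values; the AUC is integrated by the trapezoidal rule, which
equals the rank-sum formulation P(score_HK > score_TS) + 1/2 P(equal).

Cross-coverage compares, at each score threshold, the overlap of the
predicted HK set with a benchmark set against a size-matched random gene
set drawn from the same universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_io import GeneSet

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "CoverageCurve",
    "confusion_counts",
    "metrics",
    "roc_curve",
    "cross_coverage",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class RocCurve:
    """Ordered (1 - specificity, sensitivity) points from (0,0) to (1,1)."""

    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


@dataclass(frozen=True)
class CoverageCurve:
    """Forward/reverse benchmark coverage of the predicted HK set vs a
    size-matched random control, per score threshold."""

    table: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _as_call_map(calls) -> Mapping[str, str]:
    if hasattr(calls, "call_dict"):
        return calls.call_dict()
    return dict(calls)


def _as_score_map(scores) -> Mapping[str, float]:
    if hasattr(scores, "as_dict"):
        return scores.as_dict()
    return dict(scores)


def confusion_counts(
    calls, hk_truth: GeneSet, ts_truth: GeneSet
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN of HK/TS calls against disjoint-ified truth sets.

    Genes in both truth sets are excluded before counting. TP: HK-truth
    genes called HK; FN: HK-truth genes called TS; FP: TS-truth genes
    called HK; TN: TS-truth genes called TS.
    """
    call_map = _as_call_map(calls)
    overlap = hk_truth.members & ts_truth.members
    hk = hk_truth.members - overlap
    ts = ts_truth.members - overlap
    missing = [g for g in (hk | ts) if g not in call_map]
    if missing:
        raise ValueError(
            f"{len(missing)} truth genes have no call, e.g. {sorted(missing)[:5]}"
        )
    tp = sum(1 for g in hk if call_map[g] == "HK")
    fn = len(hk) - tp
    fp = sum(1 for g in ts if call_map[g] == "HK")
    tn = len(ts) - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, recall, precision and specificity in percent.

    A metric whose denominator is zero is reported as ``None`` (absent),
    never as 0 or 100.
    """
    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": pct(c.tp + c.tn, c.tp + c.tn + c.fp + c.fn),
        "recall": pct(c.tp, c.tp + c.fn),
        "precision": pct(c.tp, c.tp + c.fp),
        "specificity": pct(c.tn, c.tn + c.fp),
    }


def roc_curve(scores, hk_truth: GeneSet, ts_truth: GeneSet) -> RocCurve:
    """ROC of a continuous score against benchmark HK (positive) and TS
    (negative) truth sets, after overlap exclusion.

    The threshold sweeps all distinct scores; tied scores move the curve
    diagonally, so the trapezoidal AUC equals
    P(score_HK > score_TS) + 1/2 P(equal).
    """
    score_map = _as_score_map(scores)
    overlap = hk_truth.members & ts_truth.members
    pos = sorted(hk_truth.members - overlap)
    neg = sorted(ts_truth.members - overlap)
    if not pos or not neg:
        raise ValueError("both truth classes must be nonempty after overlap exclusion")
    missing = [g for g in pos + neg if g not in score_map]
    if missing:
        raise ValueError(f"scores missing for truth genes, e.g. {missing[:5]}")

    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.array([score_map[g] for g in pos + neg], dtype=float)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]

    # cumulative counts at each distinct score (call HK iff score >= cut)
    distinct = np.flatnonzero(np.diff(s) != 0)
    idx = np.concatenate([distinct, [len(s) - 1]])
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]
    tpr = np.concatenate([[0.0], tps / len(pos)])
    fpr = np.concatenate([[0.0], fps / len(neg)])
    thresholds = np.concatenate([[np.inf], s[idx]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def cross_coverage(
    scores,
    benchmark: GeneSet,
    universe: GeneSet,
    thresholds: Sequence[float],
    seed: int = 0,
    repeats: int = 1,
) -> CoverageCurve:
    """Benchmark coverage of the thresholded HK prediction vs a random
    control.

    At each threshold, genes scoring strictly above it form the predicted
    HK set; forward coverage is the percent of predicted genes in the
    benchmark, reverse coverage the percent of the benchmark predicted. A
    size-matched random set drawn (without replacement, seeded) from the
    universe provides the control percentages; with ``repeats`` > 1 the
    control columns are means over independent draws.
    """
    score_map = _as_score_map(scores)
    if not benchmark.members <= universe.members:
        raise ValueError("benchmark must be a subset of the universe")
    missing = [g for g in universe.members if g not in score_map]
    if missing:
        raise ValueError(f"scores missing for universe genes, e.g. {sorted(missing)[:5]}")

    genes = sorted(universe.members)
    s = np.array([score_map[g] for g in genes])
    bench_mask = np.array([g in benchmark.members for g in genes])
    n_bench = int(bench_mask.sum())
    rng = np.random.default_rng(seed)

    rows = []
    for thr in thresholds:
        pred_mask = s > thr
        n_pred = int(pred_mask.sum())
        hits = int((pred_mask & bench_mask).sum())
        forward = 100.0 * hits / n_pred if n_pred else None
        reverse = 100.0 * hits / n_bench if n_bench else None

        rand_fwd, rand_rev = [], []
        for _ in range(repeats):
            pick = rng.choice(len(genes), size=n_pred, replace=False)
            rhits = int(bench_mask[pick].sum())
            rand_fwd.append(100.0 * rhits / n_pred if n_pred else np.nan)
            rand_rev.append(100.0 * rhits / n_bench if n_bench else np.nan)
        rows.append(
            {
                "threshold": thr,
                "n_predicted": n_pred,
                "forward_coverage": forward,
                "reverse_coverage": reverse,
                "random_forward": float(np.mean(rand_fwd)) if n_pred else None,
                "random_reverse": float(np.mean(rand_rev)) if n_pred else None,
            }
        )
    return CoverageCurve(table=pd.DataFrame(rows))
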