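"""Expression-threshold comparator classifiers.

Four conventional ways of calling a gene "housekeeping" from a tissue panel:

* **Exp** — expressed at high intensity (x >= 200 by default) in at least
  N-1 tissues.
* **PCall** — a 'Present' detection call in at least N-1 tissues.
* **FPEI** — fraction-present weighted expression intensity: per gene,
  FP = (present tissues)/N; per tissue, FPEI = FP * intensity; HK iff
  FPEI > 100 in at least N-1 tissues.
* **TSI** — tissue specificity index, TSI = sum_i (1 - x_i/x_max) / (N-1),
  bounded in [0, 1]; HK iff TSI <= 0.1.

Every method also returns a continuous score oriented "higher = more
HK-like" so all four can enter the same ROC comparison (for TSI the score
is 1 - TSI). The N-1 tissue rule generalizes the 35-of-36 criterion to
matrices with other tissue counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .expression_io import ExpressionMatrix, PresentCallMatrix

logger = logging.getLogger("hkera")

__all__ = [
    "BaselineResult",
    "exp_classifier",
    "pcall_classifier",
    "fpei_classifier",
    "tsi_classifier",
    "tsi_index",
]


@dataclass(frozen=True)
class BaselineResult:
    """Scores and HK/TS calls of one comparator method."""

    method: str  # Exp | PCall | FPEI | TSI
    gene_ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)  # higher = more HK-like
    calls: tuple[str, ...] = field(repr=False)
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.scores.tolist()))

    def call_dict(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.calls))


def _result(method, expr_ids, scores, hk_mask, params) -> BaselineResult:
    calls = tuple("HK" if h else "TS" for h in hk_mask)
    return BaselineResult(
        method=method,
        gene_ids=expr_ids,
        scores=np.asarray(scores, dtype=float),
        calls=calls,
        parameters=params,
    )


def _default_min_tissues(n_tissues: int, min_tissues: int | None) -> int:
    mt = n_tissues - 1 if min_tissues is None else min_tissues
    if mt > n_tissues:
        raise ValueError(f"min_tissues={mt} exceeds tissue count {n_tissues}")
    return mt


def exp_classifier(
    expr: ExpressionMatrix,
    intensity_thr: float = 200.0,
    min_tissues: int | None = None,
) -> BaselineResult:
    """HK iff intensity >= ``intensity_thr`` in at least ``min_tissues``
    tissues (default N-1). Score = fraction of tissues passing."""
    mt = _default_min_tissues(expr.n_tissues, min_tissues)
    passing = (expr.values >= intensity_thr).sum(axis=1)
    return _result(
        "Exp",
        expr.gene_ids,
        passing / expr.n_tissues,
        passing >= mt,
        {"intensity_thr": intensity_thr, "min_tissues": mt},
    )


def pcall_classifier(
    calls: PresentCallMatrix, min_tissues: int | None = None
) -> BaselineResult:
    """HK iff present in at least ``min_tissues`` tissues (default N-1).
    Score = fraction of tissues present."""
    n_tissues = len(calls.tissue_ids)
    mt = _default_min_tissues(n_tissues, min_tissues)
    present = calls.values.sum(axis=1)
    return _result(
        "PCall",
        calls.gene_ids,
        present / n_tissues,
        present >= mt,
        {"min_tissues": mt},
    )


def fpei_classifier(
    expr: ExpressionMatrix,
    calls: PresentCallMatrix,
    fpei_thr: float = 100.0,
    min_tissues: int | None = None,
) -> BaselineResult:
    """Fraction-present weighted expression intensity.

    Per gene, FP = present count / N; per tissue, FPEI = FP * intensity.
    HK iff FPEI > ``fpei_thr`` (strict) in at least ``min_tissues`` tissues.
    Score = fraction of tissues with FPEI above the threshold.
    """
    if not calls.matches_axes(expr):
        raise ValueError("expression and call matrices must share axes")
    mt = _default_min_tissues(expr.n_tissues, min_tissues)
    fp = calls.values.sum(axis=1) / expr.n_tissues  # (G,)
    fpei = fp[:, None] * expr.values  # (G, N)
    passing = (fpei > fpei_thr).sum(axis=1)
    return _result(
        "FPEI",
        expr.gene_ids,
        passing / expr.n_tissues,
        passing >= mt,
        {"fpei_thr": fpei_thr, "min_tissues": mt},
    )


def tsi_index(expr: ExpressionMatrix) -> np.ndarray:
    """Tissue specificity index per gene: sum_i (1 - x_i/x_max) / (N - 1).

    0 for a perfectly uniform profile, 1 for single-tissue expression.
    Genes with an all-zero profile get TSI = 1 by convention (logged).
    """
    x = expr.values
    xmax = x.max(axis=1)
    zero = xmax == 0
    if zero.any():
        logger.warning(
            "%d genes with all-zero profiles assigned TSI = 1", int(zero.sum())
        )
    safe_max = np.where(zero, 1.0, xmax)
    tsi = (1.0 - x / safe_max[:, None]).sum(axis=1) / (expr.n_tissues - 1)
    return np.where(zero, 1.0, tsi)


def tsi_classifier(expr: ExpressionMatrix, tsi_thr: float = 0.1) -> BaselineResult:
    """HK iff TSI <= ``tsi_thr`` (inclusive, so the HK-favoring bound of 0
    for constant profiles is attained). Score = 1 - TSI so that higher
    means more HK-like, matching the other methods' orientation."""
    tsi = tsi_index(expr)
    return _result(
        "TSI", expr.gene_ids, 1.0 - tsi, tsi <= tsi_thr, {"tsi_thr": tsi_thr}
    )
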