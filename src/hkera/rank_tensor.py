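"""Kendall's tau over tissue pairs and its 16-component tensor decomposition.

For a pair of genes (a, b) with per-tissue ranks r_a(t), r_b(t) over a
G-gene universe, let D(t) = r_a(t) - r_b(t). Over every unordered tissue
pair (s, t) the between-gene ranking relation is concordant when
D(s)*D(t) > 0, discordant when < 0, and tied when = 0, giving

    tau = (n_concordant - n_discordant) / M,      M = N(N-1)/2.

Each non-tied tissue pair is further classified by three binary factors:

* Stableness  (S+/S-): neither gene's rank moves by more than theta_S * G
  between the two tissues.
* Co-expression (C+/C-): the two genes' rank changes point the same way
  (product of rank changes >= 0).
* Dispersion  (D+/D-): the genes are well separated in rank in both
  tissues (min |D| >= theta_D * G).

Crossing Ranking (R+/R-) with S, C, D yields a 2x2x2x2 contingency table of
16 cells. Component A_k is the signed fraction of tissue pairs in cell k:
positive for the eight R+ cells (A1-A8), negative for the eight R- cells
(A9-A16), so that sum(A1..A16) = tau exactly. Within each R block the
(S, C, D) combinations are enumerated (+,+,+), (+,+,-), (+,-,+), (+,-,-),
(-,+,+), (-,+,-), (-,-,+), (-,-,-); hence A1 = (R+,S+,C+,D+) and
A8 = (R+,S-,C-,D-).

Ties (D(s)*D(t) = 0) contribute to neither the numerator of tau nor any of
the 16 cells, while the denominator stays M (the tau-a convention); this
keeps the conservation identity exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_io import RankMatrix

__all__ = [
    "TensorThresholds",
    "TissuePairCell",
    "TensorDecomposition",
    "N_COMPONENTS",
    "COMPONENT_NAMES",
    "classify_tissue_pair",
    "kendall_tau_pair",
    "decompose_pair",
]

N_COMPONENTS = 16
COMPONENT_NAMES = tuple(f"A{k}" for k in range(1, N_COMPONENTS + 1))

#: (ranking, stableness, coexpression, dispersion) label for each cell index.
CELL_LABELS = tuple(
    (r, s, c, d)
    for r in ("R+", "R-")
    for s in ("S+", "S-")
    for c in ("C+", "C-")
    for d in ("D+", "D-")
)


@dataclass(frozen=True)
class TensorThresholds:
    """Cutoffs for the stableness and dispersion factors, as fractions of
    the gene count G.

    theta_s : a gene's rank change between two tissues is "stable" iff
        \\|delta rank\\| <= theta_s * G. Default 0.10.
    theta_d : the two genes are "dispersed" in a tissue iff their rank
        difference satisfies \\|D\\| >= theta_d * G. Default 0.05.
    """

    theta_s: float = 0.10
    theta_d: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_s <= 1.0):
            raise ValueError(f"theta_s must be in [0, 1], got {self.theta_s}")
        if not (0.0 <= self.theta_d <= 1.0):
            raise ValueError(f"theta_d must be in [0, 1], got {self.theta_d}")


@dataclass(frozen=True)
class TissuePairCell:
    """Factor assignment of one tissue pair for one gene pair."""

    ranking: str  # "R+", "R-", or "tie"
    stableness: str  # "S+" / "S-"
    coexpression: str  # "C+" / "C-"
    dispersion: str  # "D+" / "D-"


@dataclass(frozen=True)
class TensorDecomposition:
    """Kendall's tau of one gene pair and its 16 signed components.

    Attributes
    ----------
    tau : concordance over all M = N(N-1)/2 tissue pairs, in [-1, 1].
    components : 16 signed fractions; components[0..7] >= 0 (R+ cells),
        components[8..15] <= 0 (R- cells); their sum equals ``tau``.
    cell_counts : raw tissue-pair tallies of the 16 cells.
    tie_count : tissue pairs with a zero sign product, excluded from all
        cells.
    n_pos, n_neg : tissue pairs where D > 0 (resp. < 0) in both tissues;
        n_pos + n_neg = n_concordant.
    """

    tau: float
    components: np.ndarray = field(repr=False)
    cell_counts: np.ndarray = field(repr=False)
    tie_count: int
    n_tissue_pairs: int
    n_pos: int
    n_neg: int


def _require_gene(ranks: RankMatrix, gene: str) -> int:
    try:
        return ranks.gene_index(gene)
    except KeyError:
        raise KeyError(f"gene {gene!r} not present in rank matrix") from None


def _require_tissue(ranks: RankMatrix, tissue: str) -> int:
    try:
        return ranks.tissue_ids.index(tissue)
    except ValueError:
        raise KeyError(f"tissue {tissue!r} not present in rank matrix") from None


def classify_tissue_pair(
    ranks: RankMatrix,
    gene_a: str,
    gene_b: str,
    tissue_s: str,
    tissue_t: str,
    thresholds: TensorThresholds = TensorThresholds(),
) -> TissuePairCell:
    """Assign one tissue pair to its (R, S, C, D) cell for a gene pair.

    Symmetric in tissue order and in gene order (the ranking factor depends
    on D only through the sign product D(s)*D(t)).
    """
    ia, ib = _require_gene(ranks, gene_a), _require_gene(ranks, gene_b)
    js, jt = _require_tissue(ranks, tissue_s), _require_tissue(ranks, tissue_t)
    if js == jt:
        raise ValueError("tissue_s and tissue_t must differ")
    G = ranks.n_genes
    ra_s, ra_t = ranks.values[ia, js], ranks.values[ia, jt]
    rb_s, rb_t = ranks.values[ib, js], ranks.values[ib, jt]
    d_s, d_t = ra_s - rb_s, ra_t - rb_t

    prod = d_s * d_t
    ranking = "tie" if prod == 0 else ("R+" if prod > 0 else "R-")
    stable = max(abs(ra_s - ra_t), abs(rb_s - rb_t)) <= thresholds.theta_s * G
    coexp = (ra_s - ra_t) * (rb_s - rb_t) >= 0
    disp = min(abs(d_s), abs(d_t)) >= thresholds.theta_d * G
    return TissuePairCell(
        ranking=ranking,
        stableness="S+" if stable else "S-",
        coexpression="C+" if coexp else "C-",
        dispersion="D+" if disp else "D-",
    )


def _tissue_pair_indices(n_tissues: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_tissues, k=1)


def _decompose_batch(
    rank_values: np.ndarray,
    query_idx: int,
    other_idx: np.ndarray,
    thresholds: TensorThresholds,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Decompose (query, other_j) for a batch of partner genes at once.

    Returns ``(taus, components, cell_counts, extras)`` with shapes
    ``(B,)``, ``(B, 16)``, ``(B, 16)``; ``extras`` holds per-pair tie, pos
    and neg tallies. Vectorized over the M tissue pairs, which is what makes
    feature-table construction over thousands of query x reference pairs
    tractable.
    """
    G, N = rank_values.shape
    iu, ju = _tissue_pair_indices(N)
    M = iu.size

    ra = rank_values[query_idx]  # (N,)
    rb = rank_values[other_idx]  # (B, N)
    d = ra[None, :] - rb  # (B, N)

    ds, dt = d[:, iu], d[:, ju]  # (B, M)
    prod = ds * dt
    pos_mask = prod > 0
    neg_mask = prod < 0
    tie_mask = prod == 0

    da = np.abs(ra[iu] - ra[ju])  # (M,)
    db = np.abs(rb[:, iu] - rb[:, ju])  # (B, M)
    s_minus = np.maximum(da[None, :], db) > thresholds.theta_s * G
    c_minus = (ra[iu] - ra[ju])[None, :] * (rb[:, iu] - rb[:, ju]) < 0
    d_minus = np.minimum(np.abs(ds), np.abs(dt)) < thresholds.theta_d * G

    # cell index 0..15: 8*(R-) + 4*(S-) + 2*(C-) + (D-)
    cell = (
        8 * neg_mask.astype(np.int64)
        + 4 * s_minus.astype(np.int64)
        + 2 * c_minus.astype(np.int64)
        + d_minus.astype(np.int64)
    )
    cell[tie_mask] = N_COMPONENTS  # overflow bucket, dropped below

    B = cell.shape[0]
    offsets = np.arange(B, dtype=np.int64)[:, None] * (N_COMPONENTS + 1)
    flat = np.bincount(
        (cell + offsets).ravel(), minlength=B * (N_COMPONENTS + 1)
    ).reshape(B, N_COMPONENTS + 1)
    cell_counts = flat[:, :N_COMPONENTS]
    tie_counts = flat[:, N_COMPONENTS]

    signs = np.where(np.arange(N_COMPONENTS) < 8, 1.0, -1.0)
    components = cell_counts * signs[None, :] / M
    n_conc = cell_counts[:, :8].sum(axis=1)
    n_disc = cell_counts[:, 8:].sum(axis=1)
    taus = (n_conc - n_disc) / M

    extras = {
        "tie": tie_counts,
        "n_pos": ((ds > 0) & (dt > 0)).sum(axis=1),
        "n_neg": ((ds < 0) & (dt < 0)).sum(axis=1),
        "n_conc": n_conc,
        "n_disc": n_disc,
    }
    return taus, components, cell_counts, extras


def kendall_tau_pair(
    ranks: RankMatrix, gene_a: str, gene_b: str
) -> tuple[float, int, int, int, int, int]:
    """Kendall's tau of the between-gene ranking relation over all tissue
    pairs.

    Returns ``(tau, n_conc, n_disc, n_tie, n_pos, n_neg)`` where ``n_pos``
    (``n_neg``) counts tissue pairs with D > 0 (D < 0) in both tissues;
    ``n_pos + n_neg = n_conc``. The denominator is always M = N(N-1)/2.
    """
    ia, ib = _require_gene(ranks, gene_a), _require_gene(ranks, gene_b)
    if ranks.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    taus, _, _, extras = _decompose_batch(
        ranks.values, ia, np.array([ib]), TensorThresholds()
    )
    return (
        float(taus[0]),
        int(extras["n_conc"][0]),
        int(extras["n_disc"][0]),
        int(extras["tie"][0]),
        int(extras["n_pos"][0]),
        int(extras["n_neg"][0]),
    )


def decompose_pair(
    ranks: RankMatrix,
    gene_a: str,
    gene_b: str,
    thresholds: TensorThresholds = TensorThresholds(),
) -> TensorDecomposition:
    """Decompose a gene pair's Kendall tau into the 16 signed components.

    ``sum(components) == tau`` exactly (same tie convention), and
    ``sum(cell_counts) + tie_count == N(N-1)/2``.
    """
    ia, ib = _require_gene(ranks, gene_a), _require_gene(ranks, gene_b)
    taus, comps, counts, extras = _decompose_batch(
        ranks.values, ia, np.array([ib]), thresholds
    )
    M = ranks.n_tissues * (ranks.n_tissues - 1) // 2
    return TensorDecomposition(
        tau=float(taus[0]),
        components=comps[0],
        cell_counts=counts[0],
        tie_count=int(extras["tie"][0]),
        n_tissue_pairs=M,
        n_pos=int(extras["n_pos"][0]),
        n_neg=int(extras["n_neg"][0]),
    )
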