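"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import hkera as hk


def make_rank_matrix(columns, gene_ids=None, tissue_ids=None) -> hk.RankMatrix:
    """Build a RankMatrix directly from per-tissue rank permutations.

    ``columns`` is a list of length-G sequences, one per tissue, each a
    permutation of 1..G (tie-averaged values allowed if sums match).
    """
    values = np.array(columns, dtype=float).T
    G, N = values.shape
    return hk.RankMatrix(
        gene_ids=tuple(gene_ids or (f"g{i}" for i in range(G))),
        tissue_ids=tuple(tissue_ids or (f"t{j}" for j in range(N))),
        values=values,
    )


def rank_column_with(assignments: dict[int, float], G: int) -> list[float]:
    """A permutation of 1..G placing the given ranks at the given gene
    indices and filling the rest with the unused ranks in order."""
    used = set(assignments.values())
    free = iter(r for r in range(1, G + 1) if r not in used)
    return [assignments.get(i, None) or next(free) for i in range(G)]


def brute_force_decompose(ra, rb, G, theta_s=0.10, theta_d=0.05):
    """Exhaustive per-tissue-pair enumeration of the tau decomposition.

    Independent oracle: plain Python loops over every unordered tissue
    pair, classifying each by the four factor rules, never touching the
    package's vectorized path.
    """
    N = len(ra)
    M = N * (N - 1) // 2
    counts = [0] * 16
    ties = n_pos = n_neg = 0
    for s in range(N):
        for t in range(s + 1, N):
            d_s = ra[s] - rb[s]
            d_t = ra[t] - rb[t]
            prod = d_s * d_t
            if prod == 0:
                ties += 1
                continue
            if d_s > 0 and d_t > 0:
                n_pos += 1
            if d_s < 0 and d_t < 0:
                n_neg += 1
            r_minus = prod < 0
            s_minus = max(abs(ra[s] - ra[t]), abs(rb[s] - rb[t])) > theta_s * G
            c_minus = (ra[s] - ra[t]) * (rb[s] - rb[t]) < 0
            d_minus = min(abs(d_s), abs(d_t)) < theta_d * G
            counts[8 * r_minus + 4 * s_minus + 2 * c_minus + d_minus] += 1
    components = [
        (c if k < 8 else -c) / M for k, c in enumerate(counts)
    ]
    n_conc = sum(counts[:8])
    n_disc = sum(counts[8:])
    tau = (n_conc - n_disc) / M
    return {
        "tau": tau,
        "components": components,
        "counts": counts,
        "ties": ties,
        "n_conc": n_conc,
        "n_disc": n_disc,
        "n_pos": n_pos,
        "n_neg": n_neg,
    }


@pytest.fixture(scope="session")
def small_transcriptome():
    """A compact labeled transcriptome shared by fast unit tests."""
    spec = hk.SyntheticSpec(
        n_hk=30, n_ts=30, n_mr=40, n_tissues=12, seed=11
    )
    expr, calls, truth = hk.generate_transcriptome(spec)
    return expr, calls, truth


@pytest.fixture(scope="session")
def small_ranks(small_transcriptome):
    expr, _, _ = small_transcriptome
    return hk.rank_transform(expr)


@pytest.fixture(scope="session")
def default_benchmark():
    """The default synthetic benchmark: full-size generator, 300 + 300
    labeled genes, 50-gene TS reference. Shared across the slower tests."""
    return hk.make_benchmark(seed=20)


@pytest.fixture(scope="session")
def benchmark_features(default_benchmark):
    bench = default_benchmark
    ranks = hk.rank_transform(bench.expression)
    table = hk.build_feature_table(bench.labeled_genes, bench.reference, ranks)
    return bench, ranks, table
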