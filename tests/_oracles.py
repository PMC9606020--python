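"""Independent brute-force oracles used by the test suite.

Each oracle is a literal, unvectorized restatement of the statistic it
checks, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd


def naive_ranks(values) -> list[float]:
    """Average ranks (1..N, highest value = N) by literal sorting."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # positions i..j are tied
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_ssgsea_sample(values: pd.Series, set_genes: set, alpha: float) -> float:
    """Literal positional walk of the ssGSEA statistic for one sample."""
    genes = list(values.index)
    ranks = dict(zip(genes, naive_ranks(values.to_list())))
    walk = sorted(genes, key=lambda g: (-ranks[g], g))
    members = [g for g in walk if g in set_genes]
    denom_in = sum(ranks[g] ** alpha for g in members)
    n, m = len(genes), len(members)
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in walk:
        if g in set_genes:
            cum_in += ranks[g] ** alpha
        else:
            cum_out += 1
        score += cum_in / denom_in - cum_out / (n - m)
    return score


def naive_bh(p_values) -> list[float]:
    """BH step-up as a literal min-over-suffix on the sorted p values."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order, start=1):
        # min over all j >= pos of p_(j) * m / j
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(pos, m + 1)),
            1.0,
        )
    return q


def naive_spearman(x, y) -> float:
    """Rank both vectors naively, then plain Pearson."""
    rx = np.array(naive_ranks(list(x)))
    ry = np.array(naive_ranks(list(y)))
    return float(np.corrcoef(rx, ry)[0, 1])


def enumerate_hypergeom_tail(n_universe: int, n_set: int, n_query: int, overlap: int) -> float:
    """P(|draw ∩ set| >= overlap) by full enumeration of n_query-subsets."""
    universe = range(n_universe)
    in_set = set(range(n_set))  # wlog the first n_set elements
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n_query):
        total += 1
        if len(in_set.intersection(draw)) >= overlap:
            hits += 1
    assert total == comb(n_universe, n_query)
    return hits / total
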