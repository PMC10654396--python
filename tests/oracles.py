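"""Independent brute-force oracles used to cross-check the statistics.

Everything here is deliberately naive — direct enumeration over tables,
rank assignments or parameter grids — and shares no code path with the
implementations it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def hypergeom_prob(a: int, row1: int, col1: int, n: int) -> float:
    """P(top-left cell = a) for a 2x2 table with fixed margins."""
    b = row1 - a
    c = col1 - a
    d = n - row1 - col1 + a
    if min(b, c, d) < 0:
        return 0.0
    return comb(row1, a) * comb(n - row1, c) / comb(n, col1)


def fisher_two_sided(table: tuple[int, int, int, int]) -> float:
    """Two-sided Fisher p by the minimum-likelihood summation convention."""
    a, b, c, d = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = hypergeom_prob(a, row1, col1, n)
    total = 0.0
    for x in range(0, min(row1, col1) + 1):
        p = hypergeom_prob(x, row1, col1, n)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def fisher_greater(table: tuple[int, int, int, int]) -> float:
    """One-sided (enrichment) Fisher p: upper hypergeometric tail."""
    a, b, c, d = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    return min(
        sum(hypergeom_prob(x, row1, col1, n) for x in range(a, min(row1, col1) + 1)),
        1.0,
    )


def mannwhitney_two_sided(a, b) -> float:
    """Exact two-tailed Mann-Whitney p by full enumeration of group labels.

    Assumes no ties.  The two-sided p doubles the smaller tail (capped at
    1), matching the exact-null convention.
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(a), len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2

    us = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        r = sum(i + 1 for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


def nnls_grid_search(catalog, reference, step: float = 0.01):
    """Coarse grid-search refit of a two-signature mixture.

    Scans scale x mixing-fraction for the best L2 reconstruction of the
    catalog from the two reference columns; independent check on NNLS.
    """
    ref = np.asarray(reference, dtype=float)
    assert ref.shape[1] == 2
    total = catalog.sum()
    best = None
    for frac in np.arange(0.0, 1.0 + step / 2, step):
        for scale in np.linspace(0.5 * total, 1.5 * total, 51):
            recon = scale * (frac * ref[:, 0] + (1 - frac) * ref[:, 1])
            err = np.sum((catalog - recon) ** 2)
            if best is None or err < best[0]:
                best = (err, frac, scale)
    return best[1], best[2]


def two_prop_chi2_yates(k1, n1, k2, n2) -> float:
    """Two-proportion chi-square with Yates correction, from the formula."""
    from scipy.stats import chi2

    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = table.sum(1)
    col = table.sum(0)
    n = table.sum()
    expected = np.outer(row, col) / n
    stat = np.sum(np.maximum(np.abs(table - expected) - 0.5, 0.0) ** 2 / expected)
    return float(chi2.sf(stat, 1))
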