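"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: the Fisher oracle
enumerates the full hypergeometric support directly, the signed-rank oracle
enumerates all sign assignments, and the expectation oracles use closed
forms.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of the support.

    Minimum-likelihood convention: sum the probabilities of every table
    (with the observed margins) whose probability does not exceed the
    observed table's, with a small relative tolerance for ties.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0  # degenerate table: only one (empty) outcome
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def signed_rank_exact_oracle(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating sign flips.

    Zero differences are dropped (the classic Wilcoxon convention); ranks
    of |d| use midranks for ties.  The p-value is the fraction of the 2^n
    sign assignments whose W+ is at least as extreme as observed, doubled
    and capped at 1.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return min(1.0, count / total)


def hypergeom_mean(total_count: int, clone_count: int, draw: int) -> float:
    """Expected downsampled count of a clone: draw * clone_count / total."""
    return draw * clone_count / total_count


def hypergeom_sd(total_count: int, clone_count: int, draw: int) -> float:
    p = clone_count / total_count
    fpc = (total_count - draw) / (total_count - 1)
    return math.sqrt(draw * p * (1 - p) * fpc)


def shannon_entropy_oracle(counts) -> float:
    """Direct -sum p ln p, independent of scipy."""
    counts = [c for c in counts if c > 0]
    total = sum(counts)
    return -sum((c / total) * math.log(c / total) for c in counts)
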