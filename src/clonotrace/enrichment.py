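"""Differential clone-abundance testing between paired repertoires.

Identifies clones significantly expanded from a reference sample to a
comparison sample (typically unstimulated vs 10-day peptide-stimulated
PBMCs from the same patient, or baseline vs post-treatment).  Both samples
are first downsampled to their common depth; each clone is then tested with
a two-sided Fisher exact test on the 2x2 table

    [reads in clone | reads in all other clones] x [reference | comparison]

with Benjamini-Hochberg adjustment across all clones of the pair.  Depth
matching makes the exact conditional test assumption-free on integer
counts; a negative-binomial exact test reduces toward it as dispersion
goes to zero.

Fold change is log2((alt + 0.5) / (ref + 0.5)); the 0.5 pseudocount keeps
clones absent from one sample finite.  A clone is tiered ``nominal`` when
log2 FC > 5 and unadjusted p < 0.05, and ``significant`` when additionally
the BH-adjusted p < 0.05.  Clones already present in the patient's baseline
sample are removed before calling a clone vaccine-enriched: pre-existing
clones can expand under stimulation without being vaccine-specific.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .repertoire_io import Repertoire
from .repertoire_metrics import common_depth, downsample

__all__ = [
    "Tier",
    "EnrichmentResult",
    "LOG_FC_THRESHOLD",
    "P_THRESHOLD",
    "fisher_p",
    "expansion_test",
    "filter_baseline",
    "vaccine_enriched",
]

#: Volcano-plot calling thresholds: log2 fold change above 5 with
#: unadjusted p < 0.05 (nominal tier); BH-adjusted p < 0.05 on top of that
#: for the significant tier.
LOG_FC_THRESHOLD = 5.0
P_THRESHOLD = 0.05


class Tier(enum.IntEnum):
    NONE = 0
    NOMINAL = 1
    SIGNIFICANT = 2


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-clone output of the paired expansion test."""

    cdr3_aa: str
    count_ref: int
    count_alt: int
    log_fc: float
    p_value: float
    p_adj: float
    tier: Tier


def _log2_fc(count_ref: int, count_alt: int) -> float:
    return float(np.log2((count_alt + 0.5) / (count_ref + 0.5)))


def fisher_p(table) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    ``table`` is a 2x2 array of non-negative integer counts.  This is the
    per-clone test statistic used by :func:`expansion_test`.
    """
    return float(fisher_exact(table, alternative="two-sided")[1])


def expansion_test(
    ref: Repertoire,
    alt: Repertoire,
    seed: int,
    *,
    log_fc_threshold: float = LOG_FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[EnrichmentResult]:
    """Test every clone present in either sample for expansion in ``alt``.

    Both repertoires are downsampled to their common depth (seeded) before
    testing, so the Fisher table margins are identical across clones and
    p-values are comparable.  Results are ordered by descending log2 fold
    change, ties broken lexicographically by CDR3.
    """
    if len(ref) == 0 or len(alt) == 0:
        raise ValueError("expansion_test requires two non-empty repertoires")
    depth = common_depth([ref, alt])
    seeds = np.random.SeedSequence(seed).spawn(2)
    ref_n = downsample(ref, depth, np.random.default_rng(seeds[0]))
    alt_n = downsample(alt, depth, np.random.default_rng(seeds[1]))
    if ref_n.depth != alt_n.depth:
        raise RuntimeError("depth mismatch after normalization")

    keys = sorted(set(ref_n.clones) | set(alt_n.clones))
    # identical margins for every clone => cache p-values on (ref, alt) counts
    cache: dict[tuple[int, int], float] = {}
    p_values = np.empty(len(keys))
    pairs = []
    for i, key in enumerate(keys):
        a, b = ref_n.count(key), alt_n.count(key)
        pairs.append((a, b))
        p = cache.get((a, b))
        if p is None:
            p = fisher_p([[b, depth - b], [a, depth - a]])
            cache[(a, b)] = p
        p_values[i] = p

    p_adj = multipletests(p_values, method="fdr_bh")[1]
    results = []
    for key, (a, b), p, q in zip(keys, pairs, p_values, p_adj):
        log_fc = _log2_fc(a, b)
        tier = Tier.NONE
        if log_fc > log_fc_threshold and p < p_threshold:
            tier = Tier.SIGNIFICANT if q < p_threshold else Tier.NOMINAL
        results.append(
            EnrichmentResult(
                cdr3_aa=key,
                count_ref=a,
                count_alt=b,
                log_fc=log_fc,
                p_value=p,
                p_adj=float(q),
                tier=tier,
            )
        )
    results.sort(key=lambda r: (-r.log_fc, r.cdr3_aa))
    return results


def filter_baseline(
    results: Sequence[EnrichmentResult], baseline: Repertoire
) -> list[EnrichmentResult]:
    """Drop results whose clone already occurs in the baseline sample.

    Any baseline count >= 1 excludes the clone; order is preserved.
    """
    return [r for r in results if r.cdr3_aa not in baseline]


def vaccine_enriched(
    results: Iterable[EnrichmentResult], tier: Tier | str = Tier.NOMINAL
) -> list[str]:
    """Clone keys at or above ``tier``, ordered by descending log2 FC.

    ``results`` should already have passed through :func:`filter_baseline`.
    The significant set is by construction a subset of the nominal set.
    """
    if isinstance(tier, str):
        try:
            tier = Tier[tier.upper()]
        except KeyError:
            raise ValueError(f"unknown tier {tier!r}") from None
    if tier == Tier.NONE:
        raise ValueError("tier must be 'nominal' or 'significant'")
    picked = [r for r in results if r.tier >= tier]
    picked.sort(key=lambda r: (-r.log_fc, r.cdr3_aa))
    return [r.cdr3_aa for r in picked]
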