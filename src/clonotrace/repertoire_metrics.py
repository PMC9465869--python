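"""Depth normalization and repertoire summary statistics.

Cross-sample comparisons of counts are only meaningful at a common
sequencing depth, so every comparative analysis first downsamples each
repertoire to the minimum depth of the compared set (sampling reads without
replacement — a multivariate hypergeometric draw — so counts stay integral
and no clone is ever inflated).

Summary statistics follow the standard immunosequencing definitions:
richness R (unique clones), Shannon entropy H = -sum p_i ln p_i in nats,
and clonality 1 - H/ln(R), which is 0 for a perfectly even repertoire and
1 for a monoclonal one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import entropy as _shannon

from .repertoire_io import Repertoire

__all__ = [
    "MetricsReport",
    "downsample",
    "common_depth",
    "shannon_entropy",
    "clonality",
    "diversity",
    "overlap",
    "OverlapResult",
    "repertoire_fraction",
]


@dataclass(frozen=True)
class MetricsReport:
    richness: int
    shannon_entropy: float
    clonality: float
    depth_used: int


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def downsample(rep: Repertoire, target_depth: int, seed: int | np.random.Generator) -> Repertoire:
    """Subsample a repertoire to ``target_depth`` reads without replacement.

    Draws the retained reads from the multiset of the repertoire's reads
    (multivariate hypergeometric), so the output depth equals
    ``target_depth`` exactly, no clone's count increases, and clones
    reduced to zero disappear.  Deterministic for a given seed.
    """
    depth = rep.depth
    if target_depth < 1:
        raise ValueError(f"target_depth must be >= 1, got {target_depth}")
    if target_depth > depth:
        raise ValueError(
            f"target_depth {target_depth} exceeds repertoire depth {depth}; "
            "downsample to the minimum depth of the compared set"
        )
    keys = sorted(rep.clones)  # canonical order so the draw is seed-stable
    counts = np.array([rep.clones[k].count for k in keys], dtype=np.int64)
    if target_depth == depth:
        return rep.with_counts(dict(zip(keys, counts)))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(counts, target_depth)
    return rep.with_counts({k: int(c) for k, c in zip(keys, new_counts)})


def common_depth(reps: Iterable[Repertoire]) -> int:
    """Minimum depth across a non-empty set of repertoires."""
    depths = [rep.depth for rep in reps]
    if not depths:
        raise ValueError("common_depth requires at least one repertoire")
    return min(depths)


def _counts(rep: Repertoire) -> np.ndarray:
    return np.array([c.count for c in rep.clones.values()], dtype=np.float64)


def shannon_entropy(rep: Repertoire) -> float:
    """Shannon entropy of clone frequencies, in nats."""
    if len(rep) == 0:
        raise ValueError("entropy undefined for an empty repertoire")
    return float(_shannon(_counts(rep)))


def clonality(rep: Repertoire) -> float:
    """1 - H/ln(R): 0 = perfectly even, 1 = monoclonal.

    A single-clone repertoire (R = 1, where H/ln R is 0/0) is defined as
    clonality 1 by convention.
    """
    if len(rep) == 0:
        raise ValueError("clonality undefined for an empty repertoire")
    r = len(rep)
    if r == 1:
        return 1.0
    value = 1.0 - shannon_entropy(rep) / np.log(r)
    # guard tiny negative round-off for perfectly even repertoires
    return float(min(1.0, max(0.0, value)))


def diversity(rep: Repertoire) -> MetricsReport:
    """Richness (primary diversity readout), entropy and clonality.

    Meaningful across samples only after downsampling to a shared depth;
    the depth actually used is recorded in the report.
    """
    if len(rep) == 0:
        raise ValueError("diversity undefined for an empty repertoire")
    return MetricsReport(
        richness=len(rep),
        shannon_entropy=shannon_entropy(rep),
        clonality=clonality(rep),
        depth_used=rep.depth,
    )


def overlap(rep_a: Repertoire, rep_b: Repertoire) -> OverlapResult:
    """Partition the union of clone keys into shared / unique-to-a / unique-to-b."""
    if len(rep_a) == 0 or len(rep_b) == 0:
        raise ValueError("overlap requires two non-empty repertoires")
    a, b = set(rep_a.clones), set(rep_b.clones)
    return OverlapResult(
        shared=frozenset(a & b),
        unique_a=frozenset(a - b),
        unique_b=frozenset(b - a),
    )


def repertoire_fraction(clone_keys: Iterable[str], rep: Repertoire) -> float:
    """Summed read count of ``clone_keys`` divided by the sample's total depth.

    Keys absent from the repertoire contribute zero.  For cross-sample
    comparison, ``rep`` should already be depth-normalized.
    """
    depth = rep.depth
    if depth == 0:
        raise ValueError("repertoire_fraction undefined for an empty repertoire")
    total = sum(rep.count(k) for k in set(clone_keys))
    return total / depth
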