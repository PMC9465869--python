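"""Longitudinal tracking of nominated clonotypes across blood and tumor.

Once a set of clones has been nominated (e.g. vaccine-enriched after in
vitro stimulation, or unique to a post-treatment biopsy), these operations
follow them through a patient's later unstimulated PBMC samples and tumor
biopsies: per-sample counts and repertoire fractions, detection in tumor,
persistence of shared intratumoral clones, and blood detection of clones
unique to the post-treatment biopsy.

All fractions are computed after depth-matching the samples within each
compartment (seeded downsampling to the compartment's minimum depth), so
"detected" (count >= 1) and fraction values are comparable across
timepoints.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .enrichment import EnrichmentResult
from .repertoire_io import Compartment, Repertoire, SampleMeta
from .repertoire_metrics import common_depth, downsample, repertoire_fraction

__all__ = [
    "TraceEntry",
    "TrackedClone",
    "PersistenceResult",
    "timepoint_sort_key",
    "depth_match_by_compartment",
    "track_clones",
    "persisting_abundance",
    "post_unique_in_blood",
]

_WEEK_RE = re.compile(r"(?:week|wk|w)\s*(\d+)", re.IGNORECASE)


def timepoint_sort_key(timepoint: str) -> tuple[int, float, str]:
    """Canonical ordering of timepoint labels: baseline, then weekN by N."""
    label = timepoint.strip().lower()
    if label in {"baseline", "screening", "pre", "pretreatment", "pre-treatment"}:
        return (0, 0.0, label)
    m = _WEEK_RE.fullmatch(label)
    if m:
        return (1, float(m.group(1)), label)
    return (2, 0.0, label)


def _sample_sort_key(meta: SampleMeta) -> tuple:
    return (meta.compartment.value,) + timepoint_sort_key(meta.timepoint) + (
        meta.stimulation.value,
    )


@dataclass(frozen=True)
class TraceEntry:
    meta: SampleMeta
    count: int
    fraction: float


@dataclass
class TrackedClone:
    """A nominated clonotype's presence across one patient's samples."""

    cdr3_aa: str
    origin: str
    trace: list[TraceEntry] = field(default_factory=list)
    detected_in_tumor: bool = False
    rank: int | None = None
    log_fc: float | None = None


def _check_single_patient(samples: Sequence[Repertoire]) -> str:
    patients = {rep.meta.patient_id for rep in samples}
    if len(patients) != 1:
        raise ValueError(f"samples span multiple patients: {sorted(patients)}")
    return patients.pop()


def depth_match_by_compartment(
    samples: Sequence[Repertoire], seed: int
) -> list[Repertoire]:
    """Downsample each sample to its compartment's minimum depth (seeded).

    Samples are first put in canonical order (compartment, then timepoint,
    then stimulation) so the result does not depend on input order.
    """
    ordered = sorted(samples, key=lambda rep: _sample_sort_key(rep.meta))
    by_comp: dict[Compartment, list[Repertoire]] = {}
    for rep in ordered:
        by_comp.setdefault(rep.meta.compartment, []).append(rep)
    seeds = iter(np.random.SeedSequence(seed).spawn(len(ordered)))
    matched = []
    for comp in sorted(by_comp, key=lambda c: c.value):
        depth = common_depth(by_comp[comp])
        for rep in by_comp[comp]:
            matched.append(downsample(rep, depth, np.random.default_rng(next(seeds))))
    matched.sort(key=lambda rep: _sample_sort_key(rep.meta))
    return matched


def track_clones(
    clone_keys: Iterable[str],
    samples: Sequence[Repertoire],
    seed: int,
    *,
    enrichment: Sequence[EnrichmentResult] | None = None,
    origin: str = "",
) -> list[TrackedClone]:
    """Trace each clone key through all of one patient's samples.

    Returns one :class:`TrackedClone` per key with per-sample count and
    repertoire fraction (after per-compartment depth matching) and a
    ``detected_in_tumor`` flag (count >= 1 in any tumor sample).  When the
    nominating ``enrichment`` results are supplied, clones are ranked by
    their log2 fold change (rank 1 = largest), the ordering used to label
    tracked clones.
    """
    if not samples:
        raise ValueError("track_clones requires at least one sample")
    _check_single_patient(samples)
    matched = depth_match_by_compartment(samples, seed)

    log_fc_by_key: dict[str, float] = {}
    if enrichment is not None:
        log_fc_by_key = {r.cdr3_aa: r.log_fc for r in enrichment}

    keys = sorted(set(clone_keys))
    # rank by descending nominating log FC when known, else alphabetical
    keys.sort(key=lambda k: (-log_fc_by_key.get(k, -np.inf), k))
    tracked = []
    for rank, key in enumerate(keys, start=1):
        trace = []
        in_tumor = False
        for rep in matched:
            count = rep.count(key)
            trace.append(
                TraceEntry(
                    meta=rep.meta,
                    count=count,
                    fraction=repertoire_fraction([key], rep),
                )
            )
            if count >= 1 and rep.meta.compartment == Compartment.TUMOR:
                in_tumor = True
        tracked.append(
            TrackedClone(
                cdr3_aa=key,
                origin=origin,
                trace=trace,
                detected_in_tumor=in_tumor,
                rank=rank if log_fc_by_key else None,
                log_fc=log_fc_by_key.get(key),
            )
        )
    return tracked


@dataclass
class PersistenceResult:
    """Paired abundances of clones shared by two tumor biopsies."""

    table: pd.DataFrame  # columns: cdr3_aa, count_baseline, count_post
    statistic: float | None
    p_value: float | None
    tested: bool
    reason: str = ""


def persisting_abundance(
    baseline_tumor: Repertoire, post_tumor: Repertoire, seed: int
) -> PersistenceResult:
    """Compare normalized read counts of persisting intratumoral clones.

    Restricts to clones shared by the baseline and post-treatment biopsies
    after depth matching and runs a paired two-sided Wilcoxon signed-rank
    test on the normalized counts (exact null for <= 25 shared clones).
    With fewer than two shared clones the test is skipped; when every
    paired difference is zero the test is degenerate and p is reported
    as 1.
    """
    _check_single_patient([baseline_tumor, post_tumor])
    depth = common_depth([baseline_tumor, post_tumor])
    seeds = np.random.SeedSequence(seed).spawn(2)
    base = downsample(baseline_tumor, depth, np.random.default_rng(seeds[0]))
    post = downsample(post_tumor, depth, np.random.default_rng(seeds[1]))

    shared = sorted(set(base.clones) & set(post.clones))
    table = pd.DataFrame(
        {
            "cdr3_aa": shared,
            "count_baseline": [base.count(k) for k in shared],
            "count_post": [post.count(k) for k in shared],
        }
    )
    if len(shared) < 2:
        return PersistenceResult(
            table=table, statistic=None, p_value=None, tested=False,
            reason="fewer than 2 shared clones",
        )
    diffs = table["count_post"].to_numpy() - table["count_baseline"].to_numpy()
    if np.all(diffs == 0):
        return PersistenceResult(
            table=table, statistic=0.0, p_value=1.0, tested=False,
            reason="all paired differences zero",
        )
    method = "exact" if len(shared) <= 25 else "auto"
    stat, p = wilcoxon(
        table["count_post"], table["count_baseline"],
        alternative="two-sided", method=method,
    )
    return PersistenceResult(
        table=table, statistic=float(stat), p_value=float(p), tested=True
    )


def post_unique_in_blood(
    baseline_tumor: Repertoire,
    post_tumor: Repertoire,
    pbmc_series: Sequence[Repertoire],
    seed: int,
) -> pd.DataFrame:
    """Detect clones unique to the post-treatment biopsy in serial blood.

    The key set is the clones present in the post-treatment biopsy but not
    the baseline biopsy.  For each PBMC sample (depth-matched across the
    series), reports how many of these keys are detected (count >= 1) and
    their summed repertoire fraction.
    """
    if len(post_tumor) == 0:
        raise ValueError("post-treatment tumor repertoire is empty")
    _check_single_patient([baseline_tumor, post_tumor, *pbmc_series])
    key_set = set(post_tumor.clones) - set(baseline_tumor.clones)
    matched = depth_match_by_compartment(pbmc_series, seed) if pbmc_series else []
    rows = []
    for rep in matched:
        detected = sum(1 for k in key_set if rep.count(k) >= 1)
        rows.append(
            {
                "patient_id": rep.meta.patient_id,
                "timepoint": rep.meta.timepoint,
                "depth_used": rep.depth,
                "n_detected": detected,
                "repertoire_fraction": repertoire_fraction(key_set, rep)
                if len(rep) else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "timepoint", "depth_used", "n_detected",
            "repertoire_fraction",
        ],
    )
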