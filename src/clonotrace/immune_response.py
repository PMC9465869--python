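"""Stimulation-index computation and per-patient immune-response calling.

Vaccine-specific T-cell responses are measured with a proliferation assay:
PBMCs pre-stimulated in vitro with vaccine peptides are re-stimulated with
or without peptide and proliferation is read out in triplicate (counts per
minute of 3H-thymidine incorporation).  The stimulation index (SI) is the
mean count of the peptide-stimulated wells divided by the mean count of the
unstimulated wells.  A sample is response-positive when the SI reaches 3
(threshold inclusive) for any single peptide or the peptide mixture; a
patient is a responder when any post-baseline sample within the evaluation
window is positive.  Patients with no evaluable post-baseline assay are
non-evaluable, distinct from non-responders, and are excluded from cohort
response-rate denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Iterable, Sequence

__all__ = [
    "PEPTIDES",
    "SI_THRESHOLD",
    "BASELINE_LABELS",
    "ProliferationAssay",
    "ImmuneResponseCall",
    "CohortSummary",
    "stimulation_index",
    "call_response",
    "cohort_summary",
    "objective_response_rate",
]

#: The three telomerase-derived vaccine peptides and their mixture.
PEPTIDES = ("p719-20", "p725", "p728", "mix")

#: Positivity threshold on the stimulation index (inclusive).
SI_THRESHOLD = 3.0

BASELINE_LABELS = frozenset({"baseline", "screening", "pre", "pretreatment"})


@dataclass(frozen=True)
class ProliferationAssay:
    """Triplicate proliferation counts for one peptide at one timepoint."""

    patient_id: str
    timepoint: str
    peptide: str
    stimulated_counts: tuple[float, ...]
    unstimulated_counts: tuple[float, ...]
    positive_control_counts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.peptide not in PEPTIDES:
            raise ValueError(f"unknown peptide {self.peptide!r}; expected {PEPTIDES}")
        for name in ("stimulated_counts", "unstimulated_counts"):
            counts = getattr(self, name)
            if len(counts) < 3:
                raise ValueError(f"{name} needs >= 3 replicates, got {len(counts)}")
            if any(c < 0 for c in counts):
                raise ValueError(f"{name} contains a negative count")


@dataclass
class ImmuneResponseCall:
    patient_id: str
    evaluable: bool
    responder: bool | None  # None when not evaluable
    max_si: float | None
    per_peptide_si: dict[str, float] = field(default_factory=dict)


def stimulation_index(assay: ProliferationAssay) -> float:
    """mean(stimulated) / mean(unstimulated); invalid if the latter is zero."""
    unstim_mean = sum(assay.unstimulated_counts) / len(assay.unstimulated_counts)
    if unstim_mean <= 0:
        raise ValueError(
            f"{assay.patient_id}/{assay.timepoint}/{assay.peptide}: "
            "zero mean unstimulated count; sample invalid"
        )
    stim_mean = sum(assay.stimulated_counts) / len(assay.stimulated_counts)
    return stim_mean / unstim_mean


def _default_window(timepoint: str) -> bool:
    return timepoint.strip().lower() not in BASELINE_LABELS


def call_response(
    assays: Sequence[ProliferationAssay],
    threshold: float = SI_THRESHOLD,
    window: Callable[[str], bool] | Iterable[str] | None = None,
) -> ImmuneResponseCall:
    """Call one patient responder / non-responder / non-evaluable.

    ``window`` restricts which post-baseline timepoints count toward the
    call (the evaluation window: samples up to 16 weeks after the last
    vaccination); it may be a predicate on the timepoint label or an
    explicit collection of labels.  Baseline samples never count.  The
    patient is a responder iff any in-window assay has SI >= threshold;
    ``max_si`` is the maximum in-window SI.  With no in-window assay the
    patient is non-evaluable (``responder`` is None).
    """
    if not assays:
        raise ValueError("call_response requires at least one assay")
    patients = {a.patient_id for a in assays}
    if len(patients) != 1:
        raise ValueError(f"assays span multiple patients: {sorted(patients)}")
    patient = patients.pop()

    if window is None:
        in_window = _default_window
    elif callable(window):
        in_window = window
    else:
        allowed = {str(t) for t in window}
        in_window = lambda tp: tp in allowed  # noqa: E731

    per_peptide: dict[str, float] = {}
    max_si: float | None = None
    for assay in assays:
        if not _default_window(assay.timepoint) or not in_window(assay.timepoint):
            continue
        si = stimulation_index(assay)
        if si > per_peptide.get(assay.peptide, float("-inf")):
            per_peptide[assay.peptide] = si
        if max_si is None or si > max_si:
            max_si = si

    if max_si is None:
        return ImmuneResponseCall(
            patient_id=patient, evaluable=False, responder=None, max_si=None
        )
    return ImmuneResponseCall(
        patient_id=patient,
        evaluable=True,
        responder=max_si >= threshold,
        max_si=max_si,
        per_peptide_si=per_peptide,
    )


@dataclass(frozen=True)
class CohortSummary:
    n_evaluable: int
    n_responders: int
    response_rate_pct: int  # responders / evaluable, rounded to nearest %
    median_max_si: float
    si_range: tuple[float, float]


def cohort_summary(calls: Iterable[ImmuneResponseCall]) -> CohortSummary:
    """Responder fraction and max-SI summary over the evaluable patients."""
    evaluable = [c for c in calls if c.evaluable]
    if not evaluable:
        raise ValueError("cohort_summary requires at least one evaluable call")
    n_resp = sum(1 for c in evaluable if c.responder)
    sis = sorted(c.max_si for c in evaluable)
    return CohortSummary(
        n_evaluable=len(evaluable),
        n_responders=n_resp,
        response_rate_pct=round(100 * n_resp / len(evaluable)),
        median_max_si=float(median(sis)),
        si_range=(sis[0], sis[-1]),
    )


def objective_response_rate(best_responses: Iterable[str]) -> int:
    """Percent of patients with an objective response (CR or PR), rounded.

    ``best_responses`` holds one RECIST best-overall-response label per
    enrolled patient (CR, PR, SD, PD, NE); the denominator is all of them.
    """
    labels = [str(r).strip().upper() for r in best_responses]
    if not labels:
        raise ValueError("objective_response_rate requires at least one patient")
    responders = sum(1 for r in labels if r in {"CR", "PR"})
    return round(100 * responders / len(labels))
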