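"""Reading, writing and QC of bulk TRB repertoire tables.

A *clone* (clonotype) is the set of all receptor reads sharing one CDR3
amino-acid sequence; V/J gene calls are carried as annotation only and play
no role in clone identity.  On disk, repertoires are AIRR-style rearrangement
TSVs (default columns ``junction_aa``, ``v_call``, ``j_call``,
``duplicate_count``); sample manifests are CSVs mapping each file to its
patient, timepoint, compartment and stimulation status.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "CloneRecord",
    "Compartment",
    "Stimulation",
    "SampleMeta",
    "Repertoire",
    "SkipLog",
    "collapse_clones",
    "read_repertoire",
    "write_repertoire",
    "read_manifest",
    "qc_extraction",
]

#: The 20 standard amino acids plus '*' (stop codon, marking a
#: non-productive rearrangement).  Ambiguity codes (B, J, O, U, X, Z) are
#: excluded: a clone whose CDR3 contains an ambiguous residue cannot be
#: matched reliably across samples.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")

DEFAULT_COLUMNS = {
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "count": "duplicate_count",
}


class Compartment(str, enum.Enum):
    PBMC = "PBMC"
    TUMOR = "tumor"


class Stimulation(str, enum.Enum):
    UNSTIMULATED = "unstimulated"
    STIMULATED = "stimulated"


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype in one sample: CDR3 amino-acid key plus read count."""

    cdr3_aa: str
    count: int
    v_gene: str = ""
    j_gene: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"cdr3_aa {self.cdr3_aa!r} contains invalid residues {sorted(bad)}"
            )
        if self.count < 1:
            raise ValueError(f"clone count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced sample within a patient's longitudinal set."""

    patient_id: str
    timepoint: str
    compartment: Compartment = Compartment.PBMC
    stimulation: Stimulation = Stimulation.UNSTIMULATED

    def key(self) -> tuple[str, str, str, str]:
        return (
            self.patient_id,
            self.timepoint,
            self.compartment.value,
            self.stimulation.value,
        )


@dataclass(frozen=True)
class SkipLog:
    """Rows dropped while reading a repertoire table, by reason."""

    empty_cdr3: int = 0
    nonpositive_count: int = 0
    invalid_residues: int = 0
    stop_codon: int = 0

    @property
    def total(self) -> int:
        return (
            self.empty_cdr3
            + self.nonpositive_count
            + self.invalid_residues
            + self.stop_codon
        )


@dataclass
class Repertoire:
    """A sample's clones keyed by CDR3 amino-acid sequence.

    ``depth`` is always the exact sum of clone counts.  ``extraction_fraction``
    is the fraction of raw reads from which a receptor was successfully
    extracted (a library-QC readout, optional).
    """

    meta: SampleMeta
    clones: dict[str, CloneRecord] = field(default_factory=dict)
    extraction_fraction: float | None = None
    skip_log: SkipLog = field(default_factory=SkipLog)

    def __post_init__(self) -> None:
        for key, clone in self.clones.items():
            if key != clone.cdr3_aa:
                raise ValueError(f"clone key {key!r} != record cdr3 {clone.cdr3_aa!r}")

    @property
    def depth(self) -> int:
        return sum(c.count for c in self.clones.values())

    @property
    def richness(self) -> int:
        return len(self.clones)

    def count(self, cdr3_aa: str) -> int:
        clone = self.clones.get(cdr3_aa)
        return clone.count if clone is not None else 0

    def __len__(self) -> int:
        return len(self.clones)

    def __contains__(self, cdr3_aa: str) -> bool:
        return cdr3_aa in self.clones

    def with_counts(self, counts: Mapping[str, int]) -> "Repertoire":
        """A copy holding ``counts`` (zero-count clones dropped), same meta."""
        clones = {
            k: replace(self.clones[k], count=int(v)) if k in self.clones
            else CloneRecord(cdr3_aa=k, count=int(v))
            for k, v in counts.items()
            if v > 0
        }
        return Repertoire(
            meta=self.meta,
            clones=clones,
            extraction_fraction=self.extraction_fraction,
        )


def collapse_clones(
    rows: Iterable[tuple[str, str, str, int]],
    *,
    drop_nonproductive: bool = False,
) -> tuple[dict[str, CloneRecord], SkipLog]:
    """Sum rows sharing a CDR3 amino-acid sequence into single clones.

    Rows with an empty CDR3, a non-positive count, or residues outside the
    amino-acid alphabet are skipped and tallied.  When V (or J) calls of
    merged rows disagree, the annotation is blanked — clone identity never
    depends on it.
    """
    clones: dict[str, dict] = {}
    skipped = {"empty_cdr3": 0, "nonpositive_count": 0, "invalid_residues": 0,
               "stop_codon": 0}
    for cdr3, v_gene, j_gene, count in rows:
        if not cdr3:
            skipped["empty_cdr3"] += 1
            continue
        if count <= 0:
            skipped["nonpositive_count"] += 1
            continue
        if set(cdr3) - AA_ALPHABET:
            skipped["invalid_residues"] += 1
            continue
        if drop_nonproductive and "*" in cdr3:
            skipped["stop_codon"] += 1
            continue
        entry = clones.get(cdr3)
        if entry is None:
            clones[cdr3] = {"v": v_gene, "j": j_gene, "count": int(count)}
        else:
            entry["count"] += int(count)
            if entry["v"] != v_gene:
                entry["v"] = ""
            if entry["j"] != j_gene:
                entry["j"] = ""
    records = {
        cdr3: CloneRecord(cdr3_aa=cdr3, count=e["count"], v_gene=e["v"], j_gene=e["j"])
        for cdr3, e in clones.items()
    }
    return records, SkipLog(**skipped)


def read_repertoire(
    path: str | Path,
    meta: SampleMeta,
    *,
    columns: Mapping[str, str] | None = None,
    drop_nonproductive: bool = False,
    extraction_fraction: float | None = None,
) -> Repertoire:
    """Read an AIRR-style TSV and collapse receptor rows into clones.

    Parameters
    ----------
    columns
        Mapping from the logical names ``cdr3_aa``/``v_gene``/``j_gene``/
        ``count`` to the file's column names; defaults follow AIRR
        (``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count``).
        V/J columns are optional in the file.
    drop_nonproductive
        Drop CDR3s containing a stop codon ('*').  Off by default: the
        upstream platform's productivity call is not re-derived here.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read repertoire file {path}: {exc}") from exc
    for logical in ("cdr3_aa", "count"):
        if colmap[logical] not in df.columns:
            raise ValueError(
                f"{path}: missing required column {colmap[logical]!r} ({logical})"
            )
    has_v = colmap["v_gene"] in df.columns
    has_j = colmap["j_gene"] in df.columns

    def _rows():
        for _, row in df.iterrows():
            raw = row[colmap["count"]].strip()
            try:
                count = int(float(raw)) if raw else 0
            except ValueError:
                count = 0
            yield (
                row[colmap["cdr3_aa"]].strip(),
                row[colmap["v_gene"]].strip() if has_v else "",
                row[colmap["j_gene"]].strip() if has_j else "",
                count,
            )

    clones, skip_log = collapse_clones(_rows(), drop_nonproductive=drop_nonproductive)
    return Repertoire(
        meta=meta,
        clones=clones,
        extraction_fraction=extraction_fraction,
        skip_log=skip_log,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write one clone per row as AIRR-style TSV.

    Row order is deterministic: descending count, ties broken
    lexicographically by CDR3.
    """
    ordered = sorted(rep.clones.values(), key=lambda c: (-c.count, c.cdr3_aa))
    df = pd.DataFrame(
        {
            "junction_aa": [c.cdr3_aa for c in ordered],
            "v_call": [c.v_gene for c in ordered],
            "j_call": [c.j_gene for c in ordered],
            "duplicate_count": [c.count for c in ordered],
        }
    )
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write repertoire file {path}: {exc}") from exc


MANIFEST_COLUMNS = ("patient_id", "timepoint", "compartment", "stimulation", "path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest CSV and validate uniqueness of sample keys."""
    df = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    keys = df[list(MANIFEST_COLUMNS[:4])]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].to_dict("records")
        raise ValueError(f"manifest {path}: duplicate sample keys {dupes}")
    return df


def meta_from_row(row: Mapping[str, str]) -> SampleMeta:
    return SampleMeta(
        patient_id=str(row["patient_id"]),
        timepoint=str(row["timepoint"]),
        compartment=Compartment(str(row["compartment"])),
        stimulation=Stimulation(str(row["stimulation"])),
    )


def qc_extraction(extraction_fraction: float, threshold: float = 0.95) -> str:
    """Flag a sample's receptor-extraction fraction: ``"pass"`` or ``"warn"``.

    The flag never excludes a sample — low-extraction libraries are analyzed
    with a warning attached.  Strict inequality: a fraction exactly at the
    threshold warns.
    """
    if not 0.0 <= extraction_fraction <= 1.0:
        raise ValueError(
            f"extraction fraction must be in [0, 1], got {extraction_fraction}"
        )
    return "pass" if extraction_fraction > threshold else "warn"
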