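import hypothesis
import pytest

from clonotrace.repertoire_io import (
    CloneRecord,
    Compartment,
    Repertoire,
    SampleMeta,
    Stimulation,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_repertoire(
    counts: dict[str, int],
    patient: str = "N01",
    timepoint: str = "baseline",
    compartment: Compartment = Compartment.PBMC,
    stimulation: Stimulation = Stimulation.UNSTIMULATED,
) -> Repertoire:
    meta = SampleMeta(patient, timepoint, compartment, stimulation)
    clones = {k: CloneRecord(cdr3_aa=k, count=v) for k, v in counts.items()}
    return Repertoire(meta=meta, clones=clones)


@pytest.fixture
def tiny_rep() -> Repertoire:
    return make_repertoire({"CASSA": 3, "CASSN": 1})


@pytest.fixture
def even_rep() -> Repertoire:
    return make_repertoire({f"CASS{aa}F": 10 for aa in "ACDEFGHIKL"})
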