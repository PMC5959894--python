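from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from somnotype.emr_model import (
    CodedEvent,
    Note,
    PatientRecord,
    Prescription,
    default_vocabulary,
    load_model,
)
from somnotype.synthetic_emr import SimulationConfig, simulate_corpus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

PAD = "Routine visit note body. " * 24  # ~600 chars of neutral filler


def make_note(note_id: str, text: str, pad: bool = True,
              when: date = date(2005, 6, 1)) -> Note:
    """A note padded past the 500-character inclusion filter unless asked
    otherwise; the padding contains no vocabulary expressions."""
    return Note(note_id=note_id, date=when, text=(PAD + text) if pad else text)


def make_patient(patient_id: str = "p1",
                 birth: date = date(1950, 1, 1),
                 codes: list[tuple[str, date]] = (),
                 meds: list[tuple[str, date]] = (),
                 notes: list[Note] = (),
                 death: date | None = None) -> PatientRecord:
    return PatientRecord(
        patient_id=patient_id,
        birth_date=birth,
        death_date=death,
        coded_events=tuple(CodedEvent(code=c, date=d) for c, d in codes),
        prescriptions=tuple(Prescription(medication_name=m, date=d)
                            for m, d in meds),
        notes=tuple(notes),
    )


@pytest.fixture(scope="session")
def published_model():
    return load_model("published")


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def corpus_1k():
    """A 1,000-patient seeded synthetic corpus shared across tests."""
    return simulate_corpus(SimulationConfig(n_patients=1000, seed=7))
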