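"""Candidate-cohort inclusion filters and the empirical case definition.

The candidate datamart is a deliberately over-inclusive intermediate
cohort: any patient with an insomnia billing code, an insomnia-only
medication, or a note merely *mentioning* a sleep keyword is pulled in,
provided their record is substantial enough (at least two notes of 500+
characters).  Keyword inclusion fires on benign text such as
"patient sleeps well" — that is by design; separating true cases from such
patients is the classifier's job downstream.

The empirical case definition automates the chart-review rules used to
produce reference labels: a billing code for insomnia, a prescription for a
medication indicated only for insomnia, or a note containing a
sleep-disorder expression, any one of which suffices.  It is an automated
approximation of manual review and serves as the ground-truth labeler for
synthetic corpora.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

from .emr_model import PatientRecord, VocabularyConfig
from .features import (
    count_codes,
    count_indicator_notes,
    count_prescriptions,
    normalize_text,
)

__all__ = [
    "MartDecision",
    "in_candidate_mart",
    "empirical_case_rules",
    "apply_age_exclusion",
    "DEFAULT_STUDY_END",
]

# End of the emulated study window ("between 1992 and 2010").
DEFAULT_STUDY_END = date(2010, 12, 31)


@dataclass(frozen=True)
class MartDecision:
    """Inclusion decision with reason codes stating which screening
    disjunct(s) fired and whether the note-volume requirement passed."""

    included: bool
    reasons: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.included


def in_candidate_mart(patient: PatientRecord,
                      vocab: VocabularyConfig) -> MartDecision:
    """Screen one patient for candidate-datamart inclusion.

    Included iff (insomnia billing code OR insomnia medication OR any note
    containing a candidate keyword) AND at least ``min_qualifying_notes``
    notes of ``min_note_chars``+ characters.
    """
    reasons: list[str] = []
    if count_codes(patient, vocab.insomnia_codes) > 0:
        reasons.append("insomnia_code")
    if count_prescriptions(patient, vocab.insomnia_medications) > 0:
        reasons.append("insomnia_medication")
    keywords = [normalize_text(k) for k in vocab.candidate_keywords]
    if any(any(k in normalize_text(n.text) for k in keywords)
           for n in patient.notes):
        reasons.append("keyword_note")
    screening = bool(reasons)

    n_long = sum(1 for n in patient.notes
                 if len(n.text) >= vocab.min_note_chars)
    if n_long >= vocab.min_qualifying_notes:
        reasons.append("note_volume_ok")
        note_volume = True
    else:
        reasons.append("note_volume_failed")
        note_volume = False

    return MartDecision(included=screening and note_volume,
                        reasons=tuple(reasons))


def empirical_case_rules(patient: PatientRecord,
                         vocab: VocabularyConfig) -> str:
    """Automated empirical case definition: ``"insomnia"`` iff the patient
    has an insomnia billing code, an insomnia-only prescription, or a note
    containing a sleep-disorder expression; else ``"no_insomnia"``."""
    if count_codes(patient, vocab.insomnia_codes) > 0:
        return "insomnia"
    if count_prescriptions(patient, vocab.insomnia_medications) > 0:
        return "insomnia"
    if count_indicator_notes(patient, vocab.sleep_expressions,
                             vocab.min_note_chars) > 0:
        return "insomnia"
    return "no_insomnia"


def _age_in_years(birth: date, at: date) -> int:
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years


def apply_age_exclusion(patients: Sequence[PatientRecord],
                        labels: Mapping[str, str],
                        study_end: date = DEFAULT_STUDY_END,
                        min_age: int = 18
                        ) -> tuple[list[PatientRecord], dict[str, str]]:
    """Drop patients younger than ``min_age`` at death or study end.

    Age is evaluated at the earlier of death date and ``study_end`` using
    exact calendar arithmetic; a patient whose death falls exactly on the
    18th birthday is retained (the boundary is age >= 18).  Labels without
    a matching patient pass through untouched; only labels of excluded
    patients are dropped.
    """
    kept: list[PatientRecord] = []
    excluded_ids: set[str] = set()
    for p in patients:
        if p.birth_date is None:  # defensive; the type requires a birth date
            warnings.warn(f"patient {p.patient_id}: missing birth_date, "
                          f"excluded from the age-filtered sample")
            excluded_ids.add(p.patient_id)
            continue
        asof = min(p.death_date, study_end) if p.death_date else study_end
        if _age_in_years(p.birth_date, asof) >= min_age:
            kept.append(p)
        else:
            excluded_ids.add(p.patient_id)
    new_labels = {pid: status for pid, status in labels.items()
                  if pid not in excluded_ids}
    return kept, new_labels
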