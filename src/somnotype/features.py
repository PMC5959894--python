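"""Rule-based covariate extraction from structured events and note text.

The scoring model's two text covariates count *notes* containing at least
one vocabulary expression, not individual mentions; a note packed with
matches still counts once.  Matching is deliberately literal: lowercase the
text, collapse runs of whitespace to single spaces, then substring-search
each expression.  The expression lists were curated to be non-negated
descriptors of the condition, so no negation-scope detection is applied
("patient sleeps well" contains the word "sleep" but none of the disorder
expressions, and therefore never contributes to the sleep-note count).

The 500-character minimum note length used for cohort inclusion is also
applied to text-covariate counting (one ``min_note_chars`` knob, settable
to 0 to count every note).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .emr_model import (
    FeatureVector,
    PatientRecord,
    VocabularyConfig,
    code_in_set,
)

__all__ = [
    "NoteIndicator",
    "normalize_text",
    "match_expressions",
    "count_indicator_notes",
    "count_codes",
    "count_prescriptions",
    "count_emr_facts",
    "extract_features",
    "extract_corpus_features",
    "note_indicators",
]

_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase and collapse all whitespace runs to single spaces."""
    return _WS_RE.sub(" ", text).lower()


@dataclass(frozen=True)
class NoteIndicator:
    """Expression matches found in one note: (vocabulary name, expression,
    character offset into the normalized note text)."""

    note_id: str
    matched_expressions: tuple[tuple[str, str, int], ...]


def match_expressions(text: str,
                      expressions: Sequence[str]) -> list[tuple[str, int]]:
    """Find every occurrence of every expression in the text.

    Case-insensitive substring search on whitespace-normalized text; each
    returned offset is the start of a verbatim match in the *normalized*
    text.  Overlapping matches of distinct expressions are all returned.
    Results are ordered by offset, then by expression-list position.
    """
    if not expressions:
        raise ValueError("expressions must be non-empty")
    norm = normalize_text(text)
    hits: list[tuple[int, int, str]] = []
    for rank, expr in enumerate(expressions):
        needle = normalize_text(expr)
        if not needle:
            continue
        start = 0
        while True:
            off = norm.find(needle, start)
            if off < 0:
                break
            hits.append((off, rank, expr))
            start = off + 1
    hits.sort()
    return [(expr, off) for off, _rank, expr in hits]


def note_indicators(patient: PatientRecord, vocab: VocabularyConfig
                    ) -> list[NoteIndicator]:
    """Per-note expression matches against both expression vocabularies,
    for audit/debugging of the extraction rules."""
    out = []
    for note in patient.notes:
        matched: list[tuple[str, str, int]] = []
        for vocab_name, exprs in (("sleep_expressions", vocab.sleep_expressions),
                                  ("psych_expressions", vocab.psych_expressions)):
            for expr, off in match_expressions(note.text, exprs):
                matched.append((vocab_name, expr, off))
        if matched:
            out.append(NoteIndicator(note_id=note.note_id,
                                     matched_expressions=tuple(matched)))
    return out


def count_indicator_notes(patient: PatientRecord,
                          expressions: Sequence[str],
                          min_chars: int = 500) -> int:
    """Number of distinct notes of length >= ``min_chars`` containing at
    least one expression match (note-level counting)."""
    if min_chars < 0:
        raise ValueError("min_chars must be >= 0")
    n = 0
    for note in patient.notes:
        if len(note.text) < min_chars:
            continue
        if match_expressions(note.text, expressions):
            n += 1
    return n


def count_codes(patient: PatientRecord, code_set: Iterable[str]) -> int:
    """Number of coded events (dated occurrences, not distinct codes) whose
    code belongs to the set."""
    code_set = list(code_set)
    if not code_set:
        raise ValueError("code_set must be non-empty")
    return sum(1 for ev in patient.coded_events
               if code_in_set(ev.code, code_set))


def count_prescriptions(patient: PatientRecord,
                        medications: Iterable[str]) -> int:
    """Number of prescription events whose name equals any listed variant,
    case-insensitively after trimming."""
    meds = {m.strip().lower() for m in medications}
    if not meds:
        raise ValueError("medications must be non-empty")
    return sum(1 for rx in patient.prescriptions
               if rx.medication_name.strip().lower() in meds)


def count_emr_facts(patient: PatientRecord) -> int:
    """Total number of data entries attached to the patient — every coded
    event, prescription and note, regardless of vocabulary membership.

    This utilization proxy is documented as (codes + prescriptions + notes)
    over the record representation used here; richer EMR extracts (labs,
    visit records) would extend the tally.
    """
    return (len(patient.coded_events) + len(patient.prescriptions)
            + len(patient.notes))


def extract_features(patient: PatientRecord,
                     vocab: VocabularyConfig) -> FeatureVector:
    """Assemble the seven model covariates for one patient.

    The resulting vector always satisfies the superset relation between
    ``n_emr_facts`` and the structured counts unless the configured code
    sets overlap (an event matching two sets is counted in both), which is
    reported as a configuration error.
    """
    fv = _extract_features(patient, vocab)
    if not fv.fact_tally_consistent():
        raise ValueError(
            f"patient {patient.patient_id}: structured counts exceed the "
            f"EMR-fact tally; the vocabulary code sets likely overlap")
    return fv


def _extract_features(patient: PatientRecord,
                      vocab: VocabularyConfig) -> FeatureVector:
    return FeatureVector(
        n_sleep_notes=count_indicator_notes(
            patient, vocab.sleep_expressions, vocab.min_note_chars),
        n_insomnia_codes=count_codes(patient, vocab.insomnia_codes),
        n_anxdep_codes=count_codes(patient, vocab.anxdep_codes),
        n_psych_notes=count_indicator_notes(
            patient, vocab.psych_expressions, vocab.min_note_chars),
        n_insomnia_rx=count_prescriptions(patient, vocab.insomnia_medications),
        n_joint_codes=count_codes(patient, vocab.joint_codes),
        n_emr_facts=count_emr_facts(patient),
    )


def extract_corpus_features(patients: Sequence[PatientRecord],
                            vocab: VocabularyConfig
                            ) -> dict[str, FeatureVector]:
    """Extract features for every patient, keyed by patient id."""
    return {p.patient_id: extract_features(p, vocab) for p in patients}
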