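"""Chart-review-style evaluation of a frozen, thresholded model.

Positive predictive value is estimated on an independently labeled sample
scored at the frozen threshold — never on the data the threshold was
selected from.  Undetermined chart labels are dropped before metrics, and
the under-18 age exclusion is applied the same way as during model
development.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

from .candidate_mart import DEFAULT_STUDY_END, apply_age_exclusion
from .emr_model import ChartLabel, FeatureVector, PatientRecord, ScoreResult

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "prepare_labeled_sample",
    "cohort_positive_fraction_with_codes",
    "cohort_summary",
]


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived rates at the operating threshold.
    Ratios with a zero denominator are ``None`` (undefined), never 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(scores: Sequence[ScoreResult],
                      labels: Mapping[str, str]) -> ConfusionMetrics:
    """Cross-tabulate classifications against binary chart labels.

    Every scored patient must carry a label in {insomnia, no_insomnia};
    orphans on either side are an error (drop undetermined labels with
    :func:`prepare_labeled_sample` first).
    """
    scored_ids = {s.patient_id for s in scores}
    orphans = sorted(scored_ids.symmetric_difference(labels))
    if orphans:
        raise ValueError(f"score/label id mismatch: {orphans[:10]}"
                         f"{' ...' if len(orphans) > 10 else ''}")
    bad = sorted(i for i, s in labels.items()
                 if s not in ("insomnia", "no_insomnia"))
    if bad:
        raise ValueError(f"non-binary label(s) for {bad[:10]}; exclude "
                         f"undetermined patients before computing metrics")
    tp = fp = tn = fn = 0
    for s in scores:
        truth_pos = labels[s.patient_id] == "insomnia"
        if s.classified_insomnia:
            tp, fp = (tp + 1, fp) if truth_pos else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if truth_pos else (fn, tn + 1)
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


@dataclass(frozen=True)
class LabeledSample:
    """Binary-labeled, age-filtered evaluation sample with per-reason
    exclusion counts."""

    labels: dict[str, str]
    patients: list[PatientRecord]
    n_undetermined_dropped: int
    n_age_excluded: int


def prepare_labeled_sample(labels: Sequence[ChartLabel],
                           patients: Sequence[PatientRecord],
                           study_end: date = DEFAULT_STUDY_END
                           ) -> LabeledSample:
    """Drop undetermined labels, then apply the under-18 age exclusion."""
    binary = {l.patient_id: l.status for l in labels
              if l.status != "undetermined"}
    n_undet = len(labels) - len(binary)
    labeled_patients = [p for p in patients if p.patient_id in binary]
    kept, filtered = apply_age_exclusion(labeled_patients, binary,
                                         study_end=study_end)
    return LabeledSample(labels=filtered, patients=kept,
                         n_undetermined_dropped=n_undet,
                         n_age_excluded=len(binary) - len(filtered))


def cohort_positive_fraction_with_codes(
        scores: Sequence[ScoreResult],
        features: Mapping[str, FeatureVector]) -> float | None:
    """Among classified-positive patients, the fraction holding at least
    one insomnia billing code (``None`` if there are no positives).

    In the source cohort this fraction was strikingly low — most
    algorithm-identified insomnia patients had no insomnia billing code —
    which is the motivating phenomenon for note-based phenotyping.
    """
    pos = [s for s in scores if s.classified_insomnia]
    if not pos:
        return None
    with_codes = sum(1 for s in pos
                     if features[s.patient_id].n_insomnia_codes >= 1)
    return with_codes / len(pos)


def cohort_summary(patients: Sequence[PatientRecord],
                   scores: Sequence[ScoreResult]) -> dict:
    """Generic group-by summary of a (synthetic) scored cohort: counts and
    classified-positive rate by sex."""
    by_id = {p.patient_id: p for p in patients}
    out: dict[str, dict[str, int]] = {}
    for s in scores:
        sex = by_id[s.patient_id].sex or "unknown"
        cell = out.setdefault(sex, {"n": 0, "positive": 0})
        cell["n"] += 1
        cell["positive"] += int(s.classified_insomnia)
    return out
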