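"""Synthetic labeled EMR corpora for exercising the phenotyping pipeline.

Real EMR extracts from the source institutions are not public, so this
module generates corpora with the statistical structure the algorithm
assumes: a latent insomnia status per patient, status-conditional Poisson
counts for each covariate, narrative notes that embed exactly one
vocabulary expression per planted indicator note, and benign "distractor"
notes ("patient sleeps well", "denies insomnia") that trigger keyword-based
candidate-mart screening without containing any disorder expression.

The generator records what it planted (per-patient covariate counts and
the latent status) so extraction can be checked against an exact oracle.
Prose realism is explicitly not a goal: notes are template filler padded to
a configurable length with the vocabulary phrase embedded.

Default rates (mean counts per patient) emulate a chart-reviewed candidate
cohort: prevalence 0.46 as in a labeled sample of 230 cases / 270
controls, cases enriched in sleep-disorder notes, insomnia billing codes
and hypnotic prescriptions, and both groups carrying substantial
comorbidity and utilization volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping

import numpy as np

from .emr_model import (
    CodedEvent,
    FeatureVector,
    FEATURE_NAMES,
    ModelSpec,
    Note,
    PatientRecord,
    Prescription,
    VocabularyConfig,
    default_vocabulary,
)
from .scoring import stable_logistic

__all__ = [
    "SimulationConfig",
    "SimulatedCorpus",
    "simulate_corpus",
    "simulate_from_model",
    "default_covariate_law",
    "DISTRACTOR_PHRASES",
]

# Benign sleep-adjacent phrases: they contain a candidate keyword
# ("sleep"/"insomnia") but none of the ten disorder expressions.
DISTRACTOR_PHRASES: tuple[str, ...] = (
    "patient sleeps well",
    "denies insomnia",
    "sleeping well, about 8 hours nightly",
)

# Neutral filler; deliberately free of sleep keywords and of every
# expression in both vocabularies.
_FILLER = ("Routine follow-up visit. Vitals within normal limits. "
           "Medication list reviewed and reconciled. Labs ordered. ")

# Background codes/medications outside every default vocabulary set, used
# to give records realistic non-signal volume (hypertension, diabetes,
# lipids, anemia, chest pain, pneumonia, UTI, reflux).
_OTHER_CODES = ("401.9", "250.00", "272.4", "285.9", "786.50", "486",
                "599.0", "530.81")
# Includes trazodone: a drug with secondary sleep benefit that must NOT
# count as an insomnia prescription.
_OTHER_MEDS = ("metformin", "lisinopril", "atorvastatin", "trazodone",
               "omeprazole", "aspirin")

_CASE_RATES = {
    "sleep_notes": 2.0,
    "psych_notes": 1.5,
    "insomnia_codes": 0.8,
    "anxdep_codes": 2.0,
    "joint_codes": 2.5,
    "insomnia_rx": 1.0,
    "other_events": 20.0,
    "other_notes": 3.0,
}
_CONTROL_RATES = {
    "sleep_notes": 0.1,
    "psych_notes": 0.7,
    "insomnia_codes": 0.05,
    "anxdep_codes": 1.0,
    "joint_codes": 1.8,
    "insomnia_rx": 0.05,
    "other_events": 15.0,
    "other_notes": 3.0,
}

_RATE_KEYS = tuple(_CASE_RATES)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic corpus generator.

    ``case_rates`` / ``control_rates`` are mean counts per patient for each
    planted quantity; counts are drawn Poisson.  ``distractor_fraction`` is
    the probability that a background note carries a benign sleep phrase
    (instead of neutral filler).  ``severity_sd``, when positive, applies a
    shared lognormal severity multiplier to all of a patient's rates,
    inducing positive correlation between covariates.
    """

    n_patients: int
    insomnia_prevalence: float = 0.46
    case_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_CASE_RATES))
    control_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(_CONTROL_RATES))
    distractor_fraction: float = 0.3
    note_padding_chars: int = 600
    severity_sd: float = 0.0
    birth_year_range: tuple[int, int] = (1920, 1985)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.insomnia_prevalence <= 1.0:
            raise ValueError("insomnia_prevalence must lie in [0, 1]")
        if not 0.0 <= self.distractor_fraction <= 1.0:
            raise ValueError("distractor_fraction must lie in [0, 1]")
        if self.note_padding_chars < 500:
            raise ValueError("note_padding_chars must be >= 500 so planted "
                             "notes pass the note-length filter")
        for rates in (self.case_rates, self.control_rates):
            missing = set(_RATE_KEYS) - set(rates)
            if missing:
                raise ValueError(f"rate table missing keys {sorted(missing)}")
            if any(v < 0 for v in rates.values()):
                raise ValueError("rate parameters must be >= 0")
        if self.severity_sd < 0:
            raise ValueError("severity_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedCorpus:
    """A generated corpus plus its ground truth: the latent status and the
    exact per-patient planted covariate counts."""

    patients: tuple[PatientRecord, ...]
    truth: dict[str, str]                 # patient_id -> insomnia/no_insomnia
    planted: dict[str, FeatureVector]     # patient_id -> planted covariates


def _pad(body: str, n_chars: int) -> str:
    reps = -(-max(0, n_chars - len(body)) // len(_FILLER))
    return (_FILLER * reps) + body


def _random_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def simulate_corpus(config: SimulationConfig,
                    vocab: VocabularyConfig | None = None) -> SimulatedCorpus:
    """Generate a labeled synthetic corpus.

    Identical config (including seed) yields a bit-identical corpus.  Each
    planted sleep-disorder or psychiatric note embeds exactly one randomly
    chosen vocabulary expression, so note-level extraction recovers the
    planted counts exactly.
    """
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(config.seed)
    study_start, study_end = date(1992, 1, 1), date(2010, 12, 31)

    sleep_exprs = list(vocab.sleep_expressions)
    psych_exprs = list(vocab.psych_expressions)
    insomnia_codes = sorted(vocab.insomnia_codes)
    anxdep_codes = sorted(vocab.anxdep_codes)
    joint_codes = sorted(vocab.joint_codes)
    insomnia_meds = sorted(vocab.insomnia_medications)

    patients: list[PatientRecord] = []
    truth: dict[str, str] = {}
    planted: dict[str, FeatureVector] = {}

    width = max(6, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        is_case = bool(rng.random() < config.insomnia_prevalence)
        rates = dict(config.case_rates if is_case else config.control_rates)
        if config.severity_sd > 0:
            mult = float(np.exp(rng.normal(0.0, config.severity_sd)))
            rates = {k: v * mult for k, v in rates.items()}
        k = {key: int(rng.poisson(rates[key])) for key in _RATE_KEYS}

        birth_year = int(rng.integers(config.birth_year_range[0],
                                      config.birth_year_range[1] + 1))
        birth = date(birth_year, int(rng.integers(1, 13)),
                     int(rng.integers(1, 29)))
        death = None
        if rng.random() < 0.05:
            death = _random_date(rng, date(2005, 1, 1), study_end)

        notes: list[Note] = []

        def add_note(body: str) -> None:
            notes.append(Note(
                note_id=f"{pid}-N{len(notes):04d}",
                date=_random_date(rng, study_start, study_end),
                text=_pad(body, config.note_padding_chars)))

        for _ in range(k["sleep_notes"]):
            expr = sleep_exprs[int(rng.integers(len(sleep_exprs)))]
            add_note(f"Clinician impression: {expr} documented at this visit.")
        for _ in range(k["psych_notes"]):
            expr = psych_exprs[int(rng.integers(len(psych_exprs)))]
            add_note(f"Behavioral health review: {expr} noted in interview.")
        for _ in range(k["other_notes"]):
            if rng.random() < config.distractor_fraction:
                phrase = DISTRACTOR_PHRASES[
                    int(rng.integers(len(DISTRACTOR_PHRASES)))]
                add_note(f"Review of systems: {phrase}.")
            else:
                add_note("General medical assessment, no acute complaints.")

        events: list[CodedEvent] = []
        for pool, key in ((insomnia_codes, "insomnia_codes"),
                          (anxdep_codes, "anxdep_codes"),
                          (joint_codes, "joint_codes")):
            for _ in range(k[key]):
                events.append(CodedEvent(
                    code=pool[int(rng.integers(len(pool)))],
                    date=_random_date(rng, study_start, study_end)))

        rxs: list[Prescription] = []
        for _ in range(k["insomnia_rx"]):
            rxs.append(Prescription(
                medication_name=insomnia_meds[
                    int(rng.integers(len(insomnia_meds)))],
                date=_random_date(rng, study_start, study_end)))
        for _ in range(k["other_events"]):
            if rng.random() < 0.7:
                events.append(CodedEvent(
                    code=_OTHER_CODES[int(rng.integers(len(_OTHER_CODES)))],
                    date=_random_date(rng, study_start, study_end)))
            else:
                rxs.append(Prescription(
                    medication_name=_OTHER_MEDS[
                        int(rng.integers(len(_OTHER_MEDS)))],
                    date=_random_date(rng, study_start, study_end)))

        rec = PatientRecord(
            patient_id=pid,
            birth_date=birth,
            death_date=death,
            sex="F" if rng.random() < 0.594 else "M",
            coded_events=tuple(events),
            prescriptions=tuple(rxs),
            notes=tuple(notes),
        )
        patients.append(rec)
        truth[pid] = "insomnia" if is_case else "no_insomnia"
        planted[pid] = FeatureVector(
            n_sleep_notes=k["sleep_notes"],
            n_insomnia_codes=k["insomnia_codes"],
            n_anxdep_codes=k["anxdep_codes"],
            n_psych_notes=k["psych_notes"],
            n_insomnia_rx=k["insomnia_rx"],
            n_joint_codes=k["joint_codes"],
            n_emr_facts=len(events) + len(rxs) + len(notes),
        )

    return SimulatedCorpus(patients=tuple(patients), truth=truth,
                           planted=planted)


# ---------------------------------------------------------------------------
# Direct simulation from a scoring model (for parameter-recovery studies)


def default_covariate_law() -> dict[str, tuple]:
    """Per-covariate count distributions for model-based simulation.

    Chosen so every covariate carries recoverable signal at moderate n:
    modest Poisson means for the note/code/prescription counts, and a
    heavy-tailed rounded-lognormal utilization tally (median 800 facts,
    log-sd 1.0) whose large spread makes even the tiny per-fact
    coefficient identifiable.
    """
    return {
        "n_sleep_notes": ("poisson", 0.4),
        "n_insomnia_codes": ("poisson", 0.5),
        "n_anxdep_codes": ("poisson", 1.5),
        "n_psych_notes": ("poisson", 3.0),
        "n_insomnia_rx": ("poisson", 3.0),
        "n_joint_codes": ("poisson", 10.0),
        "n_emr_facts": ("lognormal", float(np.log(800.0)), 1.0),
    }


def _draw_counts(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "poisson":
        return rng.poisson(law[1], size=n).astype(np.int64)
    if kind == "lognormal":
        return np.round(rng.lognormal(law[1], law[2], size=n)).astype(np.int64)
    if kind == "fixed":
        return np.full(n, int(law[1]), dtype=np.int64)
    raise ValueError(f"unknown covariate law {kind!r}")


def simulate_from_model(model: ModelSpec, n: int,
                        covariate_law: Mapping[str, tuple] | None = None,
                        seed: int = 0
                        ) -> tuple[dict[str, FeatureVector], dict[str, str]]:
    """Sample covariates from a count law and labels from the model.

    Each patient's label is Bernoulli of the model probability evaluated at
    their sampled covariates — i.e. the scoring model is by construction
    the true data-generating process, which is what parameter-recovery
    tests require.  The utilization tally is clamped up to the sum of the
    structured vocabulary counts where needed, preserving its superset
    semantics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    law = dict(covariate_law or default_covariate_law())
    rng = np.random.default_rng(seed)
    cols = {name: _draw_counts(law[name], n, rng) for name in FEATURE_NAMES}
    structured_sum = (cols["n_insomnia_codes"] + cols["n_anxdep_codes"]
                      + cols["n_joint_codes"] + cols["n_insomnia_rx"])
    cols["n_emr_facts"] = np.maximum(cols["n_emr_facts"], structured_sum)

    features: dict[str, FeatureVector] = {}
    labels: dict[str, str] = {}
    width = max(6, len(str(n)))
    u = rng.random(n)
    for i in range(n):
        pid = f"S{i:0{width}d}"
        fv = FeatureVector(**{name: int(cols[name][i])
                              for name in FEATURE_NAMES})
        L = model.intercept + sum(
            coef * getattr(fv, name)
            for name, coef in model.ordered_coefficients())
        p = stable_logistic(L)
        features[pid] = fv
        labels[pid] = "insomnia" if u[i] < p else "no_insomnia"
    return features, labels
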