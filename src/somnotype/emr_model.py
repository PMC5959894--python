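"""Core domain types and file formats for EMR insomnia phenotyping.

The central objects are :class:`PatientRecord` (one patient's coded events,
prescriptions and narrative notes), :class:`FeatureVector` (the seven
covariates of the published insomnia scoring equation), :class:`ModelSpec`
(intercept, coefficients and decision threshold) and
:class:`VocabularyConfig` (the ICD-9 code sets, medication name variants and
text-expression lists that drive rule-based extraction).

Patient corpora are stored either as JSON lines (one patient object per
line, notes embedded) or as a four-file CSV bundle (``patients.csv``,
``codes.csv``, ``meds.csv``, ``notes.csv`` in one directory).  Feature
matrices and chart-review labels are plain CSV; model documents are JSON;
vocabularies are YAML or JSON.  All dates are ISO-8601 calendar dates;
time of day is ignored throughout.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CodedEvent",
    "Prescription",
    "Note",
    "PatientRecord",
    "ChartLabel",
    "FeatureVector",
    "ModelSpec",
    "ScoreResult",
    "VocabularyConfig",
    "CorpusFormatError",
    "FEATURE_NAMES",
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_COEFFICIENTS",
    "PUBLISHED_THRESHOLD",
    "INSOMNIA_CODES",
    "SLEEP_EXPRESSIONS",
    "INSOMNIA_MEDICATIONS",
    "code_in_set",
    "default_vocabulary",
    "read_patients",
    "write_patients",
    "read_labels",
    "write_labels",
    "read_feature_matrix",
    "write_feature_matrix",
    "load_model",
    "save_model",
    "load_vocabulary",
    "save_vocabulary",
]

# Covariate order of the published scoring equation; every feature matrix,
# model document and summation follows this order.
FEATURE_NAMES: tuple[str, ...] = (
    "n_sleep_notes",
    "n_insomnia_codes",
    "n_anxdep_codes",
    "n_psych_notes",
    "n_insomnia_rx",
    "n_joint_codes",
    "n_emr_facts",
)

# Published model: intercept, per-covariate log-odds coefficients, and the
# probability cut point anchored at 97% specificity in the model's
# original chart-reviewed validation set.
PUBLISHED_INTERCEPT: float = -1.927027677
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "n_sleep_notes": 2.329738590,
    "n_insomnia_codes": 0.802462562,
    "n_anxdep_codes": 0.264231683,
    "n_psych_notes": 0.098835169,
    "n_insomnia_rx": 0.086364249,
    "n_joint_codes": 0.048271004,
    "n_emr_facts": 0.000231521,
}
PUBLISHED_THRESHOLD: float = 0.828

# ICD-9 codes whose presence marks an insomnia-related billing event.
INSOMNIA_CODES: frozenset[str] = frozenset(
    {"307.41", "307.42", "327.00", "327.01", "327.02", "327.09", "780.52"}
)

# The ten narrative-note expressions indicating a sleep disorder.  These are
# non-negated descriptors curated from clinical notes; matching is literal
# (case-insensitive, whitespace-normalized substring), no negation parsing.
SLEEP_EXPRESSIONS: tuple[str, ...] = (
    "poor sleep",
    "has trouble sleep",
    "reduced sleep",
    "increased sleep",
    "decreased sleep",
    "excessive sleep",
    "fragmented sleep",
    "sleeplessness",
    "sleep disruption",
    "sleeps poorly",
)

# Brand/generic name variants of medications indicated only for insomnia
# (drugs with secondary sleep benefit, e.g. trazodone, are deliberately
# absent).  Matching is case-insensitive exact equality after trimming.
INSOMNIA_MEDICATIONS: frozenset[str] = frozenset(
    {
        "ambien",
        "zolpidem",
        "ambien cr",
        "zolpidem cr",
        "lunesta",
        "eszopiclone",
        "restoril",
        "temazepam",
        "sonata",
        "zaleplon",
        "dalmane",
        "flurazepam",
        "prosom",
        "eurodin",
        "estazolam",
    }
)

# Synthetic placeholder code sets and expression list for the comorbidity
# covariates.  The exact comorbidity vocabularies behind the published
# model were never released in full, so these are plausible ICD-9 stand-ins
# intended to be overridden from a vocabulary config file in any serious use.
ANXDEP_CODES_SYNTHETIC: frozenset[str] = frozenset(
    {"300.00", "300.01", "300.02", "300.4", "296.20", "296.21", "296.22",
     "296.30", "296.33", "311"}
)
JOINT_CODES_SYNTHETIC: frozenset[str] = frozenset(
    {"714.0", "715.90", "715.96", "716.90", "719.40", "719.41", "719.45",
     "719.46"}
)
PSYCH_CODES_SYNTHETIC: frozenset[str] = frozenset(
    {"295.90", "296.80", "298.9", "301.9", "309.81"}
)
PSYCH_EXPRESSIONS_SYNTHETIC: tuple[str, ...] = (
    "depressed mood",
    "severe anxiety",
    "panic attacks",
    "suicidal ideation",
    "auditory hallucinations",
    "psychiatric hospitalization",
    "bipolar disorder",
    "ptsd symptoms",
)

_ICD9_RE = re.compile(r"^(\d{3}|V\d{2}|E\d{3})(\.\d{1,2})?$")


class CorpusFormatError(ValueError):
    """A corpus, label, model or vocabulary file failed to parse or violated
    a record invariant.  The message names the offending record/line."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise CorpusFormatError(msg)


@dataclass(frozen=True)
class CodedEvent:
    """One dated ICD-9 billing event."""

    code: str
    date: date

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", self.code.strip())
        _require(bool(_ICD9_RE.match(self.code)),
                 f"code {self.code!r} is not a valid ICD-9 code")


@dataclass(frozen=True)
class Prescription:
    """One dated pharmacy prescription event."""

    medication_name: str
    date: date

    def __post_init__(self) -> None:
        _require(bool(self.medication_name.strip()),
                 "prescription medication_name must be non-empty")


@dataclass(frozen=True)
class Note:
    """One dated free-text clinical narrative note."""

    note_id: str
    date: date
    text: str


@dataclass(frozen=True)
class PatientRecord:
    """One patient's full EMR extract.

    Demographic strings (sex, ethnicity, marital status, insurance) are
    carried through unmodified; the scoring model does not use them.
    """

    patient_id: str
    birth_date: date
    death_date: date | None = None
    sex: str = ""
    ethnicity: str = ""
    marital: str = ""
    insurance: str = ""
    coded_events: tuple[CodedEvent, ...] = ()
    prescriptions: tuple[Prescription, ...] = ()
    notes: tuple[Note, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "coded_events", tuple(self.coded_events))
        object.__setattr__(self, "prescriptions", tuple(self.prescriptions))
        object.__setattr__(self, "notes", tuple(self.notes))
        pid = self.patient_id
        _require(bool(pid), "patient_id must be non-empty")
        if self.death_date is not None:
            _require(self.death_date >= self.birth_date,
                     f"patient {pid}: death_date precedes birth_date")
        for ev in self.coded_events:
            _require(ev.date >= self.birth_date,
                     f"patient {pid}: coded event dated before birth")
        for rx in self.prescriptions:
            _require(rx.date >= self.birth_date,
                     f"patient {pid}: prescription dated before birth")
        note_ids = [n.note_id for n in self.notes]
        _require(len(note_ids) == len(set(note_ids)),
                 f"patient {pid}: duplicate note_id")
        for n in self.notes:
            _require(n.date >= self.birth_date,
                     f"patient {pid}: note dated before birth")


LABEL_STATUSES = ("insomnia", "no_insomnia", "undetermined")


@dataclass(frozen=True)
class ChartLabel:
    """Chart-review outcome for one patient."""

    patient_id: str
    status: str

    def __post_init__(self) -> None:
        _require(self.status in LABEL_STATUSES,
                 f"label status {self.status!r} not one of {LABEL_STATUSES}")


@dataclass(frozen=True)
class FeatureVector:
    """The seven covariates of the insomnia scoring equation, as counts.

    ``n_emr_facts`` is the total number of data entries attached to the
    patient (a utilization proxy).  For vectors extracted from a record or
    produced by the simulator it is a superset tally: at least as large as
    the sum of the vocabulary-restricted structured counts
    (:meth:`fact_tally_consistent`).  The constructor does not force this,
    so hypothetical what-if vectors (e.g. "five billing codes, everything
    else zero") remain valid scoring inputs.
    """

    n_sleep_notes: int = 0
    n_insomnia_codes: int = 0
    n_anxdep_codes: int = 0
    n_psych_notes: int = 0
    n_insomnia_rx: int = 0
    n_joint_codes: int = 0
    n_emr_facts: int = 0

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            _require(isinstance(v, int) and not isinstance(v, bool) and v >= 0,
                     f"{name} must be a non-negative integer, got {v!r}")

    def fact_tally_consistent(self) -> bool:
        """True when ``n_emr_facts`` covers the structured vocabulary
        counts, as it must for any vector derived from a real record."""
        return self.n_emr_facts >= (self.n_insomnia_codes
                                    + self.n_anxdep_codes
                                    + self.n_joint_codes
                                    + self.n_insomnia_rx)

    def as_array(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


@dataclass(frozen=True)
class ModelSpec:
    """A logistic scoring model: intercept, named coefficients, decision
    threshold and the variable subset it was fit on.

    ``threshold`` may be ``None`` for a freshly fit model on which
    specificity-anchored threshold selection has not yet been run;
    classification requires a threshold.
    """

    intercept: float
    coefficients: Mapping[str, float]
    threshold: float | None = None
    variable_subset: str = "combined"

    def __post_init__(self) -> None:
        coeffs = {str(k): float(v) for k, v in self.coefficients.items()}
        object.__setattr__(self, "coefficients", coeffs)
        unknown = set(coeffs) - set(FEATURE_NAMES)
        _require(not unknown, f"unknown covariate name(s) {sorted(unknown)}; "
                              f"expected a subset of {list(FEATURE_NAMES)}")
        if self.threshold is not None:
            _require(0.0 < self.threshold < 1.0,
                     f"threshold must lie in (0, 1), got {self.threshold}")
        _require(self.variable_subset in
                 ("icd_only", "structured_only", "unstructured_only", "combined"),
                 f"unknown variable_subset {self.variable_subset!r}")

    def ordered_coefficients(self) -> list[tuple[str, float]]:
        """Coefficients in fixed covariate order (stable summation)."""
        return [(n, self.coefficients[n]) for n in FEATURE_NAMES
                if n in self.coefficients]


@dataclass(frozen=True)
class ScoreResult:
    """Model evaluation for one patient: linear predictor L, probability
    p = exp(L)/(1+exp(L)), and the thresholded classification."""

    patient_id: str
    linear_predictor: float
    probability: float
    classified_insomnia: bool

    def __post_init__(self) -> None:
        expected = _logistic(self.linear_predictor)
        _require(abs(self.probability - expected) <= 1e-12,
                 "probability inconsistent with linear predictor")


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class VocabularyConfig:
    """Code sets, medication variants and expression lists driving
    extraction and cohort filters.

    Code-set entries ending in ``*`` are explicit prefix wildcards; all
    other codes compare as exact strings after whitespace trimming.
    """

    insomnia_codes: frozenset[str] = INSOMNIA_CODES
    anxdep_codes: frozenset[str] = ANXDEP_CODES_SYNTHETIC
    joint_codes: frozenset[str] = JOINT_CODES_SYNTHETIC
    psych_codes: frozenset[str] = PSYCH_CODES_SYNTHETIC
    insomnia_medications: frozenset[str] = INSOMNIA_MEDICATIONS
    sleep_expressions: tuple[str, ...] = SLEEP_EXPRESSIONS
    psych_expressions: tuple[str, ...] = PSYCH_EXPRESSIONS_SYNTHETIC
    candidate_keywords: tuple[str, ...] = ("sleep", "insomnia")
    min_note_chars: int = 500
    min_qualifying_notes: int = 2

    def __post_init__(self) -> None:
        for name in ("insomnia_codes", "anxdep_codes", "joint_codes",
                     "psych_codes", "insomnia_medications"):
            object.__setattr__(self, name, frozenset(getattr(self, name)))
            _require(len(getattr(self, name)) > 0, f"{name} must be non-empty")
        for name in ("sleep_expressions", "psych_expressions",
                     "candidate_keywords"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
            _require(len(getattr(self, name)) > 0, f"{name} must be non-empty")
        _require(self.min_note_chars >= 0, "min_note_chars must be >= 0")
        _require(self.min_qualifying_notes >= 0,
                 "min_qualifying_notes must be >= 0")


def default_vocabulary() -> VocabularyConfig:
    """The default vocabulary: published insomnia codes, medications and
    sleep expressions; synthetic placeholder comorbidity sets."""
    return VocabularyConfig()


def code_in_set(code: str, code_set: Iterable[str]) -> bool:
    """Exact-string ICD-9 membership; entries ending ``*`` match prefixes."""
    code = code.strip()
    for entry in code_set:
        entry = entry.strip()
        if entry.endswith("*"):
            if code.startswith(entry[:-1]):
                return True
        elif code == entry:
            return True
    return False


# ---------------------------------------------------------------------------
# Patient corpus IO


def _parse_date(value: str, where: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: bad date {value!r}") from exc


def _patient_from_obj(obj: dict, where: str) -> PatientRecord:
    try:
        pid = str(obj["patient_id"])
        birth = _parse_date(obj["birth_date"], where)
        death_raw = obj.get("death_date")
        death = _parse_date(death_raw, where) if death_raw else None
        events = tuple(
            CodedEvent(code=str(e["code"]), date=_parse_date(e["date"], where))
            for e in obj.get("coded_events", ())
        )
        rxs = tuple(
            Prescription(medication_name=str(r["medication"]),
                         date=_parse_date(r["date"], where))
            for r in obj.get("prescriptions", ())
        )
        notes = tuple(
            Note(note_id=str(n["note_id"]), date=_parse_date(n["date"], where),
                 text=str(n["text"]))
            for n in obj.get("notes", ())
        )
    except KeyError as exc:
        raise CorpusFormatError(f"{where}: missing field {exc}") from exc
    try:
        return PatientRecord(
            patient_id=pid,
            birth_date=birth,
            death_date=death,
            sex=str(obj.get("sex", "")),
            ethnicity=str(obj.get("ethnicity", "")),
            marital=str(obj.get("marital", "")),
            insurance=str(obj.get("insurance", "")),
            coded_events=events,
            prescriptions=rxs,
            notes=notes,
        )
    except CorpusFormatError as exc:
        raise CorpusFormatError(f"{where}: {exc}") from exc


def _patient_to_obj(p: PatientRecord) -> dict:
    return {
        "patient_id": p.patient_id,
        "birth_date": p.birth_date.isoformat(),
        "death_date": p.death_date.isoformat() if p.death_date else None,
        "sex": p.sex,
        "ethnicity": p.ethnicity,
        "marital": p.marital,
        "insurance": p.insurance,
        "coded_events": [{"code": e.code, "date": e.date.isoformat()}
                         for e in p.coded_events],
        "prescriptions": [{"medication": r.medication_name,
                           "date": r.date.isoformat()}
                          for r in p.prescriptions],
        "notes": [{"note_id": n.note_id, "date": n.date.isoformat(),
                   "text": n.text} for n in p.notes],
    }


def read_patients(path: str | Path, format: str = "jsonl") -> list[PatientRecord]:
    """Read a patient corpus in file order, enforcing record invariants.

    ``format`` is ``"jsonl"`` (one JSON object per line) or ``"csv"``
    (``path`` is a directory holding patients.csv, codes.csv, meds.csv,
    notes.csv).  Malformed content raises :class:`CorpusFormatError` naming
    the offending line or record; duplicate patient ids are an error.
    """
    path = Path(path)
    if format == "jsonl":
        records = _read_patients_jsonl(path)
    elif format == "csv":
        records = _read_patients_csv(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for rec in records:
        _require(rec.patient_id not in seen,
                 f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
    return records


def _read_patients_jsonl(path: Path) -> list[PatientRecord]:
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path.name}:{lineno}"
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{where}: invalid JSON") from exc
            records.append(_patient_from_obj(obj, where))
    return records


def _read_patients_csv(path: Path) -> list[PatientRecord]:
    if not path.is_dir():
        raise FileNotFoundError(f"{path} (expected a CSV-bundle directory)")

    def load(name: str) -> list[dict]:
        f = path / name
        if not f.exists():
            if name == "patients.csv":
                raise FileNotFoundError(f)
            return []
        with open(f, newline="", encoding="utf-8") as fh:
            return list(csv.DictReader(fh))

    by_pid: dict[str, dict] = {}
    order: list[str] = []
    for row in load("patients.csv"):
        pid = row["patient_id"]
        by_pid[pid] = {**row, "coded_events": [], "prescriptions": [],
                       "notes": []}
        order.append(pid)
    for row in load("codes.csv"):
        by_pid[row["patient_id"]]["coded_events"].append(
            {"code": row["code"], "date": row["date"]})
    for row in load("meds.csv"):
        by_pid[row["patient_id"]]["prescriptions"].append(
            {"medication": row["medication"], "date": row["date"]})
    for row in load("notes.csv"):
        by_pid[row["patient_id"]]["notes"].append(
            {"note_id": row["note_id"], "date": row["date"],
             "text": row["text"]})
    return [_patient_from_obj(by_pid[pid], f"patient {pid}") for pid in order]


def write_patients(records: Sequence[PatientRecord], path: str | Path,
                   format: str = "jsonl") -> None:
    """Write a corpus in the given format (see :func:`read_patients`)."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(_patient_to_obj(rec), ensure_ascii=False))
                fh.write("\n")
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "patients.csv", "w", newline="",
                  encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "birth_date", "death_date", "sex",
                        "ethnicity", "marital", "insurance"])
            for p in records:
                w.writerow([p.patient_id, p.birth_date.isoformat(),
                            p.death_date.isoformat() if p.death_date else "",
                            p.sex, p.ethnicity, p.marital, p.insurance])
        with open(path / "codes.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "code", "date"])
            for p in records:
                for e in p.coded_events:
                    w.writerow([p.patient_id, e.code, e.date.isoformat()])
        with open(path / "meds.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "medication", "date"])
            for p in records:
                for r in p.prescriptions:
                    w.writerow([p.patient_id, r.medication_name,
                                r.date.isoformat()])
        with open(path / "notes.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "note_id", "date", "text"])
            for p in records:
                for n in p.notes:
                    w.writerow([p.patient_id, n.note_id, n.date.isoformat(),
                                n.text])
    else:
        raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# Labels, feature matrices, models, vocabularies


def read_labels(path: str | Path) -> list[ChartLabel]:
    """Read a 2-column CSV (patient_id, status) of chart-review labels."""
    labels = []
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                labels.append(ChartLabel(patient_id=row["patient_id"],
                                         status=row["status"]))
            except (KeyError, CorpusFormatError) as exc:
                raise CorpusFormatError(f"{Path(path).name}:{i}: {exc}") from exc
    return labels


def write_labels(labels: Iterable[ChartLabel], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "status"])
        for lab in sorted(labels, key=lambda l: l.patient_id):
            w.writerow([lab.patient_id, lab.status])


def write_feature_matrix(features: Mapping[str, FeatureVector],
                         path: str | Path) -> None:
    """Write a feature matrix as CSV: header row, one row per patient,
    rows sorted by patient_id, columns in fixed covariate order."""
    _require(len(features) > 0, "feature matrix must be non-empty")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", *FEATURE_NAMES])
        for pid in sorted(features):
            w.writerow([pid, *features[pid].as_array()])


def read_feature_matrix(path: str | Path) -> dict[str, FeatureVector]:
    features: dict[str, FeatureVector] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                fv = FeatureVector(**{n: int(row[n]) for n in FEATURE_NAMES})
            except (KeyError, ValueError) as exc:
                raise CorpusFormatError(
                    f"{Path(path).name}:{i}: {exc}") from exc
            features[row["patient_id"]] = fv
    return features


def load_model(source: str | Path) -> ModelSpec:
    """Load a model document, or the literal name ``"published"`` for the
    published seven-variable model with its 0.828 decision threshold.

    A custom JSON document must provide ``intercept``, ``coefficients``
    (covariate name -> number) and an explicit ``threshold``.
    """
    if str(source) == "published":
        return ModelSpec(intercept=PUBLISHED_INTERCEPT,
                         coefficients=dict(PUBLISHED_COEFFICIENTS),
                         threshold=PUBLISHED_THRESHOLD,
                         variable_subset="combined")
    with open(source, encoding="utf-8") as fh:
        doc = json.load(fh)
    _require("intercept" in doc, "model document missing 'intercept'")
    _require("coefficients" in doc, "model document missing 'coefficients'")
    _require("threshold" in doc and doc["threshold"] is not None,
             "model document must state an explicit 'threshold'")
    return ModelSpec(intercept=float(doc["intercept"]),
                     coefficients=doc["coefficients"],
                     threshold=float(doc["threshold"]),
                     variable_subset=doc.get("variable_subset", "combined"))


def save_model(model: ModelSpec, path: str | Path) -> None:
    doc = {
        "intercept": model.intercept,
        "coefficients": dict(model.ordered_coefficients()),
        "threshold": model.threshold,
        "variable_subset": model.variable_subset,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_vocabulary(path: str | Path) -> VocabularyConfig:
    """Load a vocabulary config from YAML or JSON; unspecified fields keep
    their defaults."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(VocabularyConfig)}
    unknown = set(doc) - known
    _require(not unknown, f"unknown vocabulary field(s) {sorted(unknown)}")
    return VocabularyConfig(**doc)


def save_vocabulary(vocab: VocabularyConfig, path: str | Path) -> None:
    doc = {
        "insomnia_codes": sorted(vocab.insomnia_codes),
        "anxdep_codes": sorted(vocab.anxdep_codes),
        "joint_codes": sorted(vocab.joint_codes),
        "psych_codes": sorted(vocab.psych_codes),
        "insomnia_medications": sorted(vocab.insomnia_medications),
        "sleep_expressions": list(vocab.sleep_expressions),
        "psych_expressions": list(vocab.psych_expressions),
        "candidate_keywords": list(vocab.candidate_keywords),
        "min_note_chars": vocab.min_note_chars,
        "min_qualifying_notes": vocab.min_qualifying_notes,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
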