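"""ALTO questionnaire schema, answer domains and respondent validation.

The ALTO (Alopecia Areata Assessment Tool) is a one-page self-administered
screening questionnaire for alopecia areata (AA), an autoimmune non-scarring
hair loss.  It has five yes/no/not-sure text items (Q1, Q2, Q3, Q4, Q5), two
follow-ups administered only after an affirmative Q3 (Q3A, Q3B), and one
picture item (Q6) on which respondents may tick any of four photographs
(A-D) or declare that none is representative (E).

This module owns the data model: question identifiers, answer tokens, the
skip-logic rules, respondent records, and the cohort CSV dialect.  Scoring
lives in :mod:`altoscreen.rules`.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

log = logging.getLogger(__name__)

__all__ = [
    "QuestionId",
    "ItemAnswer",
    "PictureAnswer",
    "DiagnosisClass",
    "Diagnosis",
    "Respondent",
    "QuestionnaireSchema",
    "DEFAULT_SCHEMA",
    "InstrumentError",
    "validate_respondent",
    "applicable_questions",
    "is_evaluable",
    "read_cohort_csv",
    "write_cohort_csv",
    "COHORT_CSV_COLUMNS",
]


class InstrumentError(ValueError):
    """Fatal problem with a respondent record or schema."""


class QuestionId(str, enum.Enum):
    """The eight ALTO items; no other identifiers exist anywhere."""

    Q1 = "Q1"
    Q2 = "Q2"
    Q3 = "Q3"
    Q3A = "Q3A"
    Q3B = "Q3B"
    Q4 = "Q4"
    Q5 = "Q5"
    Q6 = "Q6"


#: The seven items answered yes/no/not-sure (everything except the picture).
ITEM_QUESTIONS: tuple[QuestionId, ...] = (
    QuestionId.Q1,
    QuestionId.Q2,
    QuestionId.Q3,
    QuestionId.Q3A,
    QuestionId.Q3B,
    QuestionId.Q4,
    QuestionId.Q5,
)


class ItemAnswer(str, enum.Enum):
    YES = "yes"
    NO = "no"
    NOT_SURE = "not_sure"
    MISSING = "missing"


PICTURE_LETTERS: tuple[str, ...] = ("A", "B", "C", "D")


@dataclass(frozen=True)
class PictureAnswer:
    """Response to the picture item Q6.

    ``selections`` holds any subset of the photographs A-D; ``none_selected``
    is the explicit "no representative photographs" choice (E).  A respondent
    may also hand the form back with the item answered but nothing ticked
    (``selections`` empty, both flags false) — that pattern occurs in real
    administrations and is distinct from a skipped item (``missing``).
    """

    selections: frozenset[str] = frozenset()
    none_selected: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        bad = self.selections - set(PICTURE_LETTERS)
        if bad:
            raise InstrumentError(f"unknown picture selections: {sorted(bad)}")
        if self.none_selected and self.selections:
            raise InstrumentError("none_selected=True requires empty selections")
        if self.missing and (self.selections or self.none_selected):
            raise InstrumentError("missing picture answer cannot carry selections")

    @classmethod
    def from_cell(cls, cell: str) -> "PictureAnswer":
        """Parse the cohort-CSV q6 cell.

        Empty cell -> missing; ``E`` -> none representative; ``none`` ->
        answered with no selection; otherwise a semicolon-joined subset of
        A-D (case-insensitive).
        """
        text = cell.strip()
        if not text:
            return cls(missing=True)
        if text.upper() == "E":
            return cls(none_selected=True)
        if text.lower() == "none":
            return cls()
        parts = [p.strip().upper() for p in text.split(";") if p.strip()]
        bad = set(parts) - set(PICTURE_LETTERS)
        if bad:
            raise InstrumentError(f"unparseable q6 cell {cell!r}")
        return cls(selections=frozenset(parts))

    def to_cell(self) -> str:
        if self.missing:
            return ""
        if self.none_selected:
            return "E"
        if not self.selections:
            return "none"
        return ";".join(sorted(self.selections))


class DiagnosisClass(str, enum.Enum):
    """Gold-standard (dermatologist) diagnosis classes."""

    TOTALIS_UNIVERSALIS = "totalis_universalis"
    PATCHY = "patchy"
    OTHER_HAIR_LOSS = "other_hair_loss"


#: Classes counted as alopecia areata when judging the screen.
AA_CLASSES = frozenset(
    {DiagnosisClass.TOTALIS_UNIVERSALIS, DiagnosisClass.PATCHY}
)


@dataclass(frozen=True)
class Diagnosis:
    cls: DiagnosisClass
    label: str = ""

    @property
    def is_aa(self) -> bool:
        return self.cls in AA_CLASSES


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Race(str, enum.Enum):
    WHITE = "white"
    AFRICAN_AMERICAN = "african_american"
    HISPANIC = "hispanic"
    ASIAN = "asian"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Respondent:
    """One participant: demographics, gold standard and item responses.

    ``answers`` always carries all seven non-picture items; items that were
    not administered (Q3A/Q3B after a non-affirmative Q3) are ``missing``.
    """

    id: str
    diagnosis: Diagnosis
    answers: Mapping[QuestionId, ItemAnswer]
    picture: PictureAnswer = PictureAnswer(missing=True)
    age: int | None = None
    sex: Sex = Sex.UNKNOWN
    race: Race = Race.UNKNOWN

    def __post_init__(self) -> None:
        missing_keys = set(ITEM_QUESTIONS) - set(self.answers)
        if missing_keys:
            raise InstrumentError(f"answers lack items {sorted(q.value for q in missing_keys)}")
        if self.answers[QuestionId.Q3] is not ItemAnswer.YES:
            for q in (QuestionId.Q3A, QuestionId.Q3B):
                if self.answers[q] is not ItemAnswer.MISSING:
                    raise InstrumentError(
                        f"{self.id}: {q.value} answered although Q3 is not 'yes'"
                    )


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Ordered items with display text and conditional-administration map."""

    items: tuple[tuple[QuestionId, str], ...]
    conditional_on: Mapping[QuestionId, QuestionId] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = [q for q, _ in self.items]
        if len(set(order)) != len(order) or set(order) != set(QuestionId):
            raise InstrumentError("schema must list each of the eight items exactly once")
        for child, parent in self.conditional_on.items():
            if order.index(parent) >= order.index(child):
                raise InstrumentError(f"conditional item {child.value} precedes its parent")

    @property
    def question_ids(self) -> tuple[QuestionId, ...]:
        return tuple(q for q, _ in self.items)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "items": [{"id": q.value, "prompt": text} for q, text in self.items],
            "conditional_on": {c.value: p.value for c, p in self.conditional_on.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuestionnaireSchema":
        doc = yaml.safe_load(Path(path).read_text())
        items = tuple((QuestionId(d["id"]), d.get("prompt", "")) for d in doc["items"])
        cond = {
            QuestionId(c): QuestionId(p)
            for c, p in (doc.get("conditional_on") or {}).items()
        }
        return cls(items=items, conditional_on=cond)


DEFAULT_SCHEMA = QuestionnaireSchema(
    items=(
        (QuestionId.Q1, "Diagnosed with alopecia areata by a dermatologist"),
        (QuestionId.Q2, "Diagnosed with alopecia areata by a non-dermatologist provider"),
        (QuestionId.Q3, "Round areas of hair loss on the face or scalp"),
        (QuestionId.Q3A, "Hair grew back in those areas"),
        (QuestionId.Q3B, "Hair loss lasted longer than 6 months"),
        (QuestionId.Q4, "Complete hair loss on the scalp"),
        (QuestionId.Q5, "Complete hair loss on the head and body"),
        (QuestionId.Q6, "Photographs representative of your hair loss"),
    ),
    conditional_on={QuestionId.Q3A: QuestionId.Q3, QuestionId.Q3B: QuestionId.Q3},
)


_ANSWER_TOKENS = {
    "yes": ItemAnswer.YES,
    "y": ItemAnswer.YES,
    "no": ItemAnswer.NO,
    "n": ItemAnswer.NO,
    "not_sure": ItemAnswer.NOT_SURE,
    "not sure": ItemAnswer.NOT_SURE,
    "notsure": ItemAnswer.NOT_SURE,
    "unsure": ItemAnswer.NOT_SURE,
    "": ItemAnswer.MISSING,
    "missing": ItemAnswer.MISSING,
}

_DIAGNOSIS_TOKENS = {c.value: c for c in DiagnosisClass}
_DIAGNOSIS_TOKENS.update({"totalis": DiagnosisClass.TOTALIS_UNIVERSALIS,
                          "universalis": DiagnosisClass.TOTALIS_UNIVERSALIS,
                          "other": DiagnosisClass.OTHER_HAIR_LOSS})


def _parse_item(cell: str) -> ItemAnswer:
    return _ANSWER_TOKENS.get(cell.strip().lower(), ItemAnswer.MISSING)


def _parse_enum(cell: str, cls, default):
    try:
        return cls(cell.strip().lower())
    except ValueError:
        return default


def validate_respondent(
    raw_record: Mapping[str, str],
    schema: QuestionnaireSchema = DEFAULT_SCHEMA,
) -> Respondent:
    """Build a well-formed :class:`Respondent` from a raw string record.

    Unparseable item answers become ``missing``.  Skip logic is enforced: if
    Q3 is not 'yes', any recorded Q3A/Q3B answer is coerced to ``missing``
    with a logged warning (those items were not administered).

    Raises :class:`InstrumentError` on a missing id, an unknown diagnosis
    class token, or duplicate question fields (case-insensitive).
    """
    keys = [k.strip().lower() for k in raw_record]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise InstrumentError(f"duplicate fields in record: {sorted(dupes)}")
    rec = {k.strip().lower(): ("" if v is None else str(v)) for k, v in raw_record.items()}

    rid = rec.get("id", "").strip()
    if not rid:
        raise InstrumentError("record has no id field")

    diag_token = rec.get("diagnosis", "").strip().lower()
    if diag_token not in _DIAGNOSIS_TOKENS:
        raise InstrumentError(f"{rid}: unknown diagnosis class {diag_token!r}")
    diagnosis = Diagnosis(_DIAGNOSIS_TOKENS[diag_token], rec.get("diagnosis_label", "").strip())

    answers = {q: _parse_item(rec.get(q.value.lower(), "")) for q in ITEM_QUESTIONS}
    if answers[QuestionId.Q3] is not ItemAnswer.YES:
        for q in (QuestionId.Q3A, QuestionId.Q3B):
            if answers[q] is not ItemAnswer.MISSING:
                log.warning(
                    "%s: %s answered but Q3 is %s; coerced to missing (not administered)",
                    rid, q.value, answers[QuestionId.Q3].value,
                )
                answers[q] = ItemAnswer.MISSING

    age_text = rec.get("age", "").strip()
    try:
        age: int | None = int(round(float(age_text)))
    except ValueError:
        age = None

    return Respondent(
        id=rid,
        diagnosis=diagnosis,
        answers=answers,
        picture=PictureAnswer.from_cell(rec.get("q6", "")),
        age=age,
        sex=_parse_enum(rec.get("sex", ""), Sex, Sex.UNKNOWN),
        race=_parse_enum(rec.get("race", ""), Race, Race.UNKNOWN),
    )


def applicable_questions(
    resp: Respondent, schema: QuestionnaireSchema = DEFAULT_SCHEMA
) -> frozenset[QuestionId]:
    """Items administered to this respondent.

    Conditional children (Q3A/Q3B) are applicable only when the parent item
    was answered 'yes'; a 'no', 'not sure' or missing parent suppresses them.
    """
    out = set(schema.question_ids)
    for child, parent in schema.conditional_on.items():
        if resp.answers.get(parent) is not ItemAnswer.YES:
            out.discard(child)
    return frozenset(out)


def is_evaluable(
    resp: Respondent,
    required: Iterable[QuestionId],
    schema: QuestionnaireSchema = DEFAULT_SCHEMA,
) -> bool:
    """True iff every required *and applicable* item has a non-missing answer.

    This implements the study's exclusion rule: a respondent enters an
    algorithm's denominator only when every question that algorithm reads,
    and that was actually administered to them, was answered.
    """
    needed = frozenset(required) & applicable_questions(resp, schema)
    for q in needed:
        if q is QuestionId.Q6:
            if resp.picture.missing:
                return False
        elif resp.answers[q] is ItemAnswer.MISSING:
            return False
    return True


COHORT_CSV_COLUMNS = [
    "id", "age", "sex", "race", "diagnosis", "diagnosis_label",
    "q1", "q2", "q3", "q3a", "q3b", "q4", "q5", "q6",
]


def write_cohort_csv(cohort: Sequence[Respondent], path: str | Path) -> None:
    """Write respondents in the cohort CSV dialect (UTF-8, fixed header)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_CSV_COLUMNS)
        for r in cohort:
            cells = [
                r.id,
                "" if r.age is None else str(r.age),
                "" if r.sex is Sex.UNKNOWN else r.sex.value,
                "" if r.race is Race.UNKNOWN else r.race.value,
                r.diagnosis.cls.value,
                r.diagnosis.label,
            ]
            for q in ITEM_QUESTIONS:
                a = r.answers[q]
                cells.append("" if a is ItemAnswer.MISSING else a.value)
            cells.append(r.picture.to_cell())
            w.writerow(cells)


def read_cohort_csv(
    path: str | Path, schema: QuestionnaireSchema = DEFAULT_SCHEMA
) -> list[Respondent]:
    """Parse a cohort CSV; row numbers are reported on malformed rows."""
    out: list[Respondent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InstrumentError(f"{path}: empty cohort file")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(validate_respondent(row, schema))
            except InstrumentError as exc:
                raise InstrumentError(f"{path} row {i}: {exc}") from exc
    return out
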