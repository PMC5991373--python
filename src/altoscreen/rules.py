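"""Boolean scoring rules for the ALTO questionnaire.

Each of the nine published scoring algorithms is a monotone boolean
expression over questionnaire atoms: ``Q1`` is true iff the respondent
answered 'yes' to item Q1, ``pic(C)`` iff photograph C was selected
(``pic(E)`` iff the explicit no-representative-photograph choice was made).
Rules are written in a tiny DSL::

    (Q1|Q2) & Q3 & any(Q3A,Q3B,Q4,Q5)

with ``&`` binding tighter than ``|`` and ``any(...)`` an n-ary OR kept for
readability.  Only algorithms 1, 3 and 5 are stated verbatim in running
text; the remaining six were published as a figure and ship here as
placeholders that raise until a transcription is supplied.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .instrument import (
    DEFAULT_SCHEMA,
    ItemAnswer,
    QuestionId,
    QuestionnaireSchema,
    Respondent,
    applicable_questions,
    is_evaluable,
)

log = logging.getLogger(__name__)

__all__ = [
    "Atom", "PicAtom", "And", "Or", "Any", "Rule",
    "RuleSyntaxError", "UntranscribedRuleError",
    "parse_rule", "serialize_rule", "required_questions",
    "UnsurePolicy", "Verdict", "evaluate",
    "AlgorithmDef", "SourceConfidence", "Label", "classify_cohort",
    "builtin_algorithms", "TEXT_VERIFIED_RULES",
]


# ---------------------------------------------------------------------------
# expression tree

@dataclass(frozen=True)
class Atom:
    question: QuestionId


PIC_TOKENS = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class PicAtom:
    selection: str

    def __post_init__(self) -> None:
        if self.selection not in PIC_TOKENS:
            raise ValueError(f"unknown picture token {self.selection!r}")


@dataclass(frozen=True)
class And:
    children: tuple["Rule", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Rule", ...]


@dataclass(frozen=True)
class Any:
    """n-ary OR over atoms; semantically identical to :class:`Or`."""

    children: tuple[Union[Atom, PicAtom], ...]


Rule = Union[Atom, PicAtom, And, Or, Any]


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the 0-based offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# parser:  expr := term ('|' term)* ; term := factor ('&' factor)*
#          factor := ATOM | pic(X) | any(atom,...) | '(' expr ')'

_ATOM_NAMES = {q.value: q for q in QuestionId if q is not QuestionId.Q6}


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _peek(self) -> str:
        self._skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _expect(self, ch: str) -> None:
        if self._peek() != ch:
            raise RuleSyntaxError(f"expected {ch!r}", self.pos)
        self.pos += 1

    def _word(self) -> str:
        self._skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos].isalnum() or self.text[self.pos] == "_"
        ):
            self.pos += 1
        if self.pos == start:
            raise RuleSyntaxError("expected an atom", start)
        return self.text[start:self.pos]

    def parse(self) -> Rule:
        node = self._expr()
        self._skip_ws()
        if self.pos != len(self.text):
            raise RuleSyntaxError("unexpected trailing input", self.pos)
        return node

    def _expr(self) -> Rule:
        terms = [self._term()]
        while self._peek() == "|":
            self.pos += 1
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def _term(self) -> Rule:
        factors = [self._factor()]
        while self._peek() == "&":
            self.pos += 1
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def _factor(self) -> Rule:
        if self._peek() == "(":
            self.pos += 1
            node = self._expr()
            self._expect(")")
            return node
        start = self.pos
        word = self._word()
        lower = word.lower()
        if lower == "pic":
            self._expect("(")
            tok = self._word().upper()
            if tok not in PIC_TOKENS:
                raise RuleSyntaxError(f"unknown picture token {tok!r}", start)
            self._expect(")")
            return PicAtom(tok)
        if lower == "any":
            self._expect("(")
            atoms = [self._any_atom()]
            while self._peek() == ",":
                self.pos += 1
                atoms.append(self._any_atom())
            self._expect(")")
            return Any(tuple(atoms))
        return self._named_atom(word, start)

    def _any_atom(self) -> Union[Atom, PicAtom]:
        start = self.pos
        word = self._word()
        if word.lower() == "pic":
            self._expect("(")
            tok = self._word().upper()
            if tok not in PIC_TOKENS:
                raise RuleSyntaxError(f"unknown picture token {tok!r}", start)
            self._expect(")")
            return PicAtom(tok)
        return self._named_atom(word, start)

    def _named_atom(self, word: str, start: int) -> Atom:
        name = word.upper()
        if name not in _ATOM_NAMES:
            raise RuleSyntaxError(f"unknown atom {word!r}", start)
        return Atom(_ATOM_NAMES[name])


def parse_rule(text: str) -> Rule:
    """Parse rule text into an expression tree.

    Round-trips with :func:`serialize_rule`.
    """
    return _Parser(text).parse()


def serialize_rule(rule: Rule) -> str:
    """Canonical serialization: fully parenthesized, atoms upper-case."""
    if isinstance(rule, Atom):
        return rule.question.value
    if isinstance(rule, PicAtom):
        return f"pic({rule.selection})"
    if isinstance(rule, Any):
        return "any(" + ",".join(serialize_rule(c) for c in rule.children) + ")"
    if isinstance(rule, And):
        return "(" + "&".join(serialize_rule(c) for c in rule.children) + ")"
    if isinstance(rule, Or):
        return "(" + "|".join(serialize_rule(c) for c in rule.children) + ")"
    raise TypeError(f"not a rule node: {rule!r}")


def required_questions(rule: Rule) -> frozenset[QuestionId]:
    """Question atoms a rule reads; picture atoms map to Q6."""
    if isinstance(rule, Atom):
        return frozenset({rule.question})
    if isinstance(rule, PicAtom):
        return frozenset({QuestionId.Q6})
    return frozenset().union(*(required_questions(c) for c in rule.children))


# ---------------------------------------------------------------------------
# evaluation

class UnsurePolicy(str, enum.Enum):
    """How a 'not sure' response enters scoring.

    The published algorithms are phrased as "answered 'yes'", so the default
    treats 'not sure' (and unanswered items) as simply not an affirmative.
    Under ``UNSURE_AS_MISSING`` both 'not sure' and missing answers are
    unknowns and propagate through three-valued logic, surfacing as an
    ``indeterminate`` verdict when decisive.
    """

    UNSURE_AS_NOT_YES = "unsure_as_not_yes"
    UNSURE_AS_MISSING = "unsure_as_missing"


class Verdict(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INDETERMINATE = "indeterminate"


def _atom_value(
    rule: Union[Atom, PicAtom],
    resp: Respondent,
    policy: UnsurePolicy,
    applicable: frozenset[QuestionId],
) -> bool | None:
    if isinstance(rule, PicAtom):
        pic = resp.picture
        if pic.missing:
            return None if policy is UnsurePolicy.UNSURE_AS_MISSING else False
        if rule.selection == "E":
            return pic.none_selected
        return rule.selection in pic.selections
    answer = resp.answers[rule.question]
    if answer is ItemAnswer.YES:
        return True
    if policy is UnsurePolicy.UNSURE_AS_NOT_YES:
        return False
    # unsure_as_missing: non-administered items are structurally negative,
    # not unknown — the respondent had no round patches to follow up on.
    if rule.question not in applicable:
        return False
    if answer in (ItemAnswer.NOT_SURE, ItemAnswer.MISSING):
        return None
    return False


def _eval(rule: Rule, resp, policy, applicable) -> bool | None:
    if isinstance(rule, (Atom, PicAtom)):
        return _atom_value(rule, resp, policy, applicable)
    values = [_eval(c, resp, policy, applicable) for c in rule.children]
    if isinstance(rule, And):
        if any(v is False for v in values):
            return False
        return None if any(v is None for v in values) else True
    # Or / Any: Kleene disjunction
    if any(v is True for v in values):
        return True
    return None if any(v is None for v in values) else False


def evaluate(
    rule: Rule,
    resp: Respondent,
    policy: UnsurePolicy = UnsurePolicy.UNSURE_AS_NOT_YES,
    schema: QuestionnaireSchema = DEFAULT_SCHEMA,
) -> Verdict:
    """Score one respondent against one rule.

    Under the default policy the result is always positive or negative;
    ``indeterminate`` can arise only under ``UNSURE_AS_MISSING`` when an
    unknown answer is decisive.
    """
    value = _eval(rule, resp, policy, applicable_questions(resp, schema))
    if value is True:
        return Verdict.POSITIVE
    if value is False:
        return Verdict.NEGATIVE
    return Verdict.INDETERMINATE


# ---------------------------------------------------------------------------
# shipped algorithm definitions

class SourceConfidence(str, enum.Enum):
    TEXT_VERIFIED = "text_verified"
    FIGURE_TRANSCRIBED = "figure_transcribed"


class UntranscribedRuleError(RuntimeError):
    """Raised when a placeholder (untranscribed) algorithm is used."""


@dataclass(frozen=True)
class AlgorithmDef:
    algorithm_id: int
    rule: Rule | None
    description: str = ""
    source_confidence: SourceConfidence = SourceConfidence.FIGURE_TRANSCRIBED

    def __post_init__(self) -> None:
        if not 1 <= self.algorithm_id <= 9:
            raise ValueError(f"algorithm_id must be 1-9, got {self.algorithm_id}")

    @property
    def is_transcribed(self) -> bool:
        return self.rule is not None

    def require_rule(self) -> Rule:
        if self.rule is None:
            raise UntranscribedRuleError(
                f"algorithm {self.algorithm_id} has no transcribed rule; "
                "supply one in the definitions file before scoring with it"
            )
        return self.rule


#: Rules stated verbatim in the published running text; the definitions
#: file may not alter these.
TEXT_VERIFIED_RULES: dict[int, str] = {
    1: "(Q1|Q2)&Q3&any(Q3A,Q3B,Q4,Q5)",
    3: "(Q1|Q2)&Q3&Q3A&any(Q3B,Q4,Q5)",
    5: "Q3&any(Q3A,Q3B,Q4,Q5)",
}


class Label(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    EXCLUDED = "excluded"


def classify_cohort(
    algo: AlgorithmDef,
    cohort: Sequence[Respondent],
    policy: UnsurePolicy = UnsurePolicy.UNSURE_AS_NOT_YES,
    schema: QuestionnaireSchema = DEFAULT_SCHEMA,
    required: Iterable[QuestionId] | None = None,
) -> dict[str, Label]:
    """Label every respondent positive, negative or excluded.

    Respondents missing any administered item the algorithm reads are
    ``excluded`` (they leave the denominator for this algorithm only, the
    default exclusion mode).  Pass ``required`` to override the exclusion
    question set — e.g. the union over all algorithms for a global mode.
    An ``indeterminate`` verdict (possible only under ``UNSURE_AS_MISSING``)
    also maps to ``excluded``.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rule = algo.require_rule()
    needed = frozenset(required) if required is not None else required_questions(rule)
    if not needed:
        raise ValueError(f"algorithm {algo.algorithm_id} references no questions")
    out: dict[str, Label] = {}
    counts = {Label.POSITIVE: 0, Label.NEGATIVE: 0, Label.EXCLUDED: 0}
    for resp in cohort:
        if not is_evaluable(resp, needed, schema):
            label = Label.EXCLUDED
        else:
            verdict = evaluate(rule, resp, policy, schema)
            label = (
                Label.POSITIVE if verdict is Verdict.POSITIVE
                else Label.NEGATIVE if verdict is Verdict.NEGATIVE
                else Label.EXCLUDED
            )
        out[resp.id] = label
        counts[label] += 1
    log.info(
        "algorithm %d: %d positive, %d negative, %d excluded of %d",
        algo.algorithm_id, counts[Label.POSITIVE], counts[Label.NEGATIVE],
        counts[Label.EXCLUDED], len(cohort),
    )
    return out


def builtin_algorithms(definitions_file: str | Path | None = None) -> list[AlgorithmDef]:
    """Load the nine shipped algorithm definitions.

    The file is a JSON array of ``{"id", "rule", "description",
    "source_confidence"}``; ``rule`` may be null for the untranscribed
    figure-only algorithms.  Algorithms 1, 3 and 5 must structurally equal
    the text-verified rules — an edited entry is an error, not a warning.
    """
    if definitions_file is None:
        raw = resources.files("altoscreen").joinpath("data/algorithms.json").read_text()
    else:
        raw = Path(definitions_file).read_text()
    entries = json.loads(raw)
    defs: dict[int, AlgorithmDef] = {}
    for entry in entries:
        aid = int(entry["id"])
        if aid in defs:
            raise ValueError(f"duplicate algorithm id {aid}")
        rule_text = entry.get("rule")
        rule = parse_rule(rule_text) if rule_text else None
        defs[aid] = AlgorithmDef(
            algorithm_id=aid,
            rule=rule,
            description=entry.get("description", ""),
            source_confidence=SourceConfidence(
                entry.get("source_confidence", "figure_transcribed")
            ),
        )
    if set(defs) != set(range(1, 10)):
        missing = sorted(set(range(1, 10)) - set(defs))
        raise ValueError(f"definitions file must define ids 1-9; missing {missing}")
    for aid, text in TEXT_VERIFIED_RULES.items():
        expected = parse_rule(text)
        if defs[aid].rule != expected:
            raise ValueError(
                f"algorithm {aid} is text-verified and must equal "
                f"{serialize_rule(expected)!r}"
            )
        if defs[aid].source_confidence is not SourceConfidence.TEXT_VERIFIED:
            raise ValueError(f"algorithm {aid} must be marked text_verified")
    return [defs[i] for i in range(1, 10)]
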