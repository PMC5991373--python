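import itertools
import json

import numpy as np
import pytest

from altoscreen.instrument import ItemAnswer, PictureAnswer, QuestionId
from altoscreen.rules import (
    Any,
    Atom,
    Label,
    RuleSyntaxError,
    TEXT_VERIFIED_RULES,
    UnsurePolicy,
    UntranscribedRuleError,
    Verdict,
    builtin_algorithms,
    classify_cohort,
    evaluate,
    parse_rule,
    required_questions,
    serialize_rule,
)
from conftest import make_respondent
from helpers import naive_eval

ANSWER_CELLS = ("yes", "no", "not_sure", "")


def respondent_from_assignment(items: dict[str, str], q6: str = "") -> object:
    """Respondent for a raw answer assignment (skip logic applied on entry)."""
    return make_respondent(**{k.lower(): v for k, v in items.items()}, q6=q6)


def truth_for(resp) -> dict:
    """Atom truth table under the default policy: only 'yes' is true."""
    truth = {
        q.value: resp.answers[q] is ItemAnswer.YES
        for q in QuestionId if q is not QuestionId.Q6
    }
    pic = resp.picture
    for letter in "ABCD":
        truth[f"pic:{letter}"] = (not pic.missing) and letter in pic.selections
    truth["pic:E"] = (not pic.missing) and pic.none_selected
    return truth


class TestParser:
    @pytest.mark.parametrize("text", list(TEXT_VERIFIED_RULES.values()) + [
        "Q3", "pic(C)", "any(Q4)", "(Q1|pic(E))&Q2", "Q1 | Q2 & Q3",
    ])
    def test_round_trips_through_canonical_serializer(self, text):
        tree = parse_rule(text)
        assert parse_rule(serialize_rule(tree)) == tree

    def test_algorithm1_tree_shape(self):
        tree = parse_rule("(Q1|Q2)&Q3&any(Q3A,Q3B,Q4,Q5)")
        assert tree.children[1] == Atom(QuestionId.Q3)
        assert isinstance(tree.children[2], Any)
        assert len(tree.children[2].children) == 4

    def test_and_binds_tighter_than_or(self):
        tree = parse_rule("Q1|Q2&Q3")
        assert serialize_rule(tree) == "(Q1|(Q2&Q3))"

    def test_single_atom(self):
        assert parse_rule("Q3") == Atom(QuestionId.Q3)

    @pytest.mark.parametrize("text,pos", [("Q1 &", 4), ("(Q1|Q2", 6), ("foo", 0)])
    def test_syntax_errors_carry_position(self, text, pos):
        with pytest.raises(RuleSyntaxError) as err:
            parse_rule(text)
        assert err.value.position == pos

    def test_unknown_atom_rejected(self):
        with pytest.raises(RuleSyntaxError, match="unknown atom"):
            parse_rule("Q1&Q9")

    def test_any_of_one_equals_bare_atom_under_evaluation(self):
        """any(Q4) and Q4 agree on every possible respondent."""
        wrapped, bare = parse_rule("any(Q4)"), parse_rule("Q4")
        for q4 in ANSWER_CELLS:
            resp = make_respondent(q4=q4)
            for policy in UnsurePolicy:
                assert evaluate(wrapped, resp, policy) == evaluate(bare, resp, policy)


class TestRequiredQuestions:
    def test_algorithm_5_reads_q3_block(self, algorithms):
        assert required_questions(algorithms[5].rule) == frozenset(
            {QuestionId.Q3, QuestionId.Q3A, QuestionId.Q3B, QuestionId.Q4, QuestionId.Q5}
        )

    def test_algorithm_1_reads_everything_but_picture(self, algorithms):
        assert required_questions(algorithms[1].rule) == frozenset(
            set(QuestionId) - {QuestionId.Q6}
        )

    def test_picture_atom_maps_to_q6(self):
        assert required_questions(parse_rule("pic(C)")) == frozenset({QuestionId.Q6})


class TestEvaluate:
    def test_algorithm_5_positive_on_q3_plus_q4(self, algorithms):
        resp = make_respondent(q3="yes", q3a="no", q3b="no", q4="yes", q5="no")
        assert evaluate(algorithms[5].rule, resp) is Verdict.POSITIVE

    def test_all_no_respondent_is_negative_for_every_rule(self, transcribed):
        resp = make_respondent(q1="no", q2="no", q3="no", q4="no", q5="no", q6="E")
        for algo in transcribed:
            assert evaluate(algo.rule, resp) is Verdict.NEGATIVE

    def test_algorithm_3_requires_affirmative_regrowth(self, algorithms):
        resp = make_respondent(q1="yes", q3="yes", q3a="not_sure", q3b="yes")
        assert evaluate(algorithms[3].rule, resp) is Verdict.NEGATIVE

    def test_default_policy_never_indeterminate(self, transcribed):
        rng = np.random.default_rng(7)
        cells = list(ANSWER_CELLS)
        for _ in range(300):
            resp = make_respondent(
                **{k: cells[rng.integers(4)] for k in ("q1", "q2", "q3", "q3a", "q3b", "q4", "q5")}
            )
            for algo in transcribed:
                assert evaluate(algo.rule, resp) is not Verdict.INDETERMINATE

    def test_unsure_as_missing_flags_decisive_unknowns(self, algorithms):
        resp = make_respondent(q3="yes", q3a="not_sure", q3b="no", q4="no", q5="no")
        assert (
            evaluate(algorithms[5].rule, resp, UnsurePolicy.UNSURE_AS_MISSING)
            is Verdict.INDETERMINATE
        )
        # a decided disjunct overrides the unknown
        resp2 = make_respondent(q3="yes", q3a="not_sure", q3b="no", q4="yes", q5="no")
        assert (
            evaluate(algorithms[5].rule, resp2, UnsurePolicy.UNSURE_AS_MISSING)
            is Verdict.POSITIVE
        )

    def test_picture_atoms(self):
        rule = parse_rule("pic(C)|pic(E)")
        assert evaluate(rule, make_respondent(q6="C")) is Verdict.POSITIVE
        assert evaluate(rule, make_respondent(q6="E")) is Verdict.POSITIVE
        assert evaluate(rule, make_respondent(q6="A;B")) is Verdict.NEGATIVE
        assert evaluate(rule, make_respondent(q6="none")) is Verdict.NEGATIVE


def test_truth_table_equivalence_against_naive_evaluator(transcribed):
    """Exhaustive sweep of the main-item assignment space vs a naive oracle."""
    main = ("q1", "q2", "q3", "q4", "q5")
    for combo in itertools.product(ANSWER_CELLS, repeat=5):
        base = dict(zip(main, combo))
        followups = (
            itertools.product(ANSWER_CELLS, repeat=2)
            if base["q3"] == "yes" else [("", "")]
        )
        for q3a, q3b in followups:
            resp = make_respondent(**base, q3a=q3a, q3b=q3b)
            truth = truth_for(resp)
            for algo in transcribed:
                expected = Verdict.POSITIVE if naive_eval(algo.rule, truth) else Verdict.NEGATIVE
                assert evaluate(algo.rule, resp) is expected


def test_monotone_rules_never_lose_positivity_when_an_answer_turns_yes(transcribed):
    rng = np.random.default_rng(11)
    items = ("q1", "q2", "q3", "q3a", "q3b", "q4", "q5")
    for _ in range(150):
        base = {k: ANSWER_CELLS[rng.integers(4)] for k in items}
        resp = make_respondent(**base)
        flip = items[rng.integers(7)]
        flipped = make_respondent(**{**base, flip: "yes"})
        for algo in transcribed:
            before = evaluate(algo.rule, resp)
            after = evaluate(algo.rule, flipped)
            assert not (before is Verdict.POSITIVE and after is Verdict.NEGATIVE)


class TestClassifyCohort:
    def test_labels_partition_the_cohort(self, algorithms, default_cohort):
        labels = classify_cohort(algorithms[1], default_cohort)
        assert set(labels) == {r.id for r in default_cohort}
        assert set(labels.values()) <= set(Label)

    def test_fully_missing_respondent_is_excluded(self, algorithms):
        labels = classify_cohort(algorithms[5], [make_respondent()])
        assert labels == {"r1": Label.EXCLUDED}

    def test_algorithm3_positives_subset_of_algorithm1(self, algorithms, default_cohort):
        """Algorithm 3 strictly strengthens algorithm 1's condition."""
        l1 = classify_cohort(algorithms[1], default_cohort)
        l3 = classify_cohort(algorithms[3], default_cohort)
        pos3 = {i for i, v in l3.items() if v is Label.POSITIVE}
        pos1 = {i for i, v in l1.items() if v is Label.POSITIVE}
        assert pos3 <= pos1
        assert len(pos3) < len(pos1)

    def test_algorithm5_positive_count_near_published(self, algorithms, default_cohort):
        """Screen-positive count within 3 binomial SDs of the published 84/239."""
        labels = classify_cohort(algorithms[5], default_cohort)
        n_pos = sum(1 for v in labels.values() if v is Label.POSITIVE)
        p = 84 / 239
        sd = (239 * p * (1 - p)) ** 0.5
        assert abs(n_pos - 84) <= 3 * sd

    def test_placeholder_algorithm_raises(self, algorithms, default_cohort):
        with pytest.raises(UntranscribedRuleError, match="algorithm 2"):
            classify_cohort(algorithms[2], default_cohort)

    def test_empty_cohort_rejected(self, algorithms):
        with pytest.raises(ValueError):
            classify_cohort(algorithms[1], [])


class TestBuiltinAlgorithms:
    def test_default_file_ships_nine_definitions(self, algorithms):
        assert sorted(algorithms) == list(range(1, 10))
        assert {i for i, a in algorithms.items() if a.is_transcribed} == {1, 3, 5}
        for i in (1, 3, 5):
            assert algorithms[i].source_confidence.value == "text_verified"

    def _entries(self):
        return [
            {"id": i, "rule": TEXT_VERIFIED_RULES.get(i),
             "source_confidence": "text_verified" if i in TEXT_VERIFIED_RULES
             else "figure_transcribed"}
            for i in range(1, 10)
        ]

    def test_missing_id_is_an_error(self, tmp_path):
        entries = [e for e in self._entries() if e["id"] != 7]
        path = tmp_path / "defs.json"
        path.write_text(json.dumps(entries))
        with pytest.raises(ValueError, match="missing \\[7\\]"):
            builtin_algorithms(path)

    def test_edited_text_verified_rule_is_an_error(self, tmp_path):
        entries = self._entries()
        entries[4]["rule"] = "Q3&Q4"  # algorithm 5 tampered
        path = tmp_path / "defs.json"
        path.write_text(json.dumps(entries))
        with pytest.raises(ValueError, match="algorithm 5"):
            builtin_algorithms(path)

    def test_duplicate_id_is_an_error(self, tmp_path):
        entries = self._entries() + [{"id": 1, "rule": "Q3"}]
        path = tmp_path / "defs.json"
        path.write_text(json.dumps(entries))
        with pytest.raises(ValueError, match="duplicate"):
            builtin_algorithms(path)

    def test_transcribing_a_placeholder_is_allowed(self, tmp_path):
        entries = self._entries()
        entries[1]["rule"] = "(Q1|Q2)&Q3"  # a transcription for algorithm 2
        path = tmp_path / "defs.json"
        path.write_text(json.dumps(entries))
        algos = {a.algorithm_id: a for a in builtin_algorithms(path)}
        assert algos[2].is_transcribed
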