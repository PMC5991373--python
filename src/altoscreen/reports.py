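"""Machine- and human-readable report tables.

Every report is written twice: a CSV meant for golden-file comparison and
downstream tooling, and an aligned text rendering for reading.  Formatting
of estimates is ``point (lower, upper)`` in percent to one decimal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort_stats import Table1Report
from .diagnostics import DiagnosticSummary, round_pct_frac
from .instrument import (
    DiagnosisClass,
    ItemAnswer,
    PICTURE_LETTERS,
    QuestionId,
    Respondent,
)

__all__ = [
    "table2_frame", "table3_frame", "table1_frame",
    "write_csv_and_text",
]

_CLASS_ORDER = (
    DiagnosisClass.TOTALIS_UNIVERSALIS,
    DiagnosisClass.PATCHY,
    DiagnosisClass.OTHER_HAIR_LOSS,
)

_ITEM_ROWS: tuple[tuple[QuestionId, str], ...] = (
    (QuestionId.Q1, "Diagnosed by dermatologist"),
    (QuestionId.Q2, "Diagnosed by non-dermatologist"),
    (QuestionId.Q3, "Round areas of HL on face/scalp"),
    (QuestionId.Q3A, "Hair grew back"),
    (QuestionId.Q3B, "HL lasted longer than 6 months"),
    (QuestionId.Q4, "Complete HL on scalp"),
    (QuestionId.Q5, "Complete HL on head and body"),
)

#: Items aggregated by the "yes to at least one" row; configurable because
#: the publication does not define which items its aggregate row spans.
DEFAULT_AGGREGATE_ITEMS = (
    QuestionId.Q1, QuestionId.Q2, QuestionId.Q3, QuestionId.Q4, QuestionId.Q5,
)


def table2_frame(
    cohort: Sequence[Respondent],
    aggregate_items: Iterable[QuestionId] = DEFAULT_AGGREGATE_ITEMS,
) -> pd.DataFrame:
    """Per-question yes counts by diagnosis class (tidy layout).

    Denominators are per-row: non-missing answers among administered
    respondents (so the Q3 follow-ups are counted among Q3='yes' answerers
    only), picture letters among picture completers.  The aggregate row
    counts respondents with at least one 'yes' among ``aggregate_items``
    over the full class size.
    """
    by_class = {c: [r for r in cohort if r.diagnosis.cls is c] for c in _CLASS_ORDER}
    rows = []

    def add(item: str, cls: DiagnosisClass, count: int, denom: int) -> None:
        rows.append(
            {
                "item": item,
                "diagnosis_class": cls.value,
                "count": count,
                "denominator": denom,
                "pct": round_pct_frac(count, denom) if denom else float("nan"),
            }
        )

    for qid, label in _ITEM_ROWS:
        for cls, members in by_class.items():
            if qid in (QuestionId.Q3A, QuestionId.Q3B):
                pool = [r for r in members if r.answers[QuestionId.Q3] is ItemAnswer.YES]
            else:
                pool = members
            answered = [r for r in pool if r.answers[qid] is not ItemAnswer.MISSING]
            yes = sum(1 for r in answered if r.answers[qid] is ItemAnswer.YES)
            add(label, cls, yes, len(answered))
    for cls, members in by_class.items():
        hit = sum(
            1 for r in members
            if any(r.answers[q] is ItemAnswer.YES for q in aggregate_items)
        )
        add("Yes to one above", cls, hit, len(members))
    for letter in PICTURE_LETTERS + ("E",):
        for cls, members in by_class.items():
            completers = [r for r in members if not r.picture.missing]
            if letter == "E":
                count = sum(1 for r in completers if r.picture.none_selected)
            else:
                count = sum(1 for r in completers if letter in r.picture.selections)
            add(f"Picture {letter}", cls, count, len(completers))
    return pd.DataFrame(rows)


def table3_frame(summaries: Sequence[DiagnosticSummary]) -> pd.DataFrame:
    """Classification-statistics rows in the published column layout."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "algorithm": s.algorithm_id,
                "n_positive": s.n_positive,
                "sensitivity": s.sensitivity.as_pct_row(),
                "spec": s.specificity.as_pct_row(),
                "ppv": s.ppv.as_pct_row() if s.ppv else "undefined",
                "npv": s.npv.as_pct_row() if s.npv else "undefined",
            }
        )
    return pd.DataFrame(
        rows, columns=["algorithm", "n_positive", "sensitivity", "spec", "ppv", "npv"]
    )


def table1_frame(report: Table1Report) -> pd.DataFrame:
    """Participant characteristics in the published row order."""
    cols = ["overall"] + [c.value for c in _CLASS_ORDER] + ["p_value"]
    total = sum(report.class_sizes.values())

    def fmt_ms(ms: tuple[float, float]) -> str:
        return f"{ms[0]:.1f} ({ms[1]:.1f})"

    def fmt_p(p: float | None) -> str:
        if p is None:
            return "degenerate"
        return "<0.001" if p < 0.001 else f"{p:.3f}"

    rows: dict[str, list[str]] = {}
    rows["n"] = [str(total)] + [str(report.class_sizes[c]) for c in _CLASS_ORDER] + [""]
    rows["Age, mean (SD)"] = (
        [fmt_ms(report.overall_age_mean_sd)]
        + [fmt_ms(report.age_mean_sd[c]) for c in _CLASS_ORDER]
        + [fmt_p(report.age_p)]
    )
    sex = report.sex_table.array
    female = sex[0]
    rows["Female, n (%)"] = (
        [f"{female.sum()} ({round_pct_frac(int(female.sum()), int(sex.sum())):.1f})"]
        + [
            f"{female[j]} ({round_pct_frac(int(female[j]), int(sex[:, j].sum())):.1f})"
            if sex[:, j].sum() else "0"
            for j in range(sex.shape[1])
        ]
        + [fmt_p(report.sex_p)]
    )
    race = report.race_table.array
    for i, label in enumerate(report.race_table.row_labels):
        rows[label.replace("_", " ").title()] = (
            [f"{race[i].sum()} ({round_pct_frac(int(race[i].sum()), int(race.sum())):.1f})"]
            + [
                f"{race[i, j]} ({round_pct_frac(int(race[i, j]), int(race[:, j].sum())):.1f})"
                if race[:, j].sum() else "0"
                for j in range(race.shape[1])
            ]
            + ([fmt_p(report.race_p)] if i == 0 else [""])
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def write_csv_and_text(frame: pd.DataFrame, out_dir: str | Path, stem: str,
                       index: bool = False) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` and an aligned ``<stem>.txt``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    txt_path = out / f"{stem}.txt"
    frame.to_csv(csv_path, index=index)
    txt_path.write_text(frame.to_string(index=index) + "\n")
    return csv_path, txt_path
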