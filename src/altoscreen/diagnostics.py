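"""Diagnostic-accuracy evaluation with exact binomial confidence intervals.

Sensitivity, specificity, PPV and NPV are empirical cohort proportions with
Clopper-Pearson ("exact") 95% intervals in the beta-quantile form::

    lower = Beta(alpha/2;   k,   n-k+1),   0 when k = 0
    upper = Beta(1-alpha/2; k+1, n-k),     1 when k = n

The module also inverts the usual reporting direction: given a published
sensitivity/specificity pair rounded to one decimal percent and the two
gold-standard group sizes, :func:`reconstruct_confusion` enumerates every
integer confusion matrix consistent with the printed values, which lets the
printed PPV, NPV and screen-positive counts be verified exactly.

Printed-table matching uses half-away-from-zero rounding to one decimal on
the percent scale (the convention of the mainstream commercial statistics
packages), computed in integer arithmetic so float representation can never
flip a boundary case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .instrument import DEFAULT_SCHEMA, Diagnosis, QuestionnaireSchema, Respondent
from .rules import AlgorithmDef, Label, UnsurePolicy, classify_cohort

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix", "ProportionCI", "DiagnosticSummary",
    "round_pct_frac", "round_pct",
    "confusion", "clopper_pearson", "summarize",
    "reconstruct_confusion", "table3_report",
]


def round_pct_frac(numerator: int, denominator: int) -> float:
    """``numerator/denominator`` as a percent, half-away-from-zero to 1 dp.

    Exact integer arithmetic: floor(1000*k/n + 1/2) / 10.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return ((2000 * numerator + denominator) // (2 * denominator)) / 10


def round_pct(x: float, decimals: int = 1) -> float:
    """Round a percent value half-away-from-zero to ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProportionCI:
    """An empirical proportion with its exact binomial interval."""

    numerator: int
    denominator: int
    lower: float
    upper: float
    alpha: float = 0.05

    @property
    def point(self) -> float:
        return self.numerator / self.denominator

    def as_pct_row(self) -> str:
        """``point (lower, upper)`` in percent to one decimal."""
        return (
            f"{round_pct_frac(self.numerator, self.denominator):.1f} "
            f"({round_pct(100 * self.lower):.1f}, {round_pct(100 * self.upper):.1f})"
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """One report row: screen-positive count and the four test characteristics."""

    algorithm_id: int
    n_positive: int
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI | None
    npv: ProportionCI | None
    n_excluded: int = 0


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> ProportionCI:
    """Exact (Clopper-Pearson) confidence interval for ``k`` successes in ``n``."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(numerator=k, denominator=n, lower=lower, upper=upper, alpha=alpha)


def confusion(
    labels: Mapping[str, Label],
    gold: Mapping[str, Diagnosis],
) -> ConfusionMatrix:
    """Cross the screen labels with the gold standard.

    Excluded respondents contribute to no cell; gold-positive means an AA
    diagnosis (totalis/universalis or patchy).
    """
    tp = fp = tn = fn = 0
    for rid, label in labels.items():
        if rid not in gold:
            raise KeyError(f"id {rid!r} labeled but absent from gold standard")
        if label is Label.EXCLUDED:
            continue
        aa = gold[rid].is_aa
        if label is Label.POSITIVE:
            tp, fp = tp + aa, fp + (not aa)
        else:
            fn, tn = fn + aa, tn + (not aa)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def summarize(cm: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticSummary:
    """Sensitivity/specificity/PPV/NPV with exact intervals for one matrix.

    PPV (NPV) is ``None`` when no respondent screened positive (negative);
    algorithm_id is 0 here and overwritten by :func:`table3_report`.
    """
    if cm.n_case < 1 or cm.n_control < 1:
        raise ValueError("both gold classes must be non-empty")
    return DiagnosticSummary(
        algorithm_id=0,
        n_positive=cm.n_positive,
        sensitivity=clopper_pearson(cm.tp, cm.n_case, alpha),
        specificity=clopper_pearson(cm.tn, cm.n_control, alpha),
        ppv=clopper_pearson(cm.tp, cm.n_positive, alpha) if cm.n_positive else None,
        npv=clopper_pearson(cm.tn, cm.tn + cm.fn, alpha) if cm.tn + cm.fn else None,
    )


def reconstruct_confusion(
    sens_pct: float,
    spec_pct: float,
    n_case: int,
    n_control: int,
) -> list[ConfusionMatrix]:
    """Every integer confusion matrix consistent with printed summaries.

    Searches all ``tp in [0, n_case]`` and ``tn in [0, n_control]`` whose
    sensitivity and specificity, rounded half-away-from-zero to one decimal
    percent, equal the inputs.  An empty list means the printed pair is
    inconsistent with the stated group sizes.  Ordered by (tp, tn).
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= sens_pct <= 100 and 0 <= spec_pct <= 100):
        raise ValueError("percents must lie in [0, 100]")

    def matches(n: int, target: float) -> np.ndarray:
        k = np.arange(n + 1, dtype=np.int64)
        tenths = (2000 * k + n) // (2 * n)  # floor(1000k/n + 1/2)
        return k[np.abs(tenths / 10 - target) < 1e-9]

    tps = matches(n_case, sens_pct)
    tns = matches(n_control, spec_pct)
    return [
        ConfusionMatrix(tp=int(tp), fn=n_case - int(tp),
                        tn=int(tn), fp=n_control - int(tn))
        for tp in tps for tn in tns
    ]


def table3_report(
    cohort: Sequence[Respondent],
    algos: Sequence[AlgorithmDef],
    policy: UnsurePolicy = UnsurePolicy.UNSURE_AS_NOT_YES,
    alpha: float = 0.05,
    schema: QuestionnaireSchema = DEFAULT_SCHEMA,
    exclusion_mode: str = "per_algorithm",
) -> list[DiagnosticSummary]:
    """Classification-statistics rows, one per algorithm.

    ``exclusion_mode='per_algorithm'`` (default) drops a respondent only
    from the denominators of algorithms whose required questions they left
    unanswered; ``'global'`` drops anyone missing any question required by
    any of the supplied algorithms from every row.
    """
    if not cohort or not algos:
        raise ValueError("cohort and algorithm list must be non-empty")
    if exclusion_mode not in ("per_algorithm", "global"):
        raise ValueError(f"unknown exclusion mode {exclusion_mode!r}")
    required = None
    if exclusion_mode == "global":
        from .rules import required_questions
        required = frozenset().union(
            *(required_questions(a.require_rule()) for a in algos)
        )
    gold = {r.id: r.diagnosis for r in cohort}
    rows: list[DiagnosticSummary] = []
    for algo in algos:
        labels = classify_cohort(algo, cohort, policy, schema, required=required)
        n_excluded = sum(1 for v in labels.values() if v is Label.EXCLUDED)
        log.info("algorithm %d: %d excluded", algo.algorithm_id, n_excluded)
        cm = confusion(labels, gold)
        summary = summarize(cm, alpha)
        rows.append(
            DiagnosticSummary(
                algorithm_id=algo.algorithm_id,
                n_positive=summary.n_positive,
                sensitivity=summary.sensitivity,
                specificity=summary.specificity,
                ppv=summary.ppv,
                npv=summary.npv,
                n_excluded=n_excluded,
            )
        )
    return rows
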