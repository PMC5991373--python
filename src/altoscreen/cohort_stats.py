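"""Group-comparison statistics for the pilot-cohort demographics table.

Age is compared across the three diagnosis classes with classical one-way
ANOVA; categorical composition (sex, race) with Fisher's exact test in its
r x c generalization (Freeman-Halton): the p-value is the total probability,
under the margin-fixed multivariate hypergeometric null, of every table at
most as probable as the observed one.  Pairwise comparisons carry a Sidak
multiplicity adjustment, 1 - (1-p)^m.

The Freeman-Halton test is computed by *full enumeration* of the table
support (no asymptotics, no hybrid approximation): the recursion walks rows
of the margin-fixed polytope and the two innermost rows are evaluated
vectorized.  A permutation Monte-Carlo estimate is available for tables too
large to enumerate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import f as f_dist
from scipy.stats import ttest_ind

from .instrument import DiagnosisClass, Race, Respondent, Sex

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable", "GroupSamples", "AnovaResult", "Table1Report",
    "EnumerationBoundError", "DegenerateDataError",
    "fisher_exact", "one_way_anova", "sidak_adjust", "table1_report",
]

_LOG_SLACK = 1e-12  # tables within this log-probability slack count as "as extreme"


class EnumerationBoundError(ValueError):
    """Table too large for exact enumeration; use method='monte_carlo'."""


class DegenerateDataError(ValueError):
    """No variance to test (e.g. all observations identical)."""


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("counts must be a non-empty 2-D grid")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() < 1:
            raise ValueError("grand total must be >= 1")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class GroupSamples:
    """Labeled numeric observations, one entry per group."""

    groups: tuple[tuple[str, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if any(len(obs) < 1 for _, obs in self.groups):
            raise ValueError("every group needs at least one observation")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.array
    return np.asarray(table, dtype=np.int64)


def fisher_exact(
    table,
    method: str = "enumerate",
    max_total: int = 500,
    n_resamples: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Freeman-Halton exact test for an r x c contingency table.

    Returns the probability-ordering p-value: the sum of the probabilities
    of all margin-fixed tables whose hypergeometric probability does not
    exceed the observed table's (within 1e-12 log slack).  With
    ``method='monte_carlo'`` a permutation estimate replaces enumeration.
    """
    arr = _as_array(table)
    if arr.ndim != 2 or (arr < 0).any():
        raise ValueError("table must be a 2-D grid of non-negative counts")
    # zero-margin rows/columns carry no information
    arr = arr[arr.sum(axis=1) > 0][:, arr.sum(axis=0) > 0]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 1.0
    total = int(arr.sum())

    if method == "monte_carlo":
        return _fisher_monte_carlo(arr, n_resamples, rng)
    if method != "enumerate":
        raise ValueError(f"unknown method {method!r}")
    if total > max_total:
        raise EnumerationBoundError(
            f"grand total {total} exceeds the enumeration bound {max_total}; "
            "call fisher_exact(..., method='monte_carlo')"
        )

    # fewer columns -> smaller innermost grids; big rows last -> they are
    # handled in the vectorized tail instead of the Python recursion
    if arr.shape[1] > arr.shape[0]:
        arr = arr.T
    arr = arr[np.argsort(arr.sum(axis=1)), :]

    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    nr, nc = arr.shape
    lf = gammaln(np.arange(total + 2) + 1.0)  # lf[k] = log k!
    const = lf[rows].sum() + lf[cols].sum() - lf[total]
    obs = const - lf[arr].sum()
    thresh = obs + _LOG_SLACK

    tail_dims = [int(min(rows[nr - 2], c)) + 1 for c in cols[:-1]]
    if float(np.prod(tail_dims)) > 4e6:
        raise EnumerationBoundError(
            "margin structure too large for enumeration; "
            "call fisher_exact(..., method='monte_carlo')"
        )

    p_total = 0.0

    def tail(colrem: np.ndarray, acc: float) -> None:
        """Sum over the last two rows given remaining column margins."""
        nonlocal p_total
        r_pen = int(rows[nr - 2])
        grids = np.meshgrid(
            *[np.arange(min(r_pen, int(colrem[j])) + 1) for j in range(nc - 1)],
            indexing="ij", sparse=True,
        )
        x_last = r_pen - sum(grids)
        valid = (x_last >= 0) & (x_last <= int(colrem[-1]))
        x_last_c = np.clip(x_last, 0, int(colrem[-1]))
        lp = acc - lf[x_last_c] - lf[int(colrem[-1]) - x_last_c]
        for j, g in enumerate(grids):
            lp = lp - lf[g] - lf[int(colrem[j]) - g]
        mask = valid & (lp <= thresh)
        if mask.any():
            p_total += float(np.exp(lp[mask]).sum())

    def rec(i: int, colrem: np.ndarray, acc: float) -> None:
        if i == nr - 2:
            tail(colrem, acc)
            return
        r = int(rows[i])

        def cells(j: int, rem: int, sub: np.ndarray, acc2: float) -> None:
            if j == nc - 1:
                if rem <= sub[-1]:
                    nxt = sub.copy()
                    nxt[-1] -= rem
                    rec(i + 1, nxt, acc2 - lf[rem])
                return
            hi = min(rem, int(sub[j]))
            lo = max(0, rem - int(sub[j + 1:].sum()))
            for x in range(lo, hi + 1):
                nxt = sub.copy()
                nxt[j] -= x
                cells(j + 1, rem - x, nxt, acc2 - lf[x])

        cells(0, r, colrem, acc)

    rec(0, cols.copy(), const)
    return min(p_total, 1.0)


def _fisher_monte_carlo(
    arr: np.ndarray, n_resamples: int, rng: np.random.Generator | None
) -> float:
    rng = np.random.default_rng(rng)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    total = int(arr.sum())
    nr, nc = arr.shape
    lf = gammaln(np.arange(total + 2) + 1.0)
    const = lf[rows].sum() + lf[cols].sum() - lf[total]
    obs = const - lf[arr].sum()
    row_of = np.repeat(np.arange(nr), rows)
    col_of = np.repeat(np.arange(nc), cols)
    hits = 0
    for _ in range(n_resamples):
        counts = np.bincount(
            row_of * nc + rng.permutation(col_of), minlength=nr * nc
        )
        if const - lf[counts].sum() <= obs + _LOG_SLACK:
            hits += 1
    return (hits + 1) / (n_resamples + 1)


def one_way_anova(samples) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition).

    Accepts a :class:`GroupSamples` or a plain sequence of observation
    sequences.  Raises :class:`DegenerateDataError` when the within-group
    variance is zero (the F statistic is then undefined or infinite).
    """
    if isinstance(samples, GroupSamples):
        groups = [np.asarray(obs, dtype=float) for _, obs in samples.groups]
    else:
        groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            raise DegenerateDataError("all observations identical; F undefined")
        raise DegenerateDataError("zero within-group variance; p degenerate")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(f_dist.sf(f_stat, df_between, df_within))
    return AnovaResult(float(f_stat), p, df_between, df_within)


def sidak_adjust(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Sidak multiplicity adjustment: ``1 - (1-p)^m``, capped at 1."""
    p_arr = np.asarray(p_values, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p_arr)
    if m < len(p_arr):
        raise ValueError("m must be at least the number of p-values")
    return [float(min(1.0, -np.expm1(m * np.log1p(-p)))) if p < 1 else 1.0
            for p in p_arr]


_CLASS_ORDER = (
    DiagnosisClass.TOTALIS_UNIVERSALIS,
    DiagnosisClass.PATCHY,
    DiagnosisClass.OTHER_HAIR_LOSS,
)
_RACE_ORDER = (Race.WHITE, Race.AFRICAN_AMERICAN, Race.HISPANIC, Race.ASIAN, Race.OTHER)


@dataclass
class Table1Report:
    """Participant-characteristics summary across the diagnosis classes."""

    class_sizes: dict[DiagnosisClass, int]
    age_mean_sd: dict[DiagnosisClass, tuple[float, float]]
    overall_age_mean_sd: tuple[float, float]
    sex_table: ContingencyTable
    race_table: ContingencyTable
    age_p: float | None  # None when ANOVA is degenerate
    sex_p: float
    race_p: float
    pairwise_age: dict[tuple[DiagnosisClass, DiagnosisClass], tuple[float, float]] = field(
        default_factory=dict
    )  # (raw p, Sidak-adjusted p)
    degenerate_age: bool = False


def table1_report(
    cohort: Sequence[Respondent],
    fisher_method: str = "enumerate",
    pairwise_m: int = 3,
) -> Table1Report:
    """Demographics by diagnosis class with overall and pairwise tests.

    Percent denominators follow the known values only (unknown age, sex or
    race never excludes a respondent from anything else).  Pairwise age
    contrasts are Welch t tests, Sidak-adjusted for ``pairwise_m``
    comparisons.  Classes with no respondents are reported with n=0 but
    excluded from every test.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    sizes = {c: 0 for c in _CLASS_ORDER}
    ages: dict[DiagnosisClass, list[float]] = {c: [] for c in _CLASS_ORDER}
    sex_counts = {c: {Sex.FEMALE: 0, Sex.MALE: 0} for c in _CLASS_ORDER}
    race_counts = {c: {r: 0 for r in _RACE_ORDER} for c in _CLASS_ORDER}
    for resp in cohort:
        c = resp.diagnosis.cls
        sizes[c] += 1
        if resp.age is not None:
            ages[c].append(float(resp.age))
        if resp.sex is not Sex.UNKNOWN:
            sex_counts[c][resp.sex] += 1
        if resp.race is not Race.UNKNOWN:
            race_counts[c][resp.race] += 1

    present = [c for c in _CLASS_ORDER if sizes[c] > 0]
    all_ages = [a for c in present for a in ages[c]]

    def mean_sd(x: Sequence[float]) -> tuple[float, float]:
        if not x:
            return (float("nan"), float("nan"))
        arr = np.asarray(x)
        return (float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)

    age_p: float | None
    degenerate = False
    try:
        age_p = one_way_anova([ages[c] for c in present if len(ages[c]) >= 2]).p_value
    except (DegenerateDataError, ValueError):
        age_p, degenerate = None, True

    pairwise: dict[tuple[DiagnosisClass, DiagnosisClass], tuple[float, float]] = {}
    raw_ps, pairs = [], []
    for c1, c2 in itertools.combinations(present, 2):
        if len(ages[c1]) >= 2 and len(ages[c2]) >= 2:
            if np.var(ages[c1]) == 0 and np.var(ages[c2]) == 0:
                continue  # Welch t undefined on two constant samples
            res = ttest_ind(ages[c1], ages[c2], equal_var=False)
            pairs.append((c1, c2))
            raw_ps.append(float(res.pvalue))
    if raw_ps:
        adj = sidak_adjust(raw_ps, m=max(pairwise_m, len(raw_ps)))
        pairwise = {pair: (raw, a) for pair, raw, a in zip(pairs, raw_ps, adj)}

    sex_table = ContingencyTable(
        counts=tuple(
            tuple(sex_counts[c][s] for c in present) for s in (Sex.FEMALE, Sex.MALE)
        ),
        row_labels=("female", "male"),
        col_labels=tuple(c.value for c in present),
    )
    race_table = ContingencyTable(
        counts=tuple(tuple(race_counts[c][r] for c in present) for r in _RACE_ORDER),
        row_labels=tuple(r.value for r in _RACE_ORDER),
        col_labels=tuple(c.value for c in present),
    )
    return Table1Report(
        class_sizes=sizes,
        age_mean_sd={c: mean_sd(ages[c]) for c in _CLASS_ORDER},
        overall_age_mean_sd=mean_sd(all_ages),
        sex_table=sex_table,
        race_table=race_table,
        age_p=age_p,
        sex_p=fisher_exact(sex_table, method=fisher_method),
        race_p=fisher_exact(race_table, method=fisher_method),
        pairwise_age=pairwise,
        degenerate_age=degenerate,
    )
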