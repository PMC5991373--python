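"""Seeded synthetic cohorts with the pilot study's response structure.

The published study reports only per-class marginals: class sizes (13
totalis/universalis, 46 patchy, 180 other hair loss), per-item yes
fractions by class, conditional follow-up rates given an affirmative Q3,
picture-selection fractions among item completers, item-level missing
counts and the demographic composition.  The generator reproduces exactly
those marginals:

* item answers are conditionally independent given the diagnosis class
  (the joint distribution is unidentified from printed marginals), except
  for two structural constraints — Q3A/Q3B exist only after Q3='yes'
  (skip logic), and universal body-hair loss implies complete scalp loss
  (Q5='yes' forces Q4='yes', with Q4's marginal preserved);
* missingness is missing-completely-at-random at per-class, per-item rates
  chosen to mirror the printed denominators;
* picture completers either declare no representative photograph or tick
  each photograph independently, at rates that preserve the printed
  per-photograph marginals (an answered-but-empty selection therefore has
  positive probability, as it does in the printed data);
* ages are normal, truncated at the study's eligibility floor of 18 years.

An optional per-class *dependence* parameter couples the provider-diagnosis
items (Q1/Q2) with Q3 through a shared latent uniform (comonotone for
positive values, antithetic for negative), preserving every marginal.
:func:`calibrate` hill-climbs these parameters so that simulated
algorithm-level operating points move toward published targets; because the
true joint distribution is unidentified, this is a documented
stochastic-search contract, not an optimality claim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .instrument import (
    Diagnosis,
    DiagnosisClass,
    ItemAnswer,
    PictureAnswer,
    QuestionId,
    Race,
    Respondent,
    Sex,
)

log = logging.getLogger(__name__)

__all__ = ["ClassProfile", "CohortSpec", "default_spec", "generate", "calibrate"]

_ITEMS = ("q1", "q2", "q3", "q3a", "q3b", "q4", "q5")
_LETTERS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ClassProfile:
    """Generative parameters for one diagnosis class.

    ``p_yes`` for q3a/q3b is conditional on Q3='yes'; ``picture_probs``
    are per-photograph inclusion probabilities among Q6 completers and
    ``p_picture_none`` the probability of the explicit 'none representative'
    choice.  ``missing_rates`` are per-item MCAR rates (for q3a/q3b:
    conditional on administration; ``age``/``sex``/``race`` entries give
    unknown-demographic rates).  ``dependence`` currently supports the key
    ``q12_q3`` in [-1, 1].
    """

    diagnosis_class: DiagnosisClass
    n: int
    p_yes: Mapping[str, float]
    p_not_sure: Mapping[str, float] = field(default_factory=dict)
    picture_probs: Mapping[str, float] = field(default_factory=dict)
    p_picture_none: float = 0.0
    age_mean: float = 45.0
    age_sd: float = 15.0
    p_female: float = 0.5
    race_probs: Mapping[str, float] = field(default_factory=dict)
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    dependence: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("class size must be non-negative")
        for item in _ITEMS:
            py = float(self.p_yes.get(item, 0.0))
            pns = float(self.p_not_sure.get(item, 0.0))
            if not (0 <= py <= 1 and 0 <= pns <= 1 and py + pns <= 1):
                raise ValueError(
                    f"{self.diagnosis_class.value}/{item}: invalid p_yes={py}, p_not_sure={pns}"
                )
        p4 = float(self.p_yes.get("q4", 0.0))
        p5 = float(self.p_yes.get("q5", 0.0))
        if p5 > p4:
            raise ValueError("p_yes[q5] cannot exceed p_yes[q4] (Q5 implies Q4)")
        if not 0 <= self.p_picture_none <= 1:
            raise ValueError("p_picture_none outside [0,1]")
        for key, p in {**self.picture_probs, **self.missing_rates}.items():
            if not 0 <= float(p) <= 1:
                raise ValueError(f"probability {key}={p} outside [0,1]")
        for letter in self.picture_probs:
            if letter not in _LETTERS:
                raise ValueError(f"unknown picture key {letter!r}")
        if self.p_picture_none < 1 and any(
            float(p) / (1 - self.p_picture_none) > 1 for p in self.picture_probs.values()
        ):
            raise ValueError("picture inclusion probability exceeds 1 among non-'none' completers")
        d = float(self.dependence.get("q12_q3", 0.0))
        if not -1 <= d <= 1:
            raise ValueError("dependence q12_q3 outside [-1,1]")


@dataclass(frozen=True)
class CohortSpec:
    profiles: tuple[ClassProfile, ...]
    seed: int = 0

    def validate(self) -> None:
        if not self.profiles:
            raise ValueError("spec has no class profiles")
        for p in self.profiles:
            p.validate()

    @property
    def total(self) -> int:
        return sum(p.n for p in self.profiles)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "profiles": [
                {
                    "diagnosis_class": p.diagnosis_class.value,
                    "n": p.n,
                    "label": p.label,
                    "p_yes": dict(p.p_yes),
                    "p_not_sure": dict(p.p_not_sure),
                    "picture_probs": dict(p.picture_probs),
                    "p_picture_none": p.p_picture_none,
                    "age_mean": p.age_mean,
                    "age_sd": p.age_sd,
                    "p_female": p.p_female,
                    "race_probs": dict(p.race_probs),
                    "missing_rates": dict(p.missing_rates),
                    "dependence": dict(p.dependence),
                }
                for p in self.profiles
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        profiles = tuple(
            ClassProfile(
                diagnosis_class=DiagnosisClass(d["diagnosis_class"]),
                n=int(d["n"]),
                p_yes={k: float(v) for k, v in (d.get("p_yes") or {}).items()},
                p_not_sure={k: float(v) for k, v in (d.get("p_not_sure") or {}).items()},
                picture_probs={k: float(v) for k, v in (d.get("picture_probs") or {}).items()},
                p_picture_none=float(d.get("p_picture_none", 0.0)),
                age_mean=float(d.get("age_mean", 45.0)),
                age_sd=float(d.get("age_sd", 15.0)),
                p_female=float(d.get("p_female", 0.5)),
                race_probs={k: float(v) for k, v in (d.get("race_probs") or {}).items()},
                missing_rates={k: float(v) for k, v in (d.get("missing_rates") or {}).items()},
                dependence={k: float(v) for k, v in (d.get("dependence") or {}).items()},
                label=d.get("label", ""),
            )
            for d in doc["profiles"]
        )
        spec = cls(profiles=profiles, seed=int(doc.get("seed", 0)))
        spec.validate()
        return spec


def _f(num: int, den: int) -> float:
    return float(Fraction(num, den))


def default_spec(seed: int = 0) -> CohortSpec:
    """The pilot study's generative conditions.

    Every probability is a printed numerator/denominator pair from the
    published per-class response table and demographics table: class sizes
    13/46/180; yes rates per item (conditional rates for the Q3 follow-ups);
    per-class missing rates mirroring the printed denominators (including
    the reduced follow-up denominators the publication leaves unexplained,
    and the fact that only 74/180 other-hair-loss respondents completed the
    picture item); age means/SDs, sex and race composition per class.
    """
    totalis = ClassProfile(
        diagnosis_class=DiagnosisClass.TOTALIS_UNIVERSALIS,
        n=13,
        label="alopecia totalis/universalis",
        p_yes={
            "q1": _f(13, 13), "q2": _f(5, 12), "q3": _f(13, 13),
            "q3a": _f(8, 13), "q3b": _f(10, 11),
            "q4": _f(12, 13), "q5": _f(11, 13),
        },
        picture_probs={"A": _f(4, 13), "B": _f(1, 13), "C": _f(11, 13), "D": _f(3, 13)},
        p_picture_none=0.0,
        age_mean=55.3, age_sd=12.8,
        p_female=_f(9, 13),
        race_probs={
            "white": _f(8, 11), "african_american": _f(2, 11),
            "hispanic": 0.0, "asian": _f(1, 11), "other": 0.0,
        },
        missing_rates={"q2": _f(1, 13), "q3b": _f(2, 13), "race": _f(2, 13)},
    )
    patchy = ClassProfile(
        diagnosis_class=DiagnosisClass.PATCHY,
        n=46,
        label="patchy alopecia",
        p_yes={
            "q1": _f(44, 46), "q2": _f(19, 45), "q3": _f(42, 46),
            "q3a": _f(38, 42), "q3b": _f(26, 40),
            "q4": _f(2, 45), "q5": _f(1, 46),
        },
        picture_probs={"A": _f(27, 46), "B": _f(8, 46), "C": _f(3, 46), "D": _f(35, 46)},
        p_picture_none=_f(1, 46),
        age_mean=39.8, age_sd=14.4,
        p_female=_f(37, 46),
        race_probs={
            "white": _f(25, 42), "african_american": _f(8, 42),
            "hispanic": _f(7, 42), "asian": _f(2, 42), "other": 0.0,
        },
        missing_rates={"q2": _f(1, 46), "q3b": _f(2, 42), "q4": _f(1, 46), "race": _f(4, 46)},
    )
    other = ClassProfile(
        diagnosis_class=DiagnosisClass.OTHER_HAIR_LOSS,
        n=180,
        label="other hair loss",
        p_yes={
            "q1": _f(29, 179), "q2": _f(7, 174), "q3": _f(58, 178),
            "q3a": _f(21, 55), "q3b": _f(40, 50),
            "q4": _f(7, 180), "q5": _f(6, 177),
        },
        picture_probs={"A": _f(8, 74), "B": _f(4, 74), "C": 0.0, "D": _f(30, 74)},
        p_picture_none=_f(27, 74),
        age_mean=49.5, age_sd=15.2,
        p_female=_f(167, 179),
        race_probs={
            "white": _f(123, 173), "african_american": _f(31, 173),
            "hispanic": _f(8, 173), "asian": _f(9, 173), "other": _f(2, 173),
        },
        missing_rates={
            "q1": _f(1, 180), "q2": _f(6, 180), "q3": _f(2, 180),
            "q3a": _f(3, 58), "q3b": _f(8, 58), "q5": _f(3, 180),
            "q6": _f(106, 180), "age": _f(1, 180), "sex": _f(1, 180),
            "race": _f(7, 180),
        },
    )
    spec = CohortSpec(profiles=(totalis, patchy, other), seed=seed)
    spec.validate()
    return spec


_AGE_FLOOR = 18.0  # study eligibility: adults only

_RACE_BY_NAME = {r.value: r for r in Race}


import functools


@functools.lru_cache(maxsize=64)
def _truncnorm_parent_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose >=18 truncation has the given moments.

    The published per-class age mean/SD are sample moments of adult-only
    data, so the truncated distribution — not the parent — must match them.
    Falls back to the naive parameters when no solution exists (truncation
    negligible or the solver fails).
    """
    from scipy.optimize import fsolve
    from scipy.stats import truncnorm

    def moments(params):
        mu, log_sigma = params
        sigma = float(np.exp(log_sigma))
        a = (_AGE_FLOOR - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    try:
        sol, info, ier, _ = fsolve(moments, [mean, np.log(sd)], full_output=True)
        if ier == 1:
            return float(sol[0]), float(np.exp(sol[1]))
    except Exception:  # pragma: no cover - solver pathologies only
        pass
    return mean, sd


def _truncated_normal_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    mu, sigma = _truncnorm_parent_params(mean, sd)
    out = rng.normal(mu, sigma, size=n)
    bad = out < _AGE_FLOOR
    while bad.any():
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out < _AGE_FLOOR
    return np.round(out).astype(int)


def _draw_item(
    rng: np.random.Generator, u: np.ndarray, p_yes: float, p_not_sure: float
) -> np.ndarray:
    """Map uniforms to answer codes 0=yes, 1=not_sure, 2=no."""
    out = np.full(u.shape, 2, dtype=np.int8)
    out[u < p_yes + p_not_sure] = 1
    out[u < p_yes] = 0
    return out


_CODE_TO_ANSWER = {0: ItemAnswer.YES, 1: ItemAnswer.NOT_SURE, 2: ItemAnswer.NO}


def generate(spec: CohortSpec, seed_override: int | None = None) -> list[Respondent]:
    """Draw one cohort; byte-identical across runs for a fixed seed.

    Class sizes are exact.  Skip logic holds by construction (Q3A/Q3B exist
    only after an affirmative, non-missing Q3) and Q5='yes' forces Q4='yes'
    while preserving Q4's marginal.
    """
    spec.validate()
    seed = spec.seed if seed_override is None else seed_override
    rng = np.random.default_rng(seed)
    cohort: list[Respondent] = []
    counter = 0
    for prof in spec.profiles:
        n = prof.n
        if n == 0:
            continue
        getp = lambda m, k: float(m.get(k, 0.0))  # noqa: E731
        miss = lambda k: getp(prof.missing_rates, k)  # noqa: E731

        ages = _truncated_normal_ages(rng, n, prof.age_mean, prof.age_sd)
        female = rng.random(n) < prof.p_female
        race_names = list(prof.race_probs) or ["unknown"]
        race_p = np.array([getp(prof.race_probs, r) for r in race_names], dtype=float)
        if race_p.sum() <= 0:
            race_p = np.ones(len(race_names))
        race_idx = rng.choice(len(race_names), size=n, p=race_p / race_p.sum())

        u3 = rng.random(n)
        q3 = _draw_item(rng, u3, getp(prof.p_yes, "q3"), getp(prof.p_not_sure, "q3"))

        # Q1/Q2 optionally couple to Q3 through a shared latent uniform
        d = float(prof.dependence.get("q12_q3", 0.0))
        codes: dict[str, np.ndarray] = {"q3": q3}
        for item in ("q1", "q2"):
            u = rng.random(n)
            if d != 0.0:
                share = rng.random(n) < abs(d)
                u = np.where(share, u3 if d > 0 else 1.0 - u3, u)
            codes[item] = _draw_item(rng, u, getp(prof.p_yes, item), getp(prof.p_not_sure, item))

        for item in ("q3a", "q3b"):
            codes[item] = _draw_item(
                rng, rng.random(n), getp(prof.p_yes, item), getp(prof.p_not_sure, item)
            )
        # Q5 first; Q4 conditional so that P(Q4=yes) stays at its marginal
        p4, p5 = getp(prof.p_yes, "q4"), getp(prof.p_yes, "q5")
        q5 = _draw_item(rng, rng.random(n), p5, getp(prof.p_not_sure, "q5"))
        p4_given_not5 = 0.0 if p5 >= 1.0 else (p4 - p5) / (1.0 - p5)
        q4 = _draw_item(rng, rng.random(n), p4_given_not5, getp(prof.p_not_sure, "q4"))
        q4[q5 == 0] = 0
        codes["q4"], codes["q5"] = q4, q5

        # picture: explicit 'none' choice, else independent per-photograph
        # ticks at rates preserving the completer marginals
        pic_none = rng.random(n) < prof.p_picture_none
        denom = 1.0 - prof.p_picture_none
        pic_sel = {
            letter: (~pic_none)
            & (rng.random(n) < (getp(prof.picture_probs, letter) / denom if denom > 0 else 0.0))
            for letter in _LETTERS
        }

        # missingness, MCAR per item; a missing Q3 suppresses its follow-ups
        item_missing = {item: rng.random(n) < miss(item) for item in _ITEMS}
        pic_missing = rng.random(n) < miss("q6")
        age_unknown = rng.random(n) < miss("age")
        sex_unknown = rng.random(n) < miss("sex")
        race_unknown = rng.random(n) < miss("race")

        q3_yes = (codes["q3"] == 0) & ~item_missing["q3"]
        for i in range(n):
            counter += 1
            answers: dict[QuestionId, ItemAnswer] = {}
            for item, qid in zip(
                _ITEMS,
                (QuestionId.Q1, QuestionId.Q2, QuestionId.Q3, QuestionId.Q3A,
                 QuestionId.Q3B, QuestionId.Q4, QuestionId.Q5),
            ):
                administered = item not in ("q3a", "q3b") or q3_yes[i]
                if not administered or item_missing[item][i]:
                    answers[qid] = ItemAnswer.MISSING
                else:
                    answers[qid] = _CODE_TO_ANSWER[int(codes[item][i])]
            if pic_missing[i]:
                picture = PictureAnswer(missing=True)
            elif pic_none[i]:
                picture = PictureAnswer(none_selected=True)
            else:
                picture = PictureAnswer(
                    selections=frozenset(
                        letter for letter in _LETTERS if pic_sel[letter][i]
                    )
                )
            cohort.append(
                Respondent(
                    id=f"S{counter:04d}",
                    diagnosis=Diagnosis(prof.diagnosis_class, prof.label),
                    answers=answers,
                    picture=picture,
                    age=None if age_unknown[i] else int(ages[i]),
                    sex=Sex.UNKNOWN if sex_unknown[i]
                    else (Sex.FEMALE if female[i] else Sex.MALE),
                    race=Race.UNKNOWN if race_unknown[i]
                    else _RACE_BY_NAME.get(race_names[int(race_idx[i])], Race.UNKNOWN),
                )
            )
    return cohort


def _operating_points(
    spec: CohortSpec,
    algos,
    replicate_seeds: Sequence[int],
) -> dict[int, tuple[float, float]]:
    """Mean simulated (sensitivity, specificity) per algorithm."""
    from .diagnostics import confusion
    from .rules import classify_cohort

    sums = {a.algorithm_id: [0.0, 0.0] for a in algos}
    for s in replicate_seeds:
        cohort = generate(spec, seed_override=int(s))
        gold = {r.id: r.diagnosis for r in cohort}
        for a in algos:
            cm = confusion(classify_cohort(a, cohort), gold)
            if cm.n_case and cm.n_control:
                sums[a.algorithm_id][0] += cm.tp / cm.n_case
                sums[a.algorithm_id][1] += cm.tn / cm.n_control
    k = len(replicate_seeds)
    return {aid: (v[0] / k, v[1] / k) for aid, v in sums.items()}


def calibrate(
    spec: CohortSpec,
    target_summaries,
    algos,
    iterations: int,
    seed: int,
    replicates: int = 10,
) -> CohortSpec:
    """Nudge within-class dependence toward published operating points.

    Random-restart hill climb over the per-class ``q12_q3`` dependence
    parameters; a proposal is kept only if the summed absolute gap between
    simulated and target mean sensitivity/specificity (over a common set of
    replicate seeds) shrinks, so the returned spec is never farther from
    the targets than the input.  Class sizes and every printed marginal are
    untouched by construction.  With ``iterations=0`` the input spec is
    returned unchanged.
    """
    spec.validate()
    targets = {t.algorithm_id: t for t in target_summaries}
    algo_map = {a.algorithm_id: a for a in algos if a.is_transcribed}
    shared = [algo_map[i] for i in targets if i in algo_map]
    if not shared:
        raise ValueError("no transcribed algorithm among the calibration targets")
    if iterations == 0:
        return spec

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    def objective(s: CohortSpec) -> float:
        pts = _operating_points(s, shared, rep_seeds)
        return sum(
            abs(pts[i][0] - targets[i].sensitivity.point)
            + abs(pts[i][1] - targets[i].specificity.point)
            for i in targets if i in pts
        )

    best, best_obj = spec, objective(spec)
    for _ in range(iterations):
        pidx = int(rng.integers(len(best.profiles)))
        prof = best.profiles[pidx]
        current = float(prof.dependence.get("q12_q3", 0.0))
        proposal = float(np.clip(current + rng.normal(0, 0.3), -1.0, 1.0))
        new_prof = replace(prof, dependence={**prof.dependence, "q12_q3": proposal})
        candidate = replace(
            best, profiles=best.profiles[:pidx] + (new_prof,) + best.profiles[pidx + 1:]
        )
        cand_obj = objective(candidate)
        if cand_obj < best_obj:
            best, best_obj = candidate, cand_obj
            log.info("calibrate: accepted dependence %.3f (objective %.4f)", proposal, cand_obj)
    return best
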