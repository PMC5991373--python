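# altoscreen

Scoring and diagnostic-accuracy analysis for the **ALTO** (Alopecia Areata
Assessment Tool) screening questionnaire.

Alopecia areata (AA) is an autoimmune, non-scarring hair loss with no
definitive biomarker, so epidemiological studies need a validated
patient-reported instrument to find cases without a dermatologist visit.
The ALTO is a one-page questionnaire: five yes/no/not-sure items (Q1–Q5),
two follow-ups administered only after an affirmative Q3 (Q3A, Q3B), and a
picture item (Q6) on which respondents tick any of four photographs (A–D)
or "no representative photographs" (E).  Nine a-priori scoring algorithms
turn the answers into a screen-positive/negative call, which is judged
against the dermatologist gold standard in a pilot cohort of 239
respondents (13 alopecia totalis/universalis + 46 patchy alopecia = 59 AA
cases; 180 other hair loss).

This package is for biostatisticians and epidemiologists who want to
re-derive, stress-test or extend that analysis:

* **instrument** — the questionnaire data model: answer domains, skip
  logic (Q3A/Q3B only after Q3 = yes), per-item missingness, the cohort
  CSV dialect, and the evaluability rule (a respondent enters an
  algorithm's denominator only if every administered item the algorithm
  reads was answered).
* **rules** — each scoring algorithm as a monotone boolean expression in a
  small DSL, e.g. algorithm 1 is `(Q1|Q2)&Q3&any(Q3A,Q3B,Q4,Q5)`.
  Algorithms 1, 3 and 5 are stated in the source's running text and are
  locked against editing; the other six were published only as a figure
  and ship as placeholders that raise until you supply a transcription.
* **diagnostics** — sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`,
  PPV, NPV with Clopper–Pearson exact 95% intervals
  (`Beta(α/2; k, n−k+1)` to `Beta(1−α/2; k+1, n−k)`), plus
  `reconstruct_confusion`, which inverts a published rounded
  sensitivity/specificity pair into every consistent integer confusion
  matrix so printed screen-positive counts, PPVs and NPVs can be verified
  exactly.
* **cohort_stats** — one-way ANOVA for age, the Freeman–Halton r×c Fisher
  exact test by full enumeration (probability ordering), and Šidák
  adjustment `1−(1−p)^m` for pairwise contrasts.
* **synthetic** — a seeded cohort generator whose defaults reproduce the
  pilot study's printed marginals (class sizes, per-class yes rates,
  conditional follow-up rates, picture-selection rates, per-item missing
  counts, demographics), so the whole pipeline runs without the
  undeposited respondent-level data.

## Worked example

Reconstruct the confusion matrix behind the published algorithm-5 row
(sensitivity 89.8%, specificity 82.8%, 59 cases vs 180 controls):

```sh
$ alto reconstruct 89.8 82.8 59 180
tp=53 fn=6 fp=31 tn=149  n_positive=84  sens=89.8 (79.2, 96.2)  spec=82.8 (76.5, 88.0)  ppv=63.1 (51.9, 73.4)  npv=96.1 (91.8, 98.6)
```

The rounded pair pins a *unique* integer matrix, and every derived number
— 84 screen-positives, PPV 63.1%, NPV 96.1%, and all four exact intervals
— equals the published row.

Simulate a cohort under the pilot conditions and score it:

```sh
$ alto simulate --seed 7 --out cohort.csv
$ alto evaluate --cohort cohort.csv --out-dir reports
 algorithm  n_positive        sensitivity                spec                 ppv                 npv
         1          54  98.0 (89.6, 100.0)   97.5 (93.6, 99.3)   92.6 (82.1, 97.9)  99.4 (96.5, 100.0)
         3          38   74.5 (60.4, 85.7)  100.0 (97.7, 100.0)  100.0 (90.7, 100.0)   92.4 (87.4, 95.9)
         5          91  98.1 (90.1, 100.0)   76.8 (69.6, 83.1)   58.2 (47.4, 68.5)  99.2 (95.7, 100.0)
```

Each row is one algorithm evaluated on the 239 synthetic respondents after
per-algorithm exclusion of those missing a required answer: `n_positive`
screen-positives, then the four test characteristics as
`point (lower, upper)` percent with exact 95% intervals.  Because the
generator draws items independently within class, single cohorts scatter
around the published operating points rather than matching them (see
`docs/methods.md`).  `alto table1 --cohort cohort.csv` adds the
demographics comparison (ANOVA for age, Fisher exact for sex/race,
Šidák-adjusted pairwise contrasts), and `alto score` emits per-respondent
verdicts.

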