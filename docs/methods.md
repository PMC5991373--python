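# Methods

## The screening problem

The ALTO questionnaire screens for alopecia areata (AA) against a
dermatologist gold standard.  A scoring algorithm maps a respondent's
answers to screen-positive/negative; the analysis surface is the usual
case–control diagnostic one: sensitivity TP/(TP+FN) over the 59 AA cases,
specificity TN/(TN+FP) over the 180 non-AA respondents, and the empirical
predictive values PPV = TP/(TP+FP), NPV = TN/(TN+FN).  Predictive values
are always computed from the observed (or reconstructed) matrix, never
from a prevalence formula: the published values are cohort-empirical, and
clinic prevalence (59/239) is far above screening-population prevalence,
so the PPVs here should not be read as field performance (spectrum bias;
the source says as much).

## Scoring rules and their evaluation

Each algorithm is a monotone boolean expression over atoms "answered yes
to item X" / "ticked photograph X" — no negations, so flipping any answer
to 'yes' can only keep or gain positivity (property-tested).  'Not sure'
enters scoring through a policy:

* `unsure_as_not_yes` (default): the published algorithms are phrased as
  "answered 'yes'", so 'not sure', 'no', missing and non-administered all
  fail an atom.  The verdict is always determinate.
* `unsure_as_missing`: 'not sure' and missing propagate as unknowns
  through Kleene three-valued logic; the verdict is `indeterminate` only
  when an unknown is decisive.  Non-administered follow-ups (Q3 ≠ yes)
  are structurally false, not unknown — the respondent had no round
  patches to follow up on.

Exclusion follows the pilot's rule: a respondent is dropped from an
algorithm's denominators when some *administered* item the rule reads is
unanswered.  The default mode applies this per algorithm (each algorithm
keeps its own evaluable subset, matching the per-row denominators implied
by the published table); a `global` mode — dropping anyone missing any
item any selected algorithm reads — is exposed because the source's
wording is ambiguous between the two.

Only algorithms 1, 3 and 5 are specified in running text:

    1: (Q1|Q2) & Q3 & any(Q3A,Q3B,Q4,Q5)
    3: (Q1|Q2) & Q3 & Q3A & any(Q3B,Q4,Q5)
    5:          Q3 & any(Q3A,Q3B,Q4,Q5)

"Q3A–Q5" is read as the instrument-order item list {Q3A, Q3B, Q4, Q5}.
The other six algorithms were published as a figure not available to this
implementation; inventing them silently would corrupt results, so they
ship as placeholders that raise on use.  The definitions file is
user-replaceable, but entries 1, 3, 5 are verified structurally against
the hard-coded text and may not be edited.

## Exact intervals and printed-table reconstruction

Confidence intervals are Clopper–Pearson in the beta-quantile form, lower
= Beta(α/2; k, n−k+1), upper = Beta(1−α/2; k+1, n−k), with the
conventional 0 and 1 at k = 0 and k = n.  "Exact binomial" admits
variants (mid-p, Blaker); the beta-quantile form reproduces every one of
the 72 printed CI bounds, which fixes the choice.  Tests cross-check the
quantile form against an independent bisection of the binomial tail sums
(10⁻⁸) and verify conservative coverage by simulation.

Printed percentages are matched under half-away-from-zero rounding to one
decimal — the convention of the mainstream commercial statistics packages
— computed in integer arithmetic (`floor((1000·2k + n) / 2n) / 10`) so a
float boundary case can never flip a digit.  All nine published
sensitivity/specificity rows reconstruct under this convention; banker's
rounding does not reproduce them.

`reconstruct_confusion` searches all (tp, tn) pairs on the published
margins (59, 180).  With n = 59 and 180, adjacent counts change the
rounded percent by 1.7 and 0.56 points, both far above the 0.1 resolution,
so each published row has a unique preimage; the function nevertheless
returns a list because other margins can make the preimage non-unique,
and an empty list (inconsistent inputs) is a reported outcome, not an
exception.  The published NPV denominators (tn+fn per algorithm) come out
of the reconstruction; residual per-algorithm exclusion differences the
source does not print are left unresolved rather than guessed.

## Demographic comparisons

Age: classical one-way ANOVA (between/within decomposition, F tail from
the F distribution), hand-computed because the contract returns both
degrees of freedom; scipy's implementation is the test oracle.  Unknown
ages are dropped.  Pairwise class contrasts use Welch t tests with Šidák
adjustment 1−(1−p)^m at m = 3 (three class pairs); the source names the
correction but not the pairwise test, so the choice is a documented
default.

Sex and race: Fisher's exact test generalized to r×c (Freeman–Halton)
with the probability-ordering definition of extremeness — the p-value is
the total null probability of margin-fixed tables no more probable than
the observed one (10⁻¹² log-slack for ties).  The implementation fully
enumerates the support: a Python recursion walks rows in ascending size
order and the two largest rows are evaluated as a vectorized grid, which
handles the pilot's 5×3 race table (grand total 226, ~8·10⁶ tables) in
about two seconds.  Enumeration is bounded (grand total ≤ 500 and a grid
guard); beyond it a margin-preserving permutation Monte-Carlo estimate
with the add-one correction is available.  The published gender table
gives p = 0.00356 → printed 0.004; the race table 0.293 → printed 0.29.
Percent denominators in the demographics report use known values only
(unknown age/sex/race never excludes a respondent from anything else).

## The synthetic generator

The generator is the package's stand-in for the undeposited
respondent-level data; it reproduces exactly the quantities the source
prints, and nothing more:

* **Class sizes** 13 / 46 / 180, drawn exactly, ids assigned
  sequentially.
* **Item marginals.**  Every probability is a printed
  numerator/denominator pair, e.g. patchy Q3 = 42/46, other-class Q1 =
  29/179.  Q2 uses the reduced denominators the printed percents imply
  (5/12, 19/45, 7/174 — the last chosen so per-class missing-Q2 counts
  sum to the printed 8).  Q3A/Q3B rates are conditional on Q3 = yes
  (8/13, 38/42, 21/55; 10/11, 26/40, 40/50); their unexplained reduced
  denominators are mirrored as item-specific missingness among the
  administered, not resolved.
* **Structure.**  Items are conditionally independent given class —
  the joint distribution is unidentified from printed marginals — except
  for skip logic and one logical constraint: complete head-and-body hair
  loss implies complete scalp loss, so Q5 = yes forces Q4 = yes, with
  Q4 drawn conditionally ((p₄−p₅)/(1−p₅) when Q5 ≠ yes) to preserve its
  marginal.
* **Pictures.**  A completer declares 'none representative' with the
  printed E-rate, otherwise ticks each photograph independently at
  p/(1−p_E), preserving every per-photograph marginal.  This implies a
  positive probability of an answered-but-empty selection — a pattern
  present in the printed data itself (the other-hair-loss column records
  47 non-E completers but only 42 selections), serialized as the CSV
  token `none` (an empty cell remains "missing").  Only 74/180
  other-class respondents completed the picture item; that is modeled as
  per-class Q6 missingness.
* **Missingness** is missing-completely-at-random at per-class, per-item
  rates chosen to mirror the printed denominators (no mechanism is
  described in the source).
* **Ages** are normal truncated at the eligibility floor of 18, with the
  parent parameters solved (moment-matching on the truncated
  distribution) so the *realized* adult-only mean/SD equal the printed
  per-class values; naive truncation would bias the patchy mean up ~2
  years and shrink the between-class gap.  Ages are stored in whole
  years.  The single unknown-age/sex respondent and the 13 unknown-race
  respondents are placed per the printed denominators.

What passing tests show — and do not show.  Marginal-recovery tests (500
seeded cohorts, every printed cell within 3 binomial SEs) validate the
marginals, and the simulated algorithm-5 mean sensitivity lands within a
point of the published 89.8% without any tuning.  But conditional
independence is an assumption, not an inference: the published
algorithm-5 *specificity* (82.8%) is not reproducible from the printed
marginals (simulated ≈ 75%), because P(any follow-up | Q3 = yes) per
class is already fixed by the printed conditional rates.  The real cohort
evidently had within-class dependence the tables cannot identify, so
operating-point proximity is a logged, non-gating check, and results on
synthetic cohorts say nothing about real-data dependence structure.

`calibrate` exposes the one dependence knob the data could motivate: a
per-class parameter in [−1, 1] coupling Q1/Q2 to Q3 through a shared
latent uniform (comonotone or antithetic), which preserves all marginals
exactly.  A hill climb with common random numbers accepts only proposals
that shrink the summed absolute gap to target operating points, so the
returned spec is never farther from the targets than the input; class
sizes and marginals are untouched by construction.  No optimality is
claimed, and algorithms that never read Q1/Q2 (algorithm 5) are
unaffected by it.

## Numerical and design choices

* Seeding: one integer seed drives a `numpy` Generator; draws occur in a
  fixed order, so cohorts are byte-identical across runs after CSV
  serialization.  Replicate seeds are derived below 2³¹.
* 'Not sure' is kept distinct from 'no' at the data layer (the option was
  added to the instrument to improve completion, not as a negative), so
  alternative scoring policies remain comparable.
* The "yes to at least one" aggregate row is configurable (default
  Q1–Q5); the source does not define which items its aggregate spans.
* Rule parsing is a recursive-descent parser with `&` over `|`
  precedence and positioned syntax errors; the canonical serialization is
  fully parenthesized and round-trips.
* Degenerate inputs are first-class: ANOVA with zero within-group
  variance raises a distinct error and the demographics report flags it;
  PPV/NPV with an empty denominator are `None`, printed as "undefined";
  reconstruction returning no candidates is a reported outcome.
* Problem sizes in the test suite: marginal recovery pools 500 cohorts of
  239; coverage simulation uses 2,000 replicates per (p, n); the rule
  engine is compared with a naive evaluator on >10,000 assignments; the
  power check for the patchy-vs-other age contrast uses 200 cohorts
  (measured power 0.89 at the published group sizes; the frozen bound is
  0.85, two Monte-Carlo SEs below).

## Known limitations

* Six of nine algorithms await figure transcription; the reconstruction
  path covers all nine published rows regardless.
* The generator cannot (and does not try to) reproduce joint response
  behavior beyond the one documented dependence parameter.
* Fisher enumeration cost grows quickly with margins; the bound is
  deliberately conservative and the Monte-Carlo path is the supported
  fallback.
* Percentages and intervals target the source's rounding convention; a
  different convention (banker's rounding) will not reproduce the
  published digits.
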