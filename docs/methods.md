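# Methods

`fqsignals` implements a complete disproportionality-analysis pipeline for
peripheral-neuropathy (PN) adverse-event reports associated with the six
FDA-approved fluoroquinolones (FQs), from spontaneous-report ingest through
Bayesian signal statistics, time-to-onset (TTO) summaries, demographic
risk-factor screening and segmented temporal trends. This note records the
models, the parameter choices that matter, and the design decisions taken
where more than one defensible option existed.

## Cohort construction

A report is one case: drugs with suspect/concomitant roles, MedDRA
preferred terms (PTs) for reactions and indications, demographics, dates
and outcome flags. The funnel is:

1. **Normalization.** Product strings are case-folded, salt suffixes
   (hydrochloride, mesylate, hemihydrate, ...) stripped, and brand names
   mapped through an editable synonym table to the six FQ generics;
   unknown names pass through unchanged so co-medications stay visible.
2. **Study window.** Reports first received in [2007-01-01, 2024-10-01)
   are retained. Year- and month-precision dates are accepted for window
   checks (interpreted as the earliest compatible day) but never for TTO.
3. **Deduplication.** Reports identical on (age rounded to whole years,
   sex, country, initial received date, sorted drug names, sorted
   indications, sorted reactions) collapse to one record — the
   conservative composite-key rule used in pharmacovigilance practice. A
   missing value matches only another missing value; the retained record
   is the one with the latest received date, ties broken by smallest case
   id. The operation is order-deterministic and idempotent.
4. **Exclusion.** Reports listing any non-FQ drug (any role) are removed,
   leaving FQ-only cases. A `suspect_only` switch restricts the check to
   suspect drugs for sensitivity analyses.
5. **Exposure.** Each surviving report gets exactly one label: a single
   FQ generic, or `Combination` when two or more distinct FQs appear.

## Vocabulary

A licensed MedDRA hierarchy cannot ship with the package, so a small CSV
vocabulary covers the 28 PN preferred terms used for flagging plus the
common neurological and concurrent non-neurological terms, each with its
system organ class. PN terms carry one of four symptom categories:
sensory hyposensitivity (numbness-type), sensory hypersensitivity
(pain-type), unclassified sensory (terms compatible with either, such as
the generic "peripheral neuropathy"), and motor (explicit motor
involvement only). The published source tables for the full 28-term list
are not reproduced in print, so roughly twenty terms are the ones named
in the text and figures and the remainder are clinically standard PN
terms; the file is user-editable and any same-schema CSV can be supplied.

## Disproportionality statistics

For a drug–event pair the contingency summary is (n11, n1+, n+1, N)
against the whole database, *including* the drug's own stratum (the
comparator is the full database, not leave-one-out). With
e11 = n1+·n+1/N, the information component is

    IC = log2((n11 + 1/2) / (e11 + 1/2))

The half-count shrinkage makes IC exactly 0 for an independent table at
any magnitude and stabilises small cells. Two 95% interval methods are
provided and stamped into every output row:

* **gamma_quantile** (default): log2 of the 2.5%/97.5% quantiles of
  Gamma(shape = n11 + 1/2, rate = e11 + 1/2), the Poisson-gamma posterior
  form of the BCPNN shrinkage estimator;
* **noren_approx**: the closed-form asymptotic approximation
  IC025 = IC − 3.3(n11+1/2)^(−1/2) − 2(n11+1/2)^(−3/2),
  IC975 = IC + 2.4(n11+1/2)^(−1/2) − (1/2)(n11+1/2)^(−3/2).

The two agree within 0.15 bits for n11 ≥ 20 (verified by sweep). A
positive signal requires IC > 2 and IC025 > 0. The association p-value
is a two-sided mid-p Poisson test of n11 against e11; published analyses
in this area rarely state their test, so the method name travels with
every row rather than being implicit.

Screens run at three units: drug × pooled-PN, drug × PT, and drug ×
symptom category, each against comparator counts supplied as a
`BackgroundSummary` (database size N and per-event totals — summary
counts, never synthetic rows). Pairs with fewer than 3 cases are emitted
with statistics suppressed and a `below_min` flag. Shared-signal
prioritization selects PTs with pooled IC > 2 that are positive signals
in at least three individual FQs (combination therapy does not count as
an individual agent).

## Reference cohort

`fqsignals.fixture` builds, with no randomness, a 37,778-case cohort
whose marginals equal every figure the published FQ–PN analysis prints:
per-exposure totals and PN counts, 11,768 neurological cases, the four
dominant PN term multiplicities, per-exposure symptom-category counts,
the 4,882/706 concurrent split, all fatality marginals, 30.2%/10.3%
age/sex missingness, and a 1,383-record day-precision TTO sub-table. A
self-check asserts every marginal at build time, including that the
cohort passes deduplication untouched (case keys are made unique by
construction through the received-date × country assignment).

Three aspects deserve emphasis:

* **Joint structure is synthetic.** Attributes never cross-tabulated in
  print (e.g. sex × drug among fatal PN cases) are assigned by
  deterministic even-spreading; only the printed marginals are
  guaranteed.
* **Category flags are explicit.** The printed per-category case counts
  are smaller than the printed carrier counts of single terms belonging
  to those categories (1,687 hyposensitivity cases vs 2,095 paraesthesia
  carriers), so no term→category map applied to per-case term sets can
  reproduce both tables. The fixture therefore stores category flags per
  case; vocabulary-derived flags remain the default for real cohorts.
* **The comparator is calibrated.** The published database-wide
  comparator counts are not printed. Back-calculating from the printed
  ICs brackets the PN background proportion in 0.0182–0.0183; the single
  value 0.01825 (with N = 20,000,000) reproduces the printed IC at two
  decimals for seven of the eight exposure rows (gemifloxacin computes
  1.90 vs the printed 1.89 under any single rate). Per-category
  comparator counts are back-calculated from the printed pooled category
  ICs; per-term counts split the pooled rate by the cohort's own event
  shares. Published interval bounds are *not* exactly reproducible: the
  source package's interval algorithm is unknown, and the printed
  combination interval is narrower than any Poisson/gamma-based width.
  The gamma and closed-form methods shipped here give (2.98, 3.06) and
  (2.97, 3.05) for the pooled stratum against the printed (2.98, 3.05).
* **The TTO histogram is one frozen choice.** {0: 520, 1: 260, 2: 80,
  3: 60, 4: 50, 5: 40, 6: 59, 7: 40, eight each of 8–30, one each of
  31–120} satisfies the reported median 1, IQR 0–6 and 1,109/1,383
  within a week; any histogram with those properties would do, and this
  one is frozen so tests are exact.

## Synthetic generator

`fqsignals.synthetic` draws cohorts whose default parameters are the
study conditions: per-drug report volumes and PN rates at the observed
Table-level values, 30.2%/10.3% age/sex missingness, piecewise yearly
trends with breakpoints at 2016 (boxed-warning revision) and 2020
(defaults 0.0/+0.08/−0.15 per year, qualitatively matching the reported
stable/rise/decline pattern), TTO available for 24.7% of PN cases with a
geometric day distribution (p = 0.18, giving median 1 and ≈80% within a
week), and age/sex-graded fatality calibrated to ≈2.4% overall. Where
the source analysis states no value (duplicate fraction 5%, concomitant
co-medication 30%), a realistic figure was chosen once and is not
tuned. Duplicates are exact key-copies; concomitant reports carry a
non-FQ drug; every mechanism's realised count lands in a `truth` record
so attrition is exactly recoverable. Coincidental key collisions between
independent draws are resolved deterministically (age/date nudges) so
injected-duplicate counts are exact, not approximate.

What the generator does **not** model: real country mixes, narrative
text, MedDRA versioning, correlated co-reporting structure, or
reporting-induced dependence between drugs. Passing operating-
characteristic tests therefore demonstrates statistical correctness of
the pipeline under idealised reporting, not performance on real FAERS
extracts.

## Descriptives, trends, TTO, risk factors

* **Contingency tests**: chi-square without continuity correction by
  default; Fisher's exact test automatically for 2×2 tables with any
  expected cell below 5. Percentages round half-up.
* **Temporal trends**: negative-binomial (NB2) regression of yearly
  counts on year, fitted by maximum likelihood per fixed segment
  (2007–2015, 2016–2019, 2020–2024; configurable). The proportion trend
  uses PN counts with log total offset rather than a binomial model,
  consistent with using NB regression throughout. 2024 covers only
  Q1–Q3 and contributes an exposure offset log(0.75). When the estimated
  dispersion collapses below 1e-8 or the Wald statistics degenerate, the
  Poisson fit is reported and flagged (`poisson_fallback`) — the NB
  slope equals the Poisson MLE in that limit.
* **TTO**: day 0 (same-day onset) is valid; negative intervals are
  excluded with a surfaced count (the source analysis does not state its
  rule, so the exclusion is logged rather than silent). Quartiles use
  inclusive linear interpolation (type 7); the frozen fixture histogram
  is convention-insensitive for the printed values. Rank-sum tests use
  the tie-corrected normal approximation without continuity correction,
  making the two-group Kruskal–Wallis test its exact square.
* **Imputation**: kNN with k = 5 over standardized age, one-hot
  sex/exposure, standardized year, seriousness and fatality. Distances
  are nan-aware Euclidean (missing dimensions dropped, rescaled by the
  usable-dimension fraction); neighbours come from records complete on
  age and sex; ages take the neighbour mean, sexes the neighbour mode
  with ties to the nearer neighbour; tie-breaks are by case id, making
  the result invariant to row order. Observed values are never altered.
* **Odds ratios**: univariate logistic regressions (exposure ref
  ciprofloxacin, sex ref male, age ref 0–17, severity ref non-serious;
  "critical" = life-threatening or fatal), Wald 95% intervals, and a
  single Bonferroni family sized by the number of estimable levels
  across the whole screen. For a binary factor the fitted OR equals the
  2×2 cross-product ratio to numerical precision (tested to six
  significant digits). The unimputed combination-vs-ciprofloxacin OR on
  the reference cohort is 4.05 by cross-product; the published
  post-imputation value (3.74) depends on imputed values that are not
  recoverable from printed tables, so the package reports both unimputed
  and post-imputation screens and does not attempt to match 3.74.

## Problem sizes in the default test run

Stochastic validations are sized to finish in minutes while keeping the
stated error margins: interval validity uses 200 random tables against
10^6-draw Monte-Carlo quantiles; detection operating characteristics use
100 seeds × 10,000-report cohorts at 8× and at 1× relative reporting;
trend recovery uses 200 simulated 9-year NB series (slope 0.15,
dispersion 0.2); Fisher's test is checked against exhaustive
hypergeometric enumeration on all 44,515 non-degenerate 2×2 tables with
N ≤ 30. The female-vs-male OR recovery check runs 12 seeds of 50,000
reports, a size at which the estimator's sampling interval comfortably
contains the injected OR 1.5.

## Known limitations

* Signals are reporting-disproportionality statistics over spontaneous
  reports: they quantify reporting patterns, not incidence or causation.
* Printed interval bounds and p-values of the source analysis are not
  exactly reproducible (unknown package internals); the package's two
  interval methods are labelled per row instead.
* The shipped vocabulary is a working subset of MedDRA, not the
  hierarchy; SOC-level traversal beyond the shipped terms is out of
  scope.
* Trend breakpoints are fixed inputs, not estimated change-points.
* The kNN imputer is O(n_missing × n_complete) in distance evaluations;
  it is chunked but deliberately exact, so imputing very large cohorts
  is the slowest optional step (and is off by default in the pipeline).
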