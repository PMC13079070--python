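# fqsignals

Pharmacovigilance signal detection for **fluoroquinolone-associated
peripheral neuropathy** (PN) from spontaneous adverse-event reports.

Fluoroquinolone antibiotics (ciprofloxacin, levofloxacin, moxifloxacin,
ofloxacin, gemifloxacin, delafloxacin) carry regulatory warnings for
persistent, potentially irreversible peripheral neuropathy. Spontaneous
reporting databases such as FAERS are the main early-warning instrument
for this kind of harm, but raw report streams are noisy: duplicated
submissions, co-medication, partial dates, missing demographics.
`fqsignals` packages the full analysis pipeline a pharmacovigilance
study of this question needs — for epidemiologists and drug-safety
scientists who want the pieces individually or the study end to end:

* **Ingest & cleaning** — dashboard-style delimited exports → normalized
  case reports; composite-key deduplication (age, sex, country, received
  date, drugs, indications, reactions); exclusion of reports with non-FQ
  co-medication; per-report exposure labels (single agent or
  `Combination`).
* **Signal statistics** — Bayesian information components (BCPNN) with
  gamma-quantile or closed-form credible intervals, mid-p Poisson
  association tests, and screening at drug, preferred-term and
  symptom-category level.
* **Descriptives & trends** — demographic/outcome tables, chi-square and
  Fisher tests, segmented negative-binomial yearly-trend fits with
  breakpoints at the 2016 boxed-warning revision and 2020.
* **Time-to-onset** — day-precision onset intervals, quartile summaries,
  ECDF curves, rank-sum / Kruskal–Wallis subgroup tests.
* **Risk factors** — kNN imputation of missing age/sex and univariate
  logistic odds-ratio screening with Bonferroni adjustment.
* **Synthetic data** — a generator with controlled statistical structure
  (injected duplicates, co-medication, trends, missingness) plus a
  deterministic 37,778-case reference cohort reproducing the printed
  marginals of the published FQ–PN analysis.

## The statistic at the core

For a drug–event pair, with `n11` joint reports, `n1+` drug reports,
`n+1` event reports and `N` database reports, the expected joint count
under independence is `e11 = n1+ · n+1 / N`, and the information
component is

```
IC = log2( (n11 + ½) / (e11 + ½) )
```

with a 95% credible interval from the Gamma(n11 + ½, e11 + ½) posterior
(or a closed-form approximation). A **positive signal** is `IC > 2` with
the lower interval bound above 0 — disproportionate reporting worth
clinical follow-up, *not* an incidence or causal estimate.

## Worked example

Run the pipeline on the built-in reference cohort:

```
fqsignals run-all --source fixture --out out/
```

prints (abridged):

```json
{
  "headline": {
    "n_reports": 37778,
    "n_pn": 5588,
    "pn_percent": 14.8,
    "neuro_percent": 31.2,
    "concurrent_pct": 87.37,
    "combination_pn_share": 43.32,
    "hypersensitivity_pct": 47.91,
    "motor_pct": 0.63
  },
  "signals": {
    "ic_all_fqs": 3.02,
    "ic_ciprofloxacin": 3.12,
    "ic_combination": 4.54,
    "positive_signals": ["All FQs", "CFX", "Combination", "LFX", "MFX", "OFX"]
  }
}
```

Reading the output: 5,588 of 37,778 FQ-only reports (14.8%) mention a PN
term; pooled FQ exposure reports PN eight-fold above its database
expectation (IC 3.02 ≈ log2 8.1); ciprofloxacin is the strongest single
agent (IC 3.12) and concurrent use of two or more fluoroquinolones the
strongest stratum overall (IC 4.54, with 43.32% of combination reports
mentioning PN). Gemifloxacin and delafloxacin stay below the signal
threshold at their small report counts. The same run writes tidy CSVs
(cohort, signal tables at three screening units, yearly series and trend
fits, TTO summaries and ECDF, risk-factor odds ratios) plus
`manifest.json` with every headline number; reruns are byte-identical.

The same library surface works on simulated cohorts
(`--source simulate`, seeded) and on your own dashboard-style exports
(`--source file --input-path reports.csv`, column map configurable via
YAML).

## Layout

```
src/fqsignals/
  core.py                ingest, dedup, exclusion, exposure, flags
  vocabulary.py          PT → SOC / PN / symptom-category mapping (editable CSV)
  synthetic.py           seeded cohort generator with injected ground truth
  fixture.py             deterministic reference cohort (self-checked)
  disproportionality.py  IC statistics, screens, signal rules
  trends.py              descriptives, contingency tests, NB trend fits
  tto.py                 time-to-onset summaries and rank tests
  risk_factors.py        kNN imputation, odds-ratio screening
  pipeline.py / cli.py   end-to-end orchestration and `fqsignals` CLI
docs/methods.md          models, parameter choices, limitations
```

See `docs/methods.md` for the statistical details and the design
decisions behind the reference cohort.
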