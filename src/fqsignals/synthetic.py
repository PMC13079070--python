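"""Synthetic spontaneous-report cohorts with controlled statistical structure.

The generator emulates the *shape* of a public-dashboard FAERS extract for
the six FDA-approved fluoroquinolones: per-drug report volumes and
peripheral-neuropathy (PN) reporting rates, piecewise log-linear yearly
reporting trends with breakpoints at the 2016 boxed-warning revision and
at 2020, demographic missingness (about 30% of ages and 10% of sexes
unrecorded), exact-key duplicate records, concomitant non-FQ
co-medication, geometric-tailed time-to-onset for the subset of reports
carrying day-precision dates, and age/sex-dependent fatality.

Every stochastic mechanism writes its realised counts into a ``truth``
record so that attrition and recovery tests can assert against injected
ground truth. The whole-database comparator is carried as summary counts
(database size and per-event report totals), never as millions of rows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._dates import PartialDate
from .core import (
    COMBINATION,
    EXPOSURE_CODES,
    EXPOSURE_ORDER,
    FQ_GENERICS,
    AdverseEventReport,
    age_group,
    dedup_key,
)
from .disproportionality import BackgroundSummary
from .vocabulary import PTVocabulary

_CODE_TO_GENERIC = {code: name for name, code in EXPOSURE_CODES.items()}

# Default study conditions: per-drug report volumes and PN reporting rates
# matching the observed 2007-2024 Q3 fluoroquinolone extract.
_DEFAULT_TOTALS = {
    "CFX": 14434, "LFX": 13598, "MFX": 7439, "OFX": 588, "GFX": 142, "DFX": 72,
    COMBINATION: 1505,
}
_GRAND_TOTAL = sum(_DEFAULT_TOTALS.values())
DEFAULT_DRUG_MIX = {k: v / _GRAND_TOTAL for k, v in _DEFAULT_TOTALS.items()}
DEFAULT_PN_RATES = {
    "CFX": 2291 / 14434, "LFX": 1942 / 13598, "MFX": 642 / 7439, "OFX": 46 / 588,
    "GFX": 11 / 142, "DFX": 4 / 72, COMBINATION: 652 / 1505,
}

# PN preferred-term draw weights: the four dominant manifestations at their
# observed multiplicities, the remaining terms sharing a light tail.
_PN_PT_WEIGHTS = {
    "Paraesthesia": 2095.0,
    "Peripheral neuropathy": 1986.0,
    "Hypoaesthesia": 1637.0,
    "Burning sensation": 1066.0,
}
_PN_TAIL_WEIGHT = 60.0

_NON_PN_NEURO_PTS = ["Dizziness", "Headache", "Tremor", "Somnolence", "Dysgeusia"]
_NON_NEURO_PTS = [
    "Tendonitis", "Arthralgia", "Myalgia", "Pain in extremity", "Fatigue", "Asthenia",
    "Insomnia", "Anxiety", "Nausea", "Diarrhoea", "Rash", "Tendon rupture",
]
_CONCOMITANT_NON_FQ = ["metformin", "lisinopril", "atorvastatin", "omeprazole", "prednisone"]
_COUNTRIES = ["US", "US", "US", "US", "US", "US", "US", "GB", "DE", "FR", "CA", "JP"]

# Fatality odds grow with age and are slightly higher in males; calibrated
# so the cohort-wide fatality is near the observed 2.4%.
DEFAULT_FATALITY_RATES: Dict[Tuple[str, str], float] = {
    ("0-17", "female"): 0.004, ("0-17", "male"): 0.005, ("0-17", "unknown"): 0.004,
    ("18-34", "female"): 0.007, ("18-34", "male"): 0.009, ("18-34", "unknown"): 0.008,
    ("35-64", "female"): 0.015, ("35-64", "male"): 0.020, ("35-64", "unknown"): 0.017,
    ("65+", "female"): 0.045, ("65+", "male"): 0.060, ("65+", "unknown"): 0.050,
    ("unknown", "female"): 0.018, ("unknown", "male"): 0.024, ("unknown", "unknown"): 0.020,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable study conditions for a synthetic cohort."""

    n_reports: int = 10_000
    drug_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRUG_MIX))
    pn_rate_by_drug: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PN_RATES))
    background_n: int = 20_000_000
    background_pn_rate: float = 0.01825
    # piecewise log-linear yearly trend: per-year log-rate slopes for the
    # 2007-2015, 2016-2019 and 2020-2024 segments
    yearly_trend: Tuple[float, float, float] = (0.0, 0.08, -0.15)
    trend_breakpoints: Tuple[int, int] = (2016, 2020)
    missing_age_rate: float = 0.302
    missing_sex_rate: float = 0.103
    duplicate_rate: float = 0.05
    concomitant_rate: float = 0.30
    tto_available_rate: float = 0.247
    tto_geometric_p: float = 0.18
    pn_sex_or: float = 1.0  # female-vs-male odds ratio on the PN rate
    fatality_rate_by_age_sex: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_FATALITY_RATES)
    )
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.background_pn_rate, self.missing_age_rate, self.missing_sex_rate,
            self.duplicate_rate, self.concomitant_rate, self.tto_available_rate,
            self.tto_geometric_p, *self.drug_mix.values(), *self.pn_rate_by_drug.values(),
            *self.fatality_rate_by_age_sex.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.drug_mix.values()) - 1.0) > 1e-9:
            raise ValueError("drug_mix must sum to 1")
        if set(self.drug_mix) != set(EXPOSURE_ORDER):
            raise ValueError("drug_mix must cover the seven exposure labels")
        if self.n_reports < 0 or self.background_n < self.n_reports:
            raise ValueError("background_n must be at least n_reports")
        if self.pn_sex_or <= 0:
            raise ValueError("pn_sex_or must be positive")


def _pn_pt_pool(vocab: PTVocabulary) -> Tuple[List[str], np.ndarray]:
    terms = sorted(vocab.pn_terms())
    weights = np.array([_PN_PT_WEIGHTS.get(t, _PN_TAIL_WEIGHT) for t in terms])
    return terms, weights / weights.sum()


def build_background(params: GeneratorParams, vocab: Optional[PTVocabulary] = None) -> BackgroundSummary:
    """Comparator summary consistent with the generator's event weights."""
    vocab = vocab or PTVocabulary.default()
    events = {"PN": int(round(params.background_pn_rate * params.background_n))}
    terms, weights = _pn_pt_pool(vocab)
    cat_rates: Dict[str, float] = {}
    for term, w in zip(terms, weights):
        rate = params.background_pn_rate * w
        events[term] = max(1, int(round(rate * params.background_n)))
        cat = vocab.lookup(term).category
        cat_rates[cat] = cat_rates.get(cat, 0.0) + rate
    for cat, rate in cat_rates.items():
        events[cat] = max(1, int(round(rate * params.background_n)))
    return BackgroundSummary(n_total=params.background_n, events=events)


def _year_weights(params: GeneratorParams) -> Tuple[np.ndarray, np.ndarray]:
    years = np.arange(2007, 2025)
    b1, b2 = params.trend_breakpoints
    s1, s2, s3 = params.yearly_trend
    log_rate = np.zeros_like(years, dtype=float)
    level = 0.0
    for i, year in enumerate(years):
        if year < b1:
            slope = s1
        elif year < b2:
            slope = s2
        else:
            slope = s3
        level = level + slope if i else 0.0
        log_rate[i] = level
    weights = np.exp(log_rate)
    weights[years == 2024] *= 0.75  # partial year: Q1-Q3 only
    return years, weights / weights.sum()


def generate_cohort(
    params: GeneratorParams, vocab: Optional[PTVocabulary] = None
) -> Tuple[List[AdverseEventReport], dict]:
    """Draw a reproducible synthetic cohort and its injected ground truth.

    Injected duplicates are exact copies (fresh case id, identical
    dedup-key fields); injected concomitant reports carry at least one
    non-FQ drug and are therefore removed by the exclusion step. ``truth``
    records the realised counts of every mechanism.
    """
    params.validate()
    vocab = vocab or PTVocabulary.default()
    rng = np.random.default_rng(params.seed)

    n_dup = int(round(params.n_reports * params.duplicate_rate))
    n_unique = params.n_reports - n_dup

    labels = np.array(EXPOSURE_ORDER, dtype=object)
    mix = np.array([params.drug_mix[label] for label in EXPOSURE_ORDER])
    exposure = rng.choice(labels, size=n_unique, p=mix)

    sex_obs = rng.choice(np.array(["female", "male"], dtype=object), size=n_unique, p=[0.56, 0.44])
    sex = sex_obs.copy()
    sex[rng.random(n_unique) < params.missing_sex_rate] = "unknown"

    age = np.clip(rng.normal(47.0, 17.0, size=n_unique), 0.0, 100.0).round(1)
    age_missing = rng.random(n_unique) < params.missing_age_rate

    base_rate = np.array([params.pn_rate_by_drug[e] for e in exposure])
    if params.pn_sex_or != 1.0:
        # treat the per-drug rate as the male rate; shift female odds by the OR
        odds = base_rate / (1.0 - base_rate)
        female_rate = odds * params.pn_sex_or / (1.0 + odds * params.pn_sex_or)
        base_rate = np.where(sex_obs == "female", female_rate, base_rate)
    is_pn = rng.random(n_unique) < base_rate

    years, weights = _year_weights(params)
    year = rng.choice(years, size=n_unique, p=weights)
    max_doy = np.where(year == 2024, 273, 365)  # study window closes after Q3 2024
    doy = rng.integers(0, max_doy)
    received = [dt.date(int(y), 1, 1) + dt.timedelta(days=int(d)) for y, d in zip(year, doy)]

    country = rng.choice(np.array(_COUNTRIES, dtype=object), size=n_unique)
    reporter = rng.choice(
        np.array(["consumer", "healthcare_professional", "other"], dtype=object),
        size=n_unique, p=[0.60, 0.32, 0.08],
    )

    terms, pt_weights = _pn_pt_pool(vocab)
    pn_pt = rng.choice(np.array(terms, dtype=object), size=n_unique, p=pt_weights)
    concurrent = rng.random(n_unique) < 0.87
    neuro_extra = rng.random(n_unique) < 0.19
    non_pn_neuro = rng.choice(np.array(_NON_PN_NEURO_PTS, dtype=object), size=n_unique)
    non_neuro = rng.choice(np.array(_NON_NEURO_PTS, dtype=object), size=n_unique)

    fatal_rate = np.array(
        [
            params.fatality_rate_by_age_sex.get(
                (age_group(None if miss else a), s), 0.02
            )
            for a, miss, s in zip(age, age_missing, sex)
        ]
    )
    fatal = rng.random(n_unique) < fatal_rate
    serious = fatal | (rng.random(n_unique) < 0.72)

    tto_has = is_pn & (rng.random(n_unique) < params.tto_available_rate)
    tto_days = rng.geometric(params.tto_geometric_p, size=n_unique) - 1

    concomitant_mask = rng.random(n_unique) < params.concomitant_rate
    extra_drug = rng.choice(np.array(_CONCOMITANT_NON_FQ, dtype=object), size=n_unique)

    comb_pairs = [
        ("ciprofloxacin", "levofloxacin"),
        ("ciprofloxacin", "levofloxacin", "moxifloxacin"),
        ("ciprofloxacin", "moxifloxacin"),
        ("levofloxacin", "moxifloxacin"),
    ]
    comb_idx = rng.integers(0, len(comb_pairs), size=n_unique)

    reports: List[AdverseEventReport] = []
    for i in range(n_unique):
        if exposure[i] == COMBINATION:
            drugs = tuple((name, "suspect") for name in comb_pairs[comb_idx[i]])
        else:
            drugs = ((_CODE_TO_GENERIC[exposure[i]], "suspect"),)
        if concomitant_mask[i]:
            drugs = drugs + ((extra_drug[i], "concomitant"),)
        reactions = set()
        if is_pn[i]:
            reactions.add(pn_pt[i])
            if concurrent[i]:
                reactions.add(non_neuro[i])
        elif neuro_extra[i]:
            reactions.add(non_pn_neuro[i])
        else:
            reactions.add(non_neuro[i])
        rd = received[i]
        if tto_has[i]:
            start = PartialDate(rd.year, rd.month, rd.day)
            onset = rd + dt.timedelta(days=int(tto_days[i]))
            event = PartialDate(onset.year, onset.month, onset.day)
        else:
            start = None
            event = PartialDate(rd.year)
        outcomes = frozenset({"death"}) if fatal[i] else (
            frozenset({"hospitalization"}) if serious[i] else frozenset({"non_serious"})
        )
        reports.append(
            AdverseEventReport(
                case_id=f"S{i:07d}",
                drugs=drugs,
                reaction_pts=frozenset(reactions),
                indication_pts=frozenset({"Bacterial infection"}),
                sex=str(sex[i]),
                age_years=None if age_missing[i] else float(age[i]),
                country=str(country[i]),
                received_date=rd,
                event_date=event,
                start_date=start,
                serious=bool(serious[i]),
                outcome_flags=outcomes,
                reporter=str(reporter[i]),
            )
        )

    reports = _make_keys_unique(reports)

    dup_sources = rng.choice(n_unique, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    duplicates = [
        replace(reports[int(j)], case_id=f"S{n_unique + k:07d}")
        for k, j in enumerate(dup_sources)
    ]

    all_reports = reports + duplicates
    n_concomitant = int(concomitant_mask.sum())
    clean = [r for i, r in enumerate(reports) if not concomitant_mask[i]]
    per_drug = {e: 0 for e in EXPOSURE_ORDER}
    pn_per_drug = {e: 0 for e in EXPOSURE_ORDER}
    for i, r in enumerate(reports):
        if concomitant_mask[i]:
            continue
        per_drug[exposure[i]] += 1
        pn_per_drug[exposure[i]] += int(is_pn[i])
    truth = {
        "seed": params.seed,
        "n_reports": params.n_reports,
        "n_unique": n_unique,
        "n_duplicates": n_dup,
        "n_concomitant": n_concomitant,
        "expected_flow": {
            "n_raw": params.n_reports,
            "n_after_dedup": n_unique,
            "n_after_exclusion": n_unique - n_concomitant,
            "n_pn": sum(pn_per_drug.values()),
        },
        "per_drug_totals": per_drug,
        "per_drug_pn": pn_per_drug,
        "background": build_background(params, vocab),
    }
    return all_reports, truth


def _make_keys_unique(reports: List[AdverseEventReport]) -> List[AdverseEventReport]:
    """Nudge colliding reports so every base report has a distinct dedup key.

    Required for exact attrition-recovery: without it, coincidental key
    collisions between independently drawn reports would be removed by
    deduplication and miscounted as injected duplicates. Observed ages are
    shifted by whole years (wrapping at 100); reports without an observed
    age get their received date shifted by one day.
    """
    out = list(reports)
    for _ in range(64):
        seen: Dict[tuple, int] = {}
        collisions = []
        for i, r in enumerate(out):
            key = dedup_key(r)
            if key in seen:
                collisions.append(i)
            else:
                seen[key] = i
        if not collisions:
            return out
        for i in collisions:
            r = out[i]
            if r.age_years is not None:
                out[i] = replace(r, age_years=float((r.age_years + 1.0) % 100.0))
            else:
                # stay inside the study window when shifting the date
                shifted = r.received_date + dt.timedelta(days=1)
                if shifted >= dt.date(2024, 10, 1):
                    shifted = r.received_date - dt.timedelta(days=1)
                out[i] = replace(r, received_date=shifted)
    raise RuntimeError("could not resolve dedup-key collisions")  # pragma: no cover
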