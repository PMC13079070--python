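"""Deterministic reference cohort reproducing the study's printed marginals.

This module constructs, without any randomness, a case-level cohort of
exactly 37,778 fluoroquinolone-only reports whose marginal counts equal
every figure the published analysis reports: per-exposure totals and
peripheral-neuropathy (PN) counts, the neurological-event total, the
multiplicities of the four dominant PN preferred terms, per-exposure
symptom-category counts, the concurrent-event split, all fatality
marginals, demographic missingness, and a 1,383-record day-precision
time-to-onset (TTO) sub-table.

Joint attributes the published tables never cross-tabulate (for example
sex by drug among fatal PN cases) are assigned by deterministic
round-robin/even-spreading rules: the cohort guarantees the printed
marginals and nothing more.

Symptom-category flags are stored explicitly on each case rather than
derived from its preferred terms. The printed per-category case counts
are smaller than the printed carrier counts of single terms belonging to
those categories (1,687 hyposensitivity cases versus 2,095 paraesthesia
carriers), so no term-to-category map can generate both sets of counts
from per-case term lists; the real per-case term combinations are simply
not recoverable from the published tables. Vocabulary-derived category
flags remain the default for every other cohort.

The TTO day histogram {0: 520, 1: 260, 2: 80, 3: 60, 4: 50, 5: 40,
6: 59, 7: 40, one each of 31..120, eight each of 8..30} is one frozen
deterministic choice satisfying the reported median 1 day, interquartile
range 0-6 and 1,109/1,383 onsets within a week.

The whole-database comparator is a summary (N = 20,000,000 reports;
PN proportion 0.01825). The proportion is a calibration constant: the
published comparator counts are not printed, and back-calculation from
the reported information components brackets the PN background rate in
0.0182-0.0183. The single value 0.01825 reproduces the printed IC at two
decimals for seven of the eight exposure rows (gemifloxacin computes
1.90 versus the printed 1.89 under any single rate).
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._dates import PartialDate
from .core import (
    COMBINATION,
    EXPOSURE_ORDER,
    AdverseEventReport,
    age_group,
    cohort_frame,
    dedup_key,
)
from .disproportionality import BackgroundSummary
from .vocabulary import CATEGORIES, PTVocabulary

# ---------------------------------------------------------------------------
# printed marginals

N_COHORT = 37_778
N_PN = 5_588
N_NEURO = 11_768

EXPOSURE_TOTALS: Dict[str, int] = {
    "CFX": 14_434, "LFX": 13_598, "MFX": 7_439, "OFX": 588, "GFX": 142, "DFX": 72,
    COMBINATION: 1_505,
}
PN_COUNTS: Dict[str, int] = {
    "CFX": 2_291, "LFX": 1_942, "MFX": 642, "OFX": 46, "GFX": 11, "DFX": 4,
    COMBINATION: 652,
}

# per-exposure (hyposensitivity, hypersensitivity, unclassified_sensory, motor)
CATEGORY_COUNTS: Dict[str, Tuple[int, int, int, int]] = {
    "CFX": (776, 1322, 565, 9),
    "LFX": (548, 863, 705, 20),
    "MFX": (232, 343, 102, 0),
    "OFX": (14, 28, 8, 0),
    "GFX": (5, 7, 0, 0),
    "DFX": (2, 2, 1, 0),
    COMBINATION: (110, 112, 453, 6),
}

PT_MULTIPLICITY: Dict[str, int] = {
    "Paraesthesia": 2_095,
    "Peripheral neuropathy": 1_986,
    "Hypoaesthesia": 1_637,
    "Burning sensation": 1_066,
}

N_CONCURRENT = 4_882  # PN cases also reporting non-PN events
N_PN_ONLY = 706

FATAL_TOTAL = 898
FATAL_PN = 25
FATAL_SEX = {"male": 413, "female": 327, "unknown": 158}
FATAL_AGE = {"0-17": 14, "18-34": 66, "35-64": 204, "65+": 327, "unknown": 287}
FATAL_COMBINATION = 33
FATAL_MONOTHERAPY = 865

MISSING_AGE = 11_406
MISSING_SEX = 3_908

TTO_N = 1_383
TTO_HISTOGRAM: Dict[int, int] = {0: 520, 1: 260, 2: 80, 3: 60, 4: 50, 5: 40, 6: 59, 7: 40}

BACKGROUND_N = 20_000_000
BACKGROUND_PN_RATE = 0.01825

_WINDOW_START = dt.date(2007, 1, 1)
_WINDOW_LAST = dt.date(2024, 9, 30)
_N_DAYS = (_WINDOW_LAST - _WINDOW_START).days + 1
_COUNTRIES = ["US", "GB", "DE", "FR", "CA", "JP"]

_CONCURRENT_PTS = [
    "Tendonitis", "Arthralgia", "Myalgia", "Pain in extremity", "Fatigue", "Asthenia",
    "Insomnia", "Anxiety", "Depression", "Nausea", "Dizziness", "Headache", "Tremor",
    "Rash", "Tendon rupture",
]
_NEURO_NON_PN_PTS = ["Dizziness", "Headache", "Tremor", "Somnolence", "Dysgeusia"]
_NON_NEURO_PTS = ["Tendonitis", "Arthralgia", "Nausea", "Fatigue", "Rash", "Diarrhoea", "Myalgia"]
_SERIOUS_OUTCOMES = ["hospitalization", "disability", "life_threatening", "other_serious"]
_REPORTER_CYCLE = ["consumer", "consumer", "consumer", "healthcare_professional", "other"]
_SEX_CYCLE = ["female", "male", "female", "male", "female"]
_AGE_CYCLE = [8.0, 22.0, 28.0, 33.0, 41.0, 45.0, 47.0, 50.0, 54.0, 58.0, 62.0, 68.0, 72.0, 80.0, 36.0, 49.0]
_FATAL_AGE_VALUES = {"0-17": 10.0, "18-34": 25.0, "35-64": 50.0, "65+": 72.0}

_CODE_TO_GENERIC = {
    "CFX": "ciprofloxacin", "LFX": "levofloxacin", "MFX": "moxifloxacin",
    "OFX": "ofloxacin", "GFX": "gemifloxacin", "DFX": "delafloxacin",
}
_PN_COMB_DRUGS = (
    [("ciprofloxacin", "levofloxacin")] * 300
    + [("ciprofloxacin", "levofloxacin", "moxifloxacin")] * 218
)
_PN_COMB_TAIL = [
    ("ciprofloxacin", "moxifloxacin"),
    ("levofloxacin", "moxifloxacin"),
    ("ciprofloxacin", "ofloxacin"),
]
_NON_PN_COMB_CYCLE = [
    ("ciprofloxacin", "levofloxacin"),
    ("ciprofloxacin", "moxifloxacin"),
    ("levofloxacin", "moxifloxacin"),
]


def _spread_flags(n: int, k: int) -> np.ndarray:
    """Boolean vector with exactly k True values spread evenly over n slots."""
    if not 0 <= k <= n:
        raise ValueError(f"cannot spread {k} flags over {n} slots")
    idx = np.arange(n, dtype=np.int64)
    return ((idx + 1) * k) // n > (idx * k) // n


def _largest_remainder(weights: Dict[str, int], total: int) -> Dict[str, int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    denom = sum(weights.values())
    raw = {k: total * v / denom for k, v in weights.items()}
    alloc = {k: int(np.floor(x)) for k, x in raw.items()}
    shortfall = total - sum(alloc.values())
    order = sorted(weights, key=lambda k: (raw[k] - alloc[k], weights[k]), reverse=True)
    for k in order[:shortfall]:
        alloc[k] += 1
    return alloc


def _tto_values() -> List[int]:
    values: List[int] = []
    for day, count in sorted(TTO_HISTOGRAM.items()):
        values.extend([day] * count)
    values.extend(d for d in range(8, 31) for _ in range(8))  # 184 onsets at 8-30 days
    values.extend(range(31, 121))  # 90 late onsets beyond 30 days
    return values


def _category_plan(exposure: str) -> List[Tuple[bool, bool, bool, bool]]:
    """Per-case category flags for one exposure's PN cases.

    Cases carrying two categories (the overhang of the per-category sums
    over the PN case count) are placed first and flagged with the two
    largest categories (hypo + hyper); the remainder carry single flags.
    """
    hypo, hyper, uncl, motor = CATEGORY_COUNTS[exposure]
    n_pn = PN_COUNTS[exposure]
    dual = hypo + hyper + uncl + motor - n_pn
    if dual < 0 or hypo < dual or hyper < dual:
        raise ValueError(f"inconsistent category counts for {exposure}")
    plan: List[Tuple[bool, bool, bool, bool]] = []
    plan.extend([(True, True, False, False)] * dual)
    plan.extend([(True, False, False, False)] * (hypo - dual))
    plan.extend([(False, True, False, False)] * (hyper - dual))
    plan.extend([(False, False, True, False)] * uncl)
    plan.extend([(False, False, False, True)] * motor)
    assert len(plan) == n_pn
    return plan


def _pn_pts_for_rank(rank: int) -> Tuple[str, ...]:
    """PN preferred terms of the PN case with global rank ``rank``.

    Primary terms fill the printed multiplicities in order (2,095
    paraesthesia, 1,986 peripheral neuropathy, then hypoaesthesia); the
    first 1,196 cases carry a second term so the hypoaesthesia and
    burning-sensation carrier counts also land exactly.
    """
    if rank < 2_095:
        primary = "Paraesthesia"
    elif rank < 2_095 + 1_986:
        primary = "Peripheral neuropathy"
    else:
        primary = "Hypoaesthesia"
    if rank < 1_066:
        return (primary, "Burning sensation")
    if rank < 1_196:
        return (primary, "Hypoaesthesia")
    return (primary,)


def build_fixture_reports() -> Tuple[List[AdverseEventReport], List[Tuple[bool, bool, bool, bool]]]:
    """Construct the reference cohort and its explicit category flags."""
    mono_totals = {e: EXPOSURE_TOTALS[e] for e in EXPOSURE_ORDER if e != COMBINATION}
    fatal_mono_alloc = _largest_remainder(mono_totals, FATAL_MONOTHERAPY)

    # --- per-case scaffolding, in exposure order with PN cases first -----
    exposures: List[str] = []
    is_pn: List[bool] = []
    fatal: List[bool] = []
    cat_flags: List[Tuple[bool, bool, bool, bool]] = []
    drugs_per_case: List[Tuple[str, ...]] = []
    neuro_non_pn: List[bool] = []

    nonpn_sizes = {e: EXPOSURE_TOTALS[e] - PN_COUNTS[e] for e in EXPOSURE_ORDER}
    neuro_alloc = _largest_remainder(nonpn_sizes, N_NEURO - N_PN)

    for exposure in EXPOSURE_ORDER:
        n_total, n_pn = EXPOSURE_TOTALS[exposure], PN_COUNTS[exposure]
        n_nonpn = n_total - n_pn
        if exposure == COMBINATION:
            fatal_quota = FATAL_COMBINATION
            pn_fatal_quota = 0
        else:
            fatal_quota = fatal_mono_alloc[exposure]
            pn_fatal_quota = FATAL_PN if exposure == "CFX" else 0
        pn_fatal = _spread_flags(n_pn, pn_fatal_quota)
        nonpn_fatal = _spread_flags(n_nonpn, fatal_quota - pn_fatal_quota)
        nonpn_neuro = _spread_flags(n_nonpn, neuro_alloc[exposure])
        plan = _category_plan(exposure)

        for j in range(n_pn):
            exposures.append(exposure)
            is_pn.append(True)
            fatal.append(bool(pn_fatal[j]))
            cat_flags.append(plan[j])
            neuro_non_pn.append(False)
            if exposure == COMBINATION:
                if j < len(_PN_COMB_DRUGS):
                    drugs_per_case.append(_PN_COMB_DRUGS[j])
                else:
                    drugs_per_case.append(_PN_COMB_TAIL[j % len(_PN_COMB_TAIL)])
            else:
                drugs_per_case.append((_CODE_TO_GENERIC[exposure],))
        for j in range(n_nonpn):
            exposures.append(exposure)
            is_pn.append(False)
            fatal.append(bool(nonpn_fatal[j]))
            cat_flags.append((False, False, False, False))
            neuro_non_pn.append(bool(nonpn_neuro[j]))
            if exposure == COMBINATION:
                drugs_per_case.append(_NON_PN_COMB_CYCLE[j % len(_NON_PN_COMB_CYCLE)])
            else:
                drugs_per_case.append((_CODE_TO_GENERIC[exposure],))

    n = len(exposures)
    assert n == N_COHORT

    # --- PN-level assignments keyed by global PN rank --------------------
    pn_rank = np.full(n, -1, dtype=np.int64)
    pn_rank[np.asarray(is_pn)] = np.arange(N_PN)
    concurrent_mask = _spread_flags(N_PN, N_CONCURRENT)
    tto_mask = _spread_flags(N_PN, TTO_N)
    tto_values = _tto_values()
    tto_of_rank = np.full(N_PN, -1, dtype=np.int64)
    tto_of_rank[tto_mask] = tto_values

    # --- fatality attributes by fatal rank -------------------------------
    fatal_idx = [i for i in range(n) if fatal[i]]
    assert len(fatal_idx) == FATAL_TOTAL
    fatal_sex = {}
    fatal_age = {}
    sex_edges = np.cumsum([FATAL_SEX["male"], FATAL_SEX["female"], FATAL_SEX["unknown"]])
    age_keys = ["0-17", "18-34", "35-64", "65+", "unknown"]
    age_edges = np.cumsum([FATAL_AGE[k] for k in age_keys])
    for f, i in enumerate(fatal_idx):
        fatal_sex[i] = "male" if f < sex_edges[0] else ("female" if f < sex_edges[1] else "unknown")
        group = age_keys[int(np.searchsorted(age_edges, f, side="right"))]
        fatal_age[i] = None if group == "unknown" else _FATAL_AGE_VALUES[group]

    # --- demographic missingness over non-fatal cases --------------------
    n_nonfatal = n - FATAL_TOTAL
    sex_missing = _spread_flags(n_nonfatal, MISSING_SEX - FATAL_SEX["unknown"])
    age_missing = np.roll(_spread_flags(n_nonfatal, MISSING_AGE - FATAL_AGE["unknown"]), n_nonfatal // 2)
    assert age_missing.sum() == MISSING_AGE - FATAL_AGE["unknown"]

    # --- assemble reports -------------------------------------------------
    reports: List[AdverseEventReport] = []
    nonfatal_rank = 0
    for i in range(n):
        received = _WINDOW_START + dt.timedelta(days=i % _N_DAYS)
        country = _COUNTRIES[i // _N_DAYS]
        if fatal[i]:
            sex = fatal_sex[i]
            age = fatal_age[i]
        else:
            g = nonfatal_rank
            nonfatal_rank += 1
            sex = "unknown" if sex_missing[g] else _SEX_CYCLE[g % len(_SEX_CYCLE)]
            age = None if age_missing[g] else _AGE_CYCLE[g % len(_AGE_CYCLE)]

        reactions: set = set()
        start_date = None
        event_date: PartialDate | None = PartialDate(received.year)
        if is_pn[i]:
            r = int(pn_rank[i])
            reactions.update(_pn_pts_for_rank(r))
            if concurrent_mask[r]:
                reactions.add(_CONCURRENT_PTS[r % len(_CONCURRENT_PTS)])
            if tto_of_rank[r] >= 0:
                start = received - dt.timedelta(days=30)
                onset = start + dt.timedelta(days=int(tto_of_rank[r]))
                start_date = PartialDate(start.year, start.month, start.day)
                event_date = PartialDate(onset.year, onset.month, onset.day)
        elif neuro_non_pn[i]:
            reactions.add(_NEURO_NON_PN_PTS[i % len(_NEURO_NON_PN_PTS)])
        else:
            reactions.add(_NON_NEURO_PTS[i % len(_NON_NEURO_PTS)])

        if fatal[i]:
            serious = True
            outcomes = frozenset({"death"})
        else:
            serious = (i % 4) != 0
            outcomes = frozenset({_SERIOUS_OUTCOMES[i % 4 - 1]}) if serious else frozenset({"non_serious"})

        reports.append(
            AdverseEventReport(
                case_id=f"P{i:05d}",
                drugs=tuple((name, "suspect") for name in drugs_per_case[i]),
                reaction_pts=frozenset(reactions),
                indication_pts=frozenset({"Bacterial infection"}),
                sex=sex,
                age_years=age,
                country=country,
                received_date=received,
                event_date=event_date,
                start_date=start_date,
                serious=serious,
                outcome_flags=outcomes,
                reporter=_REPORTER_CYCLE[i % len(_REPORTER_CYCLE)],
            )
        )
    return reports, cat_flags


def build_background_summary(vocab: PTVocabulary | None = None) -> BackgroundSummary:
    """Whole-database comparator for the reference cohort.

    The pooled PN count follows the 0.01825 calibration; per-term and
    per-category comparator counts are not published and are synthesised
    as the pooled rate split by the cohort's own event shares (per-term)
    or back-calculated from the printed pooled per-category information
    components (per-category).
    """
    events = {"PN": int(round(BACKGROUND_PN_RATE * BACKGROUND_N))}
    for pt, mult in PT_MULTIPLICITY.items():
        events[pt] = int(round(BACKGROUND_PN_RATE * (mult / N_PN) * BACKGROUND_N))
    # rates solving log2((n11+.5)/(rate*37778+.5)) = printed pooled category IC
    printed_total_ic = {
        "hyposensitivity": (1_687, 2.87),
        "hypersensitivity": (2_677, 3.18),
        "unclassified_sensory": (1_834, 3.50),
        "motor": (35, 3.16),
    }
    for cat, (n11, ic) in printed_total_ic.items():
        rate = ((n11 + 0.5) / 2.0 ** ic - 0.5) / N_COHORT
        events[cat] = int(round(rate * BACKGROUND_N))
    return BackgroundSummary(n_total=BACKGROUND_N, events=events)


def build_paper_marginals_fixture(
    vocab: PTVocabulary | None = None, verify: bool = True
) -> Tuple[pd.DataFrame, BackgroundSummary]:
    """Build the reference cohort frame and its comparator summary."""
    vocab = vocab or PTVocabulary.default()
    reports, cat_flags = build_fixture_reports()
    frame = cohort_frame(reports, vocab)
    flags = np.array(cat_flags, dtype=bool)
    for k, cat in enumerate(CATEGORIES):
        frame[f"cat_{cat}"] = flags[:, k]
    background = build_background_summary(vocab)
    if verify:
        verify_fixture(frame, background, reports)
    return frame, background


def verify_fixture(
    frame: pd.DataFrame,
    background: BackgroundSummary,
    reports: List[AdverseEventReport] | None = None,
) -> None:
    """Assert every printed marginal the cohort is built to reproduce."""

    def check(name: str, got, want) -> None:
        if got != want:
            raise AssertionError(f"fixture self-check failed: {name}: got {got}, want {want}")

    check("cohort size", len(frame), N_COHORT)
    for exposure in EXPOSURE_ORDER:
        sub = frame[frame["exposure"] == exposure]
        check(f"{exposure} total", len(sub), EXPOSURE_TOTALS[exposure])
        check(f"{exposure} PN", int(sub["has_pn"].sum()), PN_COUNTS[exposure])
        got_cats = tuple(int(sub[f"cat_{c}"].sum()) for c in CATEGORIES)
        check(f"{exposure} categories", got_cats, CATEGORY_COUNTS[exposure])
    check("PN total", int(frame["has_pn"].sum()), N_PN)
    check("neuro total", int(frame["has_neuro"].sum()), N_NEURO)

    pn = frame[frame["has_pn"]]
    for pt, mult in PT_MULTIPLICITY.items():
        check(f"{pt} carriers", int(pn["pn_pts"].map(lambda pts, _p=pt: _p in pts).sum()), mult)
    check("concurrent PN cases", int(pn["concurrent_non_pn"].sum()), N_CONCURRENT)
    check("PN-only cases", int((~pn["concurrent_non_pn"]).sum()), N_PN_ONLY)

    check("fatal total", int(frame["fatal"].sum()), FATAL_TOTAL)
    check("fatal PN", int(pn["fatal"].sum()), FATAL_PN)
    fatal = frame[frame["fatal"]]
    for sex, count in FATAL_SEX.items():
        check(f"fatal sex {sex}", int((fatal["sex"] == sex).sum()), count)
    for group, count in FATAL_AGE.items():
        check(f"fatal age {group}", int((fatal["age_group"] == group).sum()), count)
    check("fatal combination", int((fatal["exposure"] == COMBINATION).sum()), FATAL_COMBINATION)
    check("fatal monotherapy", int((fatal["exposure"] != COMBINATION).sum()), FATAL_MONOTHERAPY)

    check("missing age", int(frame["age_years"].isna().sum()), MISSING_AGE)
    check("missing sex", int((frame["sex"] == "unknown").sum()), MISSING_SEX)

    tto = [
        (r.event_date.to_date() - r.start_date.to_date()).days
        for r in (reports or [])
        if r.start_date is not None
        and r.start_date.precision == "day"
        and r.event_date is not None
        and r.event_date.precision == "day"
    ]
    if reports is not None:
        check("TTO records", len(tto), TTO_N)
        check("TTO within 7 days", sum(1 for t in tto if t <= 7), 1_109)
        ordered = sorted(tto)
        check("TTO median", ordered[len(ordered) // 2], 1)
        hist = {d: tto.count(d) for d in TTO_HISTOGRAM}
        check("TTO histogram head", hist, TTO_HISTOGRAM)
        check("dedup-stable", len({dedup_key(r) for r in reports}), N_COHORT)

    check("background N", background.n_total, BACKGROUND_N)
    check("background PN count", background.nplus1("PN"), int(BACKGROUND_PN_RATE * BACKGROUND_N))
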