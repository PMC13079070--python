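"""Case-report data model, ingest, deduplication and exposure assignment.

The unit of analysis is one spontaneous adverse-event report (AER): the
drugs it lists (with suspect/concomitant role), the coded reaction and
indication preferred terms (PTs), demographics, key dates and outcome
flags. Reports arrive as delimited dashboard-style exports with one row
per case and semicolon-separated multi-value cells.

The cohort pipeline mirrors standard pharmacovigilance practice:

1. normalize drug names to canonical generics (brand names and salt
   suffixes collapsed);
2. deduplicate on the composite key (age, sex, country, initial received
   date, drugs, indications, reactions) — the conservative rule used by
   the WHO Uppsala Monitoring Centre;
3. exclude reports listing any non-fluoroquinolone drug, so that every
   retained case has a fluoroquinolone (FQ) as the sole medication class;
4. assign each surviving report a single exposure label (one of the six
   FQ generics, or ``Combination`` when two or more distinct FQs appear);
5. flag reports whose reactions include neurological and/or
   peripheral-neuropathy (PN) PTs.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import pandas as pd

from ._dates import PartialDate, parse_partial_date
from .vocabulary import CATEGORIES, PTVocabulary

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised when an input file or run configuration is malformed."""


# ---------------------------------------------------------------------------
# constants

FQ_GENERICS = frozenset(
    {"ciprofloxacin", "levofloxacin", "moxifloxacin", "ofloxacin", "gemifloxacin", "delafloxacin"}
)

EXPOSURE_CODES = {
    "ciprofloxacin": "CFX",
    "levofloxacin": "LFX",
    "moxifloxacin": "MFX",
    "ofloxacin": "OFX",
    "gemifloxacin": "GFX",
    "delafloxacin": "DFX",
}
COMBINATION = "Combination"
EXPOSURE_ORDER = ["CFX", "LFX", "MFX", "OFX", "GFX", "DFX", COMBINATION]
ALL_FQ_LABEL = "All FQs"

SEXES = ("female", "male", "unknown")
REPORTERS = ("consumer", "healthcare_professional", "other", "unknown")
OUTCOME_FLAGS = ("death", "life_threatening", "hospitalization", "disability", "other_serious", "non_serious")

STUDY_WINDOW = (dt.date(2007, 1, 1), dt.date(2024, 10, 1))  # half-open [start, end)

AGE_GROUPS = ("0-17", "18-34", "35-64", "65+")

_SALT_SUFFIXES = {
    "HYDROCHLORIDE", "HCL", "MESYLATE", "MEGLUMINE", "HEMIHYDRATE", "MONOHYDRATE",
    "DIHYDRATE", "SODIUM", "LACTATE", "SESQUIHYDRATE",
}

_MISSING = "__missing__"  # sentinel: missing matches missing in the dedup key


def age_group(age_years: Optional[float]) -> str:
    if age_years is None or pd.isna(age_years):
        return "unknown"
    if age_years < 18:
        return "0-17"
    if age_years < 35:
        return "18-34"
    if age_years < 65:
        return "35-64"
    return "65+"


# ---------------------------------------------------------------------------
# report model


@dataclass(frozen=True)
class AdverseEventReport:
    """One spontaneous adverse-event report after ingest."""

    case_id: str
    drugs: Tuple[Tuple[str, str], ...]  # (canonical name, role) with role in {suspect, concomitant}
    reaction_pts: FrozenSet[str]
    indication_pts: FrozenSet[str] = frozenset()
    sex: str = "unknown"
    age_years: Optional[float] = None
    country: Optional[str] = None
    received_date: Optional[dt.date] = None
    event_date: Optional[PartialDate] = None
    start_date: Optional[PartialDate] = None
    serious: bool = False
    outcome_flags: FrozenSet[str] = frozenset()
    reporter: str = "unknown"

    def __post_init__(self) -> None:
        if self.age_years is not None and not 0 <= self.age_years <= 122:
            raise ValueError(f"{self.case_id}: age {self.age_years} outside [0, 122]")
        if "death" in self.outcome_flags and not self.serious:
            raise ValueError(f"{self.case_id}: fatal outcome implies a serious report")
        unknown = self.outcome_flags - set(OUTCOME_FLAGS)
        if unknown:
            raise ValueError(f"{self.case_id}: unknown outcome flags {sorted(unknown)}")

    @property
    def drug_names(self) -> FrozenSet[str]:
        return frozenset(name for name, _ in self.drugs)

    @property
    def fatal(self) -> bool:
        return "death" in self.outcome_flags


def dedup_key(report: AdverseEventReport) -> tuple:
    """Composite duplicate-detection key.

    Deterministic and insensitive to the ordering of the drug, indication
    and reaction lists. Missing values match only other missing values
    (encoded by a shared sentinel). Ages are rounded to whole years because
    exports mix integer and decimal ages.
    """
    age = _MISSING if report.age_years is None else int(round(report.age_years))
    return (
        age,
        report.sex or "unknown",
        report.country if report.country else _MISSING,
        report.received_date if report.received_date else _MISSING,
        tuple(sorted(report.drug_names)),
        tuple(sorted(report.indication_pts)),
        tuple(sorted(report.reaction_pts)),
    )


@dataclass
class CohortFlow:
    """Attrition counts through the dedup/exclusion funnel."""

    n_raw: int
    n_after_dedup: int
    n_after_exclusion: int
    n_pn: int

    def __post_init__(self) -> None:
        counts = (self.n_raw, self.n_after_dedup, self.n_after_exclusion, self.n_pn)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative attrition count: {counts}")
        if not self.n_raw >= self.n_after_dedup >= self.n_after_exclusion >= self.n_pn:
            raise ValueError(f"attrition counts must be non-increasing: {counts}")

    def to_dict(self) -> Dict[str, int]:
        return {
            "n_raw": self.n_raw,
            "n_after_dedup": self.n_after_dedup,
            "n_after_exclusion": self.n_after_exclusion,
            "n_pn": self.n_pn,
        }


# ---------------------------------------------------------------------------
# ingest


@dataclass(frozen=True)
class ColumnMap:
    """Header names of a dashboard-style export; edit to fit other exports."""

    case_id: str = "Case ID"
    suspect: str = "Suspect Product Names"
    concomitant: str = "Concomitant Product Names"
    reactions: str = "Reactions"
    indications: str = "Reason for Use"
    sex: str = "Sex"
    age: str = "Patient Age"
    country: str = "Country where Event occurred"
    received: str = "Initial FDA Received Date"
    event_date: str = "Event Date"
    start_date: str = "Therapy Start Date"
    serious: str = "Serious"
    outcomes: str = "Outcomes"
    reporter: str = "Reporter Type"
    separator: str = ";"

    # columns a file must provide; the rest default to missing/unknown
    MANDATORY = ("case_id", "suspect", "reactions", "received")


def load_default_synonyms() -> Dict[str, str]:
    ref = resources.files("fqsignals.data") / "drug_synonyms.csv"
    with resources.as_file(ref) as path, open(path, newline="", encoding="utf-8") as fh:
        return {row["raw"].strip().upper(): row["canonical"].strip() for row in csv.DictReader(fh)}


def normalize_drug_name(raw: str, synonyms: Optional[Dict[str, str]] = None) -> str:
    """Map a raw product string to a canonical generic name.

    Case-insensitive; trailing salt suffixes (hydrochloride, mesylate, ...)
    are stripped before lookup. Names outside the synonym table pass through
    lower-cased, so non-FQ co-medications keep an identity mapping.
    """
    if synonyms is None:
        synonyms = load_default_synonyms()
    text = " ".join(str(raw).split()).strip()
    if not text:
        raise ValueError("empty drug name")
    tokens = text.upper().split()
    while len(tokens) > 1 and tokens[-1] in _SALT_SUFFIXES:
        tokens.pop()
    key = " ".join(tokens)
    return synonyms.get(key, key.lower())


def _split_cell(cell: str, sep: str) -> List[str]:
    return [part.strip() for part in str(cell).split(sep) if part.strip()]


def _parse_age(cell: str) -> Optional[float]:
    text = str(cell).strip().upper()
    if not text or text in {"NAN", "NA", "UNKNOWN", "NOT SPECIFIED"}:
        return None
    parts = text.split()
    try:
        value = float(parts[0])
    except ValueError:
        return None
    unit = parts[1] if len(parts) > 1 else "YR"
    if unit.startswith("MON"):
        value /= 12.0
    elif unit.startswith(("DY", "DAY")):
        value /= 365.25
    elif unit.startswith(("DEC",)):
        value *= 10.0
    if not 0 <= value <= 122:
        return None
    return value


_SEX_MAP = {"f": "female", "female": "female", "m": "male", "male": "male"}
_REPORTER_MAP = {
    "consumer": "consumer",
    "healthcare professional": "healthcare_professional",
    "healthcare_professional": "healthcare_professional",
    "other": "other",
}
_OUTCOME_MAP = {
    "died": "death",
    "death": "death",
    "life threatening": "life_threatening",
    "life_threatening": "life_threatening",
    "hospitalized": "hospitalization",
    "hospitalization": "hospitalization",
    "disabled": "disability",
    "disability": "disability",
    "other outcomes": "other_serious",
    "other serious": "other_serious",
    "other_serious": "other_serious",
    "non-serious": "non_serious",
    "non_serious": "non_serious",
}


def read_dashboard_export(
    path, columns: Optional[ColumnMap] = None, synonyms: Optional[Dict[str, str]] = None
) -> List[AdverseEventReport]:
    """Read a delimited dashboard-style export into report objects.

    Unparseable fields degrade to missing/unknown; rows are never dropped
    here. Reports with an empty reaction cell are retained (flagged invalid
    downstream) with a record-level warning.
    """
    columns = columns or ColumnMap()
    if synonyms is None:
        synonyms = load_default_synonyms()
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, sep=None, engine="python")
    for attr in ColumnMap.MANDATORY:
        name = getattr(columns, attr)
        if name not in frame.columns:
            raise ConfigurationError(f"mandatory column {name!r} ({attr}) missing from {path.name}")

    def cell(row, attr: str) -> str:
        name = getattr(columns, attr)
        return row.get(name, "") if name in frame.columns else ""

    sep = columns.separator
    reports: List[AdverseEventReport] = []
    for _, row in frame.iterrows():
        drugs: List[Tuple[str, str]] = []
        for raw in _split_cell(cell(row, "suspect"), sep):
            drugs.append((normalize_drug_name(raw, synonyms), "suspect"))
        for raw in _split_cell(cell(row, "concomitant"), sep):
            drugs.append((normalize_drug_name(raw, synonyms), "concomitant"))
        reactions = frozenset(_split_cell(cell(row, "reactions"), sep))
        case_id = str(cell(row, "case_id")).strip()
        if not reactions:
            logger.warning("case %s has no reaction PTs; retained but invalid downstream", case_id)
        received = parse_partial_date(cell(row, "received"))
        outcome_raw = [t.strip().lower() for t in _split_cell(cell(row, "outcomes"), sep)]
        outcomes = frozenset(_OUTCOME_MAP[t] for t in outcome_raw if t in _OUTCOME_MAP)
        serious = str(cell(row, "serious")).strip().lower() in {"yes", "y", "true", "1", "serious"}
        if "death" in outcomes:
            serious = True
        reports.append(
            AdverseEventReport(
                case_id=case_id,
                drugs=tuple(drugs),
                reaction_pts=reactions,
                indication_pts=frozenset(_split_cell(cell(row, "indications"), sep)),
                sex=_SEX_MAP.get(str(cell(row, "sex")).strip().lower(), "unknown"),
                age_years=_parse_age(cell(row, "age")),
                country=str(cell(row, "country")).strip() or None,
                received_date=received.floor_date() if received else None,
                event_date=parse_partial_date(cell(row, "event_date")),
                start_date=parse_partial_date(cell(row, "start_date")),
                serious=serious,
                outcome_flags=outcomes,
                reporter=_REPORTER_MAP.get(str(cell(row, "reporter")).strip().lower(), "unknown"),
            )
        )
    return reports


def filter_study_window(
    reports: Iterable[AdverseEventReport], window: Tuple[dt.date, dt.date] = STUDY_WINDOW
) -> List[AdverseEventReport]:
    """Keep reports first received inside the half-open study window."""
    start, end = window
    return [r for r in reports if r.received_date is not None and start <= r.received_date < end]


# ---------------------------------------------------------------------------
# dedup / exclusion / exposure / flags


def deduplicate(reports: Sequence[AdverseEventReport]) -> List[AdverseEventReport]:
    """Collapse reports sharing the composite key to a single record.

    Within a duplicate group the retained report is the one with the latest
    received date, ties broken by lexicographically smallest case id. The
    output preserves the input order of the groups' first occurrences, so
    the operation is deterministic and idempotent.
    """
    best: Dict[tuple, Tuple[int, AdverseEventReport]] = {}
    order: List[tuple] = []
    for idx, report in enumerate(reports):
        key = dedup_key(report)
        if key not in best:
            best[key] = (idx, report)
            order.append(key)
        else:
            first_idx, kept = best[key]
            kept_date = kept.received_date or dt.date.min
            new_date = report.received_date or dt.date.min
            if (new_date, _neg_str(report.case_id)) > (kept_date, _neg_str(kept.case_id)):
                best[key] = (first_idx, report)
    return [best[key][1] for key in order]


class _neg_str(str):
    """Orders strings descending inside an ascending tuple comparison."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def exclude_concomitant(
    reports: Sequence[AdverseEventReport],
    fq_set: FrozenSet[str] = FQ_GENERICS,
    suspect_only: bool = False,
) -> Tuple[List[AdverseEventReport], int]:
    """Drop reports listing any drug outside ``fq_set``.

    By default all listed drugs count regardless of role; ``suspect_only``
    restricts the check to suspect drugs.
    """
    kept: List[AdverseEventReport] = []
    for report in reports:
        names = [name for name, role in report.drugs if not suspect_only or role == "suspect"]
        if names and all(name in fq_set for name in names):
            kept.append(report)
    return kept, len(reports) - len(kept)


def assign_exposure(report: AdverseEventReport, fq_set: FrozenSet[str] = FQ_GENERICS) -> str:
    """Single exposure label per report; two or more distinct FQs -> Combination."""
    fq_names = sorted(report.drug_names & fq_set)
    if not fq_names:
        raise ValueError(f"{report.case_id}: no FQ drug; report should not have survived exclusion")
    if len(fq_names) >= 2:
        return COMBINATION
    return EXPOSURE_CODES[fq_names[0]]


class EventFlags(NamedTuple):
    has_neuro: bool
    has_pn: bool
    pn_pts: FrozenSet[str]
    concurrent_non_pn: bool


def flag_events(report: AdverseEventReport, vocab: PTVocabulary) -> EventFlags:
    """Neurological/PN reaction flags for one report.

    ``concurrent_non_pn`` marks PN cases that also report at least one
    reaction outside the PN term list (PN accompanied by other AEs).
    """
    pn_pts = vocab.pn_subset(report.reaction_pts)
    has_pn = bool(pn_pts)
    has_neuro = has_pn or any(vocab.is_neuro(p) for p in report.reaction_pts)
    concurrent = has_pn and bool(report.reaction_pts - pn_pts)
    return EventFlags(has_neuro, has_pn, pn_pts, concurrent)


# ---------------------------------------------------------------------------
# analysis frame


def cohort_frame(reports: Sequence[AdverseEventReport], vocab: PTVocabulary) -> pd.DataFrame:
    """One row per report with the derived columns every analysis consumes.

    Category flags (``cat_*``) derive from the PN terms present via the
    vocabulary; callers holding richer per-case information (e.g. the
    deterministic reference cohort) may overwrite them.
    """
    rows = []
    for report in reports:
        flags = flag_events(report, vocab)
        cats = vocab.categories_of(flags.pn_pts)
        rows.append(
            {
                "case_id": report.case_id,
                "exposure": assign_exposure(report),
                "sex": report.sex,
                "age_years": report.age_years,
                "age_group": age_group(report.age_years),
                "country": report.country or "unknown",
                "received_date": report.received_date,
                "year": report.received_date.year if report.received_date else None,
                "serious": report.serious,
                "fatal": report.fatal,
                "outcome_flags": "|".join(sorted(report.outcome_flags)),
                "reporter": report.reporter,
                "reactions": tuple(sorted(report.reaction_pts)),
                "has_neuro": flags.has_neuro,
                "has_pn": flags.has_pn,
                "pn_pts": tuple(sorted(flags.pn_pts)),
                "concurrent_non_pn": flags.concurrent_non_pn,
                **{f"cat_{c}": (c in cats) for c in CATEGORIES},
                "start_date": report.start_date,
                "event_date": report.event_date,
            }
        )
    columns = [
        "case_id", "exposure", "sex", "age_years", "age_group", "country", "received_date",
        "year", "serious", "fatal", "outcome_flags", "reporter", "reactions", "has_neuro",
        "has_pn", "pn_pts", "concurrent_non_pn",
        *[f"cat_{c}" for c in CATEGORIES], "start_date", "event_date",
    ]
    return pd.DataFrame(rows, columns=columns)


def build_cohort(
    reports: Sequence[AdverseEventReport],
    vocab: PTVocabulary,
    fq_set: FrozenSet[str] = FQ_GENERICS,
    suspect_only: bool = False,
    apply_window: bool = True,
) -> Tuple[pd.DataFrame, CohortFlow]:
    """Run the full attrition funnel and return the analysis frame + flow."""
    n_raw = len(reports)
    windowed = filter_study_window(reports) if apply_window else list(reports)
    deduped = deduplicate(windowed)
    kept, _ = exclude_concomitant(deduped, fq_set, suspect_only=suspect_only)
    frame = cohort_frame(kept, vocab)
    flow = CohortFlow(
        n_raw=n_raw,
        n_after_dedup=len(deduped),
        n_after_exclusion=len(kept),
        n_pn=int(frame["has_pn"].sum()) if len(frame) else 0,
    )
    return frame, flow
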