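"""Bayesian disproportionality statistics (information components) and screening.

The information component (IC) compares the observed count ``n11`` of
reports mentioning both a drug and an event against the count ``e11``
expected under independence within the whole reporting database:

    e11 = n1+ * n+1 / N
    IC  = log2( (n11 + 1/2) / (e11 + 1/2) )

The half-count shrinkage stabilises low-count cells (IC of an exactly
independent table is 0 at any magnitude). Uncertainty is summarised by a
95% credible interval, either

* ``gamma_quantile`` (default): log2 of the 2.5%/97.5% quantiles of a
  Gamma(shape = n11 + 1/2, rate = e11 + 1/2) posterior — the standard
  Poisson-gamma form of the BCPNN shrinkage estimator; or
* ``noren_approx``: the closed-form asymptotic approximation
  IC025 = IC - 3.3 (n11+1/2)^(-1/2) - 2 (n11+1/2)^(-3/2),
  IC975 = IC + 2.4 (n11+1/2)^(-1/2) - 1/2 (n11+1/2)^(-3/2).

A pair is a positive signal when IC > 2 and IC025 > 0. The association
p-value is a two-sided mid-p Poisson test of ``n11`` against mean ``e11``;
the method name is stamped into every output row because different
pharmacovigilance packages make different choices here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

from .core import ALL_FQ_LABEL, COMBINATION, EXPOSURE_ORDER
from .vocabulary import CATEGORIES, PTVocabulary

logger = logging.getLogger(__name__)

IC_SIGNAL_THRESHOLD = 2.0
IC025_SIGNAL_THRESHOLD = 0.0
MIN_CASES_DEFAULT = 3
INTERVAL_METHODS = ("gamma_quantile", "noren_approx")


@dataclass(frozen=True)
class ContingencyTable:
    """(n11, n1+, n+1, N) for one drug-event pair against the whole database."""

    n11: int
    n1plus: int
    nplus1: int
    N: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n1plus, self.nplus1, self.N) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n11 > min(self.n1plus, self.nplus1):
            raise ValueError(f"n11={self.n11} exceeds a margin ({self.n1plus}, {self.nplus1})")
        if max(self.n1plus, self.nplus1) > self.N:
            raise ValueError("margins exceed the database size N")


@dataclass(frozen=True)
class ICResult:
    e11: float
    ic: float
    ic025: float
    ic975: float
    p_value: float
    method: str
    positive_signal: bool


@dataclass(frozen=True)
class BackgroundSummary:
    """Whole-database comparator carried as summary counts, not raw rows.

    ``events`` maps an event definition (the pooled PN outcome, a single
    PT, or a symptom category) to its database-wide report count n+1.
    The summary deliberately includes the drug stratum of interest: the
    comparator is the full database, not a leave-one-out background.
    """

    n_total: int
    events: Dict[str, int]

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("background N must be positive")
        for event, count in self.events.items():
            if not 0 <= count <= self.n_total:
                raise ValueError(f"background count for {event!r} outside [0, N]")

    def nplus1(self, event: str) -> Optional[int]:
        return self.events.get(event)


def expected_count(tbl: ContingencyTable) -> float:
    """Independence expectation e11 = n1+ n+1 / N."""
    if tbl.N == 0:
        raise ValueError("empty database: N = 0")
    return tbl.n1plus * tbl.nplus1 / tbl.N


def ic_point(tbl: ContingencyTable) -> float:
    e11 = expected_count(tbl)
    return math.log2((tbl.n11 + 0.5) / (e11 + 0.5))


def ic_interval(tbl: ContingencyTable, level: float = 0.95, method: str = "gamma_quantile"):
    """Credible interval for the IC; see module docstring for the two forms."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"interval level must be in (0, 1), got {level}")
    if method not in INTERVAL_METHODS:
        raise ValueError(f"unknown interval method {method!r}")
    shape = tbl.n11 + 0.5
    rate = expected_count(tbl) + 0.5
    alpha = (1.0 - level) / 2.0
    if method == "gamma_quantile":
        lo = math.log2(stats.gamma.ppf(alpha, a=shape, scale=1.0 / rate))
        hi = math.log2(stats.gamma.ppf(1.0 - alpha, a=shape, scale=1.0 / rate))
        return lo, hi
    ic = ic_point(tbl)
    lo = ic - 3.3 * shape ** -0.5 - 2.0 * shape ** -1.5
    hi = ic + 2.4 * shape ** -0.5 - 0.5 * shape ** -1.5
    return lo, hi


def ic_pvalue(tbl: ContingencyTable) -> float:
    """Two-sided mid-p Poisson test of n11 against the independence mean."""
    e11 = expected_count(tbl)
    if e11 == 0:
        return 0.0 if tbl.n11 > 0 else 1.0
    x = tbl.n11
    pmf = stats.poisson.pmf(x, e11)
    lower = stats.poisson.cdf(x - 1, e11) + 0.5 * pmf  # P(X < x) + pmf/2
    upper = stats.poisson.sf(x, e11) + 0.5 * pmf  # P(X > x) + pmf/2
    return float(min(1.0, 2.0 * min(lower, upper)))


def ic_result(tbl: ContingencyTable, method: str = "gamma_quantile", level: float = 0.95) -> ICResult:
    e11 = expected_count(tbl)
    ic = ic_point(tbl)
    lo, hi = ic_interval(tbl, level=level, method=method)
    p = ic_pvalue(tbl)
    return ICResult(
        e11=e11,
        ic=ic,
        ic025=lo,
        ic975=hi,
        p_value=p,
        method=method,
        positive_signal=bool(ic > IC_SIGNAL_THRESHOLD and lo > IC025_SIGNAL_THRESHOLD),
    )


# ---------------------------------------------------------------------------
# cohort-level screening

_UNITS = ("drug_overall", "drug_by_pt", "drug_by_category")
PN_EVENT = "PN"


def _exposure_counts(frame: pd.DataFrame) -> Dict[str, int]:
    counts = frame["exposure"].value_counts().to_dict()
    return {exp: int(counts.get(exp, 0)) for exp in EXPOSURE_ORDER}


def _event_cases(frame: pd.DataFrame, unit: str, vocab: Optional[PTVocabulary]) -> Dict[str, pd.Series]:
    """Boolean case membership per event definition."""
    if unit == "drug_overall":
        return {PN_EVENT: frame["has_pn"]}
    if unit == "drug_by_category":
        return {cat: frame[f"cat_{cat}"] for cat in CATEGORIES}
    if unit == "drug_by_pt":
        pts: Set[str] = set()
        for case_pts in frame.loc[frame["has_pn"], "pn_pts"]:
            pts.update(case_pts)
        return {
            pt: frame["pn_pts"].map(lambda case_pts, _pt=pt: _pt in case_pts)
            for pt in sorted(pts)
        }
    raise ValueError(f"unknown screening unit {unit!r}")


def screen(
    frame: pd.DataFrame,
    background: BackgroundSummary,
    vocab: Optional[PTVocabulary] = None,
    unit: str = "drug_overall",
    min_cases: int = MIN_CASES_DEFAULT,
    method: str = "gamma_quantile",
    include_pooled: bool = True,
) -> pd.DataFrame:
    """Disproportionality screen over exposures x event definitions.

    Emits one row per (exposure, event); rows with fewer than ``min_cases``
    observed cases keep their counts but have the IC columns suppressed and
    a ``below_min`` flag, mirroring the reporting rule of requiring three
    or more cases before interpreting a signal. Events without a comparator
    count in ``background`` are skipped with a log entry.
    """
    if unit not in _UNITS:
        raise ValueError(f"unknown screening unit {unit!r}")
    exposures = _exposure_counts(frame)
    events = _event_cases(frame, unit, vocab)
    labels = [exp for exp in EXPOSURE_ORDER if exposures[exp] > 0]
    if include_pooled:
        labels.append(ALL_FQ_LABEL)

    rows: List[dict] = []
    for event, member in events.items():
        nplus1 = background.nplus1(event)
        if nplus1 is None:
            logger.warning("event %r has no background comparator count; skipped", event)
            continue
        for exp in labels:
            if exp == ALL_FQ_LABEL:
                n11 = int(member.sum())
                n1plus = int(len(frame))
            else:
                mask = frame["exposure"] == exp
                n11 = int(member[mask].sum())
                n1plus = exposures[exp]
            row = {
                "exposure": exp,
                "event": event,
                "n11": n11,
                "n1plus": n1plus,
                "nplus1": nplus1,
                "N": background.n_total,
                "below_min": n11 < min_cases,
            }
            if n11 < min_cases:
                row.update(
                    e11=np.nan, ic=np.nan, ic025=np.nan, ic975=np.nan,
                    p_value=np.nan, method=method, positive_signal=False,
                )
            else:
                res = ic_result(ContingencyTable(n11, n1plus, nplus1, background.n_total), method=method)
                row.update(
                    e11=res.e11, ic=res.ic, ic025=res.ic025, ic975=res.ic975,
                    p_value=res.p_value, method=res.method, positive_signal=res.positive_signal,
                )
            rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["event", "exposure"], kind="stable").reset_index(drop=True)
    return out


def shared_signal_prioritization(pt_screen: pd.DataFrame, min_individual: int = 3) -> Set[str]:
    """PTs with a strong pooled signal confirmed by several individual FQs.

    Selects PTs whose pooled (all-FQ) IC exceeds 2 and which are positive
    signals in at least ``min_individual`` individual fluoroquinolones
    (combination therapy does not count as an individual agent).
    """
    individual = set(EXPOSURE_ORDER) - {COMBINATION}
    selected: Set[str] = set()
    for pt, group in pt_screen.groupby("event"):
        pooled = group[group["exposure"] == ALL_FQ_LABEL]
        if pooled.empty or not (pooled["ic"].iloc[0] > IC_SIGNAL_THRESHOLD):
            continue
        n_pos = int(group[group["exposure"].isin(individual)]["positive_signal"].sum())
        if n_pos >= min_individual:
            selected.add(pt)
    return selected


def ic_matrix(screen_table: pd.DataFrame) -> pd.DataFrame:
    """Exposure x event matrix of IC values (heat-map-ready)."""
    return screen_table.pivot(index="event", columns="exposure", values="ic")
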