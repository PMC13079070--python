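"""Descriptive tables, contingency tests and segmented yearly-trend fits.

Covers the descriptive surface of the analysis: demographic and outcome
breakdowns by exposure (overall and within the peripheral-neuropathy
subset), the concurrent-event and fatality summaries, chi-square/Fisher
tests for categorical contrasts, and piecewise negative-binomial
regression of yearly report counts with fixed breakpoints at the 2016
boxed-warning revision and at 2020.

Percentages in report tables are rounded half-up to match the
presentation convention of published pharmacovigilance tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import AGE_GROUPS, COMBINATION, EXPOSURE_ORDER
from .vocabulary import CATEGORIES, PTVocabulary

logger = logging.getLogger(__name__)

TREND_SEGMENTS = [(2007, 2015), (2016, 2019), (2020, 2024)]
PARTIAL_YEAR_FRACTION = {2024: 0.75}  # Q1-Q3 only


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding (2.345 -> 2.35), as printed tables use."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numer: int, denom: int, digits: int = 2) -> float:
    return round_half_up(100.0 * numer / denom, digits) if denom else float("nan")


# ---------------------------------------------------------------------------
# descriptive tables


def _breakdown(frame: pd.DataFrame, column: str) -> pd.DataFrame:
    """Counts and within-exposure percentages of one attribute by exposure."""
    if frame.empty:
        return pd.DataFrame(columns=["exposure", column, "n", "pct"])
    rows = []
    for exposure, sub in frame.groupby("exposure", sort=False):
        total = len(sub)
        for level, count in sub[column].value_counts().sort_index().items():
            rows.append({"exposure": exposure, column: level, "n": int(count), "pct": _pct(count, total)})
    return pd.DataFrame(rows)


def cohort_summary(frame: pd.DataFrame, vocab: Optional[PTVocabulary] = None, top_k: int = 20) -> dict:
    """Nested descriptive tables plus the headline shares of the analysis.

    Returns a dict with ``headline`` (scalar percentages), ``tables``
    (per-attribute breakdowns, overall and within the PN subset),
    ``pn_pt_counts`` (carrier counts of each PN term among PN cases) and
    ``concurrent_pts`` (top concurrent non-PN terms with SOC labels).
    """
    n = len(frame)
    pn = frame[frame["has_pn"]] if n else frame
    n_pn = len(pn)
    comb = frame[frame["exposure"] == COMBINATION] if n else frame

    headline = {
        "n_reports": n,
        "n_pn": n_pn,
        "n_neuro": int(frame["has_neuro"].sum()) if n else 0,
        "pn_percent": _pct(n_pn, n, 1),
        "neuro_percent": _pct(int(frame["has_neuro"].sum()), n, 1) if n else float("nan"),
        "pn_share_of_neuro": _pct(n_pn, int(frame["has_neuro"].sum()), 1) if n else float("nan"),
        "concurrent_pct": _pct(int(pn["concurrent_non_pn"].sum()), n_pn),
        "pn_only_pct": _pct(n_pn - int(pn["concurrent_non_pn"].sum()), n_pn),
        "combination_pn_share": _pct(int(comb["has_pn"].sum()), len(comb)) if n else float("nan"),
    }
    for cat in CATEGORIES:
        count = int(pn[f"cat_{cat}"].sum()) if n_pn else 0
        headline[f"{cat}_pct"] = _pct(count, n_pn)
        headline[f"{cat}_n"] = count

    pt_counts: Dict[str, int] = {}
    for pts in pn["pn_pts"] if n_pn else []:
        for pt in pts:
            pt_counts[pt] = pt_counts.get(pt, 0) + 1
    pn_pt_table = pd.DataFrame(
        [{"pt": pt, "n": c, "pct_of_pn": _pct(c, n_pn)} for pt, c in
         sorted(pt_counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    )

    concurrent_counts: Dict[str, int] = {}
    if n_pn:
        pn_terms = set(pt_counts)
        for reactions, pts in zip(pn["reactions"], pn["pn_pts"]):
            for pt in set(reactions) - set(pts):
                concurrent_counts[pt] = concurrent_counts.get(pt, 0) + 1
    concurrent_table = pd.DataFrame(
        [
            {"pt": pt, "n": c, "soc": vocab.soc_of(pt) if vocab else "Unknown"}
            for pt, c in sorted(concurrent_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        ]
    )

    tables = {}
    for column in ["sex", "age_group", "reporter", "country", "serious", "outcome_flags"]:
        tables[column] = _breakdown(frame, column)
        tables[f"pn_{column}"] = _breakdown(pn, column)

    return {
        "headline": headline,
        "tables": tables,
        "pn_pt_counts": pn_pt_table,
        "concurrent_pts": concurrent_table,
    }


# ---------------------------------------------------------------------------
# contingency tests


def contingency_test(table, method: str = "auto") -> Tuple[float, float]:
    """Chi-square or Fisher exact test of an r x c count table.

    ``auto`` uses Fisher's exact test for 2x2 tables with any expected
    cell below 5 and the chi-square test (without continuity correction)
    otherwise. Returns ``(statistic, p)``; for Fisher the statistic is
    the sample odds ratio.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must be a 2-D array of non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate contingency table: zero row or column margin")
    if method not in {"auto", "chi_square", "fisher"}:
        raise ValueError(f"unknown test method {method!r}")
    if method == "auto":
        if arr.shape == (2, 2):
            expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
            method = "fisher" if (expected < 5).any() else "chi_square"
        else:
            method = "chi_square"
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        odds, p = stats.fisher_exact(arr.astype(int))
        return float(odds), float(p)
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


# ---------------------------------------------------------------------------
# yearly series and trend fits


def yearly_series(frame: pd.DataFrame, years: Sequence[int] = range(2007, 2025)) -> pd.DataFrame:
    """Annual report totals and PN counts; conserves the cohort size."""
    out = pd.DataFrame({"year": list(years)})
    if len(frame):
        counts = frame.groupby("year").agg(n_total=("case_id", "size"), n_pn=("has_pn", "sum"))
        out = out.merge(counts, left_on="year", right_index=True, how="left").fillna(0)
    else:
        out["n_total"] = 0
        out["n_pn"] = 0
    out["n_total"] = out["n_total"].astype(int)
    out["n_pn"] = out["n_pn"].astype(int)
    return out


@dataclass(frozen=True)
class TrendFit:
    segment: Tuple[int, int]
    slope: float  # per-year change in log reporting rate
    slope_se: float
    dispersion: float  # NB2 alpha; 0 under the Poisson fallback
    p_slope: float
    model: str  # "negative_binomial" or "poisson_fallback"

    def __post_init__(self) -> None:
        lo, hi = self.segment
        if not (2007 <= lo <= hi <= 2024):
            raise ValueError(f"segment {self.segment} outside the study years")


def nb_trend(
    series: pd.DataFrame,
    segment: Tuple[int, int],
    response: str = "counts",
    partial_year_fraction: Optional[Dict[int, float]] = None,
) -> TrendFit:
    """Maximum-likelihood negative-binomial fit of a yearly-count segment.

    ``response='counts'`` models the annual totals; ``response=
    'pn_counts_with_offset'`` models PN counts with ``log(n_total)`` as
    offset (a reporting-proportion trend). Partial years contribute an
    exposure-fraction offset so a short final year does not mimic a drop.
    When the estimated dispersion collapses to zero the Poisson fit is
    reported instead, flagged via ``model``.
    """
    if response not in {"counts", "pn_counts_with_offset"}:
        raise ValueError(f"unknown response {response!r}")
    if partial_year_fraction is None:
        partial_year_fraction = PARTIAL_YEAR_FRACTION
    lo, hi = segment
    sub = series[(series["year"] >= lo) & (series["year"] <= hi)].sort_values("year")
    if len(sub) < 3:
        raise ValueError(f"segment {segment} has fewer than 3 years of data")
    y = (sub["n_total"] if response == "counts" else sub["n_pn"]).to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero counts in segment; nothing to fit")
    frac = sub["year"].map(lambda yr: partial_year_fraction.get(int(yr), 1.0)).to_numpy(dtype=float)
    offset = np.log(frac)
    if response == "pn_counts_with_offset":
        n_total = sub["n_total"].to_numpy(dtype=float)
        if np.any(n_total == 0):
            raise ValueError("offset response requires nonzero yearly totals")
        offset = offset + np.log(n_total)
    years = sub["year"].to_numpy(dtype=float)
    X = sm.add_constant(years - years.mean())

    alpha = 0.0
    result = None
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # boundary dispersion warns; handled via fallback
            model = sm.NegativeBinomial(y, X, offset=offset)
            result = model.fit(disp=0, maxiter=200)
        alpha = float(result.params[-1])
        if not result.mle_retvals.get("converged", True):
            result = None
    except Exception:  # noqa: BLE001 - fall back to Poisson below
        result = None
    if result is not None and alpha > 1e-8:
        slope, se = float(result.params[1]), float(result.bse[1])
        p = float(result.pvalues[1])
        if np.isfinite(se) and np.isfinite(p):
            return TrendFit(segment, slope, se, alpha, p, "negative_binomial")
    logger.info("dispersion at boundary or NB fit failed for %s; using Poisson", segment)
    pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    return TrendFit(segment, float(pois.params[1]), float(pois.bse[1]), 0.0,
                    float(pois.pvalues[1]), "poisson_fallback")


def fit_trend_segments(
    series: pd.DataFrame,
    segments: Sequence[Tuple[int, int]] = tuple(TREND_SEGMENTS),
    response: str = "counts",
) -> List[TrendFit]:
    return [nb_trend(series, seg, response=response) for seg in segments]


# ---------------------------------------------------------------------------
# fatality summary


def fatality_summary(frame: pd.DataFrame) -> dict:
    """Fatal-outcome breakdowns by sex, age group, PN status and therapy type.

    Includes the monotherapy-versus-combination fatal proportions and
    their 2x2 test (skipped for degenerate tables, e.g. no deaths).
    """
    fatal = frame[frame["fatal"]] if len(frame) else frame
    n_fatal = len(fatal)
    mono = frame[frame["exposure"] != COMBINATION]
    comb = frame[frame["exposure"] == COMBINATION]
    mono_fatal = int(mono["fatal"].sum()) if len(mono) else 0
    comb_fatal = int(comb["fatal"].sum()) if len(comb) else 0

    by_sex = {s: int((fatal["sex"] == s).sum()) for s in ("male", "female", "unknown")}
    by_age = {g: int((fatal["age_group"] == g).sum()) for g in AGE_GROUPS + ("unknown",)}
    table_2x2 = [[mono_fatal, len(mono) - mono_fatal], [comb_fatal, len(comb) - comb_fatal]]
    try:
        stat, p = contingency_test(table_2x2, method="auto")
    except ValueError:
        stat, p = float("nan"), float("nan")

    return {
        "n_fatal": n_fatal,
        "fatal_pct_of_cohort": _pct(n_fatal, len(frame)),
        "n_fatal_pn": int(fatal["has_pn"].sum()) if n_fatal else 0,
        "by_sex": by_sex,
        "male_share_pct": _pct(by_sex["male"], n_fatal),
        "female_share_pct": _pct(by_sex["female"], n_fatal),
        "by_age_group": by_age,
        "by_exposure": {e: int((fatal["exposure"] == e).sum()) for e in EXPOSURE_ORDER},
        "monotherapy_fatal": mono_fatal,
        "monotherapy_fatal_pct": _pct(mono_fatal, len(mono)),
        "combination_fatal": comb_fatal,
        "combination_fatal_pct": _pct(comb_fatal, len(comb)),
        "mono_vs_combination_test": {"statistic": stat, "p": p},
    }
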