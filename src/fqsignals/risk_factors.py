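"""Demographic risk-factor screening: kNN imputation and univariate odds ratios.

Missing ages and sexes are completed by k-nearest-neighbour imputation
(k = 5 by default) over a mixed numeric/one-hot feature embedding
(exposure label, age, sex, report year, seriousness, fatal outcome).
Distances are Euclidean over the dimensions observed in both records,
rescaled by the fraction of usable dimensions — the convention of
nan-aware Euclidean distance. Missing ages take the neighbour mean;
missing sexes take the neighbour mode, ties resolved in favour of the
nearer neighbour. Imputation is deterministic and invariant to row
order (ties in distance break on case id) and never alters an observed
value.

Odds ratios for reporting a peripheral-neuropathy event come from
univariate logistic regressions, one per factor, each level contrasted
with a stated reference (exposure vs ciprofloxacin, female vs male, age
groups vs 0-17, severity vs non-serious), with Wald 95% intervals and
Bonferroni-adjusted p-values over the whole screening family. For a
binary factor the fitted odds ratio equals the 2x2 cross-product ratio
exactly. These are reporting odds ratios over a spontaneous-report
cohort: they characterise reporting patterns, not causal risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core import COMBINATION, EXPOSURE_ORDER

logger = logging.getLogger(__name__)

DEFAULT_REFERENCES = {"exposure": "CFX", "sex": "male", "age_group": "0-17", "severity": "non_serious"}


@dataclass(frozen=True)
class ImputationSpec:
    k: int = 5
    variables: Tuple[str, ...] = ("exposure", "age", "sex", "year", "serious", "fatal")

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


@dataclass(frozen=True)
class ORResult:
    factor: str
    level: str
    reference: str
    n: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float
    estimable: bool


# ---------------------------------------------------------------------------
# imputation


def _feature_matrix(frame: pd.DataFrame, spec: ImputationSpec) -> np.ndarray:
    """Numeric embedding; NaN marks a missing variable (all its columns)."""
    n = len(frame)
    cols: List[np.ndarray] = []
    if "exposure" in spec.variables:
        for exp in EXPOSURE_ORDER:
            cols.append((frame["exposure"] == exp).to_numpy(dtype=float))
    if "age" in spec.variables:
        age = frame["age_years"].to_numpy(dtype=float)
        observed = age[~np.isnan(age)]
        scale = observed.std() or 1.0
        center = observed.mean() if observed.size else 0.0
        cols.append((age - center) / scale)
    if "sex" in spec.variables:
        sex = frame["sex"].to_numpy()
        female = np.where(sex == "unknown", np.nan, (sex == "female").astype(float))
        male = np.where(sex == "unknown", np.nan, (sex == "male").astype(float))
        cols.extend([female, male])
    if "year" in spec.variables:
        year = frame["year"].to_numpy(dtype=float)
        scale = np.nanstd(year) or 1.0
        cols.append((year - np.nanmean(year)) / scale)
    if "serious" in spec.variables:
        cols.append(frame["serious"].to_numpy(dtype=float))
    if "fatal" in spec.variables:
        cols.append(frame["fatal"].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def knn_impute(frame: pd.DataFrame, spec: Optional[ImputationSpec] = None) -> pd.DataFrame:
    """Return a copy of the cohort with missing age/sex completed and flagged.

    Neighbours are drawn from records complete on both age and sex; at
    least ``k`` such records must exist.
    """
    spec = spec or ImputationSpec()
    out = frame.copy()
    out["age_imputed"] = False
    out["sex_imputed"] = False

    age_missing = out["age_years"].isna().to_numpy()
    sex_missing = (out["sex"] == "unknown").to_numpy()
    targets = np.flatnonzero(age_missing | sex_missing)
    if targets.size == 0:
        return out

    complete = np.flatnonzero(~age_missing & ~sex_missing)
    if complete.size < spec.k:
        raise ValueError(f"kNN imputation needs at least k={spec.k} complete records, found {complete.size}")

    X = _feature_matrix(out, spec)
    # deterministic, order-invariant: pool sorted by case id, stable argsort
    pool_order = complete[np.argsort(out["case_id"].to_numpy()[complete], kind="stable")]
    pool_X = X[pool_order]
    pool_age = out["age_years"].to_numpy(dtype=float)[pool_order]
    pool_sex = out["sex"].to_numpy()[pool_order]

    new_age = out["age_years"].to_numpy(dtype=float).copy()
    new_sex = out["sex"].to_numpy(dtype=object).copy()
    chunk = 2048
    for lo in range(0, targets.size, chunk):
        idx = targets[lo:lo + chunk]
        dist = nan_euclidean_distances(X[idx], pool_X)
        order = np.argsort(dist, axis=1, kind="stable")[:, : spec.k]
        for row, i in enumerate(idx):
            neighbours = order[row]
            if age_missing[i]:
                new_age[i] = float(pool_age[neighbours].mean())
            if sex_missing[i]:
                votes: Dict[str, int] = {}
                for j in neighbours:
                    votes[pool_sex[j]] = votes.get(pool_sex[j], 0) + 1
                top = max(votes.values())
                winners = {s for s, v in votes.items() if v == top}
                for j in neighbours:  # tie -> the nearer neighbour's value
                    if pool_sex[j] in winners:
                        new_sex[i] = pool_sex[j]
                        break
    out["age_years"] = new_age
    out["sex"] = new_sex
    out.loc[age_missing, "age_imputed"] = True
    out.loc[sex_missing, "sex_imputed"] = True
    # refresh the derived age grouping for downstream screens
    from .core import age_group

    out["age_group"] = out["age_years"].map(age_group)
    return out


# ---------------------------------------------------------------------------
# univariate odds ratios


def severity_level(row: pd.Series) -> str:
    """Three-level outcome severity: non-serious / serious / critical."""
    if row["fatal"] or "life_threatening" in str(row["outcome_flags"]):
        return "critical"
    return "serious" if row["serious"] else "non_serious"


def univariate_or(
    frame: pd.DataFrame,
    factor: str,
    reference: Optional[str] = None,
    outcome: str = "has_pn",
    drop_levels: Sequence[str] = ("unknown",),
) -> List[ORResult]:
    """One univariate logistic regression of the PN flag on one factor.

    Emits one row per non-reference level. Levels with an empty outcome
    cell are flagged non-estimable instead of being fitted.
    """
    if factor == "severity" and "severity" not in frame.columns:
        frame = frame.assign(severity=frame.apply(severity_level, axis=1))
    reference = reference or DEFAULT_REFERENCES.get(factor)
    if reference is None:
        raise ValueError(f"no reference level for factor {factor!r}")
    data = frame[~frame[factor].astype(str).isin(drop_levels)]
    levels = sorted(data[factor].astype(str).unique())
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from factor {factor!r}")

    y = data[outcome].to_numpy(dtype=float)
    results: List[ORResult] = []
    contrast = [lv for lv in levels if lv != reference]
    estimable = []
    for lv in contrast:
        mask = (data[factor].astype(str) == lv).to_numpy()
        a, b = y[mask].sum(), (1 - y[mask]).sum()
        if a == 0 or b == 0:
            results.append(ORResult(factor, lv, reference, int(mask.sum()), float("nan"),
                                    float("nan"), float("nan"), float("nan"), float("nan"), False))
        else:
            estimable.append(lv)
    ref_mask = (data[factor].astype(str) == reference).to_numpy()
    if y[ref_mask].sum() == 0 or (1 - y[ref_mask]).sum() == 0:
        logger.warning("reference level %r has an empty outcome cell; factor %s skipped", reference, factor)
        return results

    if estimable:
        keep = data[factor].astype(str).isin(estimable + [reference]).to_numpy()
        sub = data[keep]
        dummies = pd.get_dummies(sub[factor].astype(str))[estimable].to_numpy(dtype=float)
        X = sm.add_constant(dummies)
        fit = sm.Logit(sub[outcome].to_numpy(dtype=float), X).fit(disp=0, method="newton", tol=1e-10)
        for pos, lv in enumerate(estimable, start=1):
            beta, se = float(fit.params[pos]), float(fit.bse[pos])
            results.append(
                ORResult(
                    factor=factor,
                    level=lv,
                    reference=reference,
                    n=int((sub[factor].astype(str) == lv).sum()),
                    odds_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                    ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                    p_raw=float(fit.pvalues[pos]),
                    p_bonferroni=float("nan"),
                    estimable=True,
                )
            )
    results.sort(key=lambda r: r.level)
    return results


def bonferroni(p_values: Sequence[float], m: int) -> List[float]:
    """Classical Bonferroni adjustment p_adj = min(1, m p), order-preserving."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than the {len(p_values)} p-values supplied")
    for p in p_values:
        if not (np.isnan(p) or 0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return [min(1.0, p * m) if not np.isnan(p) else float("nan") for p in p_values]


def screen_risk_factors(
    frame: pd.DataFrame,
    factors: Sequence[str] = ("exposure", "sex", "age_group", "severity"),
    references: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Univariate OR screen across factors with one shared Bonferroni family.

    The family size m is the number of estimable non-reference levels
    tested across all factors in the run; it is logged and stamped into
    the output.
    """
    references = {**DEFAULT_REFERENCES, **(references or {})}
    all_results: List[ORResult] = []
    for factor in factors:
        all_results.extend(univariate_or(frame, factor, references.get(factor)))
    estimable = [r for r in all_results if r.estimable]
    m = len(estimable)
    logger.info("Bonferroni family size m=%d across factors %s", m, list(factors))
    adjusted = iter(bonferroni([r.p_raw for r in estimable], m))
    rows = []
    for r in all_results:
        row = r.__dict__.copy()
        row["p_bonferroni"] = next(adjusted) if r.estimable else float("nan")
        row["m_family"] = m
        rows.append(row)
    return pd.DataFrame(rows)
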