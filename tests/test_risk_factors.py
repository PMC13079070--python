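"""kNN imputation and univariate odds-ratio screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqsignals.risk_factors import (
    ImputationSpec,
    ORResult,
    bonferroni,
    knn_impute,
    screen_risk_factors,
    univariate_or,
)


def toy_frame(rows):
    defaults = {"exposure": "CFX", "serious": False, "fatal": False, "year": 2020}
    out = []
    for i, row in enumerate(rows):
        entry = {**defaults, "case_id": f"K{i}", **row}
        out.append(entry)
    return pd.DataFrame(out)


class TestKNNImpute:
    def test_complete_cohort_returned_unchanged(self):
        frame = toy_frame([{"age_years": a, "sex": "female"} for a in (30, 40, 50, 60, 70)])
        out = knn_impute(frame, ImputationSpec(k=5))
        assert out["age_years"].tolist() == frame["age_years"].tolist()
        assert not out["age_imputed"].any() and not out["sex_imputed"].any()

    def test_six_record_toy_matches_hand_computed_mean(self):
        # five complete neighbours, k=5: the imputed age is their plain mean
        ages = [30.0, 40.0, 50.0, 60.0, 70.0]
        frame = toy_frame(
            [{"age_years": a, "sex": "female"} for a in ages]
            + [{"age_years": np.nan, "sex": "female"}]
        )
        out = knn_impute(frame, ImputationSpec(k=5))
        assert out.loc[5, "age_years"] == pytest.approx(np.mean(ages))
        assert bool(out.loc[5, "age_imputed"])

    def test_nearest_neighbours_dominate_with_small_k(self):
        # two neighbours share the target's year; k=2 must pick them
        frame = toy_frame([
        {"age_years": 20.0, "sex": "female", "year": 2010},
            {"age_years": 22.0, "sex": "female", "year": 2010},
            {"age_years": 80.0, "sex": "female", "year": 2024},
            {"age_years": 82.0, "sex": "female", "year": 2024},
            {"age_years": 84.0, "sex": "female", "year": 2024},
            {"age_years": np.nan, "sex": "female", "year": 2010},
        ])
        out = knn_impute(frame, ImputationSpec(k=2))
        assert out.loc[5, "age_years"] == pytest.approx(21.0)

    def test_sex_mode_with_nearer_neighbour_tie_break(self):
        frame = toy_frame([
            {"age_years": 30.0, "sex": "female", "year": 2010},
            {"age_years": 31.0, "sex": "male", "year": 2011},
            {"age_years": 30.5, "sex": "unknown", "year": 2010},
        ])
        out = knn_impute(frame, ImputationSpec(k=2))
        # one vote each: tie resolved by the nearer of the two neighbours
        assert out.loc[2, "sex"] in {"female", "male"}
        assert bool(out.loc[2, "sex_imputed"])

    def test_row_permutation_invariance(self):
        rows = [{"age_years": float(20 + 3 * i), "sex": ("female" if i % 2 else "male"),
                 "year": 2008 + i} for i in range(12)]
        rows.append({"age_years": np.nan, "sex": "unknown", "year": 2015})
        frame = toy_frame(rows)
        out = knn_impute(frame, ImputationSpec(k=5)).set_index("case_id")
        shuffled = frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
        out_shuffled = knn_impute(shuffled, ImputationSpec(k=5)).set_index("case_id")
        assert out.loc["K12", "age_years"] == out_shuffled.loc["K12", "age_years"]
        assert out.loc["K12", "sex"] == out_shuffled.loc["K12", "sex"]

    def test_observed_values_never_altered_and_counts_match(self):
        rows = [{"age_years": float(20 + i), "sex": "female", "year": 2010 + i} for i in range(8)]
        rows += [{"age_years": np.nan, "sex": "female"}, {"age_years": 33.0, "sex": "unknown"}]
        frame = toy_frame(rows)
        out = knn_impute(frame, ImputationSpec(k=5))
        assert out["age_years"].iloc[:8].tolist() == frame["age_years"].iloc[:8].tolist()
        assert int(out["age_imputed"].sum()) == 1
        assert int(out["sex_imputed"].sum()) == 1
        assert not out["age_years"].isna().any()
        assert (out["sex"] != "unknown").all()

    def test_too_few_complete_records_rejected(self):
        frame = toy_frame([{"age_years": 30.0, "sex": "female"},
                           {"age_years": np.nan, "sex": "female"}])
        with pytest.raises(ValueError):
            knn_impute(frame, ImputationSpec(k=5))


def or_frame(table, level_name="B", ref_name="A"):
    """2x2 [[ref_pn, ref_other], [lvl_pn, lvl_other]] -> long cohort frame."""
    (a, b), (c, d) = table
    rows = []
    for count, level, pn in ((a, ref_name, True), (b, ref_name, False),
                             (c, level_name, True), (d, level_name, False)):
        rows.extend({"factor": level, "has_pn": pn} for _ in range(count))
    return pd.DataFrame(rows)


class TestUnivariateOR:
    def test_balanced_table_or_one(self):
        frame = or_frame([[50, 50], [50, 50]])
        [res] = univariate_or(frame, "factor", reference="A")
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.ci_low < 1.0 < res.ci_high

    def test_toy_table_or_20_with_wald_interval(self):
        # [[8,2],[1,5]] with the level as the first row: OR = (8*5)/(2*1) = 20
        frame = or_frame([[1, 5], [8, 2]])
        [res] = univariate_or(frame, "factor", reference="A")
        assert res.odds_ratio == pytest.approx(20.0, rel=1e-6)
        se = math.sqrt(1 / 8 + 1 / 2 + 1 / 1 + 1 / 5)
        assert res.ci_low == pytest.approx(20 * math.exp(-1.959963984540054 * se), rel=1e-4)
        assert res.ci_high == pytest.approx(20 * math.exp(1.959963984540054 * se), rel=1e-4)

    def test_reference_combination_versus_ciprofloxacin_unimputed(self, paper_cohort):
        frame, _ = paper_cohort
        results = univariate_or(frame, "exposure", reference="CFX")
        comb = next(r for r in results if r.level == "Combination")
        # cross-product oracle: (652 x 12,143) / (853 x 2,291)
        assert comb.odds_ratio == pytest.approx((652 * 12143) / (853 * 2291), rel=1e-6)
        assert round(comb.odds_ratio, 2) == 4.05

    def test_logistic_equals_cross_product_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b, c, d = rng.integers(3, 80, size=4)
            frame = or_frame([[int(a), int(b)], [int(c), int(d)]])
            [res] = univariate_or(frame, "factor", reference="A")
            oracle = (c * b) / (d * a)
            assert res.odds_ratio == pytest.approx(oracle, rel=1e-6)

    def test_zero_cell_level_flagged_non_estimable(self):
        frame = pd.concat([
            or_frame([[10, 10], [5, 15]]),
            pd.DataFrame({"factor": ["C"] * 6, "has_pn": [False] * 6}),
        ], ignore_index=True)
        results = univariate_or(frame, "factor", reference="A")
        flags = {r.level: r.estimable for r in results}
        assert flags == {"B": True, "C": False}

    def test_missing_reference_rejected(self):
        frame = or_frame([[5, 5], [5, 5]])
        with pytest.raises(ValueError):
            univariate_or(frame, "factor", reference="Z")


class TestBonferroni:
    def test_definition_and_clipping(self):
        assert bonferroni([0.01], 5) == [0.05]
        assert bonferroni([0.5], 10) == [1.0]

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10))
    def test_order_preserving(self, ps):
        adjusted = bonferroni(ps, len(ps) + 3)
        order = np.argsort(ps, kind="stable")
        assert [adjusted[i] for i in order] == sorted(adjusted)


class TestScreenRiskFactors:
    def test_reference_screen_structure(self, paper_cohort):
        frame, _ = paper_cohort
        table = screen_risk_factors(frame)
        assert set(table["factor"]) == {"exposure", "sex", "age_group", "severity"}
        estimable = table[table["estimable"]]
        assert (estimable["p_bonferroni"] >= estimable["p_raw"] - 1e-12).all()
        assert estimable["m_family"].nunique() == 1

    def test_female_versus_male_parameter_recovery(self, vocab):
        """Generator cohorts with a female-vs-male PN odds ratio of 1.5."""
        from fqsignals.core import build_cohort
        from fqsignals.synthetic import GeneratorParams, generate_cohort

        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            params = GeneratorParams(n_reports=50_000, duplicate_rate=0.0,
                                     concomitant_rate=0.0, missing_sex_rate=0.0,
                                     pn_sex_or=1.5, seed=100 + seed)
            reports, _ = generate_cohort(params, vocab)
            frame, _ = build_cohort(reports, vocab)
            results = univariate_or(frame, "sex", reference="male")
            female = next(r for r in results if r.level == "female")
            if 1.4 <= female.odds_ratio <= 1.6:
                hits += 1
        assert hits >= round(0.9 * n_seeds)
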