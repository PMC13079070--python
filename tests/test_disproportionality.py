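"""Information-component statistics and cohort screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fqsignals.disproportionality import (
    BackgroundSummary,
    ContingencyTable,
    expected_count,
    ic_interval,
    ic_point,
    ic_pvalue,
    ic_result,
    screen,
    shared_signal_prioritization,
)


class TestContingencyTable:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ContingencyTable(50, 40, 100, 1000)  # n11 > n1+
        with pytest.raises(ValueError):
            ContingencyTable(5, 2000, 100, 1000)  # margin > N

    @pytest.mark.parametrize(
        "table,expected",
        [
            ((25, 100, 2500, 10_000), 25.0),
            ((40, 100, 1000, 10_000), 10.0),
        ],
    )
    def test_expected_count(self, table, expected):
        assert expected_count(ContingencyTable(*table)) == pytest.approx(expected)

    def test_expected_count_on_reference_ciprofloxacin_stratum(self, paper_cohort):
        _, background = paper_cohort
        tbl = ContingencyTable(2291, 14_434, background.nplus1("PN"), background.n_total)
        assert expected_count(tbl) == pytest.approx(263.42, abs=0.01)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            expected_count(ContingencyTable(0, 0, 0, 0))


class TestICPoint:
    def test_zero_at_exact_independence(self):
        assert ic_point(ContingencyTable(25, 100, 2500, 10_000)) == 0.0
        assert ic_point(ContingencyTable(2500, 10_000, 250_000, 1_000_000)) == 0.0

    def test_closed_form_value(self):
        tbl = ContingencyTable(40, 100, 1000, 10_000)
        assert ic_point(tbl) == pytest.approx(math.log2(40.5 / 10.5), rel=1e-12)

    def test_reference_ciprofloxacin_ic_rounds_to_printed_value(self, paper_cohort):
        _, background = paper_cohort
        tbl = ContingencyTable(2291, 14_434, background.nplus1("PN"), background.n_total)
        assert round(ic_point(tbl), 2) == 3.12

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=400))
    def test_monotone_in_n11_for_fixed_margins(self, n11):
        base = ic_point(ContingencyTable(n11, 500, 10_000, 1_000_000))
        higher = ic_point(ContingencyTable(n11 + 1, 500, 10_000, 1_000_000))
        assert higher > base


class TestICInterval:
    def test_level_validated(self):
        with pytest.raises(ValueError):
            ic_interval(ContingencyTable(5, 10, 100, 1000), level=1.5)

    def test_gamma_brackets_point_estimate(self):
        tbl = ContingencyTable(40, 100, 1000, 10_000)
        lo, hi = ic_interval(tbl, method="gamma_quantile")
        assert lo < ic_point(tbl) < hi

    def test_noren_agrees_with_gamma_above_20_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n11 = int(rng.integers(20, 5000))
            n1p = n11 + int(rng.integers(0, 5000))
            np1 = n11 + int(rng.integers(0, 100_000))
            N = max(n1p, np1) + int(rng.integers(100_000, 10_000_000))
            tbl = ContingencyTable(n11, n1p, np1, N)
            glo, ghi = ic_interval(tbl, method="gamma_quantile")
            nlo, nhi = ic_interval(tbl, method="noren_approx")
            assert abs(glo - nlo) < 0.15 and abs(ghi - nhi) < 0.15

    def test_width_shrinks_with_information(self):
        widths = []
        for scale in (1, 10, 100, 1000):
            tbl = ContingencyTable(40 * scale, 100 * scale, 1000 * scale, 10_000 * scale)
            lo, hi = ic_interval(tbl)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 0.05

    def test_gamma_matches_monte_carlo_quantiles(self):
        rng = np.random.default_rng(7)
        tbl = ContingencyTable(120, 500, 24_000, 1_000_000)
        lo, hi = ic_interval(tbl, method="gamma_quantile")
        draws = rng.gamma(tbl.n11 + 0.5, 1.0 / (expected_count(tbl) + 0.5), size=500_000)
        mc_lo, mc_hi = np.log2(np.quantile(draws, [0.025, 0.975]))
        assert lo == pytest.approx(mc_lo, abs=0.01)
        assert hi == pytest.approx(mc_hi, abs=0.01)


class TestICPValue:
    def test_near_one_at_the_null_center(self):
        tbl = ContingencyTable(1000, 10_000, 100_000, 1_000_000)
        assert ic_pvalue(tbl) > 0.9

    def test_strong_excess_is_tiny_against_exact_tail(self):
        tbl = ContingencyTable(40, 100, 1000, 10_000)  # e11 = 10
        p = ic_pvalue(tbl)
        exact_tail = 2 * (stats.poisson.sf(40, 10) + 0.5 * stats.poisson.pmf(40, 10))
        assert p == pytest.approx(exact_tail, rel=1e-9)
        assert p < 1e-6

    def test_monotone_in_departure_beyond_the_mode(self):
        ps = [ic_pvalue(ContingencyTable(n11, 10_000, 10_000, 1_000_000)) for n11 in (150, 200, 300)]
        assert ps == sorted(ps, reverse=True)


class TestScreen:
    def test_reference_overall_screen_has_eight_rows(self, paper_cohort):
        frame, background = paper_cohort
        table = screen(frame, background, unit="drug_overall")
        assert len(table) == 8  # 7 exposures + pooled
        pooled = table[table["exposure"] == "All FQs"]
        assert round(float(pooled["ic"].iloc[0]), 2) == 3.02

    def test_reference_combination_ic(self, paper_cohort):
        frame, background = paper_cohort
        table = screen(frame, background, unit="drug_overall")
        comb = table[table["exposure"] == "Combination"]
        assert round(float(comb["ic"].iloc[0]), 2) == 4.54

    def test_below_min_rows_suppressed_not_dropped(self, paper_cohort, vocab):
        frame, background = paper_cohort
        table = screen(frame, background, vocab, unit="drug_by_pt", min_cases=3)
        dfx = table[(table["exposure"] == "DFX")]
        assert len(dfx) > 0
        below = dfx[dfx["below_min"]]
        assert (below["n11"] < 3).all()
        assert below["ic"].isna().all()
        assert (~below["positive_signal"]).all()

    def test_order_invariance(self, paper_cohort):
        frame, background = paper_cohort
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = screen(frame, background, unit="drug_overall").reset_index(drop=True)
        b = screen(shuffled, background, unit="drug_overall").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_reference_category_totals_reproduce_printed_ics(self, paper_cohort, vocab):
        frame, background = paper_cohort
        table = screen(frame, background, vocab, unit="drug_by_category")
        pooled = table[table["exposure"] == "All FQs"].set_index("event")
        printed = {"hyposensitivity": 2.87, "hypersensitivity": 3.18,
                   "unclassified_sensory": 3.50, "motor": 3.16}
        for cat, ic in printed.items():
            assert round(float(pooled.loc[cat, "ic"]), 2) == ic


class TestSharedSignalPrioritization:
    @staticmethod
    def _row(exposure, event, ic, positive):
        return {"exposure": exposure, "event": event, "ic": ic, "positive_signal": positive}

    def _table(self, pooled_ic, n_positive):
        rows = [self._row("All FQs", "pt1", pooled_ic, pooled_ic > 2)]
        drugs = ["CFX", "LFX", "MFX", "OFX", "GFX", "DFX"]
        for i, d in enumerate(drugs):
            rows.append(self._row(d, "pt1", 2.5 if i < n_positive else 0.5, i < n_positive))
        return pd.DataFrame(rows)

    def test_two_positive_drugs_excluded(self):
        assert shared_signal_prioritization(self._table(3.0, 2)) == set()

    def test_weak_pooled_ic_excluded(self):
        assert shared_signal_prioritization(self._table(1.9, 3)) == set()

    def test_boundary_three_positive_and_strong_pooled_included(self):
        assert shared_signal_prioritization(self._table(3.0, 3)) == {"pt1"}

    def test_combination_does_not_count_as_individual(self):
        table = self._table(3.0, 2)
        table = pd.concat(
            [table, pd.DataFrame([self._row("Combination", "pt1", 4.0, True)])],
            ignore_index=True,
        )
        assert shared_signal_prioritization(table) == set()

    def test_exactly_seven_qualifying_pts_returned(self):
        frames = []
        pts = [f"pt{i}" for i in range(10)]
        for i, pt in enumerate(pts):
            qualifies = i < 7
            t = self._table(3.0 if qualifies else 1.0, 4 if qualifies else 1)
            t["event"] = pt
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        assert shared_signal_prioritization(table) == set(pts[:7])


class TestBackground:
    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            BackgroundSummary(n_total=0, events={})
        with pytest.raises(ValueError):
            BackgroundSummary(n_total=100, events={"PN": 200})
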