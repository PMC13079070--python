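"""Ingest, normalization, deduplication, exclusion and flagging."""

import datetime as dt
import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqsignals._dates import PartialDate, parse_partial_date
from fqsignals.core import (
    CohortFlow,
    ColumnMap,
    ConfigurationError,
    assign_exposure,
    dedup_key,
    deduplicate,
    exclude_concomitant,
    flag_events,
    normalize_drug_name,
    read_dashboard_export,
)

HEADER = (
    "Case ID,Suspect Product Names,Concomitant Product Names,Reactions,Reason for Use,"
    "Sex,Patient Age,Country where Event occurred,Initial FDA Received Date,Event Date,"
    "Therapy Start Date,Serious,Outcomes,Reporter Type"
)


def write_csv(tmp_path, rows, header=HEADER):
    path = tmp_path / "export.csv"
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestPartialDates:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("2016", PartialDate(2016)),
            ("2016-05", PartialDate(2016, 5)),
            ("2016-05-17", PartialDate(2016, 5, 17)),
            ("05/17/2016", PartialDate(2016, 5, 17)),
            ("17-May-2016", PartialDate(2016, 5, 17)),
            ("garbage", None),
            ("", None),
        ],
    )
    def test_parsing(self, raw, expected):
        assert parse_partial_date(raw) == expected

    def test_day_arithmetic_requires_day_precision(self):
        with pytest.raises(ValueError):
            PartialDate(2016, 5).to_date()


class TestIngest:
    def test_header_only_file_yields_empty_list(self, tmp_path):
        assert read_dashboard_export(write_csv(tmp_path, [])) == []

    def test_multivalue_cells_and_partial_dates(self, tmp_path):
        rows = [
            '1,"CIPRO; VITAMIN C",,Paraesthesia,Infection,F,54,US,2020-01-02,2016,,Yes,Hospitalized,Consumer',
            '2,LEVAQUIN,,"Paraesthesia; Tendonitis",Infection,M,33,US,2020-01-03,2020-01-01,2019-12-25,No,Non-Serious,Consumer',
            "3,AVELOX,,Dizziness,,U,,GB,2020-02-01,,,No,,Other",
        ]
        reports = read_dashboard_export(write_csv(tmp_path, rows))
        assert len(reports) == 3
        first = reports[0]
        assert first.drug_names == {"ciprofloxacin", "vitamin c"}
        assert first.event_date == PartialDate(2016)  # year precision retained
        assert first.event_date.precision == "year"
        second = reports[1]
        assert second.reaction_pts == {"Paraesthesia", "Tendonitis"}
        assert second.start_date.precision == "day"
        third = reports[2]
        assert third.sex == "unknown" and third.age_years is None

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("Case ID,Reactions,Initial FDA Received Date\n1,Paraesthesia,2020-01-01\n")
        with pytest.raises(ConfigurationError, match="Suspect Product Names"):
            read_dashboard_export(path)

    def test_empty_reaction_cell_retained_with_warning(self, tmp_path, caplog):
        rows = ["1,CIPRO,,,Infection,F,54,US,2020-01-02,,,No,,Consumer"]
        with caplog.at_level("WARNING"):
            reports = read_dashboard_export(write_csv(tmp_path, rows))
        assert len(reports) == 1 and reports[0].reaction_pts == frozenset()
        assert any("no reaction" in r.message for r in caplog.records)


class TestNormalizeDrugName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("CIPRO", "ciprofloxacin"),
            ("Levofloxacin Hemihydrate", "levofloxacin"),
            ("  moxifloxacin  HYDROCHLORIDE ", "moxifloxacin"),
            ("METFORMIN", "metformin"),
        ],
    )
    def test_canonicalization(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            normalize_drug_name("   ")


class TestDeduplicate:
    def test_identical_key_keeps_smallest_case_id(self, make_report):
        a = make_report(case_id="B")
        b = make_report(case_id="A")
        kept = deduplicate([a, b])
        assert [r.case_id for r in kept] == ["A"]

    def test_latest_received_date_wins_over_case_id(self, make_report):
        # different received dates are different keys, unless one field is
        # missing in both; here keys share everything except received date,
        # so both survive — the tie-break applies only inside a key group
        a = make_report(case_id="A", received=dt.date(2020, 6, 1))
        b = make_report(case_id="B", received=dt.date(2020, 6, 2))
        assert len(deduplicate([a, b])) == 2

    def test_one_differing_reaction_keeps_both(self, make_report):
        a = make_report(case_id="A", reactions=("Paraesthesia",))
        b = make_report(case_id="B", reactions=("Paraesthesia", "Tendonitis"))
        assert len(deduplicate([a, b])) == 2

    def test_missing_matches_missing_only(self, make_report):
        a = make_report(case_id="A", age=None)
        b = make_report(case_id="B", age=None)
        c = make_report(case_id="C", age=40.0)
        assert len(deduplicate([a, b, c])) == 2

    def test_key_invariant_to_list_ordering(self, make_report):
        a = make_report(drugs=(("ciprofloxacin", "suspect"), ("levofloxacin", "suspect")),
                        reactions=("Paraesthesia", "Tendonitis"))
        b = make_report(drugs=(("levofloxacin", "suspect"), ("ciprofloxacin", "suspect")),
                        reactions=("Tendonitis", "Paraesthesia"))
        assert dedup_key(a) == dedup_key(b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["A", "B", "C", "D"]),
                              st.sampled_from([30.0, 40.0, None]),
                              st.sampled_from(["US", "GB"])), max_size=12))
    def test_idempotent(self, specs):
        from fqsignals.core import AdverseEventReport

        reports = [
            AdverseEventReport(
                case_id=cid,  # deliberately reused ids across rows
                drugs=(("ciprofloxacin", "suspect"),),
                reaction_pts=frozenset({"Paraesthesia"}),
                sex="female",
                age_years=age,
                country=country,
                received_date=dt.date(2020, 6, 1),
            )
            for cid, age, country in specs
        ]
        once = deduplicate(reports)
        assert deduplicate(once) == once


class TestExclusionAndExposure:
    def test_pure_fq_report_retained(self, make_report):
        kept, n_excluded = exclude_concomitant([make_report()])
        assert len(kept) == 1 and n_excluded == 0

    def test_non_fq_comedication_excluded(self, make_report):
        r = make_report(drugs=(("ciprofloxacin", "suspect"), ("metformin", "concomitant")))
        kept, n_excluded = exclude_concomitant([r])
        assert kept == [] and n_excluded == 1

    def test_suspect_only_mode_ignores_concomitant_roles(self, make_report):
        r = make_report(drugs=(("ciprofloxacin", "suspect"), ("metformin", "concomitant")))
        kept, _ = exclude_concomitant([r], suspect_only=True)
        assert len(kept) == 1

    def test_exclusion_output_is_subset(self, make_report):
        reports = [make_report(case_id=str(i)) for i in range(5)]
        kept, _ = exclude_concomitant(reports)
        assert set(kept) <= set(reports)

    @pytest.mark.parametrize(
        "drugs,expected",
        [
            ((("ciprofloxacin", "suspect"),), "CFX"),
            ((("ciprofloxacin", "suspect"), ("levofloxacin", "suspect")), "Combination"),
            ((("ciprofloxacin", "suspect"), ("ciprofloxacin", "concomitant")), "CFX"),
        ],
    )
    def test_exposure_labels(self, make_report, drugs, expected):
        assert assign_exposure(make_report(drugs=drugs)) == expected

    def test_exposure_without_fq_is_a_logic_error(self, make_report):
        with pytest.raises(ValueError):
            assign_exposure(make_report(drugs=(("metformin", "suspect"),)))


class TestFlags:
    def test_pn_only(self, make_report, vocab):
        flags = flag_events(make_report(reactions=("Paraesthesia",)), vocab)
        assert flags.has_pn and flags.has_neuro and not flags.concurrent_non_pn

    def test_pn_with_concurrent(self, make_report, vocab):
        flags = flag_events(make_report(reactions=("Paraesthesia", "Tendonitis")), vocab)
        assert flags.has_pn and flags.concurrent_non_pn

    def test_neuro_non_pn(self, make_report, vocab):
        flags = flag_events(make_report(reactions=("Headache",)), vocab)
        assert flags.has_neuro and not flags.has_pn

    def test_unknown_pt_treated_non_neuro(self, make_report, vocab):
        flags = flag_events(make_report(reactions=("Completely Unknown Term",)), vocab)
        assert not flags.has_neuro and not flags.has_pn


class TestCohortFlow:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            CohortFlow(10, 12, 9, 1)
        flow = CohortFlow(10, 9, 8, 2)
        assert flow.to_dict()["n_after_exclusion"] == 8
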