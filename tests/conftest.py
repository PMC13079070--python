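import datetime as dt

import pytest

from fqsignals.core import AdverseEventReport
from fqsignals.fixture import build_fixture_reports, build_paper_marginals_fixture
from fqsignals.vocabulary import PTVocabulary


@pytest.fixture(scope="session")
def vocab() -> PTVocabulary:
    return PTVocabulary.default()


@pytest.fixture(scope="session")
def paper_cohort(vocab):
    """Reference cohort frame + comparator summary (self-checked at build)."""
    return build_paper_marginals_fixture(vocab)


@pytest.fixture(scope="session")
def paper_reports():
    reports, _cats = build_fixture_reports()
    return reports


@pytest.fixture()
def make_report():
    def _make(
        case_id="C1",
        drugs=(("ciprofloxacin", "suspect"),),
        reactions=("Paraesthesia",),
        indications=("Bacterial infection",),
        sex="female",
        age=50.0,
        country="US",
        received=dt.date(2020, 6, 1),
        serious=False,
        outcomes=frozenset({"non_serious"}),
        **kwargs,
    ) -> AdverseEventReport:
        return AdverseEventReport(
            case_id=case_id,
            drugs=tuple(drugs),
            reaction_pts=frozenset(reactions),
            indication_pts=frozenset(indications),
            sex=sex,
            age_years=age,
            country=country,
            received_date=received,
            serious=serious,
            outcome_flags=frozenset(outcomes),
            **kwargs,
        )

    return _make
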