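import pytest

from pvkit.contingency import ContingencyTable
from pvkit.records import CleanReport, DrugEntry
from pvkit.synthetic_srs import (
    SimulationConfig,
    corrupt_dates,
    generate_reports,
    inject_duplicates,
)


def make_report(report_id, drug, pts, role="PS", **kw):
    """Minimal CleanReport for contingency/screening tests."""
    return CleanReport(
        report_id=str(report_id),
        drug_entries=[DrugEntry(name=drug, role=role)],
        reaction_pts=tuple(pts),
        **kw,
    )


@pytest.fixture
def toy_reports():
    """Six-report toy database: 2 drug+event, 1 drug-only, 1 event-only,
    2 neither, for the label 'HEADACHE' and target 'ASPIRIN'."""
    return [
        make_report(1, "ASPIRIN", ["HEADACHE"]),
        make_report(2, "ASPIRIN", ["HEADACHE", "NAUSEA"]),
        make_report(3, "ASPIRIN", ["NAUSEA"]),
        make_report(4, "OTHERDRUG", ["HEADACHE"]),
        make_report(5, "OTHERDRUG", ["NAUSEA"]),
        make_report(6, "OTHERDRUG", ["RASH"]),
    ]


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_reports=2_000,
        n_drugs=5,
        n_events=50,
        signal_pairs=((0, 3, 10.0),),
        p_duplicate=0.10,
        p_bad_date=0.20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Full generator chain: reports + duplicates + corrupted dates."""
    cohort = generate_reports(small_cfg)
    cohort = inject_duplicates(cohort, small_cfg)
    cohort = corrupt_dates(cohort, small_cfg)
    return cohort


def table(a, b, c, d, label="X", level="PT"):
    return ContingencyTable(label=label, level=level, a=a, b=b, c=c, d=d)
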