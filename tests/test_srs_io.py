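import textwrap

import pytest

from pvkit import srs_io
from pvkit.records import CleanReport, DrugEntry, PartialDate, RawCase
from pvkit.srs_io import (
    FormatError,
    deduplicate,
    filter_primary_suspect,
    load_term_map,
    map_pt_to_soc,
    match_drug_names,
    read_faers_quarter,
    read_generic_csv,
    summarize_demographics,
    to_clean_report,
)


def _write(path, text):
    path.write_text(textwrap.dedent(text).lstrip("\n"), encoding="utf-8")


@pytest.fixture
def faers_dir(tmp_path):
    """Hand-written 3-case quarter, values asserted literally below."""
    _write(tmp_path / "demo.txt", """
        PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$WT$WT_COD$REPORTER_COUNTRY$OCCP_COD
        1001$100$20230101$20221215$F$54$YR$61.5$KG$US$MD
        2001$200$20230201$202212$M$6$MON$$$FR$CN
        3001$300$20230301$$UNK$$$$$JP$
        BADROW$ONLY$THREE
    """)
    _write(tmp_path / "drug.txt", """
        PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME
        1001$100$1$PS$CANCIDAS 50 MG VIAL
        1001$100$2$C$PARACETAMOL
        2001$200$1$1$CASPOFUNGIN ACETATE
        3001$300$1$SS$MICAFUNGIN
    """)
    _write(tmp_path / "reac.txt", """
        PRIMARYID$CASEID$PT
        1001$100$HEPATOTOXICITY
        1001$100$PYREXIA
        2001$200$RASH
        3001$300$SEPSIS
    """)
    _write(tmp_path / "ther.txt", """
        PRIMARYID$CASEID$DSG_DRUG_SEQ$START_DT
        1001$100$1$20221210
        2001$200$1$20221201
    """)
    _write(tmp_path / "outc.txt", """
        PRIMARYID$CASEID$OUTC_COD
        1001$100$HO
        1001$100$DE
        2001$200$OT
    """)
    return tmp_path


class TestReadFaers:
    def test_hand_fixture_parsed_literally(self, faers_dir):
        cases, log = read_faers_quarter(faers_dir)
        by_id = {c.primary_id: c for c in cases}
        assert set(by_id) == {"1001", "2001", "3001"}
        c1 = by_id["1001"]
        assert c1.case_id == "100"
        assert c1.receipt_date == PartialDate(2023, 1, 1)
        assert c1.event_date == PartialDate(2022, 12, 15)
        assert c1.sex == "F" and c1.age == 54.0 and c1.weight == 61.5
        assert [d.name for d in c1.drugs] == ["CANCIDAS 50 MG VIAL", "PARACETAMOL"]
        assert [d.role for d in c1.drugs] == ["PS", "C"]
        assert c1.drugs[0].start_date == PartialDate(2022, 12, 10)
        assert c1.reactions == ["HEPATOTOXICITY", "PYREXIA"]
        assert c1.outcomes == ["HO", "DE"]
        c2 = by_id["2001"]
        assert c2.event_date == PartialDate(2022, 12)  # partial
        assert c2.drugs[0].role == "PS"  # numeric code 1 normalised
        assert by_id["3001"].event_date is None

    def test_malformed_row_skipped_and_counted(self, faers_dir):
        _, log = read_faers_quarter(faers_dir)
        assert log.skipped["DEMO"] == 1

    def test_missing_mandatory_table_names_it(self, faers_dir):
        (faers_dir / "reac.txt").unlink()
        with pytest.raises(FormatError, match="REAC"):
            read_faers_quarter(faers_dir)


class TestDeduplicate:
    def _case(self, pid, cid, fda):
        return RawCase(primary_id=pid, case_id=cid,
                       receipt_date=srs_io.parse_date(fda))

    def test_distinct_case_ids_identity(self):
        cases = [self._case("1", "a", "20230101"), self._case("2", "b", "20230101")]
        assert deduplicate(cases) == cases

    def test_latest_receipt_date_survives(self):
        cases = [self._case("1001", "100", "20230101"),
                 self._case("1002", "100", "20230201")]
        (kept,) = deduplicate(cases)
        assert kept.primary_id == "1002"

    def test_tie_broken_by_larger_primary_id(self):
        cases = [self._case("2001", "200", "20230101"),
                 self._case("2009", "200", "20230101")]
        (kept,) = deduplicate(cases)
        assert kept.primary_id == "2009"

    def test_idempotent(self, small_cohort):
        once = deduplicate(small_cohort.reports)
        assert deduplicate(once) == once


class TestDrugMatching:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Cancidas 50 mg vial", True),
            ("CASPOFUNGIN ACETATE", True),
            ("MICAFUNGIN", False),
        ],
    )
    def test_substring_match(self, name, expected):
        case = RawCase(primary_id="1", case_id="1",
                       drugs=[DrugEntry(name=name)])
        assert match_drug_names(case, ["CASPOFUNGIN", "CANCIDAS"]) == [expected]

    def test_empty_names_rejected(self):
        with pytest.raises(ValueError):
            match_drug_names(RawCase(primary_id="1", case_id="1"), [])


class TestFilterPrimarySuspect:
    def _case(self, role, name="CASPOFUNGIN"):
        return RawCase(primary_id="1", case_id="1",
                       drugs=[DrugEntry(name=name, role=role)],
                       reactions=["RASH"])

    def test_role_rules(self):
        assert filter_primary_suspect([self._case("C")], ["CASPOFUNGIN"]) == []
        out = filter_primary_suspect([self._case("PS")], ["CASPOFUNGIN"])
        assert len(out) == 1 and isinstance(out[0], CleanReport)

    def test_synthetic_cohort_ps_count_matches_truth(self, small_cohort, small_cfg):
        deduped = deduplicate(small_cohort.reports)
        # every generated report is PS for its single drug, so filtering on
        # the full drug-name universe returns every case
        out = filter_primary_suspect(deduped, ["DRUG"])
        assert len(out) == small_cohort.truth["n_cases"]


class TestTermMap:
    def test_lookup_and_unmapped_policy(self):
        r = CleanReport(report_id="1",
                        reaction_pts=("HEPATOTOXICITY", "WEIRDNESS"))
        reports, n_unmapped = map_pt_to_soc(
            [r], {"HEPATOTOXICITY": "Hepatobiliary disorders"}
        )
        assert reports[0].pt_soc["HEPATOTOXICITY"] == "Hepatobiliary disorders"
        assert reports[0].pt_soc["WEIRDNESS"] == "UNMAPPED"
        assert n_unmapped == 1

    def test_multiset_of_socs(self):
        tm = {"A": "SOC1", "B": "SOC1", "C": "SOC2"}
        r = CleanReport(report_id="1", reaction_pts=("A", "B", "C"))
        map_pt_to_soc([r], tm)
        socs = [r.pt_soc[pt] for pt in r.reaction_pts]
        assert len(socs) == 3 and len(set(socs)) == 2

    def test_empty_map_is_configuration_error(self):
        with pytest.raises(ValueError):
            map_pt_to_soc([], {})

    def test_conflicting_map_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("PT,SOC\nA,S1\nA,S2\n")
        with pytest.raises(FormatError):
            load_term_map(tmp_path / "m.csv")


class TestReadGenericCsv:
    def test_join_and_dedup(self, tmp_path):
        (tmp_path / "demo.csv").write_text(
            "Report_ID,Sex\n" + "".join(f"r{i},F\n" for i in range(5))
        )
        (tmp_path / "reac.csv").write_text(
            "Report_ID,PT\n"
            + "".join(f"r{i},RASH\n" for i in range(5))
            + "r0,RASH\n"  # exact duplicate row: dropped before join
            + "r1,NAUSEA\n"
        )
        cases, _ = read_generic_csv(tmp_path)
        assert len(cases) == 5
        by_id = {c.primary_id: c for c in cases}
        assert by_id["r0"].reactions == ["RASH"]
        assert by_id["r1"].reactions == ["RASH", "NAUSEA"]

    def test_missing_key_column(self, tmp_path):
        (tmp_path / "demo.csv").write_text("Oops,Sex\n1,F\n")
        with pytest.raises(FormatError, match="Report_ID"):
            read_generic_csv(tmp_path)


class TestSummarizeDemographics:
    def _reports(self, sexes=(), outcomes=()):
        reports = []
        i = 0
        for sex, n in sexes:
            for _ in range(n):
                reports.append(CleanReport(report_id=str(i), sex=sex,
                                           reaction_pts=("X",)))
                i += 1
        for ocs in outcomes:
            reports.append(CleanReport(report_id=str(i), outcome_codes=ocs,
                                       reaction_pts=("X",)))
            i += 1
        return reports

    def test_sex_percentages_of_tally_total(self):
        reports = self._reports(sexes=[("female", 802), ("male", 1192),
                                       ("unknown", 276)])
        out = summarize_demographics(reports)
        sex = out["sex"].set_index("category")
        assert round(float(sex.loc["Male", "pct"]), 1) == 52.5
        assert round(float(sex.loc["Female", "pct"]), 1) == 35.3

    def test_outcome_percentages(self):
        counts = {"HO": 489, "LT": 130, "DS": 18, "RI": 6, "DE": 919,
                  "OT": 427, "UNK": 281}
        reports = self._reports(outcomes=[(oc,) for oc, n in counts.items()
                                          for _ in range(n)])
        out = summarize_demographics(reports)
        oc = out["outcome"].set_index("category")
        assert round(float(oc.loc["DE", "pct"]), 1) == 40.5
        assert round(float(oc.loc["HO", "pct"]), 1) == 21.5

    def test_multivalued_outcomes_use_tally_denominator(self):
        # 2 reports, 4 outcome entries: percentages are of the 4 entries
        reports = self._reports(outcomes=[("DE", "HO"), ("DE", "LT")])
        oc = summarize_demographics(reports)["outcome"].set_index("category")
        assert float(oc.loc["DE", "pct"]) == pytest.approx(50.0)

    def test_all_unknown_degenerate(self):
        reports = [CleanReport(report_id=str(i), reaction_pts=("X",))
                   for i in range(10)]
        out = summarize_demographics(reports)
        for key in ("sex", "age", "weight"):
            df = out[key].set_index("category")
            assert df.loc["Unknown", "count"] == 10
            assert float(df.loc["Unknown", "pct"]) == pytest.approx(100.0)
            assert (df.drop("Unknown")["count"] == 0).all()

    def test_age_bands_configurable(self):
        reports = [CleanReport(report_id="1", age_years=16, reaction_pts=("X",))]
        default = summarize_demographics(reports)["age"].set_index("category")
        jader = summarize_demographics(reports, age_cuts=(15, 65))["age"] \
            .set_index("category")
        assert default.loc["<18", "count"] == 1
        assert jader.loc["15–65", "count"] == 1
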