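"""Report ingestion, normalization and drug-event aggregation."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dilipred import (
    DrugEventMatrix,
    EventLevel,
    PTSOCMap,
    ReportRecord,
    Role,
    SynonymTable,
    build_drug_event_matrix,
    filter_primary_suspect,
    map_pt_to_soc,
    normalize_drug_names,
    read_reports,
)
from dilipred.synthetic_data import ReportSimConfig, generate_reports

HEADER = "report_id,drug_name_raw,role,event_pt,date"


def _write(tmp_path, lines, sep=","):
    path = tmp_path / "reports.csv"
    path.write_text("\n".join(line.replace(",", sep) for line in lines) + "\n")
    return path


class TestReadReports:
    @pytest.mark.parametrize(
        "dialect,sep", [("simple_csv", ","), ("faers_dollar", "$")]
    )
    def test_row_count_and_fields(self, tmp_path, dialect, sep):
        role = "primary_suspect" if dialect == "simple_csv" else "PS"
        path = _write(
            tmp_path,
            [
                HEADER,
                f"r1,aspirin,{role},Hepatitis,2004Q1",
                f"r2,tylenol,{role},Nausea,2004Q2",
                f"r3,ibuprofen,other,Rash,2005Q1",
            ],
            sep=sep,
        )
        records = read_reports(path, dialect)
        assert len(records) == 3
        assert records[0].role is Role.PRIMARY_SUSPECT
        assert records[2].role is Role.OTHER
        assert records[1].event_pt == "Nausea"

    def test_malformed_row_logged_not_silently_dropped(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            [HEADER, "r1,aspirin,primary_suspect,Hepatitis,2004Q1",
             "r2,tylenol,primary_suspect,,2004Q2",
             "r3,advil,primary_suspect,Rash,2004Q3"],
        )
        with caplog.at_level(logging.WARNING):
            records = read_reports(path, "simple_csv")
        assert len(records) == 2
        assert any("rejected" in m for m in caplog.messages)

    def test_header_only_gives_empty_collection(self, tmp_path):
        assert read_reports(_write(tmp_path, [HEADER]), "simple_csv") == []

    def test_unknown_dialect_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, [HEADER])
        with pytest.raises(ValueError, match="dialect"):
            read_reports(path, "tsv")


class TestFilterPrimarySuspect:
    def test_keeps_only_flagged_records_in_order(self, toy_records):
        mixed = [toy_records[0],
                 ReportRecord("r9", "dx", Role.OTHER, "e9", "2010Q1"),
                 toy_records[1]]
        kept = filter_primary_suspect(mixed)
        assert kept == [toy_records[0], toy_records[1]]

    def test_idempotent(self, toy_records):
        once = filter_primary_suspect(toy_records)
        assert filter_primary_suspect(once) == once

    def test_none_primary_gives_empty(self):
        recs = [ReportRecord("r1", "d", Role.OTHER, "e", "2010Q1")]
        assert filter_primary_suspect(recs) == []


class TestNormalizeDrugNames:
    TABLE = SynonymTable({"tylenol": "acetaminophen"})

    def test_exact_match_after_case_and_space_folding(self):
        rec = ReportRecord("r1", "TYLENOL ", Role.PRIMARY_SUSPECT, "e", "2010Q1")
        matched, unmatched = normalize_drug_names([rec], self.TABLE)
        assert unmatched == []
        assert matched[0].canonical_drug == "acetaminophen"

    def test_name_with_dose_text_stays_unmatched(self):
        rec = ReportRecord("r1", "tylenol 500mg", Role.PRIMARY_SUSPECT, "e", "2010Q1")
        matched, unmatched = normalize_drug_names([rec], self.TABLE)
        assert matched == [] and len(unmatched) == 1

    def test_empty_table_matches_nothing(self):
        rec = ReportRecord("r1", "tylenol", Role.PRIMARY_SUSPECT, "e", "2010Q1")
        matched, unmatched = normalize_drug_names([rec], SynonymTable({}))
        assert matched == [] and len(unmatched) == 1


class TestMapPTToSOC:
    MAP = PTSOCMap({"Hepatitis": "hepatobiliary disorder",
                    "Jaundice": "hepatobiliary disorder"})

    def test_lookup_populates_soc(self):
        rec = ReportRecord("r1", "d", Role.PRIMARY_SUSPECT, "Hepatitis", "2010Q1")
        mapped, unmapped = map_pt_to_soc([rec], self.MAP)
        assert mapped[0].event_soc == "hepatobiliary disorder" and unmapped == []

    def test_unmapped_pt_excluded_from_rollup(self):
        rec = ReportRecord("r1", "d", Role.PRIMARY_SUSPECT, "Nausea", "2010Q1")
        mapped, unmapped = map_pt_to_soc([rec], self.MAP)
        assert mapped == [] and unmapped[0].event_soc is None

    def test_many_pts_share_one_soc(self):
        recs = [ReportRecord("r1", "d", Role.PRIMARY_SUSPECT, pt, "2010Q1")
                for pt in ("Hepatitis", "Jaundice")]
        mapped, _ = map_pt_to_soc(recs, self.MAP)
        assert {r.event_soc for r in mapped} == {"hepatobiliary disorder"}


class TestBuildMatrix:
    def test_counts_and_grand_total(self, toy_records):
        m = build_drug_event_matrix(toy_records)
        assert m.counts == {("d1", "e1"): 2, ("d1", "e2"): 1, ("d2", "e1"): 1}
        assert m.grand_total == 4

    def test_singleton_marginals(self):
        m = build_drug_event_matrix(
            [ReportRecord("r1", "d", Role.PRIMARY_SUSPECT, "e", "2010Q1")]
        )
        assert m.drug_marginals == {"d": 1}
        assert m.event_marginals == {"e": 1}
        assert m.grand_total == 1

    def test_soc_level_uses_soc_key(self):
        rec = ReportRecord("r1", "d", Role.PRIMARY_SUSPECT, "Hepatitis", "2010Q1",
                           event_soc="hepatobiliary disorder")
        m = build_drug_event_matrix([rec], EventLevel.SOC)
        assert m.counts == {("d", "hepatobiliary disorder"): 1}

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.sampled_from("abc"), st.sampled_from("xyz")),
            min_size=1,
            max_size=30,
        )
    )
    def test_marginal_consistency(self, pairs):
        recs = [
            ReportRecord(f"r{i}", d, Role.PRIMARY_SUSPECT, e, "2010Q1")
            for i, (d, e) in enumerate(pairs)
        ]
        m = build_drug_event_matrix(recs)
        for d, total in m.drug_marginals.items():
            assert total == sum(n for (dd, _), n in m.counts.items() if dd == d)
        for e, total in m.event_marginals.items():
            assert total == sum(n for (_, ee), n in m.counts.items() if ee == e)
        assert m.grand_total == sum(m.counts.values()) == len(pairs)

    def test_round_trip_csv(self, toy_matrix, tmp_path):
        path = tmp_path / "matrix.csv"
        toy_matrix.write_csv(path)
        again = DrugEventMatrix.read_csv(path)
        assert again.counts == toy_matrix.counts
        assert again.event_level == toy_matrix.event_level

    def test_matches_generator_bookkeeping(self):
        config = ReportSimConfig(n_drugs=5, n_events=4, n_reports=2000,
                                 planted_pairs=((1, 2, 6.0),), seed=7)
        records, truth = generate_reports(config)
        m = build_drug_event_matrix(records)
        assert m.get("D001", "E002") == truth.realized_counts[("D001", "E002")]
        assert m.grand_total == 2000
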