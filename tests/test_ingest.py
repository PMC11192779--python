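import random

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from terminome.ingest import (ConditionDesign, PeptideRecord, infer_dialect,
                              match_quant_columns, parse_modifications,
                              read_condition_file, read_peptide_report,
                              read_protease_list, validate_records)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPeptideReport:
    def test_dialect_inferred_from_defining_columns(self, tmp_path):
        path = _write(tmp_path, "r.tsv",
                      "Sequence\tModifications\tMaster Protein Accessions\n"
                      "PEPTIDE\t\tP1\nAAAK\t\tP2\nMKT\t\tP3\n")
        records, dialect, _ = read_peptide_report(path)
        assert dialect.name == "proteome_discoverer"
        assert [r.raw_sequence for r in records] == ["PEPTIDE", "AAAK", "MKT"]

    def test_missing_sequence_column_is_named(self, tmp_path):
        path = _write(tmp_path, "r.tsv",
                      "Modifications\tMaster Protein Accessions\nx\tP1\n")
        with pytest.raises(ValueError, match="sequence"):
            read_peptide_report(path)

    def test_duplicate_headers_rejected(self, tmp_path):
        path = _write(tmp_path, "r.csv", "Sequence,Sequence\nA,B\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_peptide_report(path)

    def test_fixture_report_round_trips(self, default_fixture, pd_dialect):
        records, dialect, _ = read_peptide_report(default_fixture.report)
        assert dialect.name == "proteome_discoverer"
        manifest_rows = default_fixture.manifest["rows"]
        assert len(records) == len(manifest_rows)
        for rec, truth in zip(records, manifest_rows):
            assert rec.raw_sequence == truth["sequence"]
            assert rec.accessions == truth["accession_list"]

    @pytest.mark.parametrize("dialect_name", ["spectronaut", "spectromine",
                                              "generic"])
    def test_other_dialects_round_trip(self, tmp_path, dialects, dialect_name):
        d = dialects[dialect_name]
        cols = [d.column_map["sequence"], d.column_map["modifications"],
                d.column_map["accessions"]]
        path = _write(tmp_path, "r.tsv",
                      "\t".join(cols) + "\nPEPK\t1xTMTpro [N-Term]\tP1; P2\n")
        records, inferred, _ = read_peptide_report(path)
        assert inferred.name == dialect_name
        assert records[0].raw_sequence == "PEPK"
        assert records[0].accessions == ["P1", "P2"]
        assert records[0].modifications == [("TMTpro", "N-Term")]

    def test_inference_requires_full_column_set(self, dialects):
        with pytest.raises(ValueError):
            infer_dialect(["Sequence", "Unrelated"], dialects)


class TestParseModifications:
    @pytest.mark.parametrize("text,expected", [
        ("1xTMTpro [N-Term]; 1xTMTpro [K5]",
         [("TMTpro", "N-Term"), ("TMTpro", "K5")]),
        ("2xCarbamidomethyl [C3; C8]",
         [("Carbamidomethyl", "C3"), ("Carbamidomethyl", "C8")]),
        ("", []),
        (None, []),
    ])
    def test_token_parsing(self, text, expected):
        assert parse_modifications(text) == expected


class TestValidateRecords:
    def _rec(self, seq, accs, row=1):
        return PeptideRecord(seq, [], accs, {}, row)

    def test_valid_row_kept(self):
        kept, dropped = validate_records([self._rec("PEPTIDE", ["P12345"])])
        assert len(kept) == 1 and not dropped

    def test_invalid_alphabet_dropped(self):
        kept, dropped = validate_records([self._rec("PEPTIDEX1", ["P1"], 3)])
        assert not kept and dropped == [(3, "invalid_alphabet")]

    def test_empty_accession_dropped(self):
        _, dropped = validate_records([self._rec("PEPTIDE", [], 2)])
        assert dropped == [(2, "empty_accession")]

    def test_empty_sequence_dropped(self):
        _, dropped = validate_records([self._rec("", ["P1"], 4)])
        assert dropped == [(4, "empty_sequence")]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(
        st.text(alphabet="ACDX1 ", max_size=8),
        st.lists(st.text(alphabet="PQ1", min_size=1, max_size=4),
                 max_size=2))))
    def test_partition_property(self, rows):
        records = [PeptideRecord(seq, [], accs, {}, i + 1)
                   for i, (seq, accs) in enumerate(rows)]
        kept, dropped = validate_records(records)
        assert len(kept) + len(dropped) == len(records)
        assert {r.source_row for r in kept}.isdisjoint(
            {row for row, _ in dropped})


class TestConditionFile:
    def test_parse_order_preserved(self, tmp_path):
        path = _write(tmp_path, "c.txt", "ctrl 126 127N\ntreat 128 129N\n")
        design = read_condition_file(path)
        assert design.conditions == {"ctrl": ["126", "127N"],
                                     "treat": ["128", "129N"]}
        assert list(design.conditions) == ["ctrl", "treat"]

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ValueError):
            read_condition_file(_write(tmp_path, "c.txt", "\n\n"))

    def test_duplicate_condition_errors(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            read_condition_file(_write(tmp_path, "c.txt", "ctrl a\nctrl b\n"))

    def test_name_without_substrings_errors(self, tmp_path):
        with pytest.raises(ValueError, match="no column substrings"):
            read_condition_file(_write(tmp_path, "c.txt", "ctrl\n"))


class TestMatchQuantColumns:
    def test_simple_resolution(self):
        design = ConditionDesign({"ctrl": ["126"]})
        resolved = match_quant_columns(
            design, ["Abundance 126", "Abundance 127"])
        assert resolved.resolved == {"ctrl": ["Abundance 126"]}

    def test_ambiguous_assignment_errors(self):
        design = ConditionDesign({"a": ["12"], "b": ["12"]})
        with pytest.raises(ValueError, match="claimed"):
            match_quant_columns(design, ["Abundance 126"])

    def test_zero_matches_errors(self):
        with pytest.raises(ValueError, match="matches no column"):
            match_quant_columns(ConditionDesign({"a": ["131"]}), ["Abu 126"])

    def test_fixture_design_resolves_disjoint(self, default_fixture):
        design = read_condition_file(default_fixture.condition_file)
        report = pd.read_csv(default_fixture.report, sep="\t", nrows=1)
        resolved = match_quant_columns(design, list(report.columns))
        cols = [c for v in resolved.resolved.values() for c in v]
        assert len(cols) == 10 and len(set(cols)) == 10
        assert resolved.resolved == default_fixture.manifest["quant_columns"]

    def test_column_order_independence(self, default_fixture):
        design = read_condition_file(default_fixture.condition_file)
        report = pd.read_csv(default_fixture.report, sep="\t", nrows=1)
        cols = list(report.columns)
        shuffled = cols[:]
        random.Random(5).shuffle(shuffled)
        a = match_quant_columns(design, cols).resolved
        b = match_quant_columns(design, shuffled).resolved
        assert {k: set(v) for k, v in a.items()} == \
               {k: set(v) for k, v in b.items()}


class TestProteaseList:
    def test_single_id(self, tmp_path):
        assert read_protease_list(
            _write(tmp_path, "p.txt", "M10.004\n")) == ["M10.004"]

    def test_blank_lines_skipped(self, tmp_path):
        assert read_protease_list(
            _write(tmp_path, "p.txt", "M10.004\n\nC14.003\n")) == \
            ["M10.004", "C14.003"]

    def test_malformed_id_reported_with_line(self, tmp_path):
        with pytest.raises(ValueError, match="malformed"):
            read_protease_list(_write(tmp_path, "p.txt", "MMP9\n"))
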