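import datetime as dt
import textwrap

import pytest
from hypothesis import given, strategies as st

from icpnm.srs_data import (ContingencyTable, DataError, FormatError, Report,
                            ReportDatabase, build_all_contingencies,
                            build_contingency, deduplicate_reports,
                            read_reference_set, read_reports, write_reports)


def _write(tmp_path, text, name="reports.tsv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


REPORT_FILE = """\
    report_id\treceipt_date\tdrugs\tades
    R1\t2004-01-01\tD1\tA1
    R2\t2004-01-02\tD1|D2\tA1|A2
    R3\t2004-01-03\tD2\tA2
    R4\t2004-01-04\tD1\tA2
    R5\t2004-01-05\tD3\tA1
"""


class TestReadReports:
    def test_parses_toy_file(self, tmp_path):
        db = read_reports(_write(tmp_path, REPORT_FILE))
        assert db.n_reports == 5
        assert set(db.drugs) == {"D1", "D2", "D3"}
        assert db.reports[1].drugs == frozenset({"D1", "D2"})
        assert db.reports[0].receipt_date == dt.date(2004, 1, 1)

    def test_duplicate_ids_retained_until_dedup(self, tmp_path):
        p = _write(tmp_path, """\
            report_id\treceipt_date\tdrugs\tades
            X\t2004-01-01\tD1\tA1
            X\t2004-06-01\tD2\tA1
        """)
        db = read_reports(p)
        assert db.n_reports == 2  # the reader never deduplicates

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "report_id\treceipt_date\tdrugs\nR1\t2004-01-01\tD1\n")
        with pytest.raises(FormatError, match="ades"):
            read_reports(p)

    def test_malformed_rows_dropped(self, tmp_path):
        p = _write(tmp_path, """\
            report_id\treceipt_date\tdrugs\tades
            R1\t2004-01-01\tD1\tA1
            R2\t2004-01-02\t\tA1
            R3\tnot-a-date\tD1\tA1
            R4\t2004-01-04\tD1\t
        """)
        db = read_reports(p)
        assert [r.report_id for r in db.reports] == ["R1"]

    def test_round_trip(self, tmp_path, toy_db):
        p = tmp_path / "out.tsv"
        write_reports(toy_db, p)
        again = read_reports(p)
        assert [(r.report_id, r.receipt_date, r.drugs, r.ades)
                for r in again.reports] == \
               [(r.report_id, r.receipt_date, r.drugs, r.ades)
                for r in toy_db.reports]


class TestDeduplicate:
    def _db(self, rows):
        return ReportDatabase([
            Report(rid, dt.date.fromisoformat(d), frozenset({dr}),
                   frozenset({ad})) for rid, d, dr, ad in rows])

    def test_latest_version_kept(self):
        db = self._db([("X", "2004-01-01", "D1", "A1"),
                       ("X", "2004-06-01", "D2", "A1")])
        out = deduplicate_reports(db)
        assert out.n_reports == 1
        assert out.reports[0].drugs == frozenset({"D2"})

    def test_all_unique_unchanged(self, toy_db):
        out = deduplicate_reports(toy_db)
        assert [r.report_id for r in out.reports] == \
               [r.report_id for r in toy_db.reports]

    def test_equal_dates_keep_last_in_file_order(self):
        db = self._db([("X", "2004-01-01", "D1", "A1"),
                       ("X", "2004-01-01", "D2", "A1")])
        out = deduplicate_reports(db)
        assert out.reports[0].drugs == frozenset({"D2"})

    def test_idempotent(self, toy_db):
        db = ReportDatabase(toy_db.reports + [toy_db.reports[0]])
        once = deduplicate_reports(db)
        twice = deduplicate_reports(once)
        assert [r.report_id for r in once.reports] == \
               [r.report_id for r in twice.reports]


class TestContingency:
    @pytest.mark.parametrize("drug,ade,expected", [
        ("D1", "A1", (2, 3, 3, 5)),
        ("D1", "A2", (2, 3, 3, 5)),
        ("D9", "A1", (0, 0, 3, 5)),  # absent drug: zero counts, not an error
    ])
    def test_counts(self, toy_db, drug, ade, expected):
        t = build_contingency(toy_db, drug, ade)
        assert (t.c_ij, t.c_i_plus, t.c_plus_j, t.c_plus_plus) == expected

    def test_all_cooccurring_pairs(self, toy_db):
        tables = build_all_contingencies(toy_db)
        # hand enumeration of the fixture's co-occurring pairs
        assert set(tables) == {("D1", "A1"), ("D1", "A2"), ("D2", "A1"),
                               ("D2", "A2"), ("D3", "A1")}
        assert all(t.c_ij >= 1 for t in tables.values())

    def test_explicit_single_pair(self, toy_db):
        tables = build_all_contingencies(toy_db, [("D1", "A1")])
        assert len(tables) == 1

    def test_empty_db_is_error(self):
        with pytest.raises(DataError, match="empty"):
            build_all_contingencies(ReportDatabase([]))

    @pytest.mark.parametrize("cells", [
        (3, 2, 5, 10),   # c_ij exceeds drug margin
        (1, 11, 5, 10),  # margin exceeds total
        (0, 6, 6, 10),   # inclusion-exclusion violated
        (-1, 2, 2, 10),  # negative count
    ])
    def test_invalid_tables_rejected(self, cells):
        with pytest.raises(DataError):
            ContingencyTable(*cells)

    @given(st.data())
    def test_margins_match_brute_force_rescan(self, data):
        n_drugs, n_ades = 4, 3
        rows = data.draw(st.lists(
            st.tuples(st.sets(st.sampled_from([f"D{i}" for i in range(n_drugs)]),
                              min_size=1),
                      st.sets(st.sampled_from([f"A{j}" for j in range(n_ades)]),
                              min_size=1)),
            min_size=1, max_size=30))
        db = ReportDatabase([
            Report(f"R{i}", dt.date(2004, 1, 1), frozenset(d), frozenset(a))
            for i, (d, a) in enumerate(rows)])
        for drug in db.drugs:
            for ade in db.ades:
                t = build_contingency(db, drug, ade)
                assert t.c_ij == sum(1 for r in db.reports
                                     if drug in r.drugs and ade in r.ades)
                assert t.c_plus_j == sum(1 for r in db.reports if ade in r.ades)
                assert t.c_i_plus == sum(1 for r in db.reports if drug in r.drugs)


class TestReferenceSet:
    def test_read(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("drug\tade\tlabel\nD1\tA1\tpositive\nD2\tA1\tnegative\n"
                     "D3\tA2\tpositive\n")
        ref = read_reference_set(p)
        assert len(ref) == 3
        assert ref.positives == [("D1", "A1"), ("D3", "A2")]

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("drug\tade\tlabel\nD1\tA1\tpositive\nD1\tA1\tnegative\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_reference_set(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("drug\tade\tlabel\n")
        with pytest.raises(DataError, match="empty"):
            read_reference_set(p)

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "ref.tsv"
        p.write_text("drug\tade\tlabel\nD1\tA1\tmaybe\n")
        with pytest.raises(FormatError, match="label"):
            read_reference_set(p)
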