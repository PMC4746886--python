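"""Read-provenance counting: prefix resolution and per-scaffold tallies."""

import random
from collections import Counter

import pytest
from hypothesis import given, strategies as st

from ylinkage import (
    LibraryCatalog,
    ReadAssignment,
    ScaffoldReadCount,
    count_reads_per_scaffold,
    parse_read_map,
    read_count_table,
    read_lengths,
    sex_of_read,
    write_count_table,
)
from ylinkage.errors import CatalogError, ReadMapFormatError, UnknownLibraryError
from ylinkage.provenance import ParseSummary, Sex


class TestCatalog:
    @pytest.mark.parametrize(
        "entries",
        [
            (),  # empty
            (("", "male"), ("NADD", "female")),  # empty prefix
            (("NA", "male"), ("NADD", "female")),  # nested prefixes
            (("NAAX", "male"), ("NAAX", "female")),  # duplicate
            (("NAAX", "male"), ("GFL7EVZ", "male")),  # no female library
        ],
    )
    def test_invalid_catalogs_rejected(self, entries):
        with pytest.raises(CatalogError):
            LibraryCatalog(entries=entries)

    @pytest.mark.parametrize(
        "read_id,expected",
        [
            ("NAAX00012345", Sex.MALE),
            ("GFL7EVZ123", Sex.MALE),
            ("NADK9", Sex.FEMALE),
            ("NADD0001", Sex.FEMALE),
            ("NADN42", Sex.FEMALE),
        ],
    )
    def test_sex_of_read(self, catalog, read_id, expected):
        assert sex_of_read(read_id, catalog) is expected

    def test_unknown_prefix_raises(self, catalog):
        with pytest.raises(UnknownLibraryError):
            sex_of_read("XYZ1", catalog)

    def test_matching_is_case_sensitive(self, catalog):
        with pytest.raises(UnknownLibraryError):
            sex_of_read("naax1", catalog)


class TestParseReadMap:
    def test_well_formed_rows(self, write_tsv):
        path = write_tsv(
            "map.tsv", ["S1\tNAAX1", "S1\tNADD1", "S2\tNAAX2"]
        )
        summary = ParseSummary()
        rows = list(parse_read_map(path, summary))
        assert len(rows) == 3
        assert summary.n_rows == 3
        assert rows[0] == ReadAssignment(read_id="NAAX1", scaffold_id="S1")

    def test_empty_file_empty_stream(self, write_tsv):
        path = write_tsv("empty.tsv", [])
        summary = ParseSummary()
        assert list(parse_read_map(path, summary)) == []
        assert summary.n_rows == 0

    def test_header_line_skipped_but_counted(self, write_tsv):
        path = write_tsv("map.tsv", ["#scaffold_id\tread_id", "S1\tNAAX1"])
        summary = ParseSummary()
        assert len(list(parse_read_map(path, summary))) == 1
        assert summary.n_comment_lines == 1

    def test_malformed_row_names_line(self, write_tsv):
        path = write_tsv("bad.tsv", ["S1\tNAAX1", "S2_only_one_column"])
        with pytest.raises(ReadMapFormatError) as err:
            list(parse_read_map(path))
        assert err.value.line_number == 2
        assert "line 2" in str(err.value)


class TestCounting:
    def test_simple_tally(self, catalog):
        assignments = [
            ReadAssignment("NAAX1", "S"),
            ReadAssignment("NAAX2", "S"),
            ReadAssignment("NADD1", "S"),
        ]
        result = count_reads_per_scaffold(assignments, catalog, {"S": 1000})
        (c,) = result.counts
        assert (c.n_total, c.n_male, c.n_female) == (3, 2, 1)
        assert c.male_fraction == pytest.approx(2 / 3)

    def test_zero_read_scaffold_undefined_fraction(self, catalog):
        result = count_reads_per_scaffold(
            [ReadAssignment("NAAX1", "S1")], catalog, {"S1": 100, "S2": 500}
        )
        by_id = result.by_id()
        assert by_id["S2"].n_total == 0
        assert by_id["S2"].length_bp == 500
        assert by_id["S2"].male_fraction is None

    def test_duplicates_within_scaffold_collapse(self, catalog):
        assignments = [ReadAssignment("NAAX1", "S")] * 3
        result = count_reads_per_scaffold(assignments, catalog, {"S": 10})
        assert result.counts[0].n_total == 1
        assert result.n_duplicates_collapsed == 2

    def test_multiplaced_read_counts_once_per_scaffold(self, catalog):
        assignments = [ReadAssignment("NAAX1", "S1"), ReadAssignment("NAAX1", "S2")]
        result = count_reads_per_scaffold(assignments, catalog, {"S1": 10, "S2": 10})
        assert [c.n_male for c in result.counts] == [1, 1]

    def test_unknown_prefix_policy(self, catalog):
        assignments = [ReadAssignment("XYZ1", "S"), ReadAssignment("NAAX1", "S")]
        with pytest.raises(UnknownLibraryError):
            count_reads_per_scaffold(assignments, catalog, {"S": 10})
        result = count_reads_per_scaffold(
            assignments, catalog, {"S": 10}, skip_unknown=True
        )
        assert result.n_unknown_skipped == 1
        assert result.counts[0].n_total == 1

    def test_missing_length_warns_and_records_zero(self, catalog):
        with pytest.warns(UserWarning, match="absent from the length table"):
            result = count_reads_per_scaffold(
                [ReadAssignment("NAAX1", "S")], catalog, {}
            )
        assert result.counts[0].length_bp == 0

    def test_against_brute_force_tally(self, catalog):
        """100 scaffolds x 20 randomly sexed reads vs an independent Counter."""
        rng = random.Random(1234)
        prefixes = ["NAAX", "GFL7EVZ", "NADD", "NADK", "NADN"]
        male_prefixes = {"NAAX", "GFL7EVZ"}
        rows = []
        for s in range(100):
            for r in range(20):
                rows.append((f"S{s:03d}", f"{rng.choice(prefixes)}_{s}_{r}"))
        rng.shuffle(rows)

        # independent oracle: plain Counter over the raw rows
        oracle_m, oracle_f = Counter(), Counter()
        for sid, rid in rows:
            if any(rid.startswith(p) for p in male_prefixes):
                oracle_m[sid] += 1
            else:
                oracle_f[sid] += 1

        lengths = {f"S{s:03d}": 1000 for s in range(100)}
        result = count_reads_per_scaffold(
            (ReadAssignment(rid, sid) for sid, rid in rows), catalog, lengths
        )
        assert len(result.counts) == 100
        for c in result.counts:
            assert c.n_male == oracle_m[c.scaffold_id]
            assert c.n_female == oracle_f[c.scaffold_id]
        # conservation: summed male counts equal male-prefixed input rows
        assert sum(c.n_male for c in result.counts) == sum(oracle_m.values())

    def test_permutation_invariance(self, catalog):
        rng = random.Random(7)
        rows = [
            ReadAssignment(f"{p}{i}", f"S{i % 5}")
            for i, p in enumerate(["NAAX", "NADD", "NADK"] * 20)
        ]
        lengths = {f"S{i}": 100 for i in range(5)}
        base = count_reads_per_scaffold(rows, catalog, lengths).counts
        shuffled = rows[:]
        rng.shuffle(shuffled)
        assert count_reads_per_scaffold(shuffled, catalog, lengths).counts == base


class TestCountTable:
    def test_round_trip(self, catalog, tmp_path):
        counts = [
            ScaffoldReadCount("S1", 1000, 3, 2, 1),
            ScaffoldReadCount("S2", 500, 0, 0, 0),
        ]
        path = tmp_path / "counts.tsv"
        write_count_table(counts, path)
        assert read_count_table(path) == counts

    def test_pct_male_formatting(self, tmp_path):
        # a 61 %-male control-like scaffold prints one decimal; zero reads print NA
        counts = [
            ScaffoldReadCount("GL563091like", 12_000_000, 100, 61, 39),
            ScaffoldReadCount("S0", 500, 0, 0, 0),
        ]
        path = tmp_path / "counts.tsv"
        write_count_table(counts, path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "scaffold_id", "length_bp", "n_total", "n_male", "n_female", "pct_male",
        ]
        assert lines[1].split("\t")[-1] == "61.0"
        assert lines[2].split("\t")[-1] == "NA"

    @given(
        rows=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 10_000)),
            max_size=20,
        )
    )
    def test_integer_fields_round_trip_exactly(self, tmp_path_factory, rows):
        counts = [
            ScaffoldReadCount(f"S{i}", length, m + f, m, f)
            for i, (m, f, length) in enumerate(rows)
        ]
        path = tmp_path_factory.mktemp("rt") / "counts.tsv"
        write_count_table(counts, path)
        assert read_count_table(path) == counts


class TestLengths:
    def test_from_tsv(self, write_tsv):
        path = write_tsv("len.tsv", ["#scaffold_id\tlength_bp", "S1\t100", "S2\t250"])
        assert read_lengths(path) == {"S1": 100, "S2": 250}

    def test_from_fasta(self, write_tsv):
        path = write_tsv("s.fa", [">S1 desc", "ACGTACGT", "ACGT", ">S2", "AC"])
        assert read_lengths(path) == {"S1": 12, "S2": 2}


def test_count_invariant_enforced():
    with pytest.raises(ValueError):
        ScaffoldReadCount("S", 100, 3, 2, 2)
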