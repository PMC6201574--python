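"""I/O and invariant checks for the alignment domain types."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strucdiv import (
    AlignedPair,
    AlignmentRecord,
    DomainAnnotation,
    IndelFlankSample,
    PresenceMatrix,
    read_aligned_pair,
    read_alignment_table,
    read_flank_samples,
    read_presence_matrix,
    write_aligned_pair,
    write_alignment_table,
    write_flank_samples,
    write_presence_matrix,
)
from strucdiv.errors import (
    FormatError,
    RowError,
    SchemaError,
    ValidationError,
)


def make_record(**kw):
    base = dict(
        id_a="d1a2b_", id_b="d3c4d_", superfamily_id="c.1.10",
        family_a="c.1.10.1", family_b="c.1.10.2",
        rmsd=2.345678, z_score=7.89, p_score=-0.5, n_algn=120,
    )
    base.update(kw)
    return AlignmentRecord(**base)


class TestAlignedPair:
    def test_valid_pair_counts_aligned_columns(self):
        p = AlignedPair("a", "b", "AC-D", "ACED")
        assert p.n_aligned_columns == 3

    @pytest.mark.parametrize(
        "row_a,row_b",
        [
            ("ACD", "AC"),      # unequal lengths
            ("", ""),           # empty
            ("A-D", "A-D"),     # both-gap column
            ("A-", "-A"),       # no aligned column
            ("AC1", "ACD"),     # invalid symbol
        ],
    )
    def test_invariant_violations(self, row_a, row_b):
        with pytest.raises(ValidationError):
            AlignedPair("a", "b", row_a, row_b)

    @given(
        st.lists(
            st.sampled_from(["mm", "a-", "-b"]), min_size=1, max_size=60
        ).filter(lambda cols: "mm" in cols)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_column_count_identity(self, cols):
        """aligned + gapped-in-a + gapped-in-b columns == alignment length."""
        row_a = "".join("A" if c != "a-" else "-" for c in cols)
        row_b = "".join("C" if c != "-b" else "-" for c in cols)
        p = AlignedPair("x", "y", row_a, row_b)
        gaps_a = row_a.count("-")
        gaps_b = row_b.count("-")
        assert p.n_aligned_columns + gaps_a + gaps_b == len(p)


class TestAlignmentTable:
    def test_round_trip_identity(self, tmp_path):
        records = [
            make_record(),
            make_record(id_a="dx", id_b="dy", rmsd=0.0, p_score=3.25, n_algn=50),
            make_record(id_a="dz", id_b="dw", z_score=0.0, rmsd=15.123456789),
        ]
        path = tmp_path / "tab.tsv"
        write_alignment_table(records, path)
        back = read_alignment_table(path)
        assert back == records  # exact, including floats

    def test_order_preserved(self, tmp_path):
        records = [make_record(id_a=f"d{i}", id_b=f"e{i}") for i in range(3)]
        path = tmp_path / "t.tsv"
        write_alignment_table(records, path)
        assert [r.id_a for r in read_alignment_table(path)] == ["d0", "d1", "d2"]

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_alignment_table([], path)
        assert path.read_text().strip().count("\n") == 0
        assert read_alignment_table(path) == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id_a\tid_b\n1\t2\n")
        with pytest.raises(SchemaError, match="rmsd|superfamily"):
            read_alignment_table(path)

    def test_unparsable_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_alignment_table([make_record()], path)
        text = path.read_text().replace("7.89", "seven")
        path.write_text(text)
        with pytest.raises(RowError, match="line 2"):
            read_alignment_table(path)

    def test_negative_rmsd_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_alignment_table([make_record()], path)
        path.write_text(path.read_text().replace("2.345678", "-1.0"))
        with pytest.raises(ValidationError, match=">= 0"):
            read_alignment_table(path)


class TestRecordInvariants:
    def test_self_comparison_rejected(self):
        with pytest.raises(ValidationError):
            make_record(id_b="d1a2b_")

    def test_pair_count_must_match_n_algn(self):
        pair = AlignedPair("a", "b", "ACDEF", "ACDEF")
        with pytest.raises(ValidationError):
            make_record(n_algn=4, pair=pair)
        make_record(n_algn=5, pair=pair)  # consistent: no error


class TestAlignedPairFasta:
    def test_read_simple_pair(self, tmp_path):
        f = tmp_path / "p.fasta"
        f.write_text(">a extra words\nAC-D\n>b\nACED\n")
        p = read_aligned_pair(f)
        assert (p.id_a, p.id_b) == ("a", "b")
        assert (p.row_a, p.row_b) == ("AC-D", "ACED")

    def test_write_read_round_trip(self, tmp_path):
        p = AlignedPair("dom1", "dom2", "MK-LV", "MKQLV")
        f = tmp_path / "rt.fasta"
        write_aligned_pair(p, f)
        assert read_aligned_pair(f) == p

    def test_three_records_is_format_error(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nAC\n>b\nAC\n>c\nAC\n")
        with pytest.raises(FormatError, match="2 FASTA records"):
            read_aligned_pair(f)

    def test_unequal_lengths_is_format_error(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nACD\n>b\nAC\n")
        with pytest.raises(FormatError):
            read_aligned_pair(f)

    def test_no_aligned_column_is_validation_error(self, tmp_path):
        f = tmp_path / "bad.fasta"
        f.write_text(">a\nA-\n>b\n-A\n")
        with pytest.raises(ValidationError):
            read_aligned_pair(f)


class TestPresenceMatrix:
    def matrix(self):
        return PresenceMatrix(
            superfamily_ids=["c.1.1", "d.2.1"],
            genome_ids=["e1", "e2", "b1", "a1"],
            domain_of_life=["eukaryote", "eukaryote", "bacterium", "archaeon"],
            present=np.array([[1, 1, 1, 0], [0, 1, 1, 1]], dtype=bool),
        )

    def test_round_trip(self, tmp_path):
        m = self.matrix()
        path = tmp_path / "pres.tsv"
        write_presence_matrix(m, path)
        back = read_presence_matrix(path)
        assert back.superfamily_ids == m.superfamily_ids
        assert back.genome_ids == m.genome_ids
        assert back.domain_of_life == m.domain_of_life
        assert np.array_equal(back.present, m.present)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            PresenceMatrix(["s1"], ["g1", "g2"], ["eukaryote", "bacterium"],
                           np.ones((2, 2), dtype=bool))

    def test_unknown_domain_label_rejected(self):
        with pytest.raises(ValidationError, match="domain-of-life"):
            PresenceMatrix(["s1"], ["g1"], ["plant"], np.ones((1, 1), dtype=bool))

    def test_presence_fraction(self):
        m = self.matrix()
        assert m.presence_fraction("c.1.1", "eukaryote") == 1.0
        assert m.presence_fraction("c.1.1", "archaeon") == 0.0


class TestFlankSamples:
    def test_round_trip(self, tmp_path):
        samples = [IndelFlankSample(3, 1.27), IndelFlankSample(1, 0.0)]
        path = tmp_path / "fl.tsv"
        write_flank_samples(samples, path)
        assert read_flank_samples(path) == samples

    def test_row_parses_typed(self, tmp_path):
        path = tmp_path / "fl.tsv"
        path.write_text("length\trmsd\n3\t1.27\n")
        (s,) = read_flank_samples(path)
        assert s == IndelFlankSample(length=3, rmsd=1.27)

    def test_zero_length_rejected(self, tmp_path):
        path = tmp_path / "fl.tsv"
        path.write_text("length\trmsd\n0\t1.0\n")
        with pytest.raises(ValidationError):
            read_flank_samples(path)


class TestDomainAnnotation:
    def test_class_enumeration_enforced(self):
        DomainAnnotation("d1", "c.1.1", "c.1.1.1", "c", "xray")
        with pytest.raises(ValidationError):
            DomainAnnotation("d1", "c.1.1", "c.1.1.1", "f", "xray")
        with pytest.raises(ValidationError):
            DomainAnnotation("d1", "c.1.1", "c.1.1.1", "c", "cryoem")
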