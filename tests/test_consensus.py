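"""Column classification, consensus derivation, alignment metrics, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmimmune.consensus import (CONSERVATIVE, DEFAULT_RESIDUE_CLASSES,
                                DOUBLE_GAP, IDENTICAL, NONCONSERVATIVE,
                                SINGLE_GAP, AlignedPair, alignment_metrics,
                                classify_column, derive_consensus,
                                load_residue_classes, read_aligned_pair,
                                write_consensus_fasta)
from gmimmune.errors import AlignmentFormatError

RESIDUES = sorted(DEFAULT_RESIDUE_CLASSES)


class TestClassMap:
    def test_covers_twenty_residues_once(self):
        assert len(DEFAULT_RESIDUE_CLASSES) == 20
        assert set("ACDEFGHIKLMNPQRSTVWY") == set(DEFAULT_RESIDUE_CLASSES)
        assert set(DEFAULT_RESIDUE_CLASSES.values()) == {
            "hydrophobic", "positive", "negative", "polar_uncharged", "special"}

    def test_yaml_override_roundtrip(self, tmp_path):
        path = tmp_path / "classes.yaml"
        path.write_text("\n".join(f"{r}: {c}" for r, c
                                  in DEFAULT_RESIDUE_CLASSES.items()))
        assert load_residue_classes(path) == DEFAULT_RESIDUE_CLASSES

    def test_incomplete_map_rejected(self, tmp_path):
        path = tmp_path / "classes.yaml"
        path.write_text("A: hydrophobic")
        with pytest.raises(ValueError, match="missing"):
            load_residue_classes(path)


class TestClassifyColumn:
    @pytest.mark.parametrize("q,s,outcome", [
        ("K", "K", IDENTICAL),
        ("K", "R", CONSERVATIVE),      # both positively charged
        ("K", "D", NONCONSERVATIVE),   # positive vs negative
        ("L", "I", CONSERVATIVE),      # both hydrophobic
        ("S", "C", NONCONSERVATIVE),   # polar vs special
        ("-", "W", SINGLE_GAP),
        ("W", "-", SINGLE_GAP),
        ("-", "-", DOUBLE_GAP),
        ("X", "K", NONCONSERVATIVE),   # ambiguity code: never conservative
        ("X", "X", IDENTICAL),
    ])
    def test_outcomes(self, q, s, outcome):
        assert classify_column(q, s) == outcome

    def test_unknown_symbol_rejected(self):
        with pytest.raises(AlignmentFormatError):
            classify_column("1", "K")


class TestDeriveConsensus:
    def test_identity_alignment(self):
        pair = AlignedPair("q", "s", "KACDG", "KACDG")
        cons = derive_consensus(pair)
        assert cons.sequence == "KACDG"
        assert cons.outcomes == [IDENTICAL] * 5

    def test_five_rule_fixture(self):
        """Hand-derived: K/R conservative -> K (query); gap/C -> C."""
        pair = AlignedPair("q", "s", "KA-DG", "RACDG")
        cons = derive_consensus(pair)
        assert cons.sequence == "KACDG"
        assert cons.outcomes == [CONSERVATIVE, IDENTICAL, SINGLE_GAP,
                                 IDENTICAL, IDENTICAL]

    def test_charge_swap_is_all_x(self):
        cons = derive_consensus(AlignedPair("q", "s", "KD", "DK"))
        assert cons.sequence == "XX"

    def test_double_gap_emits_dash(self):
        cons = derive_consensus(AlignedPair("q", "s", "K-", "K-"))
        assert cons.sequence == "K-"
        assert cons.outcomes == [IDENTICAL, DOUBLE_GAP]

    def test_query_bias_on_conservative_columns_only(self):
        """Swapping query/subject may change conservative outputs only."""
        q, s = "KALDS-G", "RAIEC-G"
        fwd = derive_consensus(AlignedPair("q", "s", q, s))
        rev = derive_consensus(AlignedPair("s", "q", s, q))
        for cf, cr, of, orev in zip(fwd.sequence, rev.sequence,
                                    fwd.outcomes, rev.outcomes):
            assert of == orev  # outcomes are symmetric
            if of != CONSERVATIVE:
                assert cf == cr

    @given(st.text(alphabet=RESIDUES, min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_idempotence_on_x_free_outputs(self, seq):
        pair = AlignedPair("q", "s", seq, seq)
        cons = derive_consensus(pair)
        assert "X" not in cons.sequence
        again = derive_consensus(AlignedPair("c", "c", cons.sequence,
                                             cons.sequence))
        assert again.sequence == cons.sequence

    def test_zero_x_iff_no_nonconservative(self):
        pair = AlignedPair("q", "s", "KRLD-", "RKIE-")
        cons = derive_consensus(pair)
        assert (cons.sequence.count("X") == 0) == \
            (NONCONSERVATIVE not in cons.outcomes)
        pair2 = AlignedPair("q", "s", "KD", "DK")
        cons2 = derive_consensus(pair2)
        assert cons2.sequence.count("X") == cons2.outcomes.count(NONCONSERVATIVE)

    def test_length_preserved(self):
        pair = AlignedPair("q", "s", "KA-DG--W", "RACDGA-W")
        assert len(derive_consensus(pair).sequence) == 8


class TestMetrics:
    def test_identical_full_length(self):
        seq = "ACDEFGHIKL" * 10
        pair = AlignedPair("q", "s", seq, seq)
        m = alignment_metrics(pair, query_full_length=100)
        assert m["identity_pct"] == 100.0
        assert m["coverage_pct"] == 100.0
        assert m["aligned_columns"] == 100

    def test_count_arithmetic(self):
        """10 columns, 6 identical, 2 conservative, 2 cross-class."""
        pair = AlignedPair("q", "s", "AAAAAAKLKD", "AAAAAARIDK")
        m = alignment_metrics(pair, query_full_length=10)
        assert m["identity_pct"] == 60.0

    def test_partial_coverage(self):
        pair = AlignedPair("q", "s", "A" * 50, "A" * 50)
        m = alignment_metrics(pair, query_full_length=200)
        assert m["coverage_pct"] == 25.0

    def test_identity_undefined_without_aligned_residues(self):
        pair = AlignedPair("q", "s", "A-", "-A")
        assert alignment_metrics(pair)["identity_pct"] is None


class TestIO:
    def write_fasta(self, path, records):
        path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in records))

    def test_roundtrip(self, tmp_path):
        fasta = tmp_path / "pair.fasta"
        self.write_fasta(fasta, [("q1", "KA-DG"), ("s1", "RACDG")])
        pair = read_aligned_pair(fasta)
        assert (pair.query_id, pair.subject_id) == ("q1", "s1")
        out = tmp_path / "consensus.fasta"
        write_consensus_fasta(derive_consensus(pair), out)
        assert "KACDG" in out.read_text()

    def test_lowercase_normalised(self, tmp_path):
        fasta = tmp_path / "pair.fasta"
        self.write_fasta(fasta, [("q", "ka-dg"), ("s", "racdg")])
        assert derive_consensus(read_aligned_pair(fasta)).sequence == "KACDG"

    def test_three_records_rejected(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        self.write_fasta(fasta, [("a", "KK"), ("b", "KK"), ("c", "KK")])
        with pytest.raises(AlignmentFormatError, match="2 records"):
            read_aligned_pair(fasta)

    def test_unequal_lengths_rejected(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        self.write_fasta(fasta, [("a", "KKK"), ("b", "KK")])
        with pytest.raises(AlignmentFormatError, match="lengths"):
            read_aligned_pair(fasta)

    def test_illegal_characters_rejected(self):
        with pytest.raises(AlignmentFormatError, match="illegal"):
            AlignedPair("q", "s", "K1", "KK")
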