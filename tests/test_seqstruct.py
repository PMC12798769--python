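"""Sequence/structure IO: parsing rules, round-trips, alignment oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from garnet import (
    ColumnMap,
    Mutation,
    ProteinSequence,
    SeqStructError,
    align_to_template,
    read_fasta,
    read_pdb,
    write_fasta,
    write_mutant_pdb,
    write_pdb,
)
from garnet.seqstruct import alignment_score, GAP
from garnet.synthetic import generate_toy_structure, random_template

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestFasta:
    def test_reads_records_in_order(self, tmp_path):
        p = tmp_path / "lib.fasta"
        p.write_text(">s1\nacdef\n>s2\nGHIKL\n")
        seqs = read_fasta(p)
        assert [s.id for s in seqs] == ["s1", "s2"]
        assert seqs[0].residues == "ACDEF"  # lowercase normalized

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(SeqStructError):
            read_fasta(p)

    def test_illegal_character_names_record_and_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">ok\nACDE\n>bad\nACXE\n")
        with pytest.raises(SeqStructError, match="bad.*position 3"):
            read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nDE\n")
        with pytest.raises(SeqStructError, match="duplicate"):
            read_fasta(p)

    @given(seqs=st.lists(st.text(alphabet=AA, min_size=1, max_size=30), min_size=1, max_size=8))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_preserves_sequences(self, seqs, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fasta")
        records = [ProteinSequence(f"s{i}", s) for i, s in enumerate(seqs)]
        p = tmp / "x.fasta"
        write_fasta(records, p)
        assert read_fasta(p) == records


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

class TestPdb:
    def test_round_trip_preserves_numbering_and_coordinates(self, tmp_path, helix):
        p = tmp_path / "s.pdb"
        write_pdb(helix, p)
        back = read_pdb(p, "A")
        assert back.residue_numbers == helix.residue_numbers
        assert back.sequence.residues == helix.sequence.residues
        for r1, r2 in zip(helix.residues, back.residues):
            for (n1, *c1), (n2, *c2) in zip(r1.atoms, r2.atoms):
                assert n1 == n2
                assert c1 == pytest.approx(c2, abs=1e-3)

    def test_missing_chain_is_error(self, tmp_path, helix):
        p = tmp_path / "s.pdb"
        write_pdb(helix, p)
        with pytest.raises(SeqStructError, match="chain"):
            read_pdb(p, "B")

    def test_only_first_model_is_read(self, tmp_path, helix):
        p = tmp_path / "one.pdb"
        write_pdb(helix, p)
        body = p.read_text().replace("TER\nEND\n", "")
        two = tmp_path / "two.pdb"
        two.write_text(
            "MODEL     1\n" + body + "ENDMDL\nMODEL     2\n" + body + "ENDMDL\nEND\n"
        )
        back = read_pdb(two, "A")
        assert len(back.residues) == len(helix.residues)

    def test_insertion_code_rejected(self, tmp_path):
        p = tmp_path / "icode.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1      0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1      1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1      2.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  N   GLY A   1A     3.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      5  CA  GLY A   1A     4.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      6  C   GLY A   1A     5.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(SeqStructError, match="insertion"):
            read_pdb(p, "A")

    def test_hetatm_ignored_and_backbone_required(self, tmp_path):
        p = tmp_path / "frag.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1      0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1      1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1      2.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    4  O   HOH A 101      9.000   9.000   9.000  1.00  0.00           O\n"
        )
        s = read_pdb(p, "A")
        assert len(s.residues) == 1

        q = tmp_path / "noca.pdb"
        q.write_text(
            "ATOM      1  N   ALA A   1      0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  C   ALA A   1      2.000   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(SeqStructError, match="CA"):
            read_pdb(q, "A")


class TestWriteMutant:
    def test_empty_set_preserves_structure(self, tmp_path, helix):
        p = tmp_path / "m.pdb"
        write_mutant_pdb(helix, frozenset(), p)
        back = read_pdb(p, "A")
        assert back.sequence.residues == helix.sequence.residues

    def test_single_mutation_changes_only_that_residue(self, tmp_path, helix):
        wt = helix.residues[4].one_letter
        mut = next(a for a in AA if a not in (wt, "G"))
        m = Mutation(5, wt, mut)
        p = tmp_path / "m.pdb"
        write_mutant_pdb(helix, {m}, p)
        back = read_pdb(p, "A")
        for orig, new in zip(helix.residues, back.residues):
            if orig.number == 5:
                assert new.one_letter == mut
                assert new.coord("CA") == pytest.approx(orig.coord("CA"), abs=1e-3)
            else:
                assert new.name == orig.name

    def test_wildtype_mismatch_is_error(self, tmp_path, helix):
        wt = helix.residues[0].one_letter
        wrong = next(a for a in AA if a != wt)
        other = next(a for a in AA if a not in (wt, wrong))
        with pytest.raises(SeqStructError, match="mismatch"):
            write_mutant_pdb(helix, {Mutation(1, wrong, other)}, tmp_path / "x.pdb")

    def test_position_absent_is_error(self, tmp_path, helix):
        with pytest.raises(SeqStructError, match="absent"):
            write_mutant_pdb(helix, {Mutation(999, "A", "V")}, tmp_path / "x.pdb")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def brute_force_best_score(a: str, b: str) -> float:
    """Max global alignment score by exhaustive enumeration (tiny inputs)."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return [("", "")]
        outs = []
        if i < len(a) and j < len(b):
            outs += [(a[i] + x, b[j] + y) for x, y in rec(i + 1, j + 1)]
        if i < len(a):
            outs += [(a[i] + x, GAP + y) for x, y in rec(i + 1, j)]
        if j < len(b):
            outs += [(GAP + x, b[j] + y) for x, y in rec(i, j + 1)]
        return outs

    return max(alignment_score(x, y) for x, y in rec(0, 0))


class TestAlignment:
    def test_identical_sequences_align_gapless_with_identity_map(self):
        t = ProteinSequence("t", "ACDEFG")
        a_t, a_h, cmap = align_to_template(t, ProteinSequence("h", "ACDEFG"))
        assert a_t.residues == a_h.residues == "ACDEFG"
        assert cmap.pairs == tuple((i, i + 1) for i in range(6))

    def test_single_substitution_no_gaps(self):
        t = ProteinSequence("t", "ACDEF")
        a_t, a_h, _ = align_to_template(t, ProteinSequence("h", "ACDWF"))
        assert GAP not in a_t.residues and GAP not in a_h.residues
        diffs = [i for i, (x, y) in enumerate(zip(a_t.residues, a_h.residues)) if x != y]
        assert diffs == [3]

    @pytest.mark.parametrize(
        "a,b",
        [
            ("ACD", "AD"),
            ("AD", "ACD"),
            ("WWW", "W"),
            ("ACDEF", "CDE"),
            ("MKV", "MQIV"),
            ("AAAA", "AA"),
        ],
    )
    def test_score_matches_exhaustive_oracle(self, a, b):
        ta, tb, _ = align_to_template(ProteinSequence("a", a), ProteinSequence("b", b))
        got = alignment_score(ta.residues, tb.residues)
        assert got == pytest.approx(brute_force_best_score(a, b))

    def test_column_map_inverse_is_identity(self):
        t = ProteinSequence("t", "ACDEF")
        _, _, cmap = align_to_template(t, ProteinSequence("h", "AEF"))
        for col, pos in cmap.pairs:
            assert cmap.column_for[pos] == col
            assert cmap.position_for[col] == pos

    def test_custom_residue_numbers_respected(self):
        t = ProteinSequence("t", "ACD")
        _, _, cmap = align_to_template(
            t, ProteinSequence("h", "ACD"), residue_numbers=[10, 11, 15]
        )
        assert [n for _, n in cmap.pairs] == [10, 11, 15]
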