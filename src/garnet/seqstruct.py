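"""Sequence and structure I/O.

Reads FASTA libraries (plain or pre-aligned), reads single-chain PDB
templates, writes mutant structures, and maintains the mapping between
alignment columns and template residue numbering.

PDB dialect: first MODEL only, ATOM records only (HETATM ignored),
insertion codes rejected, altloc resolved to the highest-occupancy
conformer (ties broken toward altloc 'A').  Residue numbers are the
file's author numbering and are used verbatim in mutation labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = set(AMINO_ACIDS)
_ALIGNED_ALPHABET = _ALPHABET | {GAP}

_1to3 = {v: k for k, v in protein_letters_3to1.items()}


class SeqStructError(ValueError):
    """Raised for malformed sequence or structure input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence; gaps permitted only in aligned context."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqStructError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(self.residues):
            if ch not in _ALIGNED_ALPHABET:
                raise SeqStructError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "ProteinSequence":
        return ProteinSequence(self.id, self.residues.replace(GAP, ""))


@dataclass(frozen=True)
class Residue:
    number: int                       # author numbering, 1-based
    name: str                         # 3-letter code
    atoms: tuple[tuple[str, float, float, float], ...]

    def coord(self, atom_name: str) -> tuple[float, float, float] | None:
        for name, x, y, z in self.atoms:
            if name == atom_name:
                return (x, y, z)
        return None

    @property
    def one_letter(self) -> str:
        return protein_letters_3to1.get(self.name, "X")


@dataclass(frozen=True)
class TemplateStructure:
    chain_id: str
    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise SeqStructError("residue numbers must be strictly increasing")
        for r in self.residues:
            names = {a[0] for a in r.atoms}
            missing = {"N", "CA", "C"} - names
            if missing:
                raise SeqStructError(
                    f"residue {r.number} ({r.name}) missing backbone atoms {sorted(missing)}"
                )

    @property
    def sequence(self) -> ProteinSequence:
        return ProteinSequence(
            f"chain_{self.chain_id}", "".join(r.one_letter for r in self.residues)
        )

    @property
    def residue_numbers(self) -> tuple[int, ...]:
        return tuple(r.number for r in self.residues)

    def residue_by_number(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise SeqStructError(f"residue {number} not present in structure")


@dataclass(frozen=True)
class ColumnMap:
    """Monotone pairing of alignment columns with template residue numbers."""

    pairs: tuple[tuple[int, int], ...]  # (0-based column, template residue number)

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        nums = [n for _, n in self.pairs]
        if sorted(cols) != cols or len(set(cols)) != len(cols):
            raise SeqStructError("column indices must be strictly increasing")
        if sorted(nums) != nums or len(set(nums)) != len(nums):
            raise SeqStructError("template residue numbers must be strictly increasing")

    @property
    def column_for(self) -> dict[int, int]:
        return {n: c for c, n in self.pairs}

    @property
    def position_for(self) -> dict[int, int]:
        return dict(self.pairs)

    @classmethod
    def identity(cls, residue_numbers: Sequence[int]) -> "ColumnMap":
        return cls(tuple((i, n) for i, n in enumerate(residue_numbers)))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA library, normalizing to uppercase, preserving order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqStructError(f"{path}: no FASTA records found")
    seqs = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SeqStructError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, chain: str) -> TemplateStructure:
    """Read one chain from a PDB file into a TemplateStructure.

    Only the first model is used; HETATM records are ignored; a residue
    with an insertion code is an error (numbering must stay unambiguous
    for mutation labels).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("template", str(path))
    models = list(structure)
    if not models:
        raise SeqStructError(f"{path}: no models found")
    model = models[0]
    if chain not in [c.id for c in model]:
        raise SeqStructError(f"{path}: chain {chain!r} not present")
    residues = []
    for res in model[chain]:
        hetflag, resseq, icode = res.id
        if hetflag != " ":
            continue
        if icode != " ":
            raise SeqStructError(
                f"{path}: residue {resseq}{icode.strip()} carries an insertion code; "
                "renumber the structure before use"
            )
        atoms = []
        for atom in res:
            if atom.is_disordered():
                # highest occupancy wins; tie -> altloc 'A'
                alts = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                atom = alts[0]
            x, y, z = atom.get_coord()
            atoms.append((atom.get_name(), float(x), float(y), float(z)))
        residues.append(Residue(int(resseq), res.get_resname(), tuple(atoms)))
    if not residues:
        raise SeqStructError(f"{path}: chain {chain!r} has no ATOM residues")
    return TemplateStructure(chain, tuple(residues))


def write_pdb(
    structure: TemplateStructure, path: str | Path, remarks: Sequence[str] = ()
) -> None:
    """Write ATOM records (plus REMARK lines) for a single chain."""
    with open(path, "w") as fh:
        for line in remarks:
            fh.write(f"REMARK 999 {line}\n")
        serial = 1
        for res in structure.residues:
            for name, x, y, z in res.atoms:
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:>5d} {pad_name}{'':1s}{res.name:>3s} "
                    f"{structure.chain_id}{res.number:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {name[0]:>2s}\n"
                )
                serial += 1
        fh.write("TER\nEND\n")


def write_mutant_pdb(
    structure: TemplateStructure,
    mutations,
    path: str | Path,
) -> None:
    """Write the template with mutated residue names substituted.

    No side-chain reconstruction is attempted: mutated residues keep
    backbone (N, CA, C, O) and CB atoms only; other side-chain atoms are
    dropped.  REMARK lines record the mutation labels.
    """
    by_number = {r.number: r for r in structure.residues}
    new_residues = []
    muts = sorted(mutations, key=lambda m: m.position)
    mut_by_pos = {}
    for m in muts:
        if m.position not in by_number:
            raise SeqStructError(f"mutation {m.label}: residue {m.position} absent from structure")
        found = by_number[m.position].one_letter
        if found != m.wt:
            raise SeqStructError(
                f"mutation {m.label}: wild-type mismatch at residue {m.position} "
                f"(expected {m.wt}, found {found})"
            )
        mut_by_pos[m.position] = m
    for res in structure.residues:
        if res.number in mut_by_pos:
            m = mut_by_pos[res.number]
            kept = tuple(a for a in res.atoms if a[0] in ("N", "CA", "C", "O", "CB"))
            new_residues.append(Residue(res.number, _1to3[m.mut], kept))
        else:
            new_residues.append(res)
    mutant = TemplateStructure(structure.chain_id, tuple(new_residues))
    remarks = ["MUTATIONS " + (",".join(m.label for m in muts) if muts else "NONE")]
    write_pdb(mutant, path, remarks=remarks)


# ---------------------------------------------------------------------------
# Pairwise alignment (global, affine gaps)
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _blosum(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def align_to_template(
    template: ProteinSequence,
    homolog: ProteinSequence,
    residue_numbers: Sequence[int] | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[ProteinSequence, ProteinSequence, ColumnMap]:
    """Global Needleman–Wunsch alignment of a homolog against the template.

    BLOSUM62 scoring with affine gaps: a gap of length L costs
    ``gap_open + gap_extend * L``.  Traceback ties are broken
    deterministically: diagonal (match) over up (gap in homolog) over
    left (gap in template).  Returns the aligned pair plus the column
    map onto template residue numbering (defaults to 1..L).
    """
    s, t = template.residues, homolog.residues
    if residue_numbers is None:
        residue_numbers = range(1, len(s) + 1)
    residue_numbers = list(residue_numbers)
    n, m = len(s), len(t)
    NEG = -math.inf
    # M: s[i] aligned to t[j]; Ix: gap in homolog (consume s); Iy: gap in template
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sc = _blosum(s[i - 1], t[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + sc
            Ix[i][j] = max(
                max(M[i - 1][j], Iy[i - 1][j]) - (gap_open + gap_extend),
                Ix[i - 1][j] - gap_extend,
            )
            Iy[i][j] = max(
                max(M[i][j - 1], Ix[i][j - 1]) - (gap_open + gap_extend),
                Iy[i][j - 1] - gap_extend,
            )
    # traceback; tie order: M (diagonal) > Ix (up) > Iy (left)
    i, j = n, m
    finals = [(M[n][m], "M"), (Ix[n][m], "Ix"), (Iy[n][m], "Iy")]
    best = max(v for v, _ in finals)
    state = next(name for v, name in finals if v == best)
    a_s: list[str] = []
    a_t: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            a_s.append(s[i - 1])
            a_t.append(t[j - 1])
            prev = M[i - 1][j - 1] + _blosum(s[i - 1], t[j - 1])
            sc = _blosum(s[i - 1], t[j - 1])
            for cand, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if mat[i - 1][j - 1] + sc == M[i][j]:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "Ix":
            a_s.append(s[i - 1])
            a_t.append(GAP)
            val = Ix[i][j]
            if M[i - 1][j] - (gap_open + gap_extend) == val:
                state = "M"
            elif Ix[i - 1][j] - gap_extend == val:
                state = "Ix"
            else:
                state = "Iy"
            i -= 1
        else:  # Iy
            a_s.append(GAP)
            a_t.append(t[j - 1])
            val = Iy[i][j]
            if M[i][j - 1] - (gap_open + gap_extend) == val:
                state = "M"
            elif Ix[i][j - 1] - (gap_open + gap_extend) == val:
                state = "Ix"
            else:
                state = "Iy"
            j -= 1
    aligned_template = "".join(reversed(a_s))
    aligned_homolog = "".join(reversed(a_t))
    pairs = []
    pos = 0
    for col, ch in enumerate(aligned_template):
        if ch != GAP:
            pairs.append((col, residue_numbers[pos]))
            pos += 1
    return (
        ProteinSequence(template.id, aligned_template),
        ProteinSequence(homolog.id, aligned_homolog),
        ColumnMap(tuple(pairs)),
    )


def alignment_score(
    aligned_a: str, aligned_b: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> float:
    """Score an aligned pair under the same model align_to_template uses."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == GAP:
            score -= gap_extend + (0.0 if in_gap_a else gap_open)
            in_gap_a, in_gap_b = True, False
        elif cb == GAP:
            score -= gap_extend + (0.0 if in_gap_b else gap_open)
            in_gap_b, in_gap_a = True, False
        else:
            score += _blosum(ca, cb)
            in_gap_a = in_gap_b = False
    return score
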