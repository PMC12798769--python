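"""Candidate mutation enumeration.

A candidate substitution is admitted only if it is phylogenetically
confirmed: the target residue must be observed in the corresponding
alignment column of the homolog library (at least ``min_count`` times).
Labels follow the position+residue convention, e.g. substituting
residue 4 to Glu is "4E".
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqstruct import GAP, AMINO_ACIDS, ColumnMap, ProteinSequence

_LABEL_RE = re.compile(r"^(\d+)([A-Z])$")


class MutationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Mutation:
    """One substitution relative to the template, e.g. D4E -> label '4E'."""

    position: int  # template residue number (author numbering, 1-based)
    wt: str
    mut: str

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise MutationError(f"mutation at {self.position}: wt equals mut ({self.wt})")
        if self.wt not in AMINO_ACIDS or self.mut not in AMINO_ACIDS:
            raise MutationError(f"mutation at {self.position}: non-canonical residue")

    @property
    def label(self) -> str:
        return f"{self.position}{self.mut}"


def parse_label(label: str) -> tuple[int, str]:
    """Split a label like '4E' into (4, 'E')."""
    m = _LABEL_RE.match(label)
    if not m:
        raise MutationError(f"malformed mutation label {label!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class MutationSpace:
    """The admissible substitutions plus the library column tallies."""

    candidates: frozenset[Mutation]
    column_counts: dict  # position -> Counter of library residues in that column

    @property
    def by_position(self) -> dict[int, list[Mutation]]:
        out: dict[int, list[Mutation]] = {}
        for m in sorted(self.candidates):
            out.setdefault(m.position, []).append(m)
        return out

    @property
    def by_label(self) -> dict[str, Mutation]:
        return {m.label: m for m in self.candidates}

    @property
    def positions(self) -> list[int]:
        return sorted(self.by_position)

    def library_count(self, m: Mutation) -> int:
        return self.column_counts.get(m.position, Counter())[m.mut]

    def __len__(self) -> int:
        return len(self.candidates)


def enumerate_candidates(
    template: ProteinSequence,
    aligned_library: list[ProteinSequence],
    column_map: ColumnMap,
    min_count: int = 1,
) -> MutationSpace:
    """Tally library columns and admit observed non-template residues.

    For each template position, every residue seen at least ``min_count``
    times in the mapped alignment column and differing from the template
    residue becomes a candidate.  Gaps never produce candidates.
    """
    if not aligned_library:
        raise MutationError("homolog library is empty")
    if min_count < 1:
        raise MutationError("min_count must be >= 1")
    width = len(aligned_library[0])
    for seq in aligned_library:
        if len(seq) != width:
            raise MutationError(f"library sequence {seq.id!r} breaks alignment width")
    tmpl = template.residues.replace(GAP, "")
    counts: dict[int, Counter] = {}
    cands: set[Mutation] = set()
    for idx, (col, pos) in enumerate(column_map.pairs):
        if col >= width:
            raise MutationError(f"column {col} outside alignment of width {width}")
        tally = Counter(seq.residues[col] for seq in aligned_library)
        tally.pop(GAP, None)
        counts[pos] = tally
        wt = tmpl[idx]
        for res, c in tally.items():
            if res != wt and c >= min_count:
                cands.add(Mutation(pos, wt, res))
    return MutationSpace(frozenset(cands), counts)


def apply_mutations(
    template_seq: ProteinSequence,
    mutations,
    residue_numbers=None,
) -> ProteinSequence:
    """Return the template sequence with the given substitutions applied."""
    numbers = list(residue_numbers) if residue_numbers is not None else list(
        range(1, len(template_seq) + 1)
    )
    index_of = {n: i for i, n in enumerate(numbers)}
    chars = list(template_seq.residues)
    seen: set[int] = set()
    for m in sorted(mutations):
        if m.position in seen:
            raise MutationError(f"conflicting mutations at position {m.position}")
        seen.add(m.position)
        if m.position not in index_of:
            raise MutationError(f"mutation {m.label}: position absent from template")
        i = index_of[m.position]
        if chars[i] != m.wt:
            raise MutationError(
                f"mutation {m.label}: wild-type mismatch (expected {m.wt}, found {chars[i]})"
            )
        chars[i] = m.mut
    return ProteinSequence(template_seq.id + "_mut", "".join(chars))


def diff_sequences(
    template_seq: ProteinSequence,
    mutant_seq: ProteinSequence,
    residue_numbers=None,
) -> frozenset[Mutation]:
    """Recover the mutation set separating a mutant from the template."""
    if len(template_seq) != len(mutant_seq):
        raise MutationError("sequences differ in length; substitutions only")
    numbers = list(residue_numbers) if residue_numbers is not None else list(
        range(1, len(template_seq) + 1)
    )
    out = set()
    for n, a, b in zip(numbers, template_seq.residues, mutant_seq.residues):
        if a != b:
            out.add(Mutation(n, a, b))
    return frozenset(out)


def export_candidates_tsv(space: MutationSpace, path: str | Path) -> None:
    rows = [
        {
            "position": m.position,
            "wt": m.wt,
            "mut": m.mut,
            "label": m.label,
            "library_count": space.library_count(m),
        }
        for m in sorted(space.candidates)
    ]
    pd.DataFrame(rows, columns=["position", "wt", "mut", "label", "library_count"]).to_csv(
        path, sep="\t", index=False
    )
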