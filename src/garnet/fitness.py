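"""Fitness functions for virtual evolution.

Two scores drive the genetic algorithm, both on a lower-is-better scale:

* **HiSol** — a sequence-level hydrophobicity-discrepancy score.  For
  each template position p the score accumulates h(seq_p) − h̄_p, where
  h is a hydrophobicity scale (Kyte–Doolittle by default) and h̄_p is
  the occupancy-weighted mean hydrophobicity of the non-gap residues in
  the homolog-library column mapped to p.  Columns with no non-gap
  library residues contribute nothing.  The aggregation (signed sum)
  and the scale are configurable so an alternative definition can be
  swapped in.

* **Structure energy** — a pairwise contact potential standing in for a
  full-atom force-field score.  Residue pairs at sequence separation
  >= 2 whose side-chain centroids (CB, CA for glycine) lie within a
  cutoff (6.5 Å default) contribute the Miyazawa–Jernigan contact
  energy for the (possibly mutated) residue-type pair.  An adapter is
  provided for delegating the energy to an external command (e.g. a
  Rosetta scoring script) instead.
"""

from __future__ import annotations

import math
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .mutations import Mutation, MutationError, apply_mutations
from .seqstruct import GAP, ColumnMap, ProteinSequence, TemplateStructure, write_mutant_pdb


class FitnessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Miyazawa-Jernigan inter-residue contact energies (RT units), lower triangle
# in the order C M F I L V W Y A G T S N Q D E H R K P.
# ---------------------------------------------------------------------------

_MJ_ORDER = "CMFILVWYAGTSNQDEHRKP"
_MJ_LOWER = [
    [-5.44],
    [-4.99, -5.46],
    [-5.80, -6.56, -7.26],
    [-5.50, -6.02, -6.84, -6.54],
    [-5.83, -6.41, -7.28, -7.04, -7.37],
    [-4.96, -5.32, -6.29, -6.05, -6.48, -5.52],
    [-4.95, -5.55, -6.16, -5.78, -6.14, -5.18, -5.06],
    [-4.16, -4.91, -5.66, -5.25, -5.67, -4.62, -4.66, -4.17],
    [-3.57, -3.94, -4.81, -4.58, -4.91, -4.04, -3.82, -3.36, -2.72],
    [-3.16, -3.39, -4.13, -3.78, -4.16, -3.38, -3.42, -3.01, -2.31, -2.24],
    [-3.11, -3.51, -4.28, -4.03, -4.34, -3.46, -3.22, -3.01, -2.32, -2.08, -2.12],
    [-2.86, -3.03, -4.02, -3.52, -3.92, -3.05, -2.99, -2.78, -2.01, -1.82, -1.96, -1.67],
    [-2.59, -2.95, -3.75, -3.24, -3.74, -2.83, -3.07, -2.76, -1.84, -1.74, -1.88, -1.58, -1.68],
    [-2.85, -3.30, -4.10, -3.67, -4.04, -3.07, -3.11, -2.97, -1.89, -1.66, -1.90, -1.49, -1.71, -1.54],
    [-2.41, -2.57, -3.48, -3.17, -3.40, -2.48, -2.84, -2.76, -1.70, -1.59, -1.80, -1.63, -1.68, -1.46, -1.21],
    [-2.27, -2.89, -3.56, -3.27, -3.59, -2.67, -2.99, -2.79, -1.51, -1.22, -1.74, -1.48, -1.51, -1.42, -1.02, -0.91],
    [-3.60, -3.98, -4.77, -4.14, -4.54, -3.58, -3.98, -3.52, -2.41, -2.15, -2.42, -2.11, -2.08, -1.98, -2.32, -2.15, -3.05],
    [-2.57, -3.12, -3.98, -3.63, -4.03, -3.07, -3.41, -3.16, -1.83, -1.72, -1.90, -1.62, -1.64, -1.80, -2.29, -2.27, -2.16, -1.55],
    [-1.95, -2.48, -3.36, -3.01, -3.37, -2.49, -2.69, -2.60, -1.31, -1.15, -1.31, -1.05, -1.21, -1.29, -1.68, -1.80, -1.35, -0.59, -0.12],
    [-3.07, -3.45, -4.25, -3.76, -4.20, -3.32, -3.73, -3.19, -2.03, -1.87, -1.90, -1.57, -1.53, -1.73, -1.33, -1.26, -2.25, -1.70, -0.97, -1.75],
]

MJ_CONTACT_ENERGY: dict[tuple[str, str], float] = {}
for _i, _row in enumerate(_MJ_LOWER):
    for _j, _e in enumerate(_row):
        _a, _b = _MJ_ORDER[_i], _MJ_ORDER[_j]
        MJ_CONTACT_ENERGY[(_a, _b)] = _e
        MJ_CONTACT_ENERGY[(_b, _a)] = _e


@dataclass(frozen=True)
class FitnessValue:
    score: float
    components: dict

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise FitnessError("fitness score must be finite")


@dataclass(frozen=True)
class FitnessReport:
    """Mutant-minus-template score changes."""

    delta_reu: float
    delta_hisol: float


@dataclass
class FitnessConfig:
    mode: str = "reu+hisol"  # reu | hisol | reu+hisol
    hydrophobicity_scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    contact_cutoff_angstrom: float = 6.5
    external_command: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("reu", "hisol", "reu+hisol"):
            raise FitnessError(f"unknown fitness mode {self.mode!r}")


# ---------------------------------------------------------------------------
# HiSol
# ---------------------------------------------------------------------------

def column_hydro_means(
    aligned_library: list[ProteinSequence],
    column_map: ColumnMap,
    scale: dict | None = None,
) -> dict[int, float]:
    """Mean hydrophobicity of the non-gap library residues per template position."""
    scale = scale or KYTE_DOOLITTLE
    means: dict[int, float] = {}
    for col, pos in column_map.pairs:
        vals = []
        for seq in aligned_library:
            ch = seq.residues[col]
            if ch == GAP:
                continue
            if ch not in scale:
                raise FitnessError(f"residue {ch!r} missing from hydrophobicity scale")
            vals.append(scale[ch])
        if vals:
            means[pos] = float(np.mean(vals))
    return means


def hisol_score(
    seq: ProteinSequence,
    aligned_library: list[ProteinSequence],
    column_map: ColumnMap,
    scale: dict | None = None,
    residue_numbers=None,
) -> float:
    """Signed hydrophobicity discrepancy of ``seq`` against the library."""
    scale = scale or KYTE_DOOLITTLE
    numbers = list(residue_numbers) if residue_numbers is not None else list(
        range(1, len(seq) + 1)
    )
    if len(numbers) != len(seq):
        raise FitnessError("residue numbering does not match sequence length")
    means = column_hydro_means(aligned_library, column_map, scale)
    total = 0.0
    for n, ch in zip(numbers, seq.residues):
        if ch not in scale:
            raise FitnessError(f"unknown residue {ch!r} at position {n}")
        if n in means:
            total += scale[ch] - means[n]
    return total


# ---------------------------------------------------------------------------
# Contact-potential structure energy
# ---------------------------------------------------------------------------

def _sidechain_centers(structure: TemplateStructure) -> np.ndarray:
    coords = []
    for res in structure.residues:
        c = res.coord("CB")
        if c is None:
            c = res.coord("CA")
        coords.append(c)
    return np.asarray(coords, dtype=float)


def contact_pairs(structure: TemplateStructure, cutoff: float = 6.5) -> list[tuple[int, int]]:
    """Index pairs (into the residue list) in side-chain contact.

    Contact: CB–CB distance (CA for glycine) < cutoff at sequence
    separation >= 2.  Pure geometry — independent of residue identity,
    so mutations never change the contact list.
    """
    xyz = _sidechain_centers(structure)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    n = len(xyz)
    pairs = []
    for i in range(n):
        for j in range(i + 2, n):
            if d[i, j] < cutoff:
                pairs.append((i, j))
    return pairs


def surrogate_energy(
    structure: TemplateStructure,
    mutations=frozenset(),
    cutoff: float = 6.5,
) -> float:
    """Miyazawa–Jernigan contact energy of the (mutated) template."""
    seq = structure.sequence
    numbers = structure.residue_numbers
    mutant = apply_mutations(seq, mutations, residue_numbers=numbers) if mutations else seq
    types = mutant.residues
    total = 0.0
    for i, j in contact_pairs(structure, cutoff):
        total += MJ_CONTACT_ENERGY[(types[i], types[j])]
    return total


# ---------------------------------------------------------------------------
# External energy adapter
# ---------------------------------------------------------------------------

class ExternalEnergyAdapter:
    """Delegate structure scoring to a user-configured external command.

    The command receives the mutant PDB path wherever ``{pdb}`` appears
    in the template (appended as a final argument if absent) and must
    print a single float.  Results are cached by mutation set.
    """

    def __init__(self, command_template: str, structure: TemplateStructure):
        self.command_template = command_template
        self.structure = structure
        self._cache: dict[frozenset, float] = {}
        self.calls = 0

    def __call__(self, mutations=frozenset()) -> float:
        key = frozenset(mutations)
        if key in self._cache:
            return self._cache[key]
        with tempfile.TemporaryDirectory() as tmp:
            pdb = str(Path(tmp) / "mutant.pdb")
            write_mutant_pdb(self.structure, key, pdb)
            argv = shlex.split(self.command_template)
            if any("{pdb}" in a for a in argv):
                argv = [a.replace("{pdb}", pdb) for a in argv]
            else:
                argv.append(pdb)
            proc = subprocess.run(argv, capture_output=True, text=True)
            if proc.returncode != 0:
                raise FitnessError(
                    f"external energy command failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip() or proc.stdout.strip()}"
                )
            floats = []
            for token in proc.stdout.split():
                try:
                    floats.append(float(token))
                except ValueError:
                    continue
            if not floats:
                raise FitnessError(
                    f"external energy command printed no number: {proc.stdout!r}"
                )
            value = floats[-1]
        self.calls += 1
        self._cache[key] = value
        return value


# ---------------------------------------------------------------------------
# Template-state bundle and deltas
# ---------------------------------------------------------------------------

@dataclass
class TemplateState:
    """Everything needed to score a mutation set against the template."""

    structure: TemplateStructure
    aligned_library: list[ProteinSequence]
    column_map: ColumnMap
    config: FitnessConfig = field(default_factory=FitnessConfig)

    def __post_init__(self) -> None:
        self._reu_cache: dict[frozenset, float] = {}
        self._external = (
            ExternalEnergyAdapter(self.config.external_command, self.structure)
            if self.config.external_command
            else None
        )

    @property
    def sequence(self) -> ProteinSequence:
        return self.structure.sequence

    @property
    def residue_numbers(self):
        return self.structure.residue_numbers

    def reu(self, mutations=frozenset()) -> float:
        key = frozenset(mutations)
        if key not in self._reu_cache:
            if self._external is not None:
                self._reu_cache[key] = self._external(key)
            else:
                self._reu_cache[key] = surrogate_energy(
                    self.structure, key, self.config.contact_cutoff_angstrom
                )
        return self._reu_cache[key]

    def hisol(self, mutations=frozenset()) -> float:
        mutant = apply_mutations(self.sequence, mutations, residue_numbers=self.residue_numbers)
        return hisol_score(
            mutant,
            self.aligned_library,
            self.column_map,
            self.config.hydrophobicity_scale,
            residue_numbers=self.residue_numbers,
        )

    def evaluator(self, mode: str):
        """A callable(mutation set) -> float for one GA fitness mode."""
        if mode == "reu":
            return self.reu
        if mode == "hisol":
            return self.hisol
        raise FitnessError(f"no single-score evaluator for mode {mode!r}")


def delta_scores(state: TemplateState, mutations) -> FitnessReport:
    """ΔREU and ΔHiSol of a mutation set relative to the template."""
    key = frozenset(mutations)
    return FitnessReport(
        delta_reu=state.reu(key) - state.reu(frozenset()),
        delta_hisol=state.hisol(key) - state.hisol(frozenset()),
    )
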