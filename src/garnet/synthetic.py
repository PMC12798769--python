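"""Synthetic inputs: homolog libraries, toy structures, fitness landscapes.

Everything the pipeline consumes can be generated here, seeded and
deterministic, so the full method runs without any external data.  The
generators emulate the shape of real inputs — position-specific
substitution profiles in a homolog library, a 3D backbone for the
contact-potential energy, and additive-plus-epistatic fitness
landscapes standing in for structure/sequence scores — while making no
claim to phylogenetic or structural realism (no indels, ideal helical
geometry, independent columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mutations import Mutation
from .network import MutationNetwork, powerlaw_mle
from .seqstruct import AMINO_ACIDS, ProteinSequence, Residue, TemplateStructure


# ---------------------------------------------------------------------------
# Homolog libraries
# ---------------------------------------------------------------------------

def generate_homolog_library(
    template: ProteinSequence,
    n_seqs: int,
    sub_rate: float = 0.2,
    profile_sharpness: float = 0.5,
    seed: int = 0,
    max_alternatives: int = 4,
) -> list[ProteinSequence]:
    """Sample an aligned homolog library around the template.

    Each column gets its own substitution profile: the template residue
    keeps probability 1 − sub_rate, and the remaining sub_rate mass is
    spread over up to ``max_alternatives`` alternative residues with
    Dirichlet(profile_sharpness) proportions — small sharpness makes one
    alternative dominate each column, large sharpness flattens the
    profile.  Sequences are drawn i.i.d. per column; no indels.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must be in [0, 1]")
    profiles = column_profile(template, sub_rate, profile_sharpness, seed, max_alternatives)
    sample_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    L = len(template)
    columns = np.empty((n_seqs, L), dtype="<U1")
    for p, prof in enumerate(profiles):
        letters = list(prof)
        probs = np.array([prof[a] for a in letters])
        columns[:, p] = sample_rng.choice(letters, size=n_seqs, p=probs / probs.sum())
    return [
        ProteinSequence(f"synthetic_homolog_{i}", "".join(columns[i]))
        for i in range(n_seqs)
    ]


def column_profile(
    template: ProteinSequence,
    sub_rate: float = 0.2,
    profile_sharpness: float = 0.5,
    seed: int = 0,
    max_alternatives: int = 4,
) -> list[dict[str, float]]:
    """The exact per-column distributions generate_homolog_library samples from."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    aas = list(AMINO_ACIDS)
    profiles = []
    for wt in template.residues:
        if sub_rate == 0.0:
            profiles.append({wt: 1.0})
            continue
        alternatives = [a for a in aas if a != wt]
        n_alt = min(max_alternatives, len(alternatives))
        picks = rng.choice(len(alternatives), size=n_alt, replace=False)
        alt = [alternatives[i] for i in picks]
        w = rng.dirichlet([profile_sharpness] * n_alt)
        prof = {wt: 1.0 - sub_rate}
        for a, wi in zip(alt, w):
            prof[a] = sub_rate * float(wi)
        profiles.append(prof)
    return profiles


def random_template(length: int, seed: int = 0) -> ProteinSequence:
    rng = np.random.default_rng(seed)
    return ProteinSequence(
        "synthetic_template",
        "".join(rng.choice(list(AMINO_ACIDS), size=length)),
    )


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5       # Å per residue
_HELIX_TWIST = 100.0    # degrees per residue
_HELIX_RADIUS = 2.28    # Å, gives consecutive CA-CA ~ 3.8 Å


def generate_toy_structure(sequence: ProteinSequence) -> TemplateStructure:
    """Place backbone + CB on an ideal α-helix (rise 1.5 Å, 100°/residue).

    Deterministic; N and C flank each CA along the helical path and CB
    points radially outward (absent for glycine).  Good enough for the
    contact-potential energy, which only needs CB/CA geometry.
    """
    if len(sequence) < 2:
        raise ValueError("need at least 2 residues")
    residues = []
    for i, aa in enumerate(sequence.residues):
        theta = math.radians(_HELIX_TWIST * i)
        z = _HELIX_RISE * i

        def on_helix(dt: float, dz: float, r: float = _HELIX_RADIUS):
            return (
                r * math.cos(theta + dt),
                r * math.sin(theta + dt),
                z + dz,
            )

        atoms = [
            ("N", *on_helix(-0.6, -0.5)),
            ("CA", *on_helix(0.0, 0.0)),
            ("C", *on_helix(0.6, 0.5)),
            ("O", *on_helix(0.9, 0.6)),
        ]
        if aa != "G":
            atoms.append(("CB", *on_helix(0.0, 0.0, _HELIX_RADIUS + 1.5)))
        name3 = _ONE_TO_THREE[aa]
        residues.append(Residue(i + 1, name3, tuple(atoms)))
    return TemplateStructure("A", tuple(residues))


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


# ---------------------------------------------------------------------------
# Fitness landscapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLandscape:
    """Additive + pairwise-epistatic landscape; fitness(∅) = 0, lower = better."""

    additive: dict
    epistasis: dict = field(default_factory=dict)
    noise_sd: float = 0.0

    def fitness(self, mutations, rng: np.random.Generator | None = None) -> float:
        total = 0.0
        muts = list(mutations)
        for m in muts:
            if m not in self.additive:
                raise KeyError(f"mutation {getattr(m, 'label', m)} outside the landscape")
            total += self.additive[m]
        for i in range(len(muts)):
            for j in range(i + 1, len(muts)):
                pair = frozenset((muts[i], muts[j]))
                total += self.epistasis.get(pair, 0.0)
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("noisy landscape requires an RNG")
            total += float(rng.normal(0.0, self.noise_sd))
        return total

    def evaluator(self, rng: np.random.Generator | None = None):
        return lambda mutations: self.fitness(mutations, rng)

    @property
    def beneficial(self) -> frozenset:
        return frozenset(m for m, e in self.additive.items() if e < 0)


def landscape_fitness(
    landscape: SyntheticLandscape, mutations, rng: np.random.Generator | None = None
) -> float:
    return landscape.fitness(mutations, rng)


def generate_landscape(
    candidates,
    n_beneficial: int,
    beneficial_effect: tuple[float, float] = (-2.0, -0.5),
    neutral_sd: float = 0.05,
    epistasis_frac: float = 0.05,
    epistasis_sd: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticLandscape:
    """Plant a known beneficial subset inside a candidate universe.

    ``n_beneficial`` candidates get additive effects drawn uniformly
    from ``beneficial_effect`` (negative = improving); the rest are
    near-neutral with sd ``neutral_sd``.  A sparse fraction of pairs
    carries Gaussian epistasis to exercise co-occurrence structure.
    """
    rng = np.random.default_rng(seed)
    cands = sorted(candidates)
    if n_beneficial > len(cands):
        raise ValueError("more beneficial mutations than candidates")
    idx = rng.choice(len(cands), size=n_beneficial, replace=False)
    beneficial = {cands[i] for i in idx}
    additive = {}
    for m in cands:
        if m in beneficial:
            additive[m] = float(rng.uniform(*beneficial_effect))
        else:
            additive[m] = float(rng.normal(0.0, neutral_sd))
    epistasis = {}
    if epistasis_frac > 0:
        n = len(cands)
        n_pairs = n * (n - 1) // 2
        n_epi = int(round(epistasis_frac * n_pairs))
        flat = rng.choice(n_pairs, size=n_epi, replace=False)
        pairs = []
        for f in flat:
            # unrank the f-th unordered pair
            i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * f)) // 2)
            j = int(f - i * (2 * n - i - 1) // 2 + i + 1)
            pairs.append((cands[i], cands[j]))
        for a, b in pairs:
            epistasis[frozenset((a, b))] = float(rng.normal(0.0, epistasis_sd))
    return SyntheticLandscape(additive, epistasis, noise_sd)


# ---------------------------------------------------------------------------
# Planted networks (for curation benchmarks)
# ---------------------------------------------------------------------------

def sample_discrete_powerlaw(
    gamma: float, n: int, rng: np.random.Generator, x_min: int = 1, x_max: int = 10**6
) -> np.ndarray:
    """Exact inverse-CDF samples from P(x) ∝ x^(-gamma), x in [x_min, x_max]."""
    xs = np.arange(x_min, x_max + 1, dtype=float)
    pmf = xs ** (-gamma)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.searchsorted(cdf, u) + x_min


def planted_scale_free_network(
    n_core: int = 150,
    gamma: float = 2.5,
    n_noise: int = 200,
    seed: int = 0,
    core_count: int = 5,
) -> tuple[MutationNetwork, frozenset, frozenset]:
    """A scale-free core plus planted one-off noise cliques.

    The core draws its degree sequence from a discrete power law with
    exponent ``gamma`` (capped, simplified via the configuration model)
    and represents mutations that recur across cycles: every core node
    gets occurrence count ``core_count`` and core edges count 2.  Noise
    enters as 2-cliques of fresh degree-1 nodes with occurrence count 1
    — the network signature of a spurious two-mutation elite from a
    single cycle.  Because noise only adds to the degree-1 head and
    never touches core degrees, the fitted exponent starts above the
    scale-free band and falls back into it as the noise is pruned.
    Returns (network, core labels, noise labels).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    degs = sample_discrete_powerlaw(gamma, n_core, rng, x_max=n_core - 1)
    if degs.sum() % 2:
        degs[int(rng.integers(0, n_core))] += 1
    g = nx.configuration_model(degs.tolist(), seed=int(rng.integers(0, 2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    core_labels = {i: f"core{i}" for i in g.nodes}
    node_count = {lbl: core_count for lbl in core_labels.values()}
    edge_count = {}
    for u, v in g.edges:
        edge_count[tuple(sorted((core_labels[u], core_labels[v])))] = 2
    noise = set()
    for j in range(0, n_noise - 1, 2):
        a, b = f"noise{j}", f"noise{j + 1}"
        node_count[a] = node_count[b] = 1
        edge_count[tuple(sorted((a, b)))] = 1
        noise.update((a, b))
    return (
        MutationNetwork(node_count, edge_count),
        frozenset(core_labels.values()),
        frozenset(noise),
    )
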