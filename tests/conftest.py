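import numpy as np
import pytest

from garnet import (
    ColumnMap,
    Mutation,
    MutationSpace,
    ProteinSequence,
    generate_toy_structure,
    random_template,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def template20():
    return random_template(20, seed=7)


@pytest.fixture
def helix(template20):
    return generate_toy_structure(template20)


def one_per_position_space(template: ProteinSequence) -> MutationSpace:
    """A mutation space with exactly one candidate per template position."""
    cands = set()
    for p, wt in enumerate(template.residues, start=1):
        mut = next(a for a in AA if a != wt)
        cands.add(Mutation(p, wt, mut))
    return MutationSpace(frozenset(cands), {})


@pytest.fixture
def space100():
    template = random_template(100, seed=0)
    return one_per_position_space(template)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
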