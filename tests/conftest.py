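import itertools

import numpy as np
import pytest

from infolattice import JointDistribution
from infolattice.synthetic import dirichlet_joint


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_joints(shapes, seed):
    """Flat-Dirichlet joints, one per alphabet-shape entry."""
    rng = np.random.default_rng(seed)
    return [dirichlet_joint(shape, rng) for shape in shapes]


@pytest.fixture
def triple_joints():
    """Ten random 3-variable joints with mixed alphabet sizes."""
    return random_joints([(2, 2, 2), (2, 3, 2), (3, 3, 3), (2, 2, 3)] * 3, seed=7)[:10]


@pytest.fixture
def quad_joints():
    """Five random 4-variable joints."""
    return random_joints([(2, 2, 2, 2), (2, 3, 2, 2)] * 3, seed=11)[:5]


def merge_variables(joint: JointDistribution, group: tuple[int, ...], new_var: int) -> JointDistribution:
    """Replace the variables in ``group`` by a single compound variable.

    The compound variable's states enumerate the product of the group's
    alphabets; used to express identities involving joint variables such as
    I2(X; (Y, Z)) through the pure-face API.
    """
    group = tuple(group)
    pos = {v: i for i, v in enumerate(joint.variables)}
    gidx = [pos[v] for v in group]
    rest = [v for v in joint.variables if v not in group]
    ridx = [pos[v] for v in rest]
    sizes = [joint.alphabet_sizes[i] for i in gidx]
    code_of = {
        combo: c for c, combo in enumerate(itertools.product(*[range(s) for s in sizes]))
    }
    probs = {}
    for atom, p in joint.probs.items():
        key = (code_of[tuple(atom[i] for i in gidx)],) + tuple(atom[i] for i in ridx)
        probs[key] = probs.get(key, 0.0) + p
    variables = (new_var,) + tuple(rest)
    alphabet = (len(code_of),) + tuple(joint.alphabet_sizes[i] for i in ridx)
    return JointDistribution(variables, alphabet, probs)
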