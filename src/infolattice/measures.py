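"""Entropy, multivariate mutual information and total correlation.

All values are in bits (log base 2).  Conventions: ``0 * log 0 = 0`` and
zero-probability conditioning branches are dropped.

The central quantity is the degree-``k`` interaction information

    I_k(X_1; ...; X_k) = sum over non-empty T subset of {1..k} of
                         (-1)^(|T|+1) H(X_T),

the alternating inclusion-exclusion sum of joint entropies.  ``I_1 = H`` and
``I_2`` is Shannon's mutual information (non-negative); for ``k >= 3`` the
sign carries meaning: positive values flag shared correlation, negative
values flag synergy/frustration (variables jointly dependent beyond what any
projection shows).  The total correlation ``G_k = sum_i H(X_i) - H(X_1..X_k)``
is the non-negative alternative, zero exactly on independent laws.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np

from .binning import DiscreteMatrix, estimate_joint
from .distributions import JointDistribution

Face = tuple[int, ...]


def _as_joint(obj: JointDistribution | DiscreteMatrix, subset: Sequence[int] | None) -> JointDistribution:
    if isinstance(obj, DiscreteMatrix):
        if subset is None:
            subset = tuple(range(obj.n_variables))
        return estimate_joint(obj, subset)
    if subset is None or tuple(subset) == obj.variables:
        return obj
    return obj.marginal(subset)


def entropy(joint: JointDistribution) -> float:
    """Shannon entropy H(P) in bits; 0 <= H <= log2(support size)."""
    total = joint.total_mass()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"distribution not normalized (mass {total})")
    return float(-math.fsum(p * math.log2(p) for p in joint.probs.values() if p > 0))


def joint_entropy(
    obj: JointDistribution | DiscreteMatrix, subset: Sequence[int] | None = None
) -> float:
    """Joint entropy H_k of the variables in ``subset``, in bits."""
    return entropy(_as_joint(obj, subset))


def conditional_entropy(
    joint: JointDistribution, target: Sequence[int], cond: Sequence[int]
) -> float:
    """H(target | cond) = sum_z P(z) H(target | cond = z), in bits.

    Computed by direct conditioning (the definition); equals
    ``H(target + cond) - H(cond)`` and is non-negative.
    """
    target, cond = tuple(target), tuple(cond)
    if set(target) & set(cond):
        raise ValueError("target and conditioning subsets must be disjoint")
    if not cond:
        return entropy(joint.marginal(target))
    sub = joint.marginal(target + cond)
    return float(
        math.fsum(
            w * entropy(law.marginal(target)) for w, law in sub.condition_on(cond)
        )
    )


def interaction_information(
    obj: JointDistribution | DiscreteMatrix, subset: Sequence[int] | None = None
) -> float:
    """Degree-k interaction information I_k on ``subset``, in bits.

    Alternating sum of the joint entropies of every non-empty sub-subset.
    Symmetric in its arguments; I_1 = H, I_2 >= 0, and I_k may be negative
    for k >= 3.
    """
    joint = _as_joint(obj, subset)
    vs = joint.variables
    out = 0.0
    for r in range(1, len(vs) + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for t in itertools.combinations(vs, r):
            out += sign * entropy(joint.marginal(t))
    return float(out)


#: alias under the field's other common name
mutual_information = interaction_information


def conditional_interaction_information(
    joint: JointDistribution, subset: Sequence[int], cond: Sequence[int]
) -> float:
    """I_k(subset | cond): probability-weighted I_k over conditioning outcomes.

    Satisfies the chain rule ``I_{k+1}(X0; X1..Xk) = I_k(X1..Xk)
    - I_k(X1..Xk | X0)``.
    """
    subset, cond = tuple(subset), tuple(cond)
    if set(subset) & set(cond):
        raise ValueError("subset and conditioning subset must be disjoint")
    if not cond:
        return interaction_information(joint, subset)
    sub = joint.marginal(subset + cond)
    return float(
        math.fsum(
            w * interaction_information(law.marginal(subset))
            for w, law in sub.condition_on(cond)
        )
    )


def total_correlation(
    obj: JointDistribution | DiscreteMatrix, subset: Sequence[int] | None = None
) -> float:
    """Total correlation G_k = sum_i H(X_i) - H(X_1,..,X_k), in bits.

    Non-negative; zero iff the variables are independent; G_2 = I_2.
    """
    joint = _as_joint(obj, subset)
    marg = math.fsum(entropy(joint.marginal((v,))) for v in joint.variables)
    return float(marg - entropy(joint))


def eta(joint: JointDistribution, J: Sequence[int]) -> float:
    """Atomic information component eta_J of the full law.

    ``eta_J`` is I_|J|(X_J) conditioned on the joint of all the remaining
    variables (empty conditioning when J is the full set, so eta_[n] = I_n).
    The eta values additively reassemble every pure measure:
    ``I_k(X_I) = sum over J containing I of eta_J`` and
    ``H_k(X_I) = sum over J meeting I of eta_J``.
    """
    J = tuple(int(v) for v in J)
    if not J:
        raise ValueError("J must be non-empty")
    complement = tuple(v for v in joint.variables if v not in set(J))
    if not complement:
        return interaction_information(joint, J)
    return conditional_interaction_information(joint, J, complement)


def eta_from_entropies(
    h_table: Mapping[Face, float], J: Sequence[int], variables: Sequence[int]
) -> float:
    """eta_J recovered from a complete entropy table by Moebius inversion.

    Inverts ``I_k(X_I) = sum_{J' superset I} eta_J'`` on the superset lattice:
    ``eta_J = sum_{I superset J} (-1)^(|I|-|J|) I_|I|(X_I)``, expanding each
    I term through its alternating entropy sum.  ``h_table`` must contain
    H for every non-empty subset of ``variables`` (keys are sorted tuples).
    """
    J = tuple(sorted(int(v) for v in J))
    if not J:
        raise ValueError("J must be non-empty")
    variables = tuple(sorted(int(v) for v in variables))
    if not set(J) <= set(variables):
        raise ValueError("J must be a subset of the variable set")
    for r in range(1, len(variables) + 1):
        for face in itertools.combinations(variables, r):
            if face not in h_table:
                raise KeyError(f"entropy table is missing face {face}")
    rest = tuple(v for v in variables if v not in set(J))
    out = 0.0
    for r in range(len(rest) + 1):
        for extra in itertools.combinations(rest, r):
            face = tuple(sorted(J + extra))
            sign = 1.0 if r % 2 == 0 else -1.0
            out += sign * _ik_from_table(h_table, face)
    return float(out)


def _ik_from_table(h_table: Mapping[Face, float], face: Face) -> float:
    """I_k of ``face`` from an entropy table via the alternating sum."""
    out = 0.0
    for r in range(1, len(face) + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for t in itertools.combinations(face, r):
            out += sign * h_table[tuple(sorted(t))]
    return float(out)


# -- dense fast paths --------------------------------------------------------


def entropy_dense(p: np.ndarray, axis: int | tuple[int, ...] | None = None) -> np.ndarray:
    """Entropy in bits of dense probability arrays (0 log 0 = 0)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=axis)


def interaction_information_batch(laws: np.ndarray) -> np.ndarray:
    """I_k for a batch of dense joint laws, in bits.

    ``laws`` has shape ``(B, s_1, ..., s_k)``: one dense law per leading
    index.  Used for large Monte-Carlo sweeps; agrees with
    :func:`interaction_information` on the sparse route.
    """
    laws = np.asarray(laws, dtype=float)
    k = laws.ndim - 1
    if k < 1:
        raise ValueError("laws must have at least one variable axis")
    axes = tuple(range(1, laws.ndim))
    out = np.zeros(laws.shape[0], dtype=float)
    for r in range(1, k + 1):
        sign = 1.0 if r % 2 == 1 else -1.0
        for keep in itertools.combinations(axes, r):
            drop = tuple(a for a in axes if a not in keep)
            marg = laws.sum(axis=drop) if drop else laws
            flat = marg.reshape(laws.shape[0], -1)
            out += sign * entropy_dense(flat, axis=1)
    return out
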