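"""Sparse joint probability distributions on products of finite alphabets.

A :class:`JointDistribution` carries the probability mass of an ordered subset
of discrete variables.  Support is stored sparsely (a dict keyed by code
tuples): when the law is estimated from ``m`` samples its support has at most
``m`` atoms, however large the nominal box count is.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

Atom = tuple[int, ...]

#: absolute tolerance on total mass for a distribution to count as normalized
NORMALIZATION_TOL = 1e-12


@dataclass(frozen=True)
class JointDistribution:
    """Probability mass over an ordered tuple of discrete variables.

    Parameters
    ----------
    variables
        Ordered variable indices this law is defined on (labels into the
        ambient data matrix; any hashable ints).
    alphabet_sizes
        Number of states of each variable, aligned with ``variables``.
    probs
        Sparse map from code tuples to probability mass.  Only strictly
        positive masses are kept; masses must sum to one.
    """

    variables: tuple[int, ...]
    alphabet_sizes: tuple[int, ...]
    probs: Mapping[Atom, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.variables) == 0:
            raise ValueError("a joint distribution needs at least one variable")
        if len(self.variables) != len(set(self.variables)):
            raise ValueError(f"duplicate variables in {self.variables!r}")
        if len(self.alphabet_sizes) != len(self.variables):
            raise ValueError("alphabet_sizes must align with variables")
        object.__setattr__(self, "variables", tuple(int(v) for v in self.variables))
        object.__setattr__(self, "alphabet_sizes", tuple(int(a) for a in self.alphabet_sizes))
        clean: dict[Atom, float] = {}
        for atom, p in self.probs.items():
            p = float(p)
            if p < 0:
                raise ValueError(f"negative mass {p} at atom {atom}")
            if p == 0.0:
                continue
            atom = tuple(int(c) for c in atom)
            if len(atom) != len(self.variables):
                raise ValueError(f"atom {atom} has wrong arity")
            for c, size in zip(atom, self.alphabet_sizes):
                if not 0 <= c < size:
                    raise ValueError(f"code {c} outside alphabet of size {size}")
            clean[atom] = clean.get(atom, 0.0) + p
        total = math.fsum(clean.values())
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ValueError(f"masses sum to {total!r}, not 1")
        object.__setattr__(self, "probs", clean)

    # -- basic protocol ----------------------------------------------------

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def support_size(self) -> int:
        return len(self.probs)

    def __iter__(self) -> Iterator[tuple[Atom, float]]:
        return iter(sorted(self.probs.items()))

    def total_mass(self) -> float:
        return math.fsum(self.probs.values())

    # -- construction ------------------------------------------------------

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        variables: Sequence[int] | None = None,
    ) -> "JointDistribution":
        """Build from a dense array whose axes are the variables."""
        arr = np.asarray(arr, dtype=float)
        if variables is None:
            variables = tuple(range(arr.ndim))
        probs = {
            tuple(int(i) for i in idx): float(arr[idx])
            for idx in np.ndindex(arr.shape)
            if arr[idx] > 0
        }
        return cls(tuple(variables), arr.shape, probs)

    def to_array(self) -> np.ndarray:
        """Dense representation (axes ordered as ``variables``)."""
        out = np.zeros(self.alphabet_sizes, dtype=float)
        for atom, p in self.probs.items():
            out[atom] = p
        return out

    # -- marginalization & conditioning -------------------------------------

    def _positions(self, subset: Sequence[int]) -> list[int]:
        pos = {v: i for i, v in enumerate(self.variables)}
        missing = [v for v in subset if v not in pos]
        if missing:
            raise ValueError(f"variables {missing} not in {self.variables}")
        return [pos[v] for v in subset]

    def marginal(self, subset: Sequence[int]) -> "JointDistribution":
        """Marginal law on ``subset`` (a sub-list of ``variables``).

        Reduced masses are the sums of all compatible full atoms; the total
        mass is conserved.
        """
        subset = tuple(int(v) for v in subset)
        if len(subset) == 0:
            raise ValueError("cannot marginalize to the empty subset")
        idx = self._positions(subset)
        if subset == self.variables:
            return self
        out: dict[Atom, float] = {}
        for atom, p in self.probs.items():
            key = tuple(atom[i] for i in idx)
            out[key] = out.get(key, 0.0) + p
        sizes = tuple(self.alphabet_sizes[i] for i in idx)
        return JointDistribution(subset, sizes, out)

    def condition_on(
        self, cond: Sequence[int]
    ) -> Iterator[tuple[float, "JointDistribution"]]:
        """Iterate ``(weight, conditional law)`` over outcomes of ``cond``.

        Yields, for every conditioning outcome of positive mass, its
        probability and the conditional law of the remaining variables.
        Zero-mass branches never appear (the 0*inf = 0 convention).
        """
        cond = tuple(int(v) for v in cond)
        cond_idx = self._positions(cond)
        rest = tuple(v for v in self.variables if v not in cond)
        if not rest:
            raise ValueError("conditioning on all variables leaves nothing")
        rest_idx = self._positions(rest)
        rest_sizes = tuple(self.alphabet_sizes[i] for i in rest_idx)
        groups: dict[Atom, dict[Atom, float]] = {}
        for atom, p in self.probs.items():
            z = tuple(atom[i] for i in cond_idx)
            groups.setdefault(z, {})[tuple(atom[i] for i in rest_idx)] = p
        for z in sorted(groups):
            sub = groups[z]
            w = math.fsum(sub.values())
            yield w, JointDistribution(
                rest, rest_sizes, {a: p / w for a, p in sub.items()}
            )

    # -- misc ----------------------------------------------------------------

    def permuted(self, order: Sequence[int]) -> "JointDistribution":
        """Reorder the variables (same law, permuted coordinates)."""
        idx = self._positions(order)
        if sorted(idx) != list(range(self.n_variables)):
            raise ValueError("order must be a permutation of the variables")
        probs = {
            tuple(atom[i] for i in idx): p for atom, p in self.probs.items()
        }
        return JointDistribution(
            tuple(order), tuple(self.alphabet_sizes[i] for i in idx), probs
        )


def product_distribution(
    marginals: Iterable[JointDistribution],
) -> JointDistribution:
    """Explicit product law of single-variable distributions."""
    marginals = list(marginals)
    variables: list[int] = []
    sizes: list[int] = []
    for m in marginals:
        variables.extend(m.variables)
        sizes.extend(m.alphabet_sizes)
    probs: dict[Atom, float] = {}
    for combo in itertools.product(*[list(m.probs.items()) for m in marginals]):
        atom = tuple(itertools.chain.from_iterable(a for a, _ in combo))
        p = math.prod(p for _, p in combo)
        if p > 0:
            probs[atom] = p
    # renormalize away accumulated rounding so the invariant holds exactly
    total = math.fsum(probs.values())
    probs = {a: p / total for a, p in probs.items()}
    return JointDistribution(tuple(variables), tuple(sizes), probs)
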