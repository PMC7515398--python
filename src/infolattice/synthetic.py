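"""Synthetic laws and data matrices with known information structure.

These fixtures make every other module testable without external data: the
extremal binary triples attain the I_3 bounds exactly, product laws realise
the independence null, Markov chains realise the chain criterion, and the
planted-module / two-population generators emulate grouped dependence
structure (modules of near-copies of a latent source) in continuous data
that is then pushed through the standard binning path.
"""

from __future__ import annotations

import itertools
import math
from typing import Literal, Sequence

import numpy as np

from .data import DataMatrix
from .distributions import Atom, JointDistribution, product_distribution

TripleKind = Literal["identical", "opposite", "parity-even", "parity-odd"]

_TRIPLE_SUPPORTS: dict[str, tuple[Atom, ...]] = {
    # the four I3 = +1 configurations: unbiased bits, pairwise deterministic
    "identical": ((0, 0, 0), (1, 1, 1)),
    "opposite": ((0, 0, 1), (1, 1, 0)),
    "opposite-2": ((0, 1, 0), (1, 0, 1)),
    "opposite-3": ((0, 1, 1), (1, 0, 0)),
    # the two I3 = -1 configurations: pairwise-independent unbiased bits with
    # fixed parity (third bit the XOR / XNOR of the first two) — the
    # "Borromean" laws, dependent only at degree 3
    "parity-even": ((0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 0)),
    "parity-odd": ((0, 0, 1), (0, 1, 0), (1, 0, 0), (1, 1, 1)),
}


def extremal_triple(kind: TripleKind = "identical") -> JointDistribution:
    """One of the extremal three-bit laws (I_3 = +1 or -1 exactly)."""
    try:
        support = _TRIPLE_SUPPORTS[kind]
    except KeyError:
        raise ValueError(
            f"unknown kind {kind!r}; choose from {sorted(_TRIPLE_SUPPORTS)}"
        ) from None
    p = 1.0 / len(support)
    return JointDistribution((0, 1, 2), (2, 2, 2), {atom: p for atom in support})


def independent_law(n: int, r: int) -> JointDistribution:
    """Exact product-uniform law: H_k = k log2 r and I_k = 0 for all k >= 2."""
    if r < 2:
        raise ValueError("need alphabet size r >= 2")
    uniform = [
        JointDistribution((j,), (r,), {(s,): 1.0 / r for s in range(r)})
        for j in range(n)
    ]
    return product_distribution(uniform)


def independent_samples(
    n: int, r: int, m: int, seed: int | np.random.Generator = 0
) -> DataMatrix:
    """m i.i.d. rows from the product-uniform law, as a real-valued matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.integers(0, r, size=(m, n)).astype(float)
    return DataMatrix(values)


def markov_chain_law(
    n: int, transition_kernel: np.ndarray, initial: np.ndarray | None = None
) -> JointDistribution:
    """Joint law of a stationary n-step Markov chain with the given kernel.

    ``transition_kernel`` is an (r, r) row-stochastic matrix; the initial
    distribution defaults to a stationary distribution of the kernel.
    """
    K = np.asarray(transition_kernel, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    if (K < 0).any() or not np.allclose(K.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("kernel rows must be non-negative and sum to 1")
    r = K.shape[0]
    if initial is None:
        # stationary distribution: left eigenvector of eigenvalue 1
        w, v = np.linalg.eig(K.T)
        idx = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, idx])
        pi = np.abs(pi) / np.abs(pi).sum()
    else:
        pi = np.asarray(initial, dtype=float)
        if pi.shape != (r,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-10:
            raise ValueError("initial must be a length-r probability vector")
    probs: dict[Atom, float] = {}
    for atom in itertools.product(range(r), repeat=n):
        p = pi[atom[0]]
        for a, b in zip(atom, atom[1:]):
            p *= K[a, b]
        if p > 0:
            probs[atom] = float(p)
    total = math.fsum(probs.values())
    probs = {a: p / total for a, p in probs.items()}
    return JointDistribution(tuple(range(n)), (r,) * n, probs)


def _noisy_copies(
    source: np.ndarray, n_copies: int, copy_noise: float, r: int, rng: np.random.Generator
) -> np.ndarray:
    cols = np.tile(source[:, None], (1, n_copies))
    if copy_noise > 0:
        resample = rng.random(cols.shape) < copy_noise
        cols[resample] = rng.integers(0, r, size=int(resample.sum()))
    return cols


def planted_module_samples(
    n: int,
    m: int,
    module: Sequence[int],
    copy_noise: float = 0.1,
    r: int = 2,
    seed: int | np.random.Generator = 0,
    jitter: bool = True,
) -> DataMatrix:
    """Independent noise variables with one planted dependent module.

    Module variables are noisy copies of a shared latent uniform source on
    ``r`` symbols (each entry independently resampled with probability
    ``copy_noise``); all other variables are i.i.d. uniform.  With
    ``jitter=True`` the integer codes are smeared uniformly inside unit
    cells so the matrix is genuinely continuous and exercises the binning
    path end to end (bin with N = r).
    """
    module = tuple(sorted(int(j) for j in module))
    if not set(module) <= set(range(n)):
        raise ValueError("module must be a subset of range(n)")
    if not 0 <= copy_noise < 0.5:
        raise ValueError("copy_noise must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = rng.integers(0, r, size=(m, n))
    source = rng.integers(0, r, size=m)
    codes[:, list(module)] = _noisy_copies(source, len(module), copy_noise, r, rng)
    values = codes.astype(float)
    if jitter:
        values = values + rng.random(values.shape)
    return DataMatrix(values)


def two_population_samples(
    n_vars_per_block: tuple[int, int],
    m: int,
    seed: int | np.random.Generator = 0,
    block_strengths: tuple[float, float] = (0.1, 0.1),
    r: int = 2,
    jitter: bool = True,
) -> tuple[DataMatrix, list[int]]:
    """Two variable blocks, each a noisy copy of its own latent source.

    Emulates two sub-populations with strong within-block and zero
    cross-block dependence; the longest maximal information paths should
    recover the block memberships.  Returns the matrix and per-variable
    block labels (0 or 1).
    """
    b1, b2 = n_vars_per_block
    if b1 < 1 or b2 < 1:
        raise ValueError("both blocks need at least one variable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = []
    for size, noise in zip((b1, b2), block_strengths):
        source = rng.integers(0, r, size=m)
        blocks.append(_noisy_copies(source, size, noise, r, rng))
    codes = np.concatenate(blocks, axis=1)
    values = codes.astype(float)
    if jitter:
        values = values + rng.random(values.shape)
    labels = [0] * b1 + [1] * b2
    return DataMatrix(values), labels


def simplex_draws(
    states: int,
    count: int,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, ...] | None = None,
) -> list[JointDistribution]:
    """Laws drawn uniformly (flat Dirichlet) from the simplex on ``states``.

    With ``shape`` given (its product must equal ``states``) each draw is a
    joint law over ``len(shape)`` variables; otherwise a single variable with
    ``states`` outcomes.
    """
    if states < 2:
        raise ValueError("need at least 2 states")
    if shape is not None and math.prod(shape) != states:
        raise ValueError("prod(shape) must equal states")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.dirichlet(np.ones(states), size=count)
    out = []
    for row in flat:
        row = row / row.sum()
        if shape is None:
            probs = {(i,): float(p) for i, p in enumerate(row) if p > 0}
            out.append(JointDistribution((0,), (states,), probs))
        else:
            out.append(JointDistribution.from_array(row.reshape(shape)))
    return out


def dirichlet_joint(
    alphabet_sizes: Sequence[int], rng: np.random.Generator | int = 0
) -> JointDistribution:
    """One flat-Dirichlet joint law over variables with the given alphabets."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes = tuple(int(s) for s in alphabet_sizes)
    flat = rng.dirichlet(np.ones(math.prod(sizes)))
    return JointDistribution.from_array((flat / flat.sum()).reshape(sizes))
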