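"""Equal-width discretization of real measurements and probability counting.

Probabilities are estimated non-parametrically: each variable's measured
range ``[min, max]`` is split into ``N`` equal-width bins and atomic
probabilities are the box occupancy counts divided by the number of samples.
The estimator needs no prior on the distributions; its two tuning knobs are
the graining ``N`` and the sample size ``m``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import DataMatrix
from .distributions import JointDistribution

#: default graining: 9 equal-width bins per variable
DEFAULT_N_BINS = 9


@dataclass(frozen=True)
class BinningScheme:
    """Per-variable bin counts and interval bounds (in data units)."""

    n_bins: tuple[int, ...]
    lo: tuple[float, ...]
    hi: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.n_bins) == len(self.lo) == len(self.hi)):
            raise ValueError("per-variable fields must have equal length")
        for n, lo, hi in zip(self.n_bins, self.lo, self.hi):
            if n < 1:
                raise ValueError(f"bin count {n} < 1")
            if lo > hi:
                raise ValueError(f"empty interval [{lo}, {hi}]")

    @property
    def n_variables(self) -> int:
        return len(self.n_bins)

    @property
    def n_boxes(self) -> int:
        """Total box count N1 * N2 * ... * Nn of the full grid."""
        out = 1
        for n in self.n_bins:
            out *= int(n)
        return out


@dataclass(frozen=True)
class DiscreteMatrix:
    """Integer codes of a discretized DataMatrix plus its binning scheme."""

    codes: np.ndarray
    scheme: BinningScheme
    sample_labels: tuple[str, ...]
    variable_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        if codes.shape[1] != self.scheme.n_variables:
            raise ValueError("codes/scheme width mismatch")
        for j, n in enumerate(self.scheme.n_bins):
            col = codes[:, j]
            if col.min() < 0 or col.max() >= n:
                raise ValueError(f"codes of variable {j} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_variables(self) -> int:
        return self.codes.shape[1]

    @property
    def alphabet_sizes(self) -> tuple[int, ...]:
        return self.scheme.n_bins

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=list(self.sample_labels), columns=list(self.variable_labels)
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), sep="\t")


def _per_variable(N: int | Sequence[int], n: int) -> tuple[int, ...]:
    if np.isscalar(N):
        return (int(N),) * n
    N = tuple(int(x) for x in N)  # type: ignore[arg-type]
    if len(N) != n:
        raise ValueError(f"expected {n} bin counts, got {len(N)}")
    return N


def compute_bins(matrix: DataMatrix, N: int | Sequence[int] = DEFAULT_N_BINS) -> BinningScheme:
    """Equal-width scheme on each variable's observed [min, max] range.

    A constant variable collapses to a single-point interval (one occupied
    bin, entropy 0) rather than raising: real expression matrices contain
    silent genes.
    """
    n_bins = _per_variable(N, matrix.n_variables)
    lo = matrix.values.min(axis=0)
    hi = matrix.values.max(axis=0)
    return BinningScheme(n_bins, tuple(map(float, lo)), tuple(map(float, hi)))


def discretize(
    matrix: DataMatrix,
    scheme: BinningScheme | None = None,
    N: int | Sequence[int] = DEFAULT_N_BINS,
) -> DiscreteMatrix:
    """Map each value to its bin code ``min(floor((x-lo)*N/(hi-lo)), N-1)``.

    Cells are half-open with the maximum value assigned to the last bin; a
    value sitting exactly on an interior boundary goes to the higher bin
    (forced by the floor rule).  Values outside ``[lo, hi]`` signal a
    scheme/data mismatch and raise.
    """
    if scheme is None:
        scheme = compute_bins(matrix, N)
    if scheme.n_variables != matrix.n_variables:
        raise ValueError("scheme width does not match matrix")
    x = matrix.values
    lo = np.asarray(scheme.lo)
    hi = np.asarray(scheme.hi)
    nb = np.asarray(scheme.n_bins)
    if (x < lo).any() or (x > hi).any():
        raise ValueError("values outside the binning intervals")
    width = hi - lo
    codes = np.zeros(x.shape, dtype=np.int64)
    live = width > 0
    scaled = np.zeros_like(x)
    scaled[:, live] = (x[:, live] - lo[live]) * nb[live] / width[live]
    codes[:, live] = np.minimum(np.floor(scaled[:, live]).astype(np.int64), nb[live] - 1)
    return DiscreteMatrix(
        codes, scheme, tuple(matrix.sample_labels), tuple(matrix.variable_labels)
    )


def estimate_joint(dm: DiscreteMatrix, subset: Sequence[int]) -> JointDistribution:
    """Empirical joint law of ``subset`` by elementary counting.

    Each atom's probability is (number of samples in that box) / m, so every
    mass is an integer multiple of 1/m and the support has at most
    ``min(m, prod N_j)`` atoms.  Estimating on a subset equals marginalizing
    the full-joint estimate (locality).
    """
    subset = tuple(int(j) for j in subset)
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError("subset indices must be distinct")
    for j in subset:
        if not 0 <= j < dm.n_variables:
            raise ValueError(f"variable index {j} out of range")
    m = dm.n_samples
    sub = dm.codes[:, list(subset)]
    atoms, counts = np.unique(sub, axis=0, return_counts=True)
    probs = {tuple(int(c) for c in atom): int(cnt) / m for atom, cnt in zip(atoms, counts)}
    sizes = tuple(dm.scheme.n_bins[j] for j in subset)
    return JointDistribution(subset, sizes, probs)


def marginalize(joint: JointDistribution, subset: Sequence[int]) -> JointDistribution:
    """Marginal of a joint law on a sub-list of its variables."""
    return joint.marginal(subset)
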