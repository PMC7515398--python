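"""Finite-sample diagnostics and significance tests for information values.

Two effects dominate information estimates from ``m`` samples:

* **Undersampling.**  Every empirical joint entropy obeys ``H_k <= log2 m``;
  once a face hits that ceiling (every sample alone in its box) all its
  extensions stay there.  The undersampling dimension ``k_u`` is the last
  degree at which fewer than ``p_u`` (default 5%) of faces are saturated —
  beyond it, estimates reflect sample size, not structure.

* **Shuffle bias.**  Even for truly independent columns, finite-sample I_k
  estimates are biased away from zero.  The marginal-preserving shuffle test
  permutes each column independently, pools the shuffled I_k values of all
  same-degree faces into an empirical null, and flags observed values beyond
  its quantiles.  The null means "randomly selected k-dependence preserving
  the marginals", not strict independence: the test is a specificity test.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import DiscreteMatrix
from .distributions import JointDistribution
from .lattice import Face, compute_landscape, entropy_table
from .measures import _ik_from_table, interaction_information

#: tolerance for treating an empirical entropy as saturated at log2(m)
SATURATION_TOL = 1e-9


# -- undersampling dimension -------------------------------------------------


@dataclass
class UndersamplingReport:
    """Per-degree saturation fractions and the resulting dimension k_u."""

    ku: int
    saturation_fraction: dict[int, float]
    p_u: float
    m: int
    n: int
    n_bins: tuple[int, ...]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "ku": self.ku,
            "p_u": self.p_u,
            "m": self.m,
            "n": self.n,
            "N": list(self.n_bins),
            "saturation_fraction": {str(k): v for k, v in self.saturation_fraction.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def undersampling_dimension(
    dm: DiscreteMatrix,
    p_u: float = 0.05,
    kmax: int | None = None,
    h_table: Mapping[Face, float] | None = None,
) -> UndersamplingReport:
    """Estimate k_u: the degree below which entropy saturation stays rare.

    Per degree k, the fraction of the C(n, k) faces whose H_k equals
    ``log2 m`` (within tolerance) is recorded; ``k_u`` is one less than the
    first degree where that fraction exceeds ``p_u``, or ``kmax`` when no
    degree saturates.
    """
    if dm.n_samples < 2:
        raise ValueError("need m >= 2 samples")
    if min(dm.scheme.n_bins) < 2:
        raise ValueError("undersampling analysis needs every N_j >= 2")
    n = dm.n_variables
    if kmax is None:
        kmax = n
    kmax = min(kmax, n)
    if h_table is None:
        h_table = entropy_table(dm, kmax)
    log2m = math.log2(dm.n_samples)
    fractions: dict[int, float] = {}
    ku = kmax
    for k in range(1, kmax + 1):
        faces = [f for f in h_table if len(f) == k]
        sat = sum(1 for f in faces if abs(h_table[f] - log2m) <= SATURATION_TOL)
        frac = sat / len(faces)
        fractions[k] = frac
        if frac > p_u and ku == kmax:
            ku = k - 1
    return UndersamplingReport(
        ku, fractions, p_u, dm.n_samples, n, tuple(dm.scheme.n_bins)
    )


# -- marginal-preserving shuffles ---------------------------------------------


def shuffle_matrix(dm: DiscreteMatrix, rng: np.random.Generator | int) -> DiscreteMatrix:
    """Independently permute each column: marginals are exactly preserved."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = dm.codes.copy()
    for j in range(dm.n_variables):
        codes[:, j] = codes[rng.permutation(dm.n_samples), j]
    return DiscreteMatrix(codes, dm.scheme, dm.sample_labels, dm.variable_labels)


@dataclass
class NullDistribution:
    """Pooled shuffled I_k values of one degree, with its decision thresholds."""

    k: int
    values: np.ndarray
    n_shuffles: int
    seed: int
    lower: float | None
    upper: float


@dataclass
class DependenceReport:
    """Per-face significance decisions against the shuffle null."""

    table: pd.DataFrame
    nulls: dict[int, NullDistribution]
    config: dict = field(default_factory=dict)

    @property
    def significant_faces(self) -> list[Face]:
        sig = self.table[self.table["significant"]]
        return [tuple(f) for f in sig["face_idx"]]

    def write_tsv(self, path: str | Path, labels: Sequence[str] | None = None) -> None:
        df = self.table.copy()
        if labels is not None:
            df["face"] = [";".join(labels[v] for v in f) for f in df["face_idx"]]
        else:
            df["face"] = [";".join(map(str, f)) for f in df["face_idx"]]
        cols = ["face", "degree", "observed", "lower_thr", "upper_thr", "significant", "side"]
        with open(Path(path), "w") as fh:
            fh.write(f"# {json.dumps(self.config)}\n")
            df[cols].to_csv(fh, sep="\t", index=False)


def _quantile(values: np.ndarray, q: float) -> float:
    # empirical-distribution (type 1) quantile of the pooled null
    return float(np.quantile(values, q, method="inverted_cdf"))


def dependence_test(
    dm: DiscreteMatrix,
    k_range: Sequence[int] = (2, 3),
    n_shuffles: int = 17,
    p2: float = 0.05,
    pk: float = 0.1,
    seed: int = 0,
) -> DependenceReport:
    """Shuffle test of specific k-dependence for every face of each degree.

    The null of degree k pools the I_k values of all C(n, k) faces over
    ``n_shuffles`` column-wise shuffles.  Degree 2 uses a one-sided upper
    threshold at level ``p2`` (I_2 is non-negative); degrees >= 3 use
    symmetric two-sided thresholds splitting ``pk`` equally between tails.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2:
        raise ValueError("k_range must contain degrees >= 2")
    if k_range[-1] > dm.n_variables:
        raise ValueError("k_range exceeds the number of variables")
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    kmax = k_range[-1]
    n_faces_k = {k: math.comb(dm.n_variables, k) for k in k_range}
    min_tail = min(p2, pk / 2)
    if n_shuffles * min(n_faces_k.values()) * min_tail < 1:
        import warnings

        warnings.warn(
            "pooled null too small to resolve the requested quantiles; "
            "increase n_shuffles",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    h_obs = entropy_table(dm, kmax)
    pooled: dict[int, list[float]] = {k: [] for k in k_range}
    for _ in range(n_shuffles):
        h_sh = entropy_table(shuffle_matrix(dm, rng), kmax)
        for k in k_range:
            pooled[k].extend(
                _ik_from_table(h_sh, f) for f in h_sh if len(f) == k
            )

    nulls: dict[int, NullDistribution] = {}
    rows = []
    for k in k_range:
        values = np.asarray(pooled[k])
        if k == 2:
            lower, upper = None, _quantile(values, 1 - p2)
        else:
            lower, upper = _quantile(values, pk / 2), _quantile(values, 1 - pk / 2)
        nulls[k] = NullDistribution(k, values, n_shuffles, seed, lower, upper)
        for face in (f for f in h_obs if len(f) == k):
            obs = _ik_from_table(h_obs, face)
            side = ""
            if obs > upper:
                side = "above"
            elif lower is not None and obs < lower:
                side = "below"
            rows.append(
                {
                    "face_idx": face,
                    "degree": k,
                    "observed": obs,
                    "lower_thr": lower if lower is not None else np.nan,
                    "upper_thr": upper,
                    "significant": bool(side),
                    "side": side,
                }
            )
    table = pd.DataFrame(rows)
    config = {
        "k_range": k_range,
        "n_shuffles": n_shuffles,
        "p2": p2,
        "pk": pk,
        "seed": seed,
        "m": dm.n_samples,
        "n": dm.n_variables,
    }
    return DependenceReport(table, nulls, config)


# -- exact criteria ----------------------------------------------------------


def independence_check(
    obj: JointDistribution | DiscreteMatrix,
    tol: float = 1e-10,
    kmax: int | None = None,
) -> tuple[bool, list[tuple[Face, float]]]:
    """Full independence criterion: all 2^n - n - 1 values I_k, k >= 2, vanish.

    Returns (verdict, offending faces ranked by |I_k| descending).
    """
    ls = compute_landscape(obj, measure="I", kmax=kmax)
    offending = [
        (face, value)
        for face, value in ls.entries.items()
        if len(face) >= 2 and abs(value) > tol
    ]
    offending.sort(key=lambda fv: -abs(fv[1]))
    return (not offending, offending)


def markov_consistency(
    joint: JointDistribution, ordering: Sequence[int], tol: float = 1e-9
) -> tuple[bool, dict[Face, float]]:
    """Markov-chain criterion for a proposed ordering of the variables.

    The variables form a Markov chain in the order (i_1, ..., i_n) iff, for
    every subset J of the intermediate variables, the interaction information
    of {i_1} + J + {i_n} equals I_2(X_{i_1}; X_{i_n}).  Returns the verdict
    and per-subset residuals (face -> I_k - I_2).
    """
    ordering = tuple(int(v) for v in ordering)
    if sorted(ordering) != sorted(joint.variables):
        raise ValueError("ordering must be a permutation of the joint's variables")
    first, last = ordering[0], ordering[-1]
    inner = ordering[1:-1]
    i2 = interaction_information(joint, (first, last))
    residuals: dict[Face, float] = {}
    for r in range(len(inner) + 1):
        for J in itertools.combinations(inner, r):
            face = tuple(sorted((first,) + J + (last,)))
            residuals[face] = interaction_information(joint, face) - i2
    ok = all(abs(v) <= tol for v in residuals.values())
    return ok, residuals


def low_entropy_fraction(
    r: int,
    k: int,
    epsilon: float,
    n_draws: int,
    rng: np.random.Generator | int = 0,
) -> float:
    """Fraction of uniform-simplex laws on r^k states with H <= eps*k*log2(r).

    For a law drawn uniformly (flat Dirichlet) on the simplex of ``r^k``
    states and ``0 < eps <= 1/e``, the probability that the joint entropy
    falls at or below ``eps * k * log2 r`` is at most ``eps`` — entropies of
    random laws concentrate near capacity, so saturation is the norm, not
    the exception, when the box count outruns the sample.
    """
    if not 0 < epsilon <= 1 / math.e:
        raise ValueError("epsilon must lie in (0, 1/e]")
    if r < 2 or k < 1:
        raise ValueError("need r >= 2 and k >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    laws = rng.dirichlet(np.ones(r**k), size=n_draws)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(laws > 0, laws * np.log2(np.where(laws > 0, laws, 1.0)), 0.0).sum(axis=1)
    threshold = epsilon * k * math.log2(r)
    return float(np.mean(h <= threshold))
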