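"""Landscapes and extremal paths on the simplicial lattice of variable subsets.

A *landscape* maps every face (non-empty variable subset, up to a dimension
cap ``kmax``) to a measure value H_k, I_k or G_k.  An *information path*
follows a nested chain of faces, one variable added per step; its slope at
step ``k -> k+1`` is ``I_{k+1} - I_k``, i.e. minus the conditional mutual
information of the added variable.  Extremal paths take only descending
steps (positive conditional mutual information) and end at their first
minimum — the conditional-independence criterion.

Exhaustive enumeration costs ``sum_k C(n, k)`` faces, O(2^n): feasible up to
n around 20 with a capped ``kmax``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .binning import DiscreteMatrix, compute_bins, discretize
from .data import DataMatrix
from .distributions import JointDistribution
from .measures import _ik_from_table, entropy

Face = tuple[int, ...]
MeasureKind = Literal["H", "I", "G"]

#: refuse to enumerate more faces than this without an explicit override
DEFAULT_MAX_FACES = 2_000_000


def enumerate_faces(n: int, kmax: int) -> list[Face]:
    """All non-empty subsets of {0..n-1} of size <= kmax, degree-then-lex order."""
    if not 1 <= kmax <= n:
        raise ValueError(f"need 1 <= kmax <= n, got kmax={kmax}, n={n}")
    faces: list[Face] = []
    for k in range(1, kmax + 1):
        faces.extend(itertools.combinations(range(n), k))
    return faces


@dataclass
class Landscape:
    """Per-face values of one measure over the lattice up to degree ``kmax``."""

    measure: MeasureKind
    kmax: int
    n_variables: int
    entries: dict[Face, float]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, face: Sequence[int]) -> float:
        return self.entries[tuple(sorted(int(v) for v in face))]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def complete(self) -> bool:
        expect = sum(math.comb(self.n_variables, k) for k in range(1, self.kmax + 1))
        return len(self.entries) == expect

    def degree(self, k: int) -> dict[Face, float]:
        """Entries of the C(n, k) faces of degree ``k``."""
        return {f: v for f, v in self.entries.items() if len(f) == k}

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        def name(face: Face) -> str:
            if labels is None:
                return ";".join(str(v) for v in face)
            return ";".join(labels[v] for v in face)

        rows = [
            {"degree": len(f), "face": name(f), "value_bits": v}
            for f, v in sorted(self.entries.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["degree", "face", "value_bits"])

    def write_tsv(self, path: str | Path, labels: Sequence[str] | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# measure={self.measure}")
            for key in sorted(self.meta):
                fh.write(f" {key}={self.meta[key]}")
            fh.write("\n")
            self.to_frame(labels).to_csv(fh, sep="\t", index=False)


# -- entropy tables ----------------------------------------------------------


def _empirical_entropies(dm: DiscreteMatrix, faces: Sequence[Face]) -> dict[Face, float]:
    """H_k (bits) of every requested face by box counting on the codes."""
    m = dm.n_samples
    codes = dm.codes
    sizes = dm.scheme.n_bins
    log2m = math.log2(m)
    out: dict[Face, float] = {}
    for face in faces:
        cols = list(face)
        # encode each row of the sub-matrix as a single integer key when the
        # box count fits in int64, else fall back to row-wise unique
        nboxes = 1
        for j in cols:
            nboxes *= int(sizes[j])
        if nboxes < 2**62:
            keys = np.zeros(m, dtype=np.int64)
            for j in cols:
                keys = keys * int(sizes[j]) + codes[:, j]
            _, counts = np.unique(keys, return_counts=True)
        else:
            _, counts = np.unique(codes[:, cols], axis=0, return_counts=True)
        out[face] = log2m - float((counts * np.log2(counts)).sum()) / m
    return out


def _exact_entropies(joint: JointDistribution, faces: Sequence[Face]) -> dict[Face, float]:
    return {face: entropy(joint.marginal(face)) for face in faces}


def entropy_table(
    source: DiscreteMatrix | JointDistribution, kmax: int
) -> dict[Face, float]:
    """H for every face up to degree ``kmax`` (keys: sorted variable tuples)."""
    if isinstance(source, DiscreteMatrix):
        faces = enumerate_faces(source.n_variables, kmax)
        return _empirical_entropies(source, faces)
    n = source.n_variables
    faces = [
        tuple(source.variables[i] for i in f) for f in enumerate_faces(n, kmax)
    ]
    return _exact_entropies(source, faces)


def compute_landscape(
    source: DiscreteMatrix | JointDistribution,
    measure: MeasureKind = "I",
    kmax: int | None = None,
    max_faces: int = DEFAULT_MAX_FACES,
) -> Landscape:
    """Measure values on every face up to ``kmax``.

    ``source`` is either a discretized data matrix (empirical counting) or an
    exact joint law.  I and G are derived from a shared entropy table, so
    each H_k is computed once however many alternating sums reuse it.
    """
    n = source.n_variables
    if kmax is None:
        kmax = n
    total = sum(math.comb(n, k) for k in range(1, kmax + 1))
    if total > max_faces:
        raise MemoryError(
            f"{total} faces requested (n={n}, kmax={kmax}) exceeds the cap "
            f"{max_faces}; lower kmax or raise max_faces"
        )
    h = entropy_table(source, kmax)
    meta: dict = {"n": n, "kmax": kmax}
    if isinstance(source, DiscreteMatrix):
        meta["m"] = source.n_samples
        meta["N"] = list(source.scheme.n_bins)
    if measure == "H":
        entries = dict(h)
    elif measure == "I":
        entries = {face: _ik_from_table(h, face) for face in h}
    elif measure == "G":
        entries = {
            face: math.fsum(h[(v,)] for v in face) - h[face] for face in h
        }
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return Landscape(measure, kmax, n, entries, meta)


def mean_path(landscape: Landscape) -> pd.Series:
    """Mean value per degree <value>(k), k = 1..kmax (complete landscape only)."""
    if not landscape.complete:
        raise ValueError("landscape is incomplete; cannot average per degree")
    means = {
        k: float(np.mean(list(landscape.degree(k).values())))
        for k in range(1, landscape.kmax + 1)
    }
    return pd.Series(means, name=f"mean_{landscape.measure}")


def max_tuple(landscape: Landscape, k: int, direction: Literal["max", "min"] = "max") -> Face:
    """Arg-extremal face of degree ``k``; ties go to the lexicographically smallest."""
    entries = landscape.degree(k)
    if not entries:
        raise ValueError(f"no degree-{k} entries in landscape")
    best = max if direction == "max" else min
    value = best(entries.values())
    return min(f for f, v in entries.items() if v == value)


# -- information paths -------------------------------------------------------


@dataclass
class InfoPath:
    """An ordered chain of variables with the measure value at each prefix."""

    variables: tuple[int, ...]
    values: tuple[float, ...]
    direction: Literal["max", "min"]
    stop_reason: Literal["first-minimum", "kmax-reached", "exhausted"]

    @property
    def length(self) -> int:
        return len(self.variables)

    @property
    def terminal_value(self) -> float:
        return self.values[-1]

    def core_variables(self, tol: float = 0.0) -> tuple[int, ...]:
        """The prefix whose values stay above ``tol`` (for max paths).

        A maximal path ends *at* its first minimum, so its final step — a
        large positive conditional MI landing at a value near zero — can
        drag one unrelated variable in (the "erroneous classification"
        effect).  The core is the prefix before the value collapsed.
        """
        out: list[int] = []
        for v, value in zip(self.variables, self.values):
            if value <= tol:
                break
            out.append(v)
        return tuple(out)

    def to_dict(self, labels: Sequence[str] | None = None) -> dict:
        names = (
            list(self.variables)
            if labels is None
            else [labels[v] for v in self.variables]
        )
        return {
            "direction": self.direction,
            "variables": names,
            "values": list(self.values),
            "stop_reason": self.stop_reason,
        }


def _finish_reason(path_len: int, kmax: int, n: int) -> str:
    if path_len == n:
        return "exhausted"
    if path_len == kmax:
        return "kmax-reached"
    return "first-minimum"


def extremal_paths(
    landscape: Landscape,
    direction: Literal["max", "min"] = "max",
    kmax: int | None = None,
    search: Literal["greedy", "exhaustive"] = "greedy",
    beam_width: int = 1,
    tol: float = 0.0,
) -> list[InfoPath]:
    """Longest information paths ending at their first minimum.

    A step from prefix ``F`` to ``F + {v}`` is taken only while it strictly
    descends (conditional mutual information ``I_k - I_{k+1} > tol``);
    ``direction='max'`` follows the slowest descent (maximal slope, the
    strongest persisting dependence), ``direction='min'`` the steepest.  When
    no candidate descends, the path has reached its first minimum and stops.
    Paths that are permutations of the same variable set are deduplicated;
    the result is ranked by (length, extremal terminal value).

    ``search='greedy'`` runs a beam search (width ``beam_width``) from every
    starting variable; ``'exhaustive'`` enumerates every descending chain
    (intended for n <= 12).
    """
    if landscape.measure != "I":
        raise ValueError("paths are defined on an I-landscape")
    n = landscape.n_variables
    if kmax is None:
        kmax = landscape.kmax
    kmax = min(kmax, landscape.kmax)
    if search == "exhaustive" and n > 12:
        raise ValueError("exhaustive path search is limited to n <= 12")
    prefer = max if direction == "max" else min
    finished: list[tuple[tuple[int, ...], tuple[float, ...], str]] = []

    def descending(prefix: tuple[int, ...], value: float) -> list[tuple[int, float]]:
        used = set(prefix)
        face = tuple(sorted(prefix))
        cands = []
        for v in range(n):
            if v in used:
                continue
            nxt = landscape[tuple(sorted(face + (v,)))]
            if value - nxt > tol:  # conditional MI of the step is positive
                cands.append((v, nxt))
        return cands

    if search == "exhaustive":
        def walk(prefix: tuple[int, ...], values: tuple[float, ...]) -> None:
            if len(prefix) == kmax or len(prefix) == n:
                finished.append((prefix, values, _finish_reason(len(prefix), kmax, n)))
                return
            cands = descending(prefix, values[-1])
            if not cands:
                finished.append((prefix, values, "first-minimum"))
                return
            for v, nxt in cands:
                walk(prefix + (v,), values + (nxt,))

        for start in range(n):
            walk((start,), (landscape[(start,)],))
    else:
        if beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        for start in range(n):
            frontier = [((start,), (landscape[(start,)],))]
            while frontier:
                extensions = []
                for prefix, values in frontier:
                    if len(prefix) == kmax or len(prefix) == n:
                        finished.append(
                            (prefix, values, _finish_reason(len(prefix), kmax, n))
                        )
                        continue
                    cands = descending(prefix, values[-1])
                    if not cands:
                        finished.append((prefix, values, "first-minimum"))
                        continue
                    extensions.extend(
                        (prefix + (v,), values + (nxt,)) for v, nxt in cands
                    )
                # keep the beam_width best extensions; ties to lowest indices
                extensions.sort(
                    key=lambda pv: (
                        -pv[1][-1] if direction == "max" else pv[1][-1],
                        pv[0],
                    )
                )
                frontier = extensions[:beam_width]

    # deduplicate paths supported on the same variable set; keep the ordering
    # with extremal cumulative information (it sustains the dependence longest)
    sgn = 1.0 if direction == "max" else -1.0
    by_support: dict[frozenset[int], tuple[tuple[int, ...], tuple[float, ...], str]] = {}
    for prefix, values, reason in finished:
        key = frozenset(prefix)
        old = by_support.get(key)
        if (
            old is None
            or sgn * math.fsum(values) > sgn * math.fsum(old[1])
            or (math.fsum(values) == math.fsum(old[1]) and prefix < old[0])
        ):
            by_support[key] = (prefix, values, reason)
    paths = [
        InfoPath(prefix, values, direction, reason)  # type: ignore[arg-type]
        for prefix, values, reason in by_support.values()
    ]
    paths.sort(
        key=lambda p: (
            -p.length,
            -p.terminal_value if direction == "max" else p.terminal_value,
            p.variables,
        )
    )
    return paths


def path_components(paths: Sequence[InfoPath]) -> list[list[InfoPath]]:
    """Group longest paths into components by disjointness of their supports.

    Greedy: the longest path seeds the first component; each further path
    joins the first component whose support it overlaps, else seeds a new one.
    """
    components: list[tuple[set[int], list[InfoPath]]] = []
    for p in paths:
        support = set(p.variables)
        for members, plist in components:
            if members & support:
                members |= support
                plist.append(p)
                break
        else:
            components.append((support, [p]))
    return [plist for _, plist in components]


def write_paths_json(
    paths: Sequence[InfoPath], path: str | Path, labels: Sequence[str] | None = None,
    meta: Mapping | None = None,
) -> None:
    payload = {
        "meta": dict(meta or {}),
        "paths": [p.to_dict(labels) for p in paths],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# -- graining / sample-size sweeps ------------------------------------------


@dataclass
class SweepCell:
    """Mean path of one (N, m) cell of an iso-graining / iso-sampling sweep."""

    n_bins: int
    m: int
    mean_path: pd.Series
    critical_k: int | None

    def to_dict(self) -> dict:
        return {
            "N": self.n_bins,
            "m": self.m,
            "mean_path": {int(k): float(v) for k, v in self.mean_path.items()},
            "critical_k": self.critical_k,
        }


def first_minimum(values: pd.Series) -> int | None:
    """Degree of the first local minimum of a mean path (None if monotone)."""
    ks = sorted(values.index)
    for a, b in zip(ks, ks[1:]):
        if values[b] > values[a]:
            return int(a)
    return None


def landscape_sweep(
    matrix: DataMatrix,
    N_list: Sequence[int],
    m_list: Sequence[int],
    measure: MeasureKind = "I",
    kmax: int | None = None,
    seed: int = 0,
) -> dict[tuple[int, int], SweepCell]:
    """Mean paths over a grid of grainings N and subsample sizes m.

    Each cell subsamples ``m`` rows without replacement (seeded), rebins on
    the subsample's own [min, max] ranges, and records the mean path and its
    first minimum (the critical dimension).  ``m`` equal to the full sample
    reproduces the direct mean path.
    """
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, int], SweepCell] = {}
    for m in m_list:
        if m > matrix.n_samples:
            raise ValueError(f"m={m} exceeds the {matrix.n_samples} available rows")
        for N in N_list:
            if m == matrix.n_samples:
                rows = np.arange(m)
            else:
                rows = np.sort(rng.choice(matrix.n_samples, size=m, replace=False))
            sub = DataMatrix(
                matrix.values[rows],
                sample_labels=[matrix.sample_labels[i] for i in rows],
                variable_labels=matrix.variable_labels,
                transposed=matrix.transposed,
            )
            dm = discretize(sub, compute_bins(sub, N))
            ls = compute_landscape(dm, measure=measure, kmax=kmax)
            mp = mean_path(ls)
            out[(N, m)] = SweepCell(N, m, mp, first_minimum(mp))
    return out
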