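"""Model/results interface tying the analysis pipeline together.

:class:`InformationLattice` is constructed from a data matrix and holds the
analysis configuration (graining, dimension cap, undersampling level);
``fit()`` discretizes, builds the entropy/information/total-correlation
landscapes and the undersampling report, and returns an
:class:`InformationLatticeResults` carrying them, with paths, dependence
tests and serialization hanging off the results object.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .binning import DEFAULT_N_BINS, BinningScheme, DiscreteMatrix, compute_bins, discretize
from .data import DataMatrix, read_matrix
from .lattice import (
    InfoPath,
    Landscape,
    compute_landscape,
    entropy_table,
    extremal_paths,
    max_tuple,
    mean_path,
    path_components,
    write_paths_json,
)
from .measures import _ik_from_table
from .stats import (
    DependenceReport,
    UndersamplingReport,
    dependence_test,
    independence_check,
    undersampling_dimension,
)

#: default cap on the landscape dimension for wide matrices
DEFAULT_KMAX_CAP = 12


class InformationLattice:
    """Simplicial information analysis of a samples x variables matrix.

    Parameters
    ----------
    data
        A :class:`~infolattice.data.DataMatrix`, pandas DataFrame
        (rows = samples) or 2-D array.
    n_bins
        Graining: equal-width bin count per variable (global int or
        per-variable sequence).  Default 9.
    kmax
        Dimension cap for the lattice; defaults to ``min(n, 12)``.
    p_u
        Saturation level defining the undersampling dimension (default 0.05).
    """

    def __init__(
        self,
        data: DataMatrix | pd.DataFrame | np.ndarray,
        n_bins: int | Sequence[int] = DEFAULT_N_BINS,
        kmax: int | None = None,
        p_u: float = 0.05,
    ) -> None:
        if isinstance(data, DataMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = DataMatrix.from_dataframe(data)
        else:
            self.data = DataMatrix(np.asarray(data, dtype=float))
        self.n_bins = n_bins
        self.kmax = kmax
        self.p_u = p_u

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        transpose: bool = False,
        sep: str | None = None,
        **kwargs,
    ) -> "InformationLattice":
        return cls(read_matrix(path, transpose=transpose, sep=sep), **kwargs)

    @property
    def config(self) -> dict:
        nb = self.n_bins
        return {
            "n_bins": int(nb) if np.isscalar(nb) else [int(x) for x in nb],
            "kmax": self.kmax,
            "p_u": self.p_u,
            "m": self.data.n_samples,
            "n": self.data.n_variables,
        }

    def fit(self, kmax: int | None = None) -> "InformationLatticeResults":
        """Discretize, compute landscapes and the undersampling report."""
        n = self.data.n_variables
        if kmax is None:
            kmax = self.kmax
        if kmax is None:
            kmax = min(n, DEFAULT_KMAX_CAP)
        kmax = min(kmax, n)
        scheme = compute_bins(self.data, self.n_bins)
        dm = discretize(self.data, scheme)
        h_table = entropy_table(dm, kmax)
        landscapes = {}
        for measure in ("H", "I", "G"):
            if measure == "H":
                entries = dict(h_table)
            elif measure == "I":
                entries = {f: _ik_from_table(h_table, f) for f in h_table}
            else:
                entries = {
                    f: sum(h_table[(v,)] for v in f) - h_table[f] for f in h_table
                }
            ls = Landscape(measure, kmax, n, entries,
                           {"n": n, "kmax": kmax, "m": dm.n_samples,
                            "N": list(scheme.n_bins)})
            landscapes[measure] = ls
        report = undersampling_dimension(dm, p_u=self.p_u, kmax=kmax, h_table=h_table)
        if kmax > report.ku:
            warnings.warn(
                f"landscape dimension kmax={kmax} exceeds the undersampling "
                f"dimension ku={report.ku}; entries beyond ku reflect sample "
                "size, not structure",
                stacklevel=2,
            )
        for ls in landscapes.values():
            ls.meta["ku"] = report.ku
        return InformationLatticeResults(self, dm, landscapes, report)


class InformationLatticeResults:
    """Fitted landscapes, undersampling diagnostics and downstream analyses."""

    def __init__(
        self,
        model: InformationLattice,
        discrete: DiscreteMatrix,
        landscapes: dict[str, Landscape],
        undersampling: UndersamplingReport,
    ) -> None:
        self.model = model
        self.discrete = discrete
        self.landscapes = landscapes
        self.undersampling = undersampling

    # -- accessors -----------------------------------------------------------

    @property
    def ku(self) -> int:
        return self.undersampling.ku

    @property
    def scheme(self) -> BinningScheme:
        return self.discrete.scheme

    def landscape(self, measure: Literal["H", "I", "G"] = "I") -> Landscape:
        return self.landscapes[measure]

    def mean_path(self, measure: Literal["H", "I", "G"] = "I") -> pd.Series:
        return mean_path(self.landscapes[measure])

    def max_tuple(
        self, k: int, measure: Literal["H", "I", "G"] = "I",
        direction: Literal["max", "min"] = "max",
    ) -> tuple[int, ...]:
        return max_tuple(self.landscapes[measure], k, direction)

    # -- downstream analyses -------------------------------------------------

    def paths(
        self,
        direction: Literal["max", "min"] = "max",
        kmax: int | None = None,
        search: Literal["greedy", "exhaustive"] = "greedy",
        beam_width: int = 1,
        tol: float = 0.0,
    ) -> list[InfoPath]:
        """Extremal information paths, capped at k_u unless told otherwise.

        ``tol`` is the slope resolution: a step must descend by more than
        ``tol`` bits to count.  The default 0 is the literal sign-change
        criterion (right for exact laws); on empirical landscapes a small
        positive value above the O(1/m) estimation noise keeps fluctuation
        steps from extending paths.
        """
        if kmax is None:
            kmax = min(self.landscapes["I"].kmax, max(self.ku, 1))
        return extremal_paths(
            self.landscapes["I"], direction=direction, kmax=kmax,
            search=search, beam_width=beam_width, tol=tol,
        )

    def path_components(self, **kwargs) -> list[list[InfoPath]]:
        return path_components(self.paths(**kwargs))

    def dependence_test(self, **kwargs) -> DependenceReport:
        return dependence_test(self.discrete, **kwargs)

    def independence_check(self, tol: float = 1e-9) -> tuple[bool, list]:
        return independence_check(self.discrete, tol=tol, kmax=self.landscapes["I"].kmax)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        m = self.discrete.n_samples
        n = self.discrete.n_variables
        lines = [
            "Information lattice analysis",
            "=" * 60,
            f"samples (m): {m}    variables (n): {n}",
            f"graining (N): {list(self.scheme.n_bins)}",
            f"lattice dimension cap (kmax): {self.landscapes['I'].kmax}",
            f"undersampling dimension (ku, p_u={self.undersampling.p_u}): {self.ku}",
            "",
            "per-degree summary (bits):",
        ]
        rows = []
        for k in range(1, self.landscapes["I"].kmax + 1):
            hk = list(self.landscapes["H"].degree(k).values())
            ik = self.landscapes["I"].degree(k)
            top = max_tuple(self.landscapes["I"], k, "max")
            rows.append(
                {
                    "k": k,
                    "faces": len(hk),
                    "mean_H": np.mean(hk),
                    "mean_I": np.mean(list(ik.values())),
                    "max_I": max(ik.values()),
                    "min_I": min(ik.values()),
                    "argmax_I": ";".join(map(str, top)),
                    "saturated": self.undersampling.saturation_fraction.get(k, 0.0),
                }
            )
        table = pd.DataFrame(rows)
        lines.append(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)

    def config_hash(self) -> str:
        payload = json.dumps(self.model.config, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def save(self, outdir: str | Path, seed: int | None = None, **path_kwargs) -> None:
        """Write the full report bundle (TSV/JSON) to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labels = list(self.discrete.variable_labels)
        config = dict(self.model.config)
        config["config_hash"] = self.config_hash()
        if seed is not None:
            config["seed"] = seed
        (outdir / "config.json").write_text(json.dumps(config, indent=2))
        self.discrete.write_tsv(outdir / "discrete_codes.tsv")
        for measure, ls in self.landscapes.items():
            ls.meta["config_hash"] = self.config_hash()
            ls.write_tsv(outdir / f"landscape_{measure}.tsv", labels)
        self.undersampling.to_json(outdir / "undersampling.json")
        meta = {"config_hash": self.config_hash()}
        if seed is not None:
            meta["seed"] = seed
        for direction in ("max", "min"):
            write_paths_json(
                self.paths(direction=direction, **path_kwargs),
                outdir / f"paths_{direction}.json",
                labels,
                meta=meta,
            )
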