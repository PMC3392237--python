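"""Cluster-number selection via the cluster dispersion measure.

Cluster dispersion (CD) compares the fuzzy within-cluster scatter to the
scatter of the data about its grand mean:

    CD = sum_i sum_k u_ik^M ||X_k - V_i||^2  /  sum_k ||X_k - xbar||^2

The denominator equals the numerator of a single-cluster solution (all
memberships 1, centroid at the grand mean), so CD(c=1) = 1 by
construction and smaller values indicate tighter clusters. The measure is
evaluated over a range of candidate cluster counts and interior local
minima of the resulting curve are reported as candidate parcellations;
when several minima exist they are all reported rather than adjudicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcm import ClusterSolution, consensus_runs, fcm_objective
from .types import CorrelationMap

__all__ = [
    "DispersionCurve",
    "cluster_dispersion",
    "sweep_c",
    "local_minima",
]


@dataclass
class DispersionCurve:
    """CD values over candidate cluster counts, with the solutions behind them."""

    c_values: list[int]
    cd_values: list[float]
    solutions: dict[int, ClusterSolution] = field(default_factory=dict)
    n_converged: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(set(self.c_values)) != list(self.c_values):
            raise ValueError("c values must be strictly increasing")
        if len(self.c_values) != len(self.cd_values):
            raise ValueError("c and CD lists must have equal length")
        arr = np.asarray(self.cd_values, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("CD values must be finite and non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "c": self.c_values,
                "cd": self.cd_values,
                "n_converged_runs": [
                    self.n_converged.get(c, np.nan) for c in self.c_values
                ],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def cluster_dispersion(
    features: CorrelationMap | np.ndarray, solution: ClusterSolution
) -> float:
    """Cluster dispersion of a solution on its feature matrix."""
    X = features.features if isinstance(features, CorrelationMap) else np.asarray(
        features, dtype=float
    )
    numerator = fcm_objective(
        X, solution.membership, solution.centroids, solution.fuzzifier
    )
    centered = X - X.mean(axis=0, keepdims=True)
    denominator = float(np.sum(centered**2))
    if denominator == 0:
        raise ValueError("all feature rows identical: total dispersion is zero")
    return numerator / denominator


def sweep_c(
    features: CorrelationMap | np.ndarray,
    c_min: int = 2,
    c_max: int = 20,
    runs_per_c: int = 20,
    rng_seed: int = 0,
    fuzzifier: float = 1.2,
    voxel_coords: np.ndarray | None = None,
    **fcm_kwargs,
) -> DispersionCurve:
    """Consensus-cluster every c in [c_min, c_max] and record CD per c.

    A failure at one c (e.g., no run converging) is reported as a warning
    and skipped; the sweep continues.
    """
    X = features.features if isinstance(features, CorrelationMap) else np.asarray(
        features, dtype=float
    )
    if c_max > X.shape[0]:
        raise ValueError(f"c_max={c_max} exceeds number of voxels {X.shape[0]}")
    if c_min < 1 or c_min > c_max:
        raise ValueError("need 1 <= c_min <= c_max")
    rng = np.random.default_rng(rng_seed)
    cs, cds = [], []
    solutions: dict[int, ClusterSolution] = {}
    n_converged: dict[int, int] = {}
    for c in range(c_min, c_max + 1):
        try:
            sol = consensus_runs(
                features,
                c,
                n_runs=runs_per_c,
                rng_seed=rng,
                fuzzifier=fuzzifier,
                voxel_coords=voxel_coords,
                **fcm_kwargs,
            )
        except Exception as exc:  # keep the sweep alive past a bad c
            warnings.warn(f"c={c} failed and is skipped: {exc}", stacklevel=2)
            continue
        cs.append(c)
        cds.append(cluster_dispersion(X, sol))
        solutions[c] = sol
        n_converged[c] = int(sol.seed_info.get("n_converged", runs_per_c))
    return DispersionCurve(
        c_values=cs, cd_values=cds, solutions=solutions, n_converged=n_converged
    )


def local_minima(curve: DispersionCurve) -> list[int]:
    """Interior strict local minima of the CD curve.

    c is reported iff CD(c) < CD at both neighbors on the curve; endpoints
    are excluded and ties are not reported.
    """
    if len(curve.c_values) < 3:
        raise ValueError("need at least 3 curve entries to find local minima")
    cd = np.asarray(curve.cd_values)
    minima = [
        curve.c_values[i]
        for i in range(1, len(cd) - 1)
        if cd[i] < cd[i - 1] and cd[i] < cd[i + 1]
    ]
    return minima
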