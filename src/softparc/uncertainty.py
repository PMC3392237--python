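"""Voxelwise classification uncertainty from soft memberships.

The classification uncertainty (CU) of voxel k is the geometric mean of
its membership weights:

    CU_k = ( prod_i u_ik )^(1/c)

By the AM-GM inequality CU_k <= 1/c, with equality exactly at uniform
membership, and CU_k = 0 when any weight is zero (a voxel fully excluded
from some cluster). High values mark voxels shared between networks;
low values mark voxels committed to a single network. Associating the CU
map with each cluster's membership map (spatial similarity) shows which
networks carry the shared-membership territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcm import ClusterSolution
from .similarity import spatial_similarity

__all__ = [
    "UncertaintyMap",
    "classification_uncertainty",
    "uncertainty_cluster_association",
]


@dataclass
class UncertaintyMap:
    """Per-voxel classification uncertainty in [0, 1/c]."""

    cu: np.ndarray  # (n_voxels,)
    c: int

    def __post_init__(self) -> None:
        self.cu = np.asarray(self.cu, dtype=float)
        if self.cu.ndim != 1:
            raise ValueError("cu must be a 1-D per-voxel array")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if np.any(self.cu < 0) or np.any(self.cu > 1.0 / self.c + 1e-12):
            raise ValueError("cu values must lie in [0, 1/c]")

    @property
    def n_voxels(self) -> int:
        return self.cu.shape[0]


def classification_uncertainty(membership: np.ndarray) -> UncertaintyMap:
    """Geometric mean of each voxel's membership weights.

    Computed as exp(mean(log u)) for strictly positive columns; any zero
    weight short-circuits the voxel to CU = 0 (the continuous limit).
    """
    U = np.asarray(membership, dtype=float)
    if U.ndim != 2:
        raise ValueError("membership must be a (c, n) matrix")
    if not np.allclose(U.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("membership columns must sum to 1")
    c = U.shape[0]
    cu = np.zeros(U.shape[1])
    positive = np.all(U > 0, axis=0)
    if np.any(positive):
        cu[positive] = np.exp(np.log(U[:, positive]).mean(axis=0))
    # clamp AM-GM violations from roundoff at uniform columns
    np.minimum(cu, 1.0 / c, out=cu)
    return UncertaintyMap(cu=cu, c=c)


def uncertainty_cluster_association(
    cu_map: UncertaintyMap,
    solution: ClusterSolution,
    centering: str = "centered",
) -> pd.Series:
    """Spatial similarity of the CU map with every cluster's membership map.

    Returns a Series indexed by cluster label. Centered mode is the
    default so that a cluster can be anti-associated with uncertain
    territory; a constant CU map has no spatial structure and scores 0
    against every cluster in centered mode.
    """
    if cu_map.n_voxels != solution.n_voxels:
        raise ValueError("uncertainty map and solution cover different voxel sets")
    labels = (
        list(solution.labels)
        if solution.labels is not None
        else [f"C{i + 1}" for i in range(solution.c)]
    )
    scores = [
        spatial_similarity(cu_map.cu, solution.membership[i], centering=centering)
        for i in range(solution.c)
    ]
    return pd.Series(scores, index=labels, name=f"cu_association_{centering}")
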