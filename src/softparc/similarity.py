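"""Spatial and temporal similarity between clusters, and cluster matching.

Two clusters are compared either by the overlap of their voxelwise
membership weight vectors (spatial similarity, SS) or by their centroids
in the clustering feature space (temporal similarity, TS). Both are
normalized inner products:

    SS(u1, u2) = <u1, u2> / (||u1|| ||u2||)
    TS(v1, v2) = <v1, v2> / (||v1|| ||v2||)

so self-similarity is 1 and both are invariant to positive rescaling.
Membership vectors are nonnegative, so raw SS is nonnegative; the
"centered" mode subtracts each vector's mean first, which lets SS express
anti-association (e.g., a network against the opposite system). Raw SS is
the mode used for matching and stability; centered SS for system
association. TS operates on centroid vectors in the clustering space; with
correlation-map features a centroid is a voxelwise correlation profile, so
TS between two centroids reads as the temporal coherence of the
corresponding networks (anticorrelated systems give TS near -1).

Cluster identities are carried across solutions by best-match assignment:
one-to-one (optimal assignment) when both solutions have the same number
of clusters, otherwise each cluster of the finer solution inherits the
label of its most similar reference cluster, with numeric suffixes when a
reference cluster is claimed more than once (e.g. FPC -> FPC1, FPC2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .fcm import ClusterSolution
from .types import SeedROI  # noqa: F401  (re-exported: ROI tables live with similarity)

__all__ = [
    "SimilarityMatrix",
    "MatchResult",
    "spatial_similarity",
    "temporal_similarity",
    "similarity_matrix",
    "match_clusters",
    "cross_solution_matrix",
    "run_stability_scores",
]


def _cosine(a: np.ndarray, b: np.ndarray, what: str) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError(f"zero-norm {what} vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def spatial_similarity(
    u1: np.ndarray, u2: np.ndarray, centering: str = "raw"
) -> float:
    """Normalized inner product of two membership weight vectors.

    In centered mode each vector's mean is removed first; a vector that is
    exactly constant then has zero norm and the similarity is defined as 0
    (no spatial structure to associate with).
    """
    u1 = np.asarray(u1, dtype=float).ravel()
    u2 = np.asarray(u2, dtype=float).ravel()
    if u1.shape != u2.shape:
        raise ValueError("membership vectors must have equal length")
    if centering not in ("raw", "centered"):
        raise ValueError(f"unknown centering {centering!r}")
    if centering == "centered":
        u1 = u1 - u1.mean()
        u2 = u2 - u2.mean()
        if np.linalg.norm(u1) == 0 or np.linalg.norm(u2) == 0:
            return 0.0
    return _cosine(u1, u2, "membership")


def temporal_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Normalized inner product of two centroid vectors."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError("centroid vectors must have equal length")
    return _cosine(v1, v2, "centroid")


@dataclass
class SimilarityMatrix:
    """All-pairs similarity between the clusters of two solutions."""

    values: np.ndarray  # (a, b)
    row_labels: list[str]
    col_labels: list[str]
    mode: str  # "spatial" | "temporal"
    centering: str  # "raw" | "centered"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape disagrees with labels")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("similarities must lie in [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.col_labels
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def _vectors(solution: ClusterSolution, mode: str) -> np.ndarray:
    if mode == "spatial":
        return solution.membership
    if mode == "temporal":
        return solution.centroids
    raise ValueError(f"unknown mode {mode!r}")


def _labels(solution: ClusterSolution) -> list[str]:
    if solution.labels is not None:
        return list(solution.labels)
    return [f"C{i + 1}" for i in range(solution.c)]


def similarity_matrix(
    vecs_a: np.ndarray,
    vecs_b: np.ndarray,
    mode: str = "spatial",
    centering: str = "raw",
) -> np.ndarray:
    """Pairwise similarity between the rows of two vector stacks."""
    if mode == "temporal" and centering != "raw":
        raise ValueError("temporal similarity has no centering option")
    sim = np.empty((vecs_a.shape[0], vecs_b.shape[0]))
    for i, a in enumerate(vecs_a):
        for j, b in enumerate(vecs_b):
            sim[i, j] = (
                spatial_similarity(a, b, centering)
                if mode == "spatial"
                else temporal_similarity(a, b)
            )
    return sim


@dataclass
class MatchResult:
    """Assignment of a solution's clusters onto a reference solution."""

    assignment: list[int]  # per solution cluster: matched reference index
    scores: list[float]  # similarity of each matched pair
    labels: list[str]  # derived label per solution cluster
    one_to_one: bool
    mode: str
    centering: str

    def to_json_dict(self) -> dict:
        return {
            "assignment": self.assignment,
            "scores": self.scores,
            "labels": self.labels,
            "one_to_one": self.one_to_one,
            "mode": self.mode,
            "centering": self.centering,
        }


def match_clusters(
    solution: ClusterSolution,
    reference: ClusterSolution,
    mode: str = "spatial",
    centering: str = "raw",
) -> MatchResult:
    """Label `solution`'s clusters by their best matches in `reference`.

    Equal cluster counts: optimal one-to-one assignment maximizing total
    similarity. Unequal counts: each cluster maps to its argmax reference
    cluster (many-to-one allowed); clusters sharing a reference get the
    reference label with suffixes 1, 2, ... in order of decreasing score.
    """
    if solution.n_voxels != reference.n_voxels and mode == "spatial":
        raise ValueError("solutions are defined over different voxel sets")
    sim = similarity_matrix(
        _vectors(solution, mode), _vectors(reference, mode), mode, centering
    )
    ref_labels = _labels(reference)
    if solution.c == reference.c:
        rows, cols = linear_sum_assignment(-sim)
        assignment = np.empty(solution.c, dtype=int)
        assignment[rows] = cols
        scores = [float(sim[i, assignment[i]]) for i in range(solution.c)]
        labels = [ref_labels[j] for j in assignment]
        return MatchResult(
            assignment=assignment.tolist(),
            scores=scores,
            labels=labels,
            one_to_one=True,
            mode=mode,
            centering=centering,
        )

    assignment = np.argmax(sim, axis=1)
    scores = [float(sim[i, assignment[i]]) for i in range(solution.c)]
    labels = [""] * solution.c
    for ref_idx in set(assignment.tolist()):
        members = [i for i in range(solution.c) if assignment[i] == ref_idx]
        if len(members) == 1:
            labels[members[0]] = ref_labels[ref_idx]
        else:
            members.sort(key=lambda i: -scores[i])
            for rank, i in enumerate(members, start=1):
                labels[i] = f"{ref_labels[ref_idx]}{rank}"
    return MatchResult(
        assignment=assignment.tolist(),
        scores=scores,
        labels=labels,
        one_to_one=False,
        mode=mode,
        centering=centering,
    )


def cross_solution_matrix(
    sol_a: ClusterSolution,
    sol_b: ClusterSolution,
    mode: str = "spatial",
    centering: str = "raw",
) -> SimilarityMatrix:
    """All-pairs similarity matrix between two solutions (a x b)."""
    if mode == "spatial" and sol_a.n_voxels != sol_b.n_voxels:
        raise ValueError("solutions are defined over different voxel sets")
    values = similarity_matrix(
        _vectors(sol_a, mode), _vectors(sol_b, mode), mode, centering
    )
    return SimilarityMatrix(
        values=values,
        row_labels=_labels(sol_a),
        col_labels=_labels(sol_b),
        mode=mode,
        centering=centering,
    )


def run_stability_scores(
    runs: list[ClusterSolution],
    reference: ClusterSolution,
    mode: str = "spatial",
) -> np.ndarray:
    """Matched similarity of every run's clusters against a reference.

    Returns an (n_runs, c) array: row r holds the similarity of each of
    the reference's clusters with its one-to-one match in run r. Used for
    the many-runs stability analysis (fraction of runs whose every
    network reappears with high spatial similarity).
    """
    out = np.empty((len(runs), reference.c))
    for r, sol in enumerate(runs):
        res = match_clusters(sol, reference, mode=mode)
        for i, (ref_idx, score) in enumerate(zip(res.assignment, res.scores)):
            out[r, ref_idx] = score
    return out
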