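"""Fuzzy c-means clustering with Xie-Beni convergence monitoring.

Each voxel k is described by a feature vector X_k (its row of the
correlation map) and receives a graded membership u_ik in every cluster i,
controlled by the fuzzifier M > 1:

    u_ik = [ sum_j ( d(X_k, V_i) / d(X_k, V_j) )^(2/(M-1)) ]^(-1)
    V_i  = sum_k u_ik^M X_k / sum_k u_ik^M

with Euclidean distance d. Memberships and centroids are updated
alternately. The default fuzzifier is M = 1.2, which keeps memberships
fairly crisp while still allowing shared membership at network
boundaries. Convergence is declared when the Xie-Beni index

    XB = sum_i sum_k u_ik^M ||X_k - V_i||^2 / ( n * min_{i != j} ||V_i - V_j||^2 )

changes by less than `tol` over `patience` consecutive iterations.

Because the converged solution depends on initialization, results are
typically reported as the average of many randomly initialized runs, with
clusters aligned across runs by optimal one-to-one assignment on spatial
similarity before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist

from .types import CorrelationMap, SeedROI

__all__ = [
    "ClusterSolution",
    "DEFAULT_SEED_ROIS",
    "init_random",
    "init_seeded",
    "update_memberships",
    "update_centroids",
    "fcm_objective",
    "xie_beni",
    "run_fcm",
    "consensus_runs",
]

#: Seed regions for seven canonical resting-state networks (Talairach mm).
DEFAULT_SEED_ROIS: tuple[SeedROI, ...] = (
    SeedROI("DMN", (0.0, -65.0, 31.0)),  # precuneus
    SeedROI("FPC", (43.0, 22.0, 34.0)),  # right dorsolateral prefrontal
    SeedROI("LAN", (-54.0, -23.0, -3.0)),  # left superior temporal gyrus
    SeedROI("VAN", (24.0, 38.0, 25.0)),  # right middle frontal gyrus
    SeedROI("SMN", (-45.0, -30.0, 22.0)),  # left parietal operculum
    SeedROI("VIS", (-13.0, -93.0, 18.0)),  # superior occipital gyrus
    SeedROI("DAN", (23.0, -8.0, 55.0)),  # right frontal eye field
)


@dataclass
class ClusterSolution:
    """A converged soft partition: memberships, centroids, and its history."""

    membership: np.ndarray  # (c, n), columns sum to 1
    centroids: np.ndarray  # (c, d)
    fuzzifier: float
    xie_beni_trace: list[float]
    objective_trace: list[float]
    converged: bool
    n_iter: int
    seed_info: dict[str, Any] = field(default_factory=dict)
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.membership.shape[0] != self.centroids.shape[0]:
            raise ValueError("membership and centroids disagree on cluster count")
        colsums = self.membership.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("membership columns must sum to 1")
        if self.converged and not self.xie_beni_trace:
            raise ValueError("converged solution must carry a convergence trace")
        if self.labels is not None and len(self.labels) != self.c:
            raise ValueError("labels length must equal cluster count")

    @property
    def c(self) -> int:
        return self.membership.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.membership.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Crisp assignment: argmax membership per voxel."""
        return np.argmax(self.membership, axis=0)


def _as_features(features: CorrelationMap | np.ndarray) -> np.ndarray:
    if isinstance(features, CorrelationMap):
        return features.features
    return np.asarray(features, dtype=float)


def _require_geometry(
    features: CorrelationMap | np.ndarray,
    voxel_coords: np.ndarray | None,
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    X = _as_features(features)
    if isinstance(features, CorrelationMap):
        voxel_coords = features.voxel_coords if voxel_coords is None else voxel_coords
        affine = features.affine if affine is None else affine
    if voxel_coords is None:
        raise ValueError("voxel coordinates are required for spatial initialization")
    return X, np.asarray(voxel_coords), affine


def cube_average(
    features: CorrelationMap | np.ndarray,
    center: int,
    cube_edge: int = 3,
    voxel_coords: np.ndarray | None = None,
) -> np.ndarray:
    """Mean feature row over in-mask voxels in a cube around voxel `center`.

    The cube has edge `cube_edge` grid units; out-of-mask cells are simply
    absent, so a cube holding a single in-mask voxel returns that voxel's
    feature row.
    """
    X, coords, _ = _require_geometry(features, voxel_coords)
    half = (cube_edge - 1) // 2
    cx, cy, cz = coords[center]
    sel = np.all(np.abs(coords - np.array([cx, cy, cz])) <= half, axis=1)
    return X[sel].mean(axis=0)


def init_random(
    features: CorrelationMap | np.ndarray,
    c: int,
    rng: np.random.Generator | int,
    cube_edge: int = 3,
    voxel_coords: np.ndarray | None = None,
    pool_size: int | None = None,
    refine: str = "pool",
    max_retries: int = 100,
) -> np.ndarray:
    """Random cube initialization: centroids are random-cube feature averages.

    Candidate centroids are averages of the feature rows inside a cube of
    edge `cube_edge` centered on a uniformly drawn in-mask voxel. With
    ``refine="pool"`` (default) a pool of such candidates is drawn, the
    pool is grouped into c clusters, and the medoid cube of each group
    becomes a starting centroid — a subsample-refinement that removes the
    duplicate and near-duplicate draws which otherwise trap the crisp
    (M close to 1) membership updates in split/merge local optima, while
    every starting centroid remains an actual random-cube average.
    ``refine="none"`` draws one cube per centroid with redraws on exact
    duplicates only.
    """
    X, coords, _ = _require_geometry(features, voxel_coords)
    n = X.shape[0]
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if n < c:
        raise ValueError(f"mask has {n} voxels; cannot draw {c} centroids")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    half = (cube_edge - 1) // 2
    coord_index = {tuple(xyz): i for i, xyz in enumerate(map(tuple, coords))}

    def cube_at(center: int) -> np.ndarray:
        cx, cy, cz = coords[center]
        members = [
            coord_index[(cx + dx, cy + dy, cz + dz)]
            for dx in range(-half, half + 1)
            for dy in range(-half, half + 1)
            for dz in range(-half, half + 1)
            if (cx + dx, cy + dy, cz + dz) in coord_index
        ]
        return X[members].mean(axis=0)

    if refine == "none":
        centroids: list[np.ndarray] = []
        attempts = 0
        while len(centroids) < c:
            if attempts > max_retries * c:
                raise RuntimeError(
                    f"could not draw {c} distinct cube centroids "
                    f"after {attempts} attempts"
                )
            attempts += 1
            candidate = cube_at(int(rng.integers(n)))
            if any(np.allclose(candidate, v, atol=1e-12) for v in centroids):
                continue
            centroids.append(candidate)
        return np.array(centroids)
    if refine != "pool":
        raise ValueError(f"unknown refine mode {refine!r}")

    from sklearn.cluster import KMeans

    pool_size = pool_size or min(n, max(100, 10 * c))
    pool = np.array([cube_at(int(rng.integers(n))) for _ in range(pool_size)])
    km = KMeans(
        n_clusters=c, n_init=2, random_state=int(rng.integers(2**31))
    ).fit(pool)
    centroids = []
    for k in range(c):
        members = np.flatnonzero(km.labels_ == k)
        if members.size == 0:  # degenerate pool; fall back to a random cube
            members = np.array([int(rng.integers(pool_size))])
        d2 = ((pool[members] - km.cluster_centers_[k]) ** 2).sum(axis=1)
        centroids.append(pool[members[np.argmin(d2)]])
    V = np.array(centroids)
    if np.unique(V, axis=0).shape[0] < c:
        raise RuntimeError(f"could not draw {c} distinct cube centroids")
    return V


def init_seeded(
    features: CorrelationMap | np.ndarray,
    rois: Sequence[SeedROI] = DEFAULT_SEED_ROIS,
    voxel_coords: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Seeded initialization: average features in a sphere around each ROI.

    Returns the centroid matrix and a per-ROI record (name, coordinate,
    radius, voxel count) suitable for `seed_info`.
    """
    X, coords, affine = _require_geometry(features, voxel_coords, affine)
    if affine is None:
        raise ValueError("an affine is required to resolve ROI mm coordinates")
    homog = np.column_stack([coords.astype(float), np.ones(len(coords))])
    world = (homog @ np.asarray(affine, float).T)[:, :3]

    centroids = []
    records = []
    for roi in rois:
        dist = np.linalg.norm(world - np.asarray(roi.coord, float), axis=1)
        members = np.flatnonzero(dist <= roi.radius)
        if members.size == 0:
            raise ValueError(
                f"ROI {roi.name!r} at {tuple(roi.coord)} mm has no in-mask voxel "
                f"within {roi.radius} mm"
            )
        centroids.append(X[members].mean(axis=0))
        records.append(
            {
                "name": roi.name,
                "coord": list(roi.coord),
                "radius": roi.radius,
                "n_voxels": int(members.size),
            }
        )
    return np.array(centroids), records


def update_memberships(
    features: CorrelationMap | np.ndarray, centroids: np.ndarray, fuzzifier: float
) -> np.ndarray:
    """Membership update from current centroids (c, n result).

    A voxel coincident with a centroid gets full membership in the first
    such cluster (the standard resolution of the zero-distance
    singularity).
    """
    X = _as_features(features)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    V = np.asarray(centroids, dtype=float)
    D = cdist(V, X)  # (c, n)
    U = np.zeros_like(D)
    zero_cols = np.flatnonzero(D.min(axis=0) == 0)
    ok = np.setdiff1d(np.arange(X.shape[0]), zero_cols, assume_unique=False)
    if ok.size:
        # normalize by the column minimum before exponentiating: keeps the
        # d^(-2/(M-1)) powers in range even for M close to 1
        Dn = D[:, ok] / D[:, ok].min(axis=0, keepdims=True)
        W = Dn ** (-2.0 / (fuzzifier - 1.0))
        U[:, ok] = W / W.sum(axis=0, keepdims=True)
    for k in zero_cols:
        U[np.argmin(D[:, k]), k] = 1.0
    return U


def update_centroids(
    features: CorrelationMap | np.ndarray, membership: np.ndarray, fuzzifier: float
) -> np.ndarray:
    """Centroid update: u^M-weighted mean of the feature rows."""
    X = _as_features(features)
    W = np.asarray(membership, dtype=float) ** fuzzifier
    weights = W.sum(axis=1)
    if np.any(weights == 0):
        empty = np.flatnonzero(weights == 0).tolist()
        raise ValueError(f"cluster(s) {empty} have all-zero membership weight")
    return (W @ X) / weights[:, None]


def fcm_objective(
    features: CorrelationMap | np.ndarray,
    membership: np.ndarray,
    centroids: np.ndarray,
    fuzzifier: float,
) -> float:
    """The FCM objective J_M = sum_ik u_ik^M ||X_k - V_i||^2."""
    X = _as_features(features)
    D2 = cdist(np.asarray(centroids, float), X, "sqeuclidean")
    return float(np.sum(np.asarray(membership, float) ** fuzzifier * D2))


def xie_beni(
    features: CorrelationMap | np.ndarray,
    membership: np.ndarray,
    centroids: np.ndarray,
    fuzzifier: float,
) -> float:
    """Xie-Beni index: compactness over n times minimal centroid separation."""
    V = np.asarray(centroids, dtype=float)
    if V.shape[0] < 2:
        raise ValueError("Xie-Beni index requires at least 2 clusters")
    sep = pdist(V, "sqeuclidean").min()
    if sep == 0:
        raise ValueError("coincident centroids: Xie-Beni separation is zero")
    X = _as_features(features)
    return fcm_objective(X, membership, V, fuzzifier) / (X.shape[0] * sep)


def run_fcm(
    features: CorrelationMap | np.ndarray,
    init_centroids: np.ndarray,
    fuzzifier: float = 1.2,
    tol: float = 1e-4,
    patience: int = 5,
    max_iter: int = 1000,
    seed_info: dict[str, Any] | None = None,
) -> ClusterSolution:
    """Alternate membership/centroid updates until the Xie-Beni index settles.

    Stops once the index changes by less than `tol` for `patience`
    consecutive iterations; hits `max_iter` otherwise with
    ``converged=False``.
    """
    X = _as_features(features)
    V = np.asarray(init_centroids, dtype=float).copy()
    c = V.shape[0]
    xb_trace: list[float] = []
    obj_trace: list[float] = []
    stable = 0
    converged = False
    n_iter = 0
    U = update_memberships(X, V, fuzzifier)

    if c == 1:
        V = update_centroids(X, U, fuzzifier)
        return ClusterSolution(
            membership=U,
            centroids=V,
            fuzzifier=fuzzifier,
            xie_beni_trace=[0.0],
            objective_trace=[fcm_objective(X, U, V, fuzzifier)],
            converged=True,
            n_iter=1,
            seed_info=seed_info or {},
        )

    for n_iter in range(1, max_iter + 1):
        U = update_memberships(X, V, fuzzifier)
        V = update_centroids(X, U, fuzzifier)
        xb = xie_beni(X, U, V, fuzzifier)
        obj_trace.append(fcm_objective(X, U, V, fuzzifier))
        if xb_trace and abs(xb - xb_trace[-1]) < tol:
            stable += 1
        else:
            stable = 0
        xb_trace.append(xb)
        if stable >= patience:
            converged = True
            break

    return ClusterSolution(
        membership=U,
        centroids=V,
        fuzzifier=fuzzifier,
        xie_beni_trace=xb_trace,
        objective_trace=obj_trace,
        converged=converged,
        n_iter=n_iter,
        seed_info=seed_info or {},
    )


def match_permutation(
    membership: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Permutation aligning `membership` rows to `reference` rows.

    Maximizes total cosine similarity between matched membership vectors
    via optimal one-to-one assignment. Returns `perm` such that
    ``membership[perm[i]]`` corresponds to ``reference[i]``.
    """
    a = np.asarray(reference, float)
    b = np.asarray(membership, float)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    sim = (a / np.where(na == 0, 1, na)) @ (b / np.where(nb == 0, 1, nb)).T
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(a.shape[0], dtype=int)
    perm[rows] = cols
    return perm


def consensus_runs(
    features: CorrelationMap | np.ndarray,
    c: int,
    n_runs: int = 20,
    rng_seed: int | np.random.Generator = 0,
    fuzzifier: float = 1.2,
    tol: float = 1e-4,
    patience: int = 5,
    max_iter: int = 1000,
    cube_edge: int = 3,
    voxel_coords: np.ndarray | None = None,
    return_runs: bool = False,
) -> ClusterSolution | tuple[ClusterSolution, list[ClusterSolution]]:
    """Average of `n_runs` randomly initialized FCM runs.

    Each run is aligned to the first converged run by optimal one-to-one
    assignment on spatial similarity between membership vectors; the
    aligned membership matrices are averaged entrywise (column sums stay
    1) and the centroids are recomputed from the averaged memberships.
    Runs that fail to converge are excluded and counted.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X, coords, _ = _require_geometry(features, voxel_coords)
    rng = (
        np.random.default_rng(rng_seed)
        if isinstance(rng_seed, (int, np.integer))
        else rng_seed
    )

    runs: list[ClusterSolution] = []
    n_failed = 0
    for run_idx in range(n_runs):
        init = init_random(X, c, rng, cube_edge=cube_edge, voxel_coords=coords)
        sol = run_fcm(
            X,
            init,
            fuzzifier=fuzzifier,
            tol=tol,
            patience=patience,
            max_iter=max_iter,
            seed_info={"method": "random-cube", "run": run_idx},
        )
        if sol.converged:
            runs.append(sol)
        else:
            n_failed += 1
    if not runs:
        raise RuntimeError(f"all {n_runs} runs failed to converge")
    if n_failed:
        warnings.warn(
            f"{n_failed} of {n_runs} runs did not converge and were excluded",
            stacklevel=2,
        )

    best = min(range(len(runs)), key=lambda i: runs[i].objective_trace[-1])
    reference = runs[best].membership
    aligned = []
    for sol in runs:
        perm = match_permutation(sol.membership, reference)
        aligned.append(sol.membership[perm])
    U = np.mean(aligned, axis=0)
    V = update_centroids(X, U, fuzzifier)
    consensus = ClusterSolution(
        membership=U,
        centroids=V,
        fuzzifier=fuzzifier,
        xie_beni_trace=[xie_beni(X, U, V, fuzzifier)] if c >= 2 else [0.0],
        objective_trace=[fcm_objective(X, U, V, fuzzifier)],
        converged=True,
        n_iter=max(s.n_iter for s in runs),
        seed_info={
            "method": "consensus-random-cube",
            "n_runs": n_runs,
            "n_converged": len(runs),
            "n_failed": n_failed,
        },
    )
    if return_runs:
        return consensus, runs
    return consensus
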