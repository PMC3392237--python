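"""Synthetic BOLD-like time series with planted hierarchical network structure.

The generator emulates resting-state data in which voxelwise fluctuations
organize into two large anticorrelated systems (task-negative vs
task-positive) that subdivide into networks, plus a configurable fraction
of boundary voxels whose signal loads on two networks at once.

The model is a linear factor model with a closed-form covariance, so the
expected correlation structure of any generated dataset is known exactly
and can serve as a test oracle:

    x_v(t) = sum_i w_vi * s_i(t) + noise_sd * eps_v(t)
    s_i(t) = loading_within * eta_i(t) + loading_system * sgn_i * g(t)

where g is a shared system signal, sgn_i is +1 for task-positive networks
and -1 for task-negative ones, eta_i is a network-specific signal, eps_v is
voxelwise white noise (all iid standard normal across frames), and the
weights w_vi of each voxel sum to one. After generation each voxel is
offset so its temporal mean is exactly 1000, mirroring the whole-brain
mode-1000 intensity convention of preprocessed BOLD data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import VoxelTimeSeries

__all__ = [
    "TASK_NEGATIVE",
    "TASK_POSITIVE",
    "HierarchySpec",
    "GroundTruth",
    "simulate_bold",
    "inject_spikes",
    "analytic_correlation",
    "save_synthetic_dataset",
]

TASK_NEGATIVE = "task-negative"
TASK_POSITIVE = "task-positive"


def _default_systems(n_networks: int) -> tuple[str, ...]:
    # First half task-negative, remainder task-positive; at K=7 this gives
    # the 3/4 split seen in real parcellations (DMN/FPC/LAN vs the rest).
    n_neg = max(1, n_networks // 2)
    return (TASK_NEGATIVE,) * n_neg + (TASK_POSITIVE,) * (n_networks - n_neg)


@dataclass
class HierarchySpec:
    """Parameters of the planted system -> network hierarchy.

    Parameters
    ----------
    n_networks : int
        Number of planted networks (>= 2).
    system_of_network : sequence of str, optional
        ``"task-negative"`` / ``"task-positive"`` per network. Default: first
        ``n_networks // 2`` networks task-negative, the rest task-positive.
    voxels_per_network : int or sequence of int
        Voxel count per network.
    fuzzy_fraction : float
        Fraction of voxels with split loadings on two networks, in [0, 1).
    fuzzy_primary_range : (float, float)
        The primary-network weight of a fuzzy voxel is drawn uniformly from
        this range; the partner network receives the complement.
    fuzzy_partner : {"balanced", "random", "adjacent", "within-system",
        "between-system"}
        How the partner network of a fuzzy voxel is chosen. The default
        "balanced" cycles each network's fuzzy voxels round-robin over all
        other networks, giving every network an identical shared-membership
        load (statistically exchangeable networks); "random" draws an
        independent partner per voxel.
    loading_within : float
        Loading on the network-specific signal (unitless).
    loading_system : float
        Loading on the shared system signal; its sign flips between systems,
        which makes the two system-level centroids anticorrelated.
    noise_sd : float
        Standard deviation of voxelwise white noise.
    n_frames : int
        Frames to simulate (>= 10).
    frame_interval : float
        Repetition time in seconds.
    seed : int
        Seed for the generator; fixed seed gives bit-identical output.
    grid_cross_section : (int, int)
        In-plane (x, y) size of the voxel grid; networks occupy contiguous
        blocks of scan-order positions stacked along z.
    voxel_size_mm : float
        Isotropic voxel size used to build the affine.
    """

    n_networks: int = 7
    system_of_network: Sequence[str] | None = None
    voxels_per_network: int | Sequence[int] = 100
    fuzzy_fraction: float = 0.1
    fuzzy_primary_range: tuple[float, float] = (0.7, 0.9)
    fuzzy_partner: str = "balanced"
    loading_within: float = 1.0
    loading_system: float = 0.5
    noise_sd: float = 1.15
    n_frames: int = 300
    frame_interval: float = 2.16
    seed: int = 0
    grid_cross_section: tuple[int, int] = (5, 5)
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_networks < 2:
            raise ValueError("need at least 2 networks")
        if self.system_of_network is None:
            self.system_of_network = _default_systems(self.n_networks)
        self.system_of_network = tuple(self.system_of_network)
        if len(self.system_of_network) != self.n_networks:
            raise ValueError("system_of_network length must equal n_networks")
        bad = set(self.system_of_network) - {TASK_NEGATIVE, TASK_POSITIVE}
        if bad:
            raise ValueError(f"unknown system labels: {sorted(bad)}")
        if TASK_NEGATIVE not in self.system_of_network or (
            TASK_POSITIVE not in self.system_of_network
        ):
            raise ValueError("each system needs at least one network")
        counts = self.network_sizes()
        if any(c <= 0 for c in counts):
            raise ValueError("voxel counts must be positive")
        if not 0 <= self.fuzzy_fraction < 1:
            raise ValueError("fuzzy_fraction must lie in [0, 1)")
        lo, hi = self.fuzzy_primary_range
        if not 0.5 <= lo <= hi < 1:
            raise ValueError("fuzzy_primary_range must satisfy 0.5 <= lo <= hi < 1")
        if self.fuzzy_partner not in (
            "random",
            "balanced",
            "adjacent",
            "within-system",
            "between-system",
        ):
            raise ValueError(f"unknown fuzzy_partner {self.fuzzy_partner!r}")
        for name in ("loading_within", "loading_system", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def network_sizes(self) -> list[int]:
        if np.isscalar(self.voxels_per_network):
            return [int(self.voxels_per_network)] * self.n_networks
        sizes = [int(v) for v in self.voxels_per_network]
        if len(sizes) != self.n_networks:
            raise ValueError("voxels_per_network length must equal n_networks")
        return sizes

    @property
    def n_voxels(self) -> int:
        return sum(self.network_sizes())

    @property
    def system_signs(self) -> np.ndarray:
        """+1 for task-positive networks, -1 for task-negative."""
        return np.array(
            [1.0 if s == TASK_POSITIVE else -1.0 for s in self.system_of_network]
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["system_of_network"] = list(d["system_of_network"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "HierarchySpec":
        d = json.loads(Path(path).read_text())
        d["fuzzy_primary_range"] = tuple(d["fuzzy_primary_range"])
        d["grid_cross_section"] = tuple(d["grid_cross_section"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted memberships, system labels, and boundary flags."""

    true_membership: np.ndarray  # (n_networks, n_voxels), columns sum to 1
    true_system: np.ndarray  # (n_voxels,) str labels
    boundary_mask: np.ndarray  # (n_voxels,) bool
    network_of_voxel: np.ndarray = field(default=None)  # argmax network index

    def __post_init__(self) -> None:
        self.true_membership = np.asarray(self.true_membership, dtype=float)
        colsums = self.true_membership.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("true membership columns must sum to 1")
        expected_boundary = (self.true_membership > 0).sum(axis=0) >= 2
        if not np.array_equal(np.asarray(self.boundary_mask, bool), expected_boundary):
            raise ValueError("boundary_mask inconsistent with memberships")
        if self.network_of_voxel is None:
            self.network_of_voxel = np.argmax(self.true_membership, axis=0)

    @property
    def n_voxels(self) -> int:
        return self.true_membership.shape[1]

    @property
    def n_networks(self) -> int:
        return self.true_membership.shape[0]


def _grid_coords(n_voxels: int, cross_section: tuple[int, int]) -> np.ndarray:
    a, b = cross_section
    idx = np.arange(n_voxels)
    return np.column_stack([idx % a, (idx // a) % b, idx // (a * b)])


def _partner_networks(
    i: int, k_fuzzy: int, spec: HierarchySpec, rng: np.random.Generator
) -> np.ndarray:
    """Partner network for each fuzzy voxel of network i."""
    K = spec.n_networks
    systems = spec.system_of_network
    if spec.fuzzy_partner == "random":
        others = np.array([j for j in range(K) if j != i])
        return rng.choice(others, size=k_fuzzy)
    if spec.fuzzy_partner == "balanced":
        others = [j for j in range(K) if j != i]
        return np.array([others[t % len(others)] for t in range(k_fuzzy)])
    if spec.fuzzy_partner == "adjacent":
        return np.full(k_fuzzy, (i + 1) % K)
    same = spec.fuzzy_partner == "within-system"
    for step in range(1, K):
        j = (i + step) % K
        if (systems[j] == systems[i]) == same:
            return np.full(k_fuzzy, j)
    return np.full(k_fuzzy, (i + 1) % K)  # single-network system: adjacency


def _planted_weights(
    spec: HierarchySpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (K, n) weight matrix and the fuzzy-voxel mask."""
    sizes = spec.network_sizes()
    n = sum(sizes)
    K = spec.n_networks
    W = np.zeros((K, n))
    starts = np.cumsum([0] + sizes)

    # Per-network fuzzy quotas via largest remainder, so the total count is
    # round(fuzzy_fraction * n) exactly.
    total_fuzzy = int(round(spec.fuzzy_fraction * n))
    quota = np.array([spec.fuzzy_fraction * m for m in sizes])
    base = np.floor(quota).astype(int)
    remainder = total_fuzzy - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for j in order[:remainder]:
        base[j] += 1

    fuzzy = np.zeros(n, dtype=bool)
    for i, (m, k_fuzzy) in enumerate(zip(sizes, base)):
        s = starts[i]
        W[i, s : s + m] = 1.0
        if k_fuzzy == 0:
            continue
        # the trailing voxels of each block sit at the network boundary
        vox = np.arange(s + m - k_fuzzy, s + m)
        partners = _partner_networks(i, k_fuzzy, spec, rng)
        lo, hi = spec.fuzzy_primary_range
        p = rng.uniform(lo, hi, size=k_fuzzy)
        W[i, vox] = p
        W[partners, vox] = 1.0 - p
        fuzzy[vox] = True
    return W, fuzzy


def simulate_bold(spec: HierarchySpec) -> tuple[VoxelTimeSeries, GroundTruth]:
    """Simulate mode-1000 BOLD-like series with planted hierarchy.

    Returns the time series (voxels in scan order, networks occupying
    contiguous blocks on the grid) and the ground truth against which
    clustering recovery can be scored. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    W, fuzzy = _planted_weights(spec, rng)
    K, n = W.shape
    T = spec.n_frames

    g = rng.standard_normal(T)
    eta = rng.standard_normal((K, T))
    eps = rng.standard_normal((n, T))

    signs = spec.system_signs
    S = spec.loading_within * eta + spec.loading_system * signs[:, None] * g[None, :]
    X = W.T @ S + spec.noise_sd * eps
    X += 1000.0 - X.mean(axis=1, keepdims=True)

    coords = _grid_coords(n, spec.grid_cross_section)
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    ts = VoxelTimeSeries(
        values=X,
        voxel_coords=coords,
        affine=affine,
        frame_interval=spec.frame_interval,
    )

    primary = np.argmax(W, axis=0)
    systems = np.array([spec.system_of_network[i] for i in primary])
    gt = GroundTruth(
        true_membership=W,
        true_system=systems,
        boundary_mask=fuzzy,
        network_of_voxel=primary,
    )
    return ts, gt


def analytic_correlation(spec: HierarchySpec, gt: GroundTruth) -> np.ndarray:
    """Exact correlation matrix implied by the factor model.

    Cov(x_u, x_v) = lw^2 * <w_u, w_v> + ls^2 * (w_u.sgn)(w_v.sgn)
                    + noise_sd^2 * delta_uv
    """
    W = gt.true_membership
    lw2 = spec.loading_within**2
    ls2 = spec.loading_system**2
    sys_load = spec.system_signs @ W  # (n,)
    cov = lw2 * (W.T @ W) + ls2 * np.outer(sys_load, sys_load)
    cov[np.diag_indices_from(cov)] += spec.noise_sd**2
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


def inject_spikes(
    ts: VoxelTimeSeries, frames: Sequence[int], amplitude: float
) -> VoxelTimeSeries:
    """Add a uniform spike of `amplitude` signal units at the given frames.

    Used to plant motion-like artifacts that DVARS censoring should catch.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= ts.n_frames):
        raise IndexError(
            f"frame indices out of range [0, {ts.n_frames}): {frames.tolist()}"
        )
    values = ts.values.copy()
    values[:, frames] += amplitude
    return ts.with_values(values)


def save_synthetic_dataset(
    out_dir: str | Path,
    ts: VoxelTimeSeries,
    gt: GroundTruth,
    spec: HierarchySpec | None = None,
) -> dict[str, Path]:
    """Write a synthetic dataset as NIfTI volume + mask + ground-truth CSV."""
    import pandas as pd

    from .io import save_timeseries

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out_dir / "bold.nii.gz",
        "mask": out_dir / "mask.nii.gz",
        "ground_truth": out_dir / "ground_truth.csv",
    }
    save_timeseries(paths["volume"], paths["mask"], ts)
    df = pd.DataFrame(
        {
            "voxel": np.arange(gt.n_voxels),
            "x": ts.voxel_coords[:, 0],
            "y": ts.voxel_coords[:, 1],
            "z": ts.voxel_coords[:, 2],
            "system": gt.true_system,
            "boundary": gt.boundary_mask.astype(int),
        }
    )
    for i in range(gt.n_networks):
        df[f"w_net{i}"] = gt.true_membership[i]
    df.to_csv(paths["ground_truth"], index=False)
    if spec is not None:
        paths["spec"] = out_dir / "spec.json"
        spec.to_json(paths["spec"])
    return paths
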