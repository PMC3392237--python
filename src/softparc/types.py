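"""Core data containers shared across the pipeline.

All voxelwise arrays follow a single ordering convention: voxels are
indexed in mask scan order with the x grid coordinate varying fastest.
Every container that carries voxel geometry records integer (0-based)
grid coordinates plus a 4x4 affine mapping voxel indices to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelTimeSeries",
    "FrameCensorMask",
    "CorrelationMap",
    "SeedROI",
]


@dataclass
class VoxelTimeSeries:
    """Masked voxel-by-frame BOLD matrix with grid geometry.

    Parameters
    ----------
    values : ndarray, shape (n_voxels, n_frames)
        BOLD signal in arbitrary units (mode-1000 normalized by convention).
    voxel_coords : ndarray, shape (n_voxels, 3)
        Integer 0-based grid coordinates, one row per voxel, in scan order.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (mm) affine.
    frame_interval : float
        Repetition time in seconds.
    run_boundaries : list of int
        Start frame of each acquisition run; always begins with 0.
    """

    values: np.ndarray
    voxel_coords: np.ndarray
    affine: np.ndarray
    frame_interval: float
    run_boundaries: Sequence[int] = field(default_factory=lambda: [0])

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_voxels, n_frames) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.voxel_coords.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_coords must have shape (n_voxels, 3)")
        if len(np.unique(self.voxel_coords, axis=0)) != self.n_voxels:
            raise ValueError("voxel coordinates must be unique")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        rb = list(self.run_boundaries)
        if not rb or rb[0] != 0:
            raise ValueError("run_boundaries must start at 0")
        if any(b >= self.n_frames for b in rb) or sorted(set(rb)) != rb:
            raise ValueError("run_boundaries must be strictly increasing and < n_frames")
        self.run_boundaries = rb

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def runs(self) -> list[slice]:
        """Frame slices, one per acquisition run."""
        bounds = list(self.run_boundaries) + [self.n_frames]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]

    def with_values(self, values: np.ndarray) -> "VoxelTimeSeries":
        """Copy of this series with `values` replaced (geometry shared)."""
        return replace(self, values=np.asarray(values, dtype=float))

    def world_coords(self) -> np.ndarray:
        """Voxel centers in world mm, shape (n_voxels, 3)."""
        homog = np.column_stack(
            [self.voxel_coords.astype(float), np.ones(self.n_voxels)]
        )
        return (homog @ self.affine.T)[:, :3]


@dataclass
class FrameCensorMask:
    """Per-frame keep/censor decision with the DVARS values behind it."""

    keep: np.ndarray  # bool, (n_frames,)
    dvars: np.ndarray  # percent of mode-1000 signal, (n_frames,)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.keep.shape != self.dvars.shape or self.keep.ndim != 1:
            raise ValueError("keep and dvars must be 1-D arrays of equal length")
        if np.any(self.dvars < 0):
            raise ValueError("dvars must be non-negative")

    @property
    def n_censored(self) -> int:
        return int(np.sum(~self.keep))


@dataclass
class CorrelationMap:
    """Voxel-by-voxel Pearson correlation matrix.

    Row k is voxel k's correlation profile across all voxels and serves as
    its feature vector for clustering. Geometry (coords/affine) is carried
    along when known so spatially-aware initializations remain possible.
    """

    r: np.ndarray
    voxel_coords: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("r must be a square matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(self.r < -1 - 1e-8) or np.any(self.r > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.voxel_coords is not None:
            self.voxel_coords = np.asarray(self.voxel_coords)
            if self.voxel_coords.shape != (self.n, 3):
                raise ValueError("voxel_coords must have shape (n, 3)")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n(self) -> int:
        return self.r.shape[0]

    @property
    def features(self) -> np.ndarray:
        """The n-by-n feature matrix whose rows are clustered."""
        return self.r

    def world_coords(self) -> np.ndarray:
        if self.voxel_coords is None or self.affine is None:
            raise ValueError("correlation map carries no geometry")
        homog = np.column_stack(
            [self.voxel_coords.astype(float), np.ones(self.n)]
        )
        return (homog @ self.affine.T)[:, :3]


@dataclass(frozen=True)
class SeedROI:
    """Named seed region: a stereotaxic (Talairach) coordinate and radius."""

    name: str
    coord: tuple[float, float, float]
    radius: float = 5.0  # mm

    def __post_init__(self) -> None:
        if len(self.coord) != 3 or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"ROI {self.name!r} has invalid coordinates")
        if self.radius <= 0:
            raise ValueError(f"ROI {self.name!r} has non-positive radius")
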