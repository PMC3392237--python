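"""File I/O: NIfTI volumes and masks, text tables, solution containers.

Voxel ordering is the package-wide scan order: the mask is traversed with
the x grid index varying fastest, then y, then z. Every artifact that
stores voxelwise vectors relies on this order, and loaders reproduce it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fcm import ClusterSolution
from .types import SeedROI, VoxelTimeSeries

__all__ = [
    "load_timeseries",
    "save_timeseries",
    "mask_scan_order_coords",
    "save_membership_maps",
    "save_volume_from_vector",
    "save_solution",
    "load_solution",
    "read_censor_mask",
    "write_censor_mask",
    "read_regressor_table",
    "read_roi_table",
    "sha256_file",
]


def mask_scan_order_coords(mask: np.ndarray) -> np.ndarray:
    """Integer coordinates of in-mask voxels, x fastest (scan order)."""
    mask = np.asarray(mask) != 0
    # argwhere on the (z, y, x)-transposed mask sorts by z, then y, then x;
    # flipping the columns back yields (x, y, z) rows with x fastest.
    return np.argwhere(mask.transpose(2, 1, 0))[:, ::-1]


def load_timeseries(
    volume_path: str | Path,
    mask_path: str | Path,
    frame_interval: float | None = None,
    run_boundaries: list[int] | None = None,
) -> VoxelTimeSeries:
    """Extract the masked voxel-by-frame matrix from a 4-D NIfTI volume."""
    volume_path, mask_path = Path(volume_path), Path(mask_path)
    vol_img = nib.load(volume_path)
    mask_img = nib.load(mask_path)
    if vol_img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(
            f"grid mismatch: {volume_path.name} is {vol_img.shape[:3]}, "
            f"{mask_path.name} is {mask_img.shape[:3]}"
        )
    if not np.allclose(vol_img.affine, mask_img.affine, atol=1e-4):
        raise ValueError(
            f"affine mismatch between {volume_path.name} and {mask_path.name}"
        )
    if vol_img.ndim != 4:
        raise ValueError(f"{volume_path.name} is not a 4-D volume")
    mask = np.asarray(mask_img.dataobj) != 0
    if not mask.any():
        raise ValueError(f"mask {mask_path.name} is empty")
    coords = mask_scan_order_coords(mask)
    data = np.asarray(vol_img.dataobj)
    values = data[coords[:, 0], coords[:, 1], coords[:, 2], :].astype(float)
    if frame_interval is None:
        zooms = vol_img.header.get_zooms()
        frame_interval = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        if not frame_interval:
            raise ValueError(
                f"{volume_path.name} carries no frame interval; pass frame_interval"
            )
    return VoxelTimeSeries(
        values=values,
        voxel_coords=coords,
        affine=vol_img.affine,
        frame_interval=frame_interval,
        run_boundaries=run_boundaries or [0],
    )


def _dense_shape(ts: VoxelTimeSeries) -> tuple[int, int, int]:
    return tuple(int(m) + 1 for m in ts.voxel_coords.max(axis=0))


def save_timeseries(
    volume_path: str | Path, mask_path: str | Path, ts: VoxelTimeSeries
) -> None:
    """Write a series as a 4-D NIfTI volume plus 3-D mask (float64 data)."""
    shape = _dense_shape(ts)
    vol = np.zeros(shape + (ts.n_frames,))
    mask = np.zeros(shape, dtype=np.uint8)
    cx, cy, cz = ts.voxel_coords.T
    vol[cx, cy, cz, :] = ts.values
    mask[cx, cy, cz] = 1
    img = nib.Nifti1Image(vol, ts.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (ts.frame_interval,))
    nib.save(img, str(volume_path))
    nib.save(nib.Nifti1Image(mask, ts.affine), str(mask_path))


def save_volume_from_vector(
    path: str | Path,
    vector: np.ndarray,
    voxel_coords: np.ndarray,
    affine: np.ndarray,
) -> None:
    """Write a per-voxel vector back onto its grid as a 3-D NIfTI volume."""
    vector = np.asarray(vector, dtype=float)
    coords = np.asarray(voxel_coords)
    shape = tuple(int(m) + 1 for m in coords.max(axis=0))
    vol = np.zeros(shape)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = vector
    nib.save(nib.Nifti1Image(vol, np.asarray(affine, float)), str(path))


def save_membership_maps(
    out_dir: str | Path,
    solution: ClusterSolution,
    voxel_coords: np.ndarray,
    affine: np.ndarray,
) -> list[Path]:
    """One NIfTI membership volume per cluster (values in [0, 1])."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = solution.labels or [f"C{i + 1}" for i in range(solution.c)]
    paths = []
    for i, label in enumerate(labels):
        path = out_dir / f"membership_{label}.nii.gz"
        save_volume_from_vector(path, solution.membership[i], voxel_coords, affine)
        paths.append(path)
    return paths


def save_solution(path: str | Path, solution: ClusterSolution) -> None:
    """Persist a solution as .npz (arrays) + sidecar .json (metadata)."""
    path = Path(path)
    np.savez(
        path,
        membership=solution.membership,
        centroids=solution.centroids,
    )
    meta = {
        "c": solution.c,
        "fuzzifier": solution.fuzzifier,
        "xie_beni_trace": solution.xie_beni_trace,
        "objective_trace": solution.objective_trace,
        "converged": solution.converged,
        "n_iter": solution.n_iter,
        "seed_info": solution.seed_info,
        "labels": solution.labels,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_solution(path: str | Path) -> ClusterSolution:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ClusterSolution(
        membership=arrays["membership"],
        centroids=arrays["centroids"],
        fuzzifier=meta["fuzzifier"],
        xie_beni_trace=meta["xie_beni_trace"],
        objective_trace=meta["objective_trace"],
        converged=meta["converged"],
        n_iter=meta["n_iter"],
        seed_info=meta["seed_info"],
        labels=meta["labels"],
    )


def write_censor_mask(path: str | Path, keep: np.ndarray) -> None:
    """One-column text file of 0/1 (1 = frame kept)."""
    np.savetxt(path, np.asarray(keep, dtype=int), fmt="%d")


def read_censor_mask(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)


def read_regressor_table(path: str | Path) -> np.ndarray:
    """Whitespace- or comma-separated table, one row per frame.

    A leading header line of non-numeric tokens is detected and skipped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else r"\s+"
    tokens = first.replace(",", " ").split()

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if all(_numeric(t) for t in tokens) else "infer"
    df = pd.read_csv(path, sep=sep, header=None if header == 0 else 0)
    return df.to_numpy(dtype=float)


def read_roi_table(path: str | Path, default_radius: float = 5.0) -> list[SeedROI]:
    """CSV with columns name, x, y, z[, radius] (Talairach mm)."""
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI table needs columns {sorted(required)}")
    rois = []
    for _, row in df.iterrows():
        radius = float(row["radius"]) if "radius" in df.columns else default_radius
        rois.append(
            SeedROI(
                name=str(row["name"]),
                coord=(float(row["x"]), float(row["y"]), float(row["z"])),
                radius=radius,
            )
        )
    return rois


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
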