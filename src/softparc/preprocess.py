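"""Temporal cleaning of voxel time series and correlation-map features.

The canonical order for resting-state functional-connectivity preparation
implemented here is fixed:

    detrend -> lowpass -> nuisance regression -> DVARS censoring -> correlation

Linear trends are removed per run; low-pass filtering keeps fluctuations
below 0.1 Hz; nuisance regression removes motion parameters, their
temporal derivatives, and the global (whole-mask mean) signal; frames with
DVARS above 0.5% of the mode-1000 signal are censored before correlations
are computed. The resulting n-by-n Pearson matrix is both the connectivity
estimate and the feature matrix for clustering: row k is voxel k's
correlation profile.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal

from .types import CorrelationMap, FrameCensorMask, VoxelTimeSeries

__all__ = [
    "detrend",
    "lowpass",
    "build_nuisance",
    "regress_nuisance",
    "compute_dvars",
    "correlation_map",
    "group_average",
]


def detrend(ts: VoxelTimeSeries) -> VoxelTimeSeries:
    """Remove a least-squares line (intercept + slope) per voxel, per run."""
    out = ts.values.copy()
    for run in ts.runs():
        length = run.stop - run.start
        if length < 3:
            raise ValueError(
                f"run starting at frame {run.start} has {length} frames; need >= 3"
            )
        t = np.arange(length, dtype=float)
        design = np.column_stack([np.ones(length), t])
        beta, *_ = np.linalg.lstsq(design, out[:, run].T, rcond=None)
        out[:, run] -= (design @ beta).T
    return ts.with_values(out)


def lowpass(
    ts: VoxelTimeSeries, cutoff: float = 0.1, order: int = 2
) -> VoxelTimeSeries:
    """Zero-phase Butterworth low-pass filter, applied per run.

    Forward-backward filtering doubles the effective attenuation (the
    magnitude response is |H(f)|^2) but introduces no phase shift, which
    matters because phase lags would distort voxel-pair correlations.
    DC gain is exactly 1.
    """
    nyquist = 1.0 / (2.0 * ts.frame_interval)
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist:.4g} Hz for frame_interval {ts.frame_interval} s"
        )
    b, a = signal.butter(order, cutoff / nyquist, btype="low")
    out = ts.values.copy()
    for run in ts.runs():
        out[:, run] = signal.filtfilt(b, a, out[:, run], axis=1)
    return ts.with_values(out)


def butterworth_gain(
    freq_hz: float, frame_interval: float, cutoff: float = 0.1, order: int = 2
) -> float:
    """Magnitude gain of the zero-phase filter at `freq_hz` (|H|^2)."""
    nyquist = 1.0 / (2.0 * frame_interval)
    b, a = signal.butter(order, cutoff / nyquist, btype="low")
    _, h = signal.freqz(b, a, worN=[np.pi * freq_hz / nyquist])
    return float(np.abs(h[0]) ** 2)


def build_nuisance(
    ts: VoxelTimeSeries,
    motion: np.ndarray | None = None,
    include_derivatives: bool = True,
    global_signal: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance regressor matrix (one row per frame).

    Motion parameters get backward-difference temporal derivatives (zero at
    each run start). The global signal is the mean over in-mask voxels and
    enters without a derivative.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != ts.n_frames:
            motion = motion.T
        if motion.shape[0] != ts.n_frames:
            raise ValueError("motion table must have one row per frame")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion{j}")
        if include_derivatives:
            for j in range(motion.shape[1]):
                d = np.zeros(ts.n_frames)
                for run in ts.runs():
                    d[run][1:] = np.diff(motion[run, j])
                cols.append(d)
                names.append(f"motion{j}_deriv")
    if global_signal:
        cols.append(ts.values.mean(axis=0))
        names.append("global_signal")
    if not cols:
        raise ValueError("no nuisance regressors requested")
    return np.column_stack(cols), names


def _rank_deficient_columns(design: np.ndarray) -> list[int]:
    """Indices of columns that make the design rank deficient."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return sorted(int(piv[i]) for i in range(len(diag)) if diag[i] <= tol)


def regress_nuisance(
    ts: VoxelTimeSeries, regressors: np.ndarray
) -> VoxelTimeSeries:
    """Voxelwise OLS residual against [intercept | regressors]."""
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[0] != ts.n_frames:
        raise ValueError(
            f"regressors have {R.shape[0]} rows but series has {ts.n_frames} frames"
        )
    if R.shape[1] >= ts.n_frames:
        raise ValueError("more regressors than frames")
    design = np.column_stack([np.ones(ts.n_frames), R])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _rank_deficient_columns(design)
        # column 0 is the implicit intercept
        raise ValueError(
            f"nuisance design is rank deficient; offending design columns "
            f"(0 = intercept): {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    return ts.with_values(ts.values - (design @ beta).T)


def compute_dvars(
    ts: VoxelTimeSeries, threshold: float = 0.5
) -> FrameCensorMask:
    """Frame-to-frame RMS signal change as % of mode-1000, plus keep mask.

    DVARS(t) is the RMS over voxels of the backward difference
    ``x(t) - x(t-1)``, divided by 10 so it reads as percent of the
    mode-1000 signal. The first frame of each run has DVARS 0 by
    definition. Frames with DVARS strictly greater than `threshold`
    (default 0.5%) are censored; a spike therefore censors both frames of
    each super-threshold transition.
    """
    dvars = np.zeros(ts.n_frames)
    for run in ts.runs():
        block = ts.values[:, run]
        diffs = np.diff(block, axis=1)
        dvars[run.start + 1 : run.start + block.shape[1]] = (
            np.sqrt(np.mean(diffs**2, axis=0)) / 10.0
        )
    keep = dvars <= threshold
    return FrameCensorMask(keep=keep, dvars=dvars)


def correlation_map(
    ts: VoxelTimeSeries, censor: FrameCensorMask | None = None
) -> CorrelationMap:
    """Pearson correlation between every voxel pair over kept frames."""
    if censor is None:
        values = ts.values
    else:
        if censor.keep.shape[0] != ts.n_frames:
            raise ValueError("censor mask length does not match frame count")
        values = ts.values[:, censor.keep]
    if values.shape[1] < 3:
        raise ValueError(f"need at least 3 kept frames, have {values.shape[1]}")
    sd = values.std(axis=1)
    # relative floor: a numerically constant voxel has sd at rounding level
    floor = 1e-12 * np.clip(np.abs(values).max(axis=1), 1.0, None)
    zero = np.flatnonzero(sd <= floor)
    if zero.size:
        raise ValueError(
            f"voxel(s) {zero.tolist()} have zero variance over kept frames"
        )
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMap(r=r, voxel_coords=ts.voxel_coords, affine=ts.affine)


def group_average(maps: Sequence[CorrelationMap]) -> CorrelationMap:
    """Entrywise mean of per-subject correlation maps."""
    if not maps:
        raise ValueError("no correlation maps given")
    n = maps[0].n
    for i, m in enumerate(maps):
        if m.n != n:
            raise ValueError(f"map {i} has {m.n} voxels, expected {n}")
    mean = np.mean([m.r for m in maps], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMap(
        r=mean, voxel_coords=maps[0].voxel_coords, affine=maps[0].affine
    )
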