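"""End-to-end pipeline: preprocess -> features -> cluster -> compare -> CU.

Configuration is a single declarative structure (JSON on disk). Every run
writes a manifest recording input checksums, parameters, seeds, and the
package version, so each artifact is traceable and a rerun with the same
configuration reproduces all numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fcm import ClusterSolution, consensus_runs
from .io import (
    read_regressor_table,
    read_roi_table,
    save_membership_maps,
    save_solution,
    save_volume_from_vector,
    sha256_file,
    write_censor_mask,
)
from .model_selection import local_minima, sweep_c
from .preprocess import (
    build_nuisance,
    compute_dvars,
    correlation_map,
    detrend,
    lowpass,
    regress_nuisance,
)
from .similarity import cross_solution_matrix, match_clusters
from .types import VoxelTimeSeries
from .uncertainty import classification_uncertainty, uncertainty_cluster_association

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _check_unknown(d: dict, cls, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")


@dataclass
class PreprocessConfig:
    detrend: bool = True
    lowpass_hz: float | None = 0.1
    motion_file: str | None = None
    global_signal: bool = True
    dvars_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.lowpass_hz is not None and self.lowpass_hz <= 0:
            raise ValueError("lowpass_hz must be positive (or null to disable)")
        if self.dvars_threshold <= 0:
            raise ValueError("dvars_threshold must be positive (percent units)")


@dataclass
class ClusteringConfig:
    fuzzifier: float = 1.2
    tol: float = 1e-4
    patience: int = 5
    max_iter: int = 1000
    n_runs: int = 20
    c_values: list[int] = field(default_factory=lambda: [2, 7])
    sweep: list[int] | None = None  # [c_min, c_max] or null
    runs_per_c: int = 20

    def __post_init__(self) -> None:
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier must exceed 1")
        if not self.c_values or any(c < 1 for c in self.c_values):
            raise ValueError("c_values must be positive")
        if self.c_values != sorted(self.c_values):
            raise ValueError("c_values must be increasing")
        if self.sweep is not None and (
            len(self.sweep) != 2 or self.sweep[0] > self.sweep[1]
        ):
            raise ValueError("sweep must be [c_min, c_max]")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline execution."""

    volume: str
    mask: str
    out_dir: str
    seed: int = 0
    frame_interval: float | None = None
    roi_file: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        _check_unknown(d, cls, "top-level")
        if "preprocess" in d:
            _check_unknown(d["preprocess"], PreprocessConfig, "preprocess")
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "clustering" in d:
            _check_unknown(d["clustering"], ClusteringConfig, "clustering")
            d["clustering"] = ClusteringConfig(**d["clustering"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


@_stage("preprocess")
def _preprocess_stage(ts: VoxelTimeSeries, cfg: PreprocessConfig):
    if cfg.detrend:
        ts = detrend(ts)
    if cfg.lowpass_hz is not None:
        ts = lowpass(ts, cutoff=cfg.lowpass_hz)
    motion = (
        read_regressor_table(cfg.motion_file) if cfg.motion_file else None
    )
    if motion is not None or cfg.global_signal:
        regressors, _ = build_nuisance(
            ts, motion=motion, global_signal=cfg.global_signal
        )
        ts = regress_nuisance(ts, regressors)
    censor = compute_dvars(ts, threshold=cfg.dvars_threshold)
    return ts, censor


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every configured stage and write the artifact bundle.

    Returns a mapping from artifact name to path. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    from .io import load_timeseries  # local import to keep module load light

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    try:
        ts = load_timeseries(
            config.volume, config.mask, frame_interval=config.frame_interval
        )
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    ts_clean, censor = _preprocess_stage(ts, config.preprocess)
    artifacts["censor"] = out_dir / "censor.txt"
    write_censor_mask(artifacts["censor"], censor.keep)

    try:
        cmap = correlation_map(ts_clean, censor)
    except Exception as exc:
        raise PipelineError("features", exc) from exc
    artifacts["correlation_map"] = out_dir / "correlation_map.npz"
    np.savez(
        artifacts["correlation_map"],
        r=cmap.r,
        voxel_coords=cmap.voxel_coords,
        affine=cmap.affine,
    )

    clus = config.clustering
    solutions: dict[int, ClusterSolution] = {}
    rng = np.random.default_rng(config.seed)
    for c in clus.c_values:
        try:
            sol = consensus_runs(
                cmap,
                c,
                n_runs=clus.n_runs,
                rng_seed=rng,
                fuzzifier=clus.fuzzifier,
                tol=clus.tol,
                patience=clus.patience,
                max_iter=clus.max_iter,
            )
        except Exception as exc:
            raise PipelineError(f"cluster(c={c})", exc) from exc
        solutions[c] = sol
        save_solution(out_dir / f"solution_c{c}.npz", sol)
        artifacts[f"solution_c{c}"] = out_dir / f"solution_c{c}.npz"
        save_membership_maps(
            out_dir / f"membership_c{c}", sol, cmap.voxel_coords, cmap.affine
        )
        artifacts[f"membership_c{c}"] = out_dir / f"membership_c{c}"

    if clus.sweep is not None:
        try:
            curve = sweep_c(
                cmap,
                c_min=clus.sweep[0],
                c_max=clus.sweep[1],
                runs_per_c=clus.runs_per_c,
                rng_seed=int(rng.integers(2**31)),
                fuzzifier=clus.fuzzifier,
                tol=clus.tol,
                patience=clus.patience,
                max_iter=clus.max_iter,
            )
        except Exception as exc:
            raise PipelineError("sweep", exc) from exc
        artifacts["dispersion_curve"] = out_dir / "dispersion_curve.csv"
        curve.to_csv(artifacts["dispersion_curve"])
        minima = local_minima(curve) if len(curve.c_values) >= 3 else []
        (out_dir / "dispersion_minima.json").write_text(
            json.dumps({"local_minima": minima}) + "\n"
        )
        artifacts["dispersion_minima"] = out_dir / "dispersion_minima.json"

    try:
        for c_a, c_b in zip(clus.c_values[:-1], clus.c_values[1:]):
            sol_a, sol_b = solutions[c_a], solutions[c_b]
            match = match_clusters(sol_b, sol_a, mode="spatial")
            sol_b.labels = match.labels
            for mode, centering in (("spatial", "centered"), ("temporal", "raw")):
                mat = cross_solution_matrix(sol_a, sol_b, mode, centering)
                name = f"similarity_{mode}_c{c_a}_c{c_b}"
                artifacts[name] = out_dir / f"{name}.csv"
                mat.to_csv(artifacts[name])
            name = f"assignment_c{c_b}_to_c{c_a}"
            artifacts[name] = out_dir / f"{name}.json"
            artifacts[name].write_text(
                json.dumps(match.to_json_dict(), indent=2) + "\n"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("compare", exc) from exc

    try:
        c_top = clus.c_values[-1]
        sol = solutions[c_top]
        cu = classification_uncertainty(sol.membership)
        artifacts["uncertainty_map"] = out_dir / f"uncertainty_c{c_top}.nii.gz"
        save_volume_from_vector(
            artifacts["uncertainty_map"], cu.cu, cmap.voxel_coords, cmap.affine
        )
        assoc = uncertainty_cluster_association(cu, sol)
        artifacts["uncertainty_association"] = (
            out_dir / f"uncertainty_association_c{c_top}.csv"
        )
        assoc.to_csv(artifacts["uncertainty_association"], header=True)
    except Exception as exc:
        raise PipelineError("uncertainty", exc) from exc

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "volume": sha256_file(config.volume),
            "mask": sha256_file(config.mask),
        },
        "artifacts": {k: str(v.relative_to(out_dir)) for k, v in artifacts.items()},
        "n_voxels": int(cmap.n),
        "n_frames_kept": int(np.sum(censor.keep)),
        "roi_file": config.roi_file,
    }
    if config.roi_file:
        manifest["rois"] = [
            {"name": r.name, "coord": list(r.coord), "radius": r.radius}
            for r in read_roi_table(config.roi_file)
        ]
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = out_dir / "manifest.json"
    return artifacts
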