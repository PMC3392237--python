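"""I/O round trips, configuration validation, and pipeline smoke tests."""

import json

import numpy as np
import pytest

import softparc as sp
from softparc.io import (
    load_solution,
    load_timeseries,
    mask_scan_order_coords,
    read_censor_mask,
    read_regressor_table,
    read_roi_table,
    save_solution,
    save_timeseries,
    write_censor_mask,
)
from softparc.pipeline import PipelineConfig, PipelineError, run_pipeline


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    """A small planted dataset written to disk as NIfTI + mask."""
    spec = sp.HierarchySpec(
        n_networks=4, voxels_per_network=25, n_frames=120, seed=21
    )
    ts, gt = sp.simulate_bold(spec)
    out = tmp_path_factory.mktemp("tiny")
    paths = sp.simulate.save_synthetic_dataset(out, ts, gt, spec)
    return spec, ts, gt, paths


class TestNiftiRoundTrip:
    def test_writer_loader_bit_exact(self, tiny_dataset, tmp_path):
        _, ts, _, paths = tiny_dataset
        loaded = load_timeseries(paths["volume"], paths["mask"])
        assert np.array_equal(loaded.values, ts.values)
        assert np.array_equal(loaded.voxel_coords, ts.voxel_coords)
        assert loaded.frame_interval == pytest.approx(ts.frame_interval)

    def test_mask_scan_order_x_fastest(self):
        mask = np.zeros((3, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[2, 0, 0] = mask[1, 1, 0] = mask[0, 0, 1] = True
        coords = mask_scan_order_coords(mask)
        assert coords.tolist() == [[0, 0, 0], [2, 0, 0], [1, 1, 0], [0, 0, 1]]

    def test_mismatched_affines_name_both_files(self, tiny_dataset, tmp_path):
        import nibabel as nib

        _, ts, _, paths = tiny_dataset
        bad_mask = tmp_path / "bad_mask.nii.gz"
        img = nib.load(paths["mask"])
        nib.save(
            nib.Nifti1Image(np.asarray(img.dataobj), np.diag([9, 9, 9, 1.0])),
            bad_mask,
        )
        with pytest.raises(ValueError, match="bad_mask"):
            load_timeseries(paths["volume"], bad_mask)

    def test_empty_mask_rejected(self, tiny_dataset, tmp_path):
        import nibabel as nib

        _, ts, _, paths = tiny_dataset
        img = nib.load(paths["mask"])
        empty = tmp_path / "empty.nii.gz"
        nib.save(
            nib.Nifti1Image(np.zeros(img.shape, dtype=np.uint8), img.affine), empty
        )
        with pytest.raises(ValueError, match="empty"):
            load_timeseries(paths["volume"], empty)


class TestTextTables:
    def test_censor_mask_roundtrip(self, tmp_path):
        keep = np.array([True, False, True, True])
        path = tmp_path / "censor.txt"
        write_censor_mask(path, keep)
        assert path.read_text().split() == ["1", "0", "1", "1"]
        assert np.array_equal(read_censor_mask(path), keep)

    @pytest.mark.parametrize("header", [True, False])
    @pytest.mark.parametrize("sep", [",", " "])
    def test_regressor_table_formats(self, tmp_path, header, sep):
        rows = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        lines = []
        if header:
            lines.append(sep.join(["a", "b"]))
        lines += [sep.join(str(v) for v in row) for row in rows]
        path = tmp_path / "regs.txt"
        path.write_text("\n".join(lines) + "\n")
        out = read_regressor_table(path)
        assert np.allclose(out, rows)

    def test_roi_table(self, tmp_path):
        path = tmp_path / "rois.csv"
        path.write_text("name,x,y,z\nDMN,0,-65,31\nFPC,43,22,34\n")
        rois = read_roi_table(path)
        assert rois[0].name == "DMN"
        assert rois[0].coord == (0.0, -65.0, 31.0)
        assert rois[0].radius == 5.0


class TestSolutionPersistence:
    def test_roundtrip(self, small_dataset, tmp_path):
        _, _, _, cmap = small_dataset
        sol = sp.consensus_runs(cmap, 3, n_runs=2, rng_seed=4)
        sol.labels = ["a", "b", "c"]
        path = tmp_path / "sol.npz"
        save_solution(path, sol)
        back = load_solution(path)
        assert np.array_equal(back.membership, sol.membership)
        assert np.array_equal(back.centroids, sol.centroids)
        assert back.labels == sol.labels
        assert back.converged == sol.converged


class TestPipelineConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PipelineConfig.from_dict(
                {"volume": "v", "mask": "m", "out_dir": "o", "bogus": 1}
            )
        with pytest.raises(ValueError, match="unknown"):
            PipelineConfig.from_dict(
                {
                    "volume": "v",
                    "mask": "m",
                    "out_dir": "o",
                    "clustering": {"fuzzifer": 1.2},  # typo must be caught
                }
            )

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig.from_dict(
                {
                    "volume": "v",
                    "mask": "m",
                    "out_dir": "o",
                    "clustering": {"fuzzifier": 0.9},
                }
            )


class TestRunPipeline:
    def _config(self, tiny_dataset, out_dir, **clustering):
        _, _, _, paths = tiny_dataset
        clustering = {"n_runs": 3, "c_values": [2, 4], **clustering}
        return PipelineConfig.from_dict(
            {
                "volume": str(paths["volume"]),
                "mask": str(paths["mask"]),
                "out_dir": str(out_dir),
                "seed": 5,
                "clustering": clustering,
            }
        )

    def test_smoke_emits_all_artifact_classes(self, tiny_dataset, tmp_path):
        config = self._config(tiny_dataset, tmp_path / "run")
        artifacts = run_pipeline(config)
        for key in (
            "censor",
            "correlation_map",
            "solution_c2",
            "solution_c4",
            "similarity_spatial_c2_c4",
            "similarity_temporal_c2_c4",
            "assignment_c4_to_c2",
            "uncertainty_map",
            "uncertainty_association",
            "manifest",
        ):
            assert key in artifacts and artifacts[key].exists(), key
        manifest = json.loads(artifacts["manifest"].read_text())
        assert manifest["config"]["seed"] == 5
        assert set(manifest["inputs"]) == {"volume", "mask"}

    def test_reruns_are_byte_identical(self, tiny_dataset, tmp_path):
        a = run_pipeline(self._config(tiny_dataset, tmp_path / "a"))
        b = run_pipeline(self._config(tiny_dataset, tmp_path / "b"))
        for key in ("similarity_spatial_c2_c4", "uncertainty_association"):
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_cross_solution_matrix_shape(self, tiny_dataset, tmp_path):
        import pandas as pd

        artifacts = run_pipeline(self._config(tiny_dataset, tmp_path / "shape"))
        df = pd.read_csv(artifacts["similarity_spatial_c2_c4"], index_col=0)
        assert df.shape == (2, 4)

    def test_failure_names_stage(self, tiny_dataset, tmp_path):
        config = self._config(tiny_dataset, tmp_path / "fail")
        config.volume = "missing.nii.gz"
        with pytest.raises(PipelineError, match="load"):
            run_pipeline(config)


class TestCli:
    def test_simulate_and_cluster_commands(self, tmp_path):
        from click.testing import CliRunner

        from softparc.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(
            main,
            [
                "simulate",
                "--n-networks", "3",
                "--voxels-per-network", "20",
                "--n-frames", "80",
                "--seed", "1",
                "--out", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (out / "bold.nii.gz").exists()

        feat = tmp_path / "feat"
        res = runner.invoke(
            main,
            [
                "preprocess",
                "--volume", str(out / "bold.nii.gz"),
                "--mask", str(out / "mask.nii.gz"),
                "--out", str(feat),
            ],
        )
        assert res.exit_code == 0, res.output

        res = runner.invoke(
            main,
            [
                "cluster",
                "--features", str(feat / "correlation_map.npz"),
                "--c", "3",
                "--runs", "2",
                "--out", str(tmp_path / "sol.npz"),
            ],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "sol.npz").exists()

    def test_error_exit_code_nonzero(self):
        from click.testing import CliRunner

        from softparc.cli import main

        res = CliRunner().invoke(
            main, ["cluster", "--features", "nope.npz", "--c", "2", "--out", "x"]
        )
        assert res.exit_code != 0


class TestPlotting:
    def test_dispersion_and_similarity_figures_written(self, rng, tmp_path):
        from softparc.model_selection import DispersionCurve
        from softparc.plotting import plot_dispersion_curve, plot_similarity_matrix
        from softparc.similarity import SimilarityMatrix

        curve = DispersionCurve(
            c_values=[2, 3, 4, 5], cd_values=[0.5, 0.2, 0.3, 0.25]
        )
        plot_dispersion_curve(curve, tmp_path / "curve.png")
        mat = SimilarityMatrix(
            values=rng.uniform(-1, 1, (2, 3)),
            row_labels=["TN", "TP"],
            col_labels=["a", "b", "c"],
            mode="spatial",
            centering="centered",
        )
        plot_similarity_matrix(mat, tmp_path / "sim.png")
        assert (tmp_path / "curve.png").stat().st_size > 0
        assert (tmp_path / "sim.png").stat().st_size > 0
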