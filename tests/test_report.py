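"""Association stage, pipeline driver and CLI plumbing."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

from lyothick.cli import main as cli_main
from lyothick.report import (
    SUB_RESOLUTION,
    StudyRecord,
    correlate_thickness_stability,
    run_pipeline,
)


def record(sid, mode, t_half, storage="canister"):
    return StudyRecord(
        sample_id=sid,
        thickness_mode_um=mode,
        d_vol_um=mode if isinstance(mode, str) else mode * 1.1,
        t_half_days={"0-28d": t_half},
        storage=storage,
    )


def demo_config(out_dir, order=None, sub_resolution_sample=False):
    walls = order or [2, 3, 5, 7]
    samples = []
    for w in walls:
        samples.append(
            {
                "id": f"wall{w}",
                "storage": "canister",
                "phantom": {
                    "geometry": "parallel_plates",
                    "wall_um": w * 0.64,
                    "spacing_um": 6 * 0.64,
                    "voxel_um": 0.64,
                    "shape": [48, 24, 24],
                },
                "decay": {"half_life_days": 4.0 + 2.0 * w, "c0": 1e9},
            }
        )
    if sub_resolution_sample:
        samples.append(
            {
                "id": "fine",
                "storage": "canister",
                "phantom": {
                    "geometry": "parallel_plates",
                    "wall_um": 0.64,
                    "spacing_um": 6 * 0.64,
                    "voxel_um": 0.64,
                    "shape": [48, 24, 24],
                },
                "decay": {"half_life_days": 4.0, "c0": 1e9},
            }
        )
    return {
        "output": {"directory": str(out_dir)},
        "thickness": {"bin_um": 0.5},
        "viability": {"windows": [[0, 28], [28, 56]]},
        "samples": samples,
    }


class TestAssociation:
    def test_monotone_pairs_give_spearman_one(self):
        recs = [record(f"s{i}", 1.0 + i, 3.0 + i**2) for i in range(5)]
        (res,) = [r for r in correlate_thickness_stability(recs) if r.window == "0-28d"]
        assert res.spearman_rho == pytest.approx(1.0)

    def test_collinear_pairs_give_pearson_one_and_exact_line(self):
        a, b = 2.5, 4.0
        recs = [record(f"s{i}", x, a + b * x) for i, x in enumerate([1.0, 2.0, 3.5, 5.0])]
        (res,) = correlate_thickness_stability(recs)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope_days_per_um == pytest.approx(b)
        assert res.intercept_days == pytest.approx(a)

    def test_sub_resolution_records_excluded_and_counted(self):
        recs = [record(f"s{i}", 1.0 + i, 5.0 + i) for i in range(4)]
        recs.append(record("fine", SUB_RESOLUTION, 2.0))
        (res,) = correlate_thickness_stability(recs)
        assert res.n == 4 and res.n_excluded_sub_resolution == 1

    def test_all_sentinel_is_an_error(self):
        recs = [record("a", SUB_RESOLUTION, 2.0), record("b", SUB_RESOLUTION, 3.0)]
        with pytest.raises(ValueError, match="sub-resolution"):
            correlate_thickness_stability(recs)

    def test_undefined_below_three_records(self):
        recs = [record("a", 1.0, 2.0), record("b", 2.0, 3.0)]
        (res,) = correlate_thickness_stability(recs)
        assert math.isnan(res.spearman_rho) and "undefined" in res.flags

    def test_grouping_by_storage_splits_results(self):
        recs = [record(f"c{i}", 1.0 + i, 5.0 + i, storage="canister") for i in range(3)]
        recs += [record(f"v{i}", 1.0 + i, 8.0 + i, storage="vacuum_bag") for i in range(3)]
        results = correlate_thickness_stability(recs, group_by="storage")
        assert {r.grouping for r in results} == {"canister", "vacuum_bag"}


class TestPipeline:
    def test_demo_config_runs_end_to_end(self, tmp_path):
        out = tmp_path / "out"
        summary = run_pipeline(demo_config(out, sub_resolution_sample=True))
        assert (out / "halflives.csv").exists()
        assert (out / "association.csv").exists()
        assert (out / "distributions" / "wall5.csv").exists()
        fine = [s for s in summary["samples"] if s["sample_id"] == "fine"][0]
        assert fine["mode_um"] == SUB_RESOLUTION
        rho = summary["association"][0]["spearman_rho"]
        assert rho == pytest.approx(1.0)

    def test_rerun_is_byte_identical(self, tmp_path):
        run_pipeline(demo_config(tmp_path / "a"))
        run_pipeline(demo_config(tmp_path / "b"))
        assert (tmp_path / "a" / "summary.json").read_bytes() == (
            tmp_path / "b" / "summary.json"
        ).read_bytes()

    def test_association_invariant_to_sample_order(self, tmp_path):
        s1 = run_pipeline(demo_config(tmp_path / "fwd", order=[2, 3, 5, 7]))
        s2 = run_pipeline(demo_config(tmp_path / "rev", order=[7, 5, 3, 2]))
        for a, b in zip(s1["association"], s2["association"]):
            for key in a:
                if isinstance(a[key], float):
                    assert a[key] == pytest.approx(b[key], rel=1e-9)
                else:
                    assert a[key] == b[key]

    def test_stage_error_names_sample(self, tmp_path):
        cfg = demo_config(tmp_path / "out")
        cfg["samples"][1].pop("decay")
        with pytest.raises(RuntimeError, match="viability.*wall3"):
            run_pipeline(cfg)

    def test_report_reuses_thickness_module_values(self, tmp_path):
        from lyothick.phantoms import PhantomSpec, make_parallel_plate_phantom
        from lyothick.thickness import (
            distribution_mode,
            local_thickness_map,
            thickness_distribution,
        )

        out = tmp_path / "out"
        summary = run_pipeline(demo_config(out))
        spec = PhantomSpec("parallel_plates", 5 * 0.64, 6 * 0.64, 0.64, (48, 24, 24))
        dist = thickness_distribution(local_thickness_map(make_parallel_plate_phantom(spec)))
        wall5 = [s for s in summary["samples"] if s["sample_id"] == "wall5"][0]
        assert wall5["mode_um"] == pytest.approx(distribution_mode(dist))


class TestPlotting:
    def test_svg_outputs_written(self, tmp_path):
        from lyothick.phantoms import PhantomSpec, make_parallel_plate_phantom
        from lyothick.plotting import plot_thickness_distribution, plot_thickness_vs_half_life
        from lyothick.thickness import local_thickness_map, thickness_distribution

        dist = thickness_distribution(
            local_thickness_map(
                make_parallel_plate_phantom(
                    PhantomSpec("parallel_plates", 3.0, 5.0, 1.0, (40, 20, 20))
                )
            )
        )
        plot_thickness_distribution({"wall3": dist}, tmp_path / "dist.svg")
        recs = [record(f"s{i}", 1.0 + i, 5.0 + i) for i in range(4)]
        plot_thickness_vs_half_life(recs, "0-28d", tmp_path / "assoc.svg")
        assert (tmp_path / "dist.svg").stat().st_size > 0
        assert (tmp_path / "assoc.svg").stat().st_size > 0


class TestCLI:
    def test_run_subcommand_with_toml_config(self, tmp_path):
        import tomllib

        demo = demo_config(tmp_path / "out", order=[2, 5])
        lines = ["[output]", f'directory = "{tmp_path / "out"}"', "",
                 "[viability]", "windows = [[0, 28], [28, 56]]", ""]
        for s in demo["samples"]:
            ph, dc = s["phantom"], s["decay"]
            lines += [
                "[[samples]]",
                f'id = "{s["id"]}"',
                f'storage = "{s["storage"]}"',
                "phantom = { geometry = \"parallel_plates\", "
                f'wall_um = {ph["wall_um"]}, spacing_um = {ph["spacing_um"]}, '
                f'voxel_um = {ph["voxel_um"]}, shape = {ph["shape"]} }}',
                f'decay = {{ half_life_days = {dc["half_life_days"]}, c0 = 1e9 }}',
                "",
            ]
        cfg_path = tmp_path / "study.toml"
        cfg_path.write_text("\n".join(lines))
        tomllib.loads(cfg_path.read_text())  # config is valid TOML
        res = CliRunner().invoke(cli_main, ["run", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "summary.json").exists()

    def test_segment_thickness_viability_round_trip(self, tmp_path):
        from lyothick.phantoms import (
            DecaySpec,
            PhantomSpec,
            RenderSpec,
            make_parallel_plate_phantom,
            render_greyscale,
            simulate_viability_series,
        )
        from lyothick.preprocess import write_volume
        from lyothick.viability import write_viability_csv

        bv = make_parallel_plate_phantom(
            PhantomSpec("parallel_plates", 3.0, 5.0, 1.0, (40, 20, 20))
        )
        vol = render_greyscale(bv, RenderSpec(noise_sd=5.0, seed=1))
        write_volume(vol, tmp_path / "vol.tif")
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["segment", str(tmp_path / "vol.tif"), "--voxel-um", "1.0",
             "--median-window", "3", "-o", str(tmp_path / "mask.tif")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["thickness", str(tmp_path / "mask.tif"), "--voxel-um", "1.0",
             "-o", str(tmp_path / "dist.csv")],
        )
        assert res.exit_code == 0, res.output
        summary = json.loads((tmp_path / "dist.json").read_text())
        assert 2.5 <= summary["mode_um"] <= 3.5

        s = simulate_viability_series(DecaySpec(c0=1e9, half_life_days=10.0))
        write_viability_csv([s], tmp_path / "cfu.csv")
        res = runner.invoke(
            cli_main,
            ["viability", str(tmp_path / "cfu.csv"), "-o", str(tmp_path / "hl.csv")],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        hl = pd.read_csv(tmp_path / "hl.csv")
        np.testing.assert_allclose(hl["t_half_days"], 10.0)
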