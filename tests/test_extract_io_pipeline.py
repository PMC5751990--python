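"""Map extraction on simulated phantoms, file round trips, pipeline runs."""

import json

import numpy as np
import pandas as pd
import pytest

from qusrm.acquisition import AcquisitionConfig, PhantomSpec
from qusrm.extract import ExtractionConfig, QusExtractor, build_parametric_map
from qusrm.io import (read_map_csv, read_rf_container, write_map_csv,
                      write_rf_container)
from qusrm.simulate import simulate_phantom_rf
from qusrm.spectral import ParametricMap


@pytest.fixture(scope="module")
def extraction_setup(acq, small_phantom, small_reference):
    frame = simulate_phantom_rf(small_phantom, acq, seed=1)
    refs = [simulate_phantom_rf(small_reference, acq, seed=100 + i)
            for i in range(2)]
    config = ExtractionConfig(overlap=0.8)
    return frame, refs, config


class TestExtraction:
    def test_map_grid_and_mean(self, acq, extraction_setup):
        frame, refs, config = extraction_setup
        extractor = QusExtractor(acq, refs, config)
        roi = (0, 0, frame.n_samples, frame.n_lines)
        maps = extractor.maps(frame, roi, params=("MBF", "SS", "SI"))
        mbf = maps["MBF"]
        assert mbf.values.ndim == 2
        assert mbf.mean == pytest.approx(
            np.mean(mbf.values[mbf.mask]))
        # MBF = SI + SS * midpoint cell-wise
        mid = 6.5
        assert np.allclose(
            mbf.values[mbf.mask],
            maps["SI"].values[mbf.mask] + maps["SS"].values[mbf.mask] * mid,
            atol=1e-9)

    def test_homogeneous_phantom_map_is_tight(self, acq, extraction_setup):
        # homogeneous medium: spatial spread comparable to the seed-to-seed
        # estimator noise, not larger than a few dB
        frame, refs, config = extraction_setup
        pmap = build_parametric_map(
            frame, (0, 0, frame.n_samples, frame.n_lines), "MBF", refs,
            config)
        assert np.nanstd(pmap.values[pmap.mask]) < 4.0

    def test_two_region_phantom_contrast(self, acq, small_reference):
        # higher scatterer density -> higher backscatter (MBF) in that region
        lo = PhantomSpec(extent=(8e-3, 4e-3), number_density=60.0)
        hi = PhantomSpec(extent=(8e-3, 4e-3), number_density=600.0)
        f_lo = simulate_phantom_rf(lo, acq, seed=21)
        f_hi = simulate_phantom_rf(hi, acq, seed=22)
        two_region = f_lo
        split = f_lo.n_samples // 2
        two_region.samples[split:] = f_hi.samples[split:]
        refs = [simulate_phantom_rf(small_reference, acq, seed=130 + i)
                for i in range(2)]
        pmap = build_parametric_map(
            two_region, (0, 0, two_region.n_samples, two_region.n_lines),
            "MBF", refs, ExtractionConfig(overlap=0.8))
        rows = pmap.values.shape[0]
        top = np.nanmean(pmap.values[: rows // 3])
        bottom = np.nanmean(pmap.values[-rows // 3:])
        assert bottom > top

    def test_self_normalization_nullity(self, acq, extraction_setup):
        # the frame normalized against itself: SS = SI = MBF = 0 and the
        # attenuation estimate equals the reference value exactly
        frame, _, config = extraction_setup
        extractor = QusExtractor(acq, [frame], config)
        roi = (0, 0, frame.n_samples, frame.n_lines)
        maps = extractor.maps(frame, roi, params=("MBF", "SS", "SI", "ACE"))
        for name in ("MBF", "SS", "SI"):
            vals = maps[name].values[maps[name].mask]
            assert np.allclose(vals, 0.0, atol=1e-9)
        ace = maps["ACE"].values[maps["ACE"].mask]
        assert np.allclose(ace, 0.576, atol=1e-9)

    def test_unknown_parameter_rejected(self, acq, extraction_setup):
        frame, refs, config = extraction_setup
        extractor = QusExtractor(acq, refs, config)
        with pytest.raises(ValueError, match="unknown"):
            extractor.maps(frame, (0, 0, frame.n_samples, frame.n_lines),
                           params=("XYZ",))


class TestRfContainer:
    def test_round_trip(self, tmp_path, small_frame):
        path = tmp_path / "frame.h5"
        write_rf_container(small_frame, path)
        back = read_rf_container(path)
        assert np.array_equal(back.samples, small_frame.samples)
        assert back.acquisition == small_frame.acquisition
        assert back.origin_depth == small_frame.origin_depth

    def test_missing_attribute_named(self, tmp_path, small_frame):
        import h5py

        path = tmp_path / "frame.h5"
        write_rf_container(small_frame, path)
        with h5py.File(path, "a") as h5:
            del h5.attrs["sampling_rate"]
        with pytest.raises(ValueError, match="sampling_rate"):
            read_rf_container(path)

    def test_truncated_file_clean_error(self, tmp_path):
        path = tmp_path / "broken.h5"
        path.write_bytes(b"\x89HDF\r\n\x1a\njunk")
        with pytest.raises(ValueError, match="unreadable|schema"):
            read_rf_container(path)


class TestMapCsv:
    def test_round_trip_with_mask(self, tmp_path):
        values = np.array([[1.0, 2.0], [3.0, np.nan]])
        pmap = ParametricMap(values, "MBF", units="dBr")
        path = tmp_path / "MBF.csv"
        write_map_csv(pmap, path)
        back = read_map_csv(path)
        assert back.parameter_name == "MBF"
        assert np.array_equal(back.mask, pmap.mask)
        assert np.allclose(back.values[back.mask], values[pmap.mask])
        meta = json.loads(path.with_suffix(".json").read_text())
        assert meta["units"] == "dBr"


@pytest.fixture(scope="module")
def quick_config(tmp_path_factory):
    from qusrm.classify import ClassifierConfig
    from qusrm.cohort import CohortSpec
    from qusrm.pipeline import PipelineConfig

    out = tmp_path_factory.mktemp("run")
    return PipelineConfig(
        seed=3, out_dir=str(out),
        sample_phantom=PhantomSpec(effective_radius=60e-6,
                                   attenuation_slope=1.0,
                                   extent=(8e-3, 4e-3),
                                   number_density=150.0),
        extraction=ExtractionConfig(overlap=0.7),
        cohort=CohortSpec(group_sizes={"CR": 8, "PR": 10, "NR": 8}),
        classifier=ClassifierConfig(c_grid=(2 ** 10,),
                                    gamma_grid=(2 ** -10,),
                                    n_subsets=2, n_selected=3),
        render_km_plot=False)


class TestPipeline:

    def test_smoke_run_produces_outputs(self, quick_config):
        from qusrm.pipeline import run_pipeline

        from pathlib import Path

        manifest = run_pipeline(quick_config)
        out = Path(quick_config.out_dir)
        for name in ("classification.json", "stats.json", "features.csv",
                     "survival.csv", "manifest.json"):
            assert (out / name).exists()
        assert "features.csv" in manifest.checksums
        stats = json.loads((out / "stats.json").read_text())
        assert {"group_test", "logrank", "rfs_5yr"} <= set(stats)

    def test_rerun_is_byte_identical(self, quick_config, tmp_path):
        import dataclasses

        from qusrm.pipeline import run_pipeline

        cfg2 = dataclasses.replace(quick_config, out_dir=str(tmp_path / "b"))
        manifest_a = run_pipeline(quick_config)
        manifest_b = run_pipeline(cfg2)
        for name in ("features.csv", "survival.csv", "patients.csv"):
            assert manifest_a.checksums[name] == manifest_b.checksums[name]

    def test_full_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ExtractionConfig(overlap=1.0)


class TestCli:
    def test_simulate_and_extract_commands(self, tmp_path):
        from click.testing import CliRunner

        from qusrm.cli import main

        runner = CliRunner()
        rf = tmp_path / "sample.h5"
        ref = tmp_path / "ref.h5"
        r1 = runner.invoke(main, ["simulate", "--kind", "phantom", "--seed",
                                  "1", "--out", str(rf),
                                  "--extent-mm", "8,4"])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["simulate", "--kind", "reference", "--seed",
                                  "2", "--out", str(ref),
                                  "--extent-mm", "8,4"])
        assert r2.exit_code == 0, r2.output
        out = tmp_path / "maps"
        r3 = runner.invoke(main, ["extract", "--rf", str(rf), "--ref",
                                  str(ref), "--params", "MBF,SS,SI",
                                  "--out", str(out)])
        assert r3.exit_code == 0, r3.output
        assert (out / "MBF.csv").exists()

    def test_cohort_and_survival_commands(self, tmp_path):
        from click.testing import CliRunner

        from qusrm.cli import main

        runner = CliRunner()
        r1 = runner.invoke(main, ["simulate", "--kind", "cohort", "--seed",
                                  "4", "--out", str(tmp_path)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["survival", "--survival",
                                  str(tmp_path / "survival.csv"), "--out",
                                  str(tmp_path / "surv.json")])
        assert r2.exit_code == 0, r2.output
        result = json.loads((tmp_path / "surv.json").read_text())
        assert result["rfs_5yr"]["NR"] <= result["rfs_5yr"]["CR"]
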