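import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from modsite import InvalidArgumentError, LOFConfig, ModProfile
from modsite.cli import main
from modsite.pipeline import PipelineConfig, SimulateConfig, run_detect, run_simulate

from conftest import mod_error_vector


@pytest.fixture(scope="module")
def bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    prof = ModProfile(site=150, mod_error=mod_error_vector(0.40), class_label="m7G")
    return run_simulate(
        SimulateConfig(
            out_dir=str(out), length=300, depth=400, n_replicates=3, seed=17, profiles=[prof]
        )
    )


def detect_cfg(bundle, out_dir, **kw):
    defaults = dict(
        cond1_bams=bundle["wt"], cond2_bams=bundle["ko"], out_dir=str(out_dir),
        n_reads=300, seed=5, feature_set="M", lof=LOFConfig(k=20, contamination=0.01),
        map_path=bundle["truth"],
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestRunSimulate:
    def test_bundle_contents(self, bundle):
        assert len(bundle["wt"]) == 3 and len(bundle["ko"]) == 3
        for p in bundle["wt"] + bundle["ko"] + [bundle["reference"], bundle["truth"]]:
            assert Path(p).exists()
        bed = Path(bundle["truth"]).read_text().split()
        assert int(bed[1]) == 149 and int(bed[2]) == 150  # site 150, 0-based half-open

    def test_seed_reproducibility_bit_identical(self, tmp_path):
        cfgs = [
            SimulateConfig(out_dir=str(tmp_path / d), length=60, depth=40, n_replicates=1, seed=9)
            for d in ("a", "b")
        ]
        b1, b2 = run_simulate(cfgs[0]), run_simulate(cfgs[1])
        assert Path(b1["wt"][0]).read_bytes() == Path(b2["wt"][0]).read_bytes()

    def test_stoichiometry_series_emits_per_ratio_sets(self, tmp_path):
        bundle = run_simulate(
            SimulateConfig(
                out_dir=str(tmp_path), length=60, depth=30, n_replicates=1, seed=2,
                profiles=[ModProfile(site=30)], stoichiometries=(0.0, 0.5, 1.0),
            )
        )
        assert set(bundle["mixtures"]) == {0.0, 0.5, 1.0}


class TestRunDetect:
    def test_recovers_injected_site(self, bundle, tmp_path):
        report = run_detect(detect_cfg(bundle, tmp_path))
        flagged = report.flagged
        assert 150 in flagged["pos"].tolist()
        assert (flagged.loc[flagged["pos"] == 150, "label"] == "modified").all()

    def test_null_comparison_flags_only_non_modified(self, bundle, tmp_path):
        cfg = detect_cfg(bundle, tmp_path, cond1_bams=bundle["ko"], map_path=None)
        report = run_detect(cfg)
        assert (report.flagged["label"] == "unannotated").all()

    def test_rerun_is_bit_identical(self, bundle, tmp_path):
        out = []
        for d in ("r1", "r2"):
            run_detect(detect_cfg(bundle, tmp_path / d))
            out.append((tmp_path / d / "outliers.tsv").read_bytes())
        assert out[0] == out[1]
        m1 = json.loads((tmp_path / "r1" / "manifest.json").read_text())
        m2 = json.loads((tmp_path / "r2" / "manifest.json").read_text())
        assert m1 == m2

    def test_differing_basecalling_modes_refused(self, bundle, tmp_path):
        cfg = detect_cfg(bundle, tmp_path, cond2_basecalling_mode="fast")
        with pytest.raises(InvalidArgumentError, match="basecalled"):
            run_detect(cfg)

    def test_missing_input_is_actionable_error(self, bundle, tmp_path):
        cfg = detect_cfg(bundle, tmp_path, cond1_bams=["/nonexistent.bam"])
        with pytest.raises(InvalidArgumentError, match="not found"):
            run_detect(cfg)


class TestCli:
    def test_simulate_then_pileup_and_detect(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            main,
            ["simulate", "--length", "80", "--depth", "60", "--replicates", "2",
             "--seed", "4", "--out-dir", str(tmp_path / "sim")],
        )
        assert res.exit_code == 0, res.output
        bundle = json.loads((tmp_path / "sim" / "bundle.json").read_text())
        res = runner.invoke(
            main, ["pileup", bundle["wt"][0], "--out", str(tmp_path / "p.tsv")]
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "p.tsv").exists()
        res = runner.invoke(
            main,
            ["detect", "--cond1", ",".join(bundle["wt"]), "--cond2", ",".join(bundle["ko"]),
             "--n-reads", "50", "--k", "10", "--contamination", "0.05",
             "--out-dir", str(tmp_path / "run")],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run" / "outliers.tsv").exists()

    def test_estimate_from_curve_tsv(self, tmp_path):
        import pandas as pd

        pd.DataFrame(
            {"ratio": [0, 0.5, 1], "mean": [0, 20, 40], "sd": [0.5] * 3,
             "n_seeds": 5, "site": 1, "channel": "mismatch"}
        ).to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        runner = CliRunner()
        res = runner.invoke(
            main, ["estimate", "--curve", str(tmp_path / "c.tsv"), "--observed", "30"]
        )
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["level"] == pytest.approx(0.75)

    def test_domain_errors_exit_nonzero_with_message(self, toy_sam, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            main, ["downsample", str(toy_sam), "--n", "99", "--out", str(tmp_path / "x.bam")]
        )
        assert res.exit_code != 0
        assert "3" in res.output  # names the available read count
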