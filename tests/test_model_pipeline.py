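import json
from pathlib import Path

import pytest
import yaml
from click.testing import CliRunner

from tadresponse import RunConfig, SimConfig, TadResponseModel, run_pipeline, simulate
from tadresponse.cli import main
from tadresponse.model import stage_seed


class TestModelFit:
    def test_summary_schema(self, small_results):
        s = small_results.summary_dict
        for key in (
            "seed", "n_genes", "cohort", "n_tads", "n_scored_tads",
            "pct_tads_scored", "tad_categories", "n_regions", "n_links",
            "pct_regulated_in_responsive", "pct_responsive_genes_linked",
            "dip", "permutation", "fisher", "chisq",
        ):
            assert key in s, key
        assert s["cohort"]["regulated"] == s["cohort"]["activated"] + s["cohort"]["repressed"]
        assert (
            s["n_scored_tads"]
            == s["tad_categories"]["up"]
            + s["tad_categories"]["balanced"]
            + s["tad_categories"]["down"]
        )

    def test_fit_deterministic_given_seed(self, small_sim):
        model = TadResponseModel.from_simulation(small_sim)
        s1 = model.fit(n_perm=499, dip_null=99, seed=3).summary_dict
        s2 = model.fit(n_perm=499, dip_null=99, seed=3).summary_dict
        assert s1 == s2
        s3 = model.fit(n_perm=499, dip_null=99, seed=4).summary_dict
        assert s3["permutation"]["p_value"] != s1["permutation"]["p_value"] or s3 != s1

    def test_audit_consistency(self, small_results):
        small_results.audit()

    def test_recovery_against_truth(self, small_sim, small_results):
        from tadresponse import truth_vs_inferred

        report = truth_vs_inferred(
            small_sim.truth, small_results.activities, small_results.responses
        )
        # the generator's signal is strong: direction errors should be rare
        assert report["tad_direction_error"] < 0.05

    def test_summary_text_renders(self, small_results):
        text = small_results.summary()
        assert "TAD" in text and "dip" in text and "Fisher" in text

    def test_save_writes_all_tables(self, small_results, tmp_path):
        small_results.save(tmp_path)
        for name in (
            "gene_responses.tsv", "tad_activity.tsv", "links.tsv",
            "summary.json", "dip.json",
        ):
            assert (tmp_path / name).exists(), name
        summary = json.loads((tmp_path / "summary.json").read_text())
        assert summary["seed"] == small_results.seed

    def test_plots_render(self, small_results):
        import matplotlib

        matplotlib.use("Agg")
        ax = small_results.plot_score_distribution()
        assert ax.get_xlabel().startswith("TAD score")
        ax = small_results.plot_trajectories()
        assert ax.get_legend() is not None


def test_stage_seed_is_stable_and_distinct():
    assert stage_seed(1, "dip") == stage_seed(1, "dip")
    assert stage_seed(1, "dip") != stage_seed(1, "permutation")
    assert stage_seed(1, "dip") != stage_seed(2, "dip")
    assert 0 <= stage_seed(123456, "anything") < 2**31


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("simdata")
    simulate(SimConfig(seed=21, n_chrom=1, chrom_length=15_000_000), path)
    return path


@pytest.fixture(scope="module")
def workdir(tmp_path_factory):
    return tmp_path_factory.mktemp("cli")


class TestPipeline:
    def _config(self, sim_dir, outdir):
        return RunConfig(
            regions=str(sim_dir / "regions.bed"),
            tads=str(sim_dir / "tads.bed"),
            genes=str(sim_dir / "genes.tsv"),
            expression=str(sim_dir / "expression.tsv"),
            interactions=str(sim_dir / "interactions.bedpe"),
            counts=str(sim_dir / "counts.tsv"),
            outdir=str(outdir),
            n_perm=499,
            dip_null=99,
            seed=5,
        )

    def test_run_pipeline_end_to_end(self, sim_dir, tmp_path):
        summary = run_pipeline(self._config(sim_dir, tmp_path / "out"))
        assert (tmp_path / "out" / "summary.json").exists()
        on_disk = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert on_disk["n_genes"] == summary["n_genes"]

    def test_rerun_identical(self, sim_dir, tmp_path):
        s1 = run_pipeline(self._config(sim_dir, tmp_path / "o1"))
        s2 = run_pipeline(self._config(sim_dir, tmp_path / "o2"))
        assert s1 == s2

    def test_missing_input_fails_before_outputs(self, sim_dir, tmp_path):
        cfg = self._config(sim_dir, tmp_path / "out")
        cfg.tads = str(sim_dir / "no_such.bed")
        with pytest.raises(FileNotFoundError):
            run_pipeline(cfg)
        assert not (tmp_path / "out").exists()

    def test_yaml_round_trip(self, sim_dir, tmp_path):
        cfg = self._config(sim_dir, tmp_path / "out")
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.__dict__))
        loaded = RunConfig.from_yaml(path)
        assert loaded == cfg
        path.write_text(yaml.safe_dump({**cfg.__dict__, "bogus_key": 1}))
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml(path)


class TestCli:
    def test_simulate_then_run_all_then_report(self, workdir):
        runner = CliRunner()
        sim = workdir / "sim"
        res = runner.invoke(
            main,
            ["simulate", "--outdir", str(sim), "--seed", "9",
             "--n-chrom", "1", "--chrom-length", "15000000"],
        )
        assert res.exit_code == 0, res.output
        out = workdir / "results"
        res = runner.invoke(
            main,
            [
                "run-all",
                "--regions", str(sim / "regions.bed"),
                "--tads", str(sim / "tads.bed"),
                "--genes", str(sim / "genes.tsv"),
                "--expression", str(sim / "expression.tsv"),
                "--interactions", str(sim / "interactions.bedpe"),
                "--counts", str(sim / "counts.tsv"),
                "--outdir", str(out),
                "--n-perm", "499", "--dip-null", "99", "--seed", "2",
            ],
        )
        assert res.exit_code == 0, res.output
        assert (out / "summary.json").exists()
        res = runner.invoke(main, ["report", "--results", str(out)])
        assert res.exit_code == 0 and "n_scored_tads" in res.output

    def test_stage_commands(self, workdir):
        runner = CliRunner()
        sim = workdir / "sim"  # written by the previous test
        out = workdir / "stages"
        out.mkdir(exist_ok=True)
        res = runner.invoke(
            main,
            ["classify-genes", "--expression", str(sim / "expression.tsv"),
             "--counts", str(sim / "counts.tsv"), "--out", str(out / "calls.tsv")],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            main,
            ["score-tads", "--regions", str(sim / "regions.bed"),
             "--tads", str(sim / "tads.bed"), "--out", str(out / "tads.tsv"),
             "--dip-out", str(out / "dip.json"), "--dip-null", "99"],
        )
        assert res.exit_code == 0, res.output
        assert json.loads((out / "dip.json").read_text())["n_null"] == 99
        res = runner.invoke(
            main,
            ["link-regions", "--regions", str(sim / "regions.bed"),
             "--genes", str(sim / "genes.tsv"), "--tads", str(sim / "tads.bed"),
             "--interactions", str(sim / "interactions.bedpe"),
             "--out", str(out / "links.tsv")],
        )
        assert res.exit_code == 0, res.output

    def test_enrich_and_timecourse_from_intermediates(self, workdir):
        runner = CliRunner()
        responses = workdir / "results" / "gene_responses.tsv"
        out = workdir / "stages"
        res = runner.invoke(
            main,
            ["enrich", "--gene-responses", str(responses),
             "--out", str(out / "enrich.json"), "--n-perm", "499"],
        )
        assert res.exit_code == 0, res.output
        assert "permutation" in json.loads((out / "enrich.json").read_text())
        res = runner.invoke(
            main,
            ["timecourse", "--gene-responses", str(responses),
             "--out", str(out / "tc.tsv")],
        )
        assert res.exit_code == 0, res.output

    def test_run_all_requires_inputs(self):
        runner = CliRunner()
        res = runner.invoke(main, ["run-all"])
        assert res.exit_code != 0
        assert "required" in res.output
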