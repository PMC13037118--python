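"""Configuration round-trips, CLI subcommands and pipeline orchestration."""

import json

import pytest
from click.testing import CliRunner

from pheroscan.cli import main
from pheroscan.config import PipelineConfig, TMConfig
from pheroscan.pipeline import Manifest, run_pipeline


class TestConfig:
    def test_yaml_roundtrip_lossless(self, tmp_path):
        cfg = PipelineConfig(tm=TMConfig(window=21, threshold=1.8), seed=7)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = PipelineConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError, match="phlogiston"):
            PipelineConfig.from_dict({"phlogiston": {"x": 1}})

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="windoww"):
            PipelineConfig.from_dict({"tm": {"windoww": 19}})


def _run(args):
    runner = CliRunner()
    result = runner.invoke(main, args, catch_exceptions=False)
    assert result.exit_code == 0, result.output
    return result


class TestCli:
    def test_simulate_then_scan_a(self, tmp_path):
        sim_dir, out_dir = tmp_path / "sim", tmp_path / "out"
        _run(["simulate", "a-genome", "--seed", "3", "--out", str(sim_dir),
              "--n", "2"])
        _run(["scan-a", "--genome", str(sim_dir / "genome.fasta"),
              "--out", str(out_dir)])
        truth = json.loads((sim_dir / "truth.json").read_text())
        gff = (out_dir / "a_calls.gff3").read_text()
        assert gff.count("putatively_functional") == len(truth) == 2
        peptide_lines = (out_dir / "a_peptides.tsv").read_text().splitlines()
        assert len(peptide_lines) - 1 == sum(t["data"]["n_repeats"]
                                             for t in truth)

    def test_simulate_then_scan_alpha(self, tmp_path):
        sim_dir, out_dir = tmp_path / "sim", tmp_path / "out"
        _run(["simulate", "alpha-set", "--seed", "4", "--out", str(sim_dir),
              "--n", "3"])
        _run(["scan-alpha", "--proteins", str(sim_dir / "precursors.fasta"),
              "--out", str(out_dir)])
        truth = json.loads((sim_dir / "truth.json").read_text())
        table = (out_dir / "alpha_calls.tsv").read_text()
        for t in truth:
            assert t["data"]["mature"] in table

    def test_simulate_then_classify_receptor(self, tmp_path):
        sim_dir, out_dir = tmp_path / "sim", tmp_path / "out"
        _run(["simulate", "receptor-set", "--seed", "5", "--out", str(sim_dir),
              "--n", "4"])
        _run(["classify-receptor", "--proteins",
              str(sim_dir / "receptors.fasta"), "--out", str(out_dir)])
        truth = json.loads((sim_dir / "truth.json").read_text())
        rows = [l.split("\t") for l in
                (out_dir / "receptors.tsv").read_text().splitlines()[1:]]
        assert [int(r[1]) for r in rows] == [t["data"]["n_tm"] for t in truth]

    def test_synteny_subcommand(self, tmp_path):
        sim_dir, out_dir = tmp_path / "sim", tmp_path / "out"
        _run(["simulate", "locus-pair", "--seed", "6", "--out", str(sim_dir),
              "--n", "3"])
        _run(["synteny", "--loci", str(sim_dir / "loci.tsv"),
              "--proteins", str(sim_dir / "locus_proteins.fasta"),
              "--out", str(out_dir),
              "--plot", str(out_dir / "pair.svg")])
        links = (out_dir / "links.tsv").read_text().splitlines()
        assert len(links) - 1 == 3
        assert (out_dir / "pair.svg").exists()

    def test_strategy_summary_subcommand(self, tmp_path):
        sim_dir = tmp_path / "sim"
        _run(["simulate", "cohort", "--seed", "7", "--out", str(sim_dir),
              "--n", "4"])
        out = tmp_path / "summary.tsv"
        result = _run(["strategy-summary", "--calls",
                       str(sim_dir / "features.tsv"),
                       "--strategies", str(sim_dir / "strategies.tsv"),
                       "--out", str(out), "--test-feature", "trait",
                       "--seed", "7"])
        assert out.exists()
        assert "permutation test" in result.output


class TestPipeline:
    def _make_inputs(self, tmp_path):
        sim = tmp_path / "sim"
        _run(["simulate", "a-genome", "--seed", "9", "--out", str(sim), "--n", "1"])
        _run(["simulate", "alpha-set", "--seed", "9", "--out", str(sim), "--n", "2"])
        _run(["simulate", "receptor-set", "--seed", "9", "--out", str(sim), "--n", "3"])
        _run(["simulate", "cohort", "--seed", "9", "--out", str(sim), "--n", "3"])
        manifest = tmp_path / "manifest.yaml"
        manifest.write_text(
            f"genome: {sim}/genome.fasta\n"
            f"alpha_proteins: {sim}/precursors.fasta\n"
            f"receptor_proteins: {sim}/receptors.fasta\n"
            f"strategies: {sim}/strategies.tsv\n"
            f"features: {sim}/features.tsv\n")
        return manifest

    def test_run_all_summary_matches_truth(self, tmp_path):
        manifest = self._make_inputs(tmp_path)
        out = tmp_path / "run"
        _run(["run-all", "--manifest", str(manifest), "--out", str(out)])
        summary = json.loads((out / "summary.json").read_text())
        assert summary["a_pheromone"]["n_putatively_functional"] == 1
        assert summary["alpha_pheromone"]["n_calls"] == 2
        assert summary["receptors"]["n_candidates"] == 3
        assert (out / "run.log").read_text().count("status=done") >= 4

    def test_rerun_is_byte_identical(self, tmp_path):
        manifest = self._make_inputs(tmp_path)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        _run(["run-all", "--manifest", str(manifest), "--out", str(out1)])
        _run(["run-all", "--manifest", str(manifest), "--out", str(out2)])
        for f in sorted(out1.iterdir()):
            assert (out2 / f.name).read_bytes() == f.read_bytes(), f.name

    def test_empty_manifest_gives_valid_outputs(self, tmp_path):
        manifest = tmp_path / "m.yaml"
        manifest.write_text("")
        summary = run_pipeline(Manifest.from_yaml(manifest), PipelineConfig(),
                               tmp_path / "empty")
        assert set(summary) == {"config_hash", "seed"}
        assert (tmp_path / "empty" / "summary.json").exists()

    def test_unknown_manifest_key_rejected(self, tmp_path):
        manifest = tmp_path / "m.yaml"
        manifest.write_text("genomes: x.fasta\n")
        with pytest.raises(ValueError, match="genomes"):
            Manifest.from_yaml(manifest)
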