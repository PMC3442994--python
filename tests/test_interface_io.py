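"""Fixture integrity, observation IO, configuration and the CLI surface."""

import dataclasses
import hashlib
import json
import textwrap
from importlib import resources

import pandas as pd
import pytest
from click.testing import CliRunner

from ogeshift.cli import main as cli_main
from ogeshift.interface_io import (
    FIXTURE_FILES,
    FIXTURE_ROW_COUNTS,
    RunConfig,
    fixture_observations,
    load_fixture,
    read_observations,
    run_pipeline,
    write_observations,
)
from ogeshift.oge_model import StripLayout
from ogeshift.synthetic_data import SimulationConfig, simulate_paired_dataset

# guards the transcribed tables against silent edits
FIXTURE_SHA256 = {
    "basic_shift_A": "8408d87f50601588b83d6e49680e19bb69f644db61891d27b26223c6db1e01e2",
    "same_fraction_B": "ba73c3220f36ec54a3d2fc98e6cd41b29f02399bb0d35d0ed522779d8c1026da",
    "acidic_shift_C": "e61570239847249b3573151b99326911517270d6e39de7a7b83ef3ad53c14cb3",
}


class TestFixtures:
    @pytest.mark.parametrize("name,count", sorted(FIXTURE_ROW_COUNTS.items()))
    def test_row_counts(self, name, count):
        assert len(load_fixture(name)) == count

    def test_flags_preserved_verbatim(self):
        table_a = load_fixture("basic_shift_A")
        assert list(table_a.loc[table_a["flags"] == "$", "sequence"]) == [
            "QYAVFDEK", "QLDSHIEEQFGGGR"]
        table_b = load_fixture("same_fraction_B")
        assert (table_b["flags"] == "*").sum() == 10
        table_c = load_fixture("acidic_shift_C")
        assert list(table_c.loc[table_c["flags"] == "$", "sequence"]) == [
            "QFNGLVDVYKK"]

    @pytest.mark.parametrize("name", sorted(FIXTURE_FILES))
    def test_checksums(self, name):
        blob = (resources.files("ogeshift.data") / FIXTURE_FILES[name]).read_bytes()
        assert hashlib.sha256(blob).hexdigest() == FIXTURE_SHA256[name]

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture("no_such_table")

    def test_fixture_observations_pair_up(self):
        obs = fixture_observations("acidic_shift_C")
        assert len(obs) == 22  # one unlabelled + one labelled row per peptide


class TestObservationIO:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_proteins=2, protein_length=100)
        data = simulate_paired_dataset(cfg)
        path = tmp_path / "obs.tsv"
        write_observations(path, data.observations)
        back = read_observations(path)
        assert [(o.sequence, o.label_state, o.fractions) for o in back] == [
            (o.sequence, o.label_state, o.fractions) for o in data.observations]

    def test_out_of_range_fraction_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "sequence\tlabel_state\texperiment_id\tfractions\n"
            "AYLEDFYR\tunlabelled\te1\t3\n"
            "AYLEDFYR\tlabelled\te1\t13\n")
        with pytest.raises(ValueError, match="bad.tsv:3"):
            read_observations(path)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sequence\tlabel_state\texperiment_id\tfractions\n")
        assert read_observations(path) == []

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("sequence\tfractions\nAYLEDFYR\t3\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_observations(path)


class TestRunConfig:
    def test_from_toml_overrides(self, tmp_path):
        path = tmp_path / "run.toml"
        path.write_text(textwrap.dedent("""\
            min_replicates = 2
            shift_threshold = 1.0
            [layout]
            ph_min = 3.0
            ph_max = 11.0
            n_wells = 24
            [pka_overrides]
            n_terminus = 9.0
            K = 10.5
        """))
        cfg = RunConfig.from_toml(path)
        assert cfg.min_replicates == 2
        assert cfg.layout == StripLayout(3.0, 11.0, 24)
        assert cfg.pka_table.n_terminus == 9.0
        assert cfg.pka_table.side_chain["K"] == 10.5

    def test_overrides_do_not_touch_the_packaged_default(self):
        from ogeshift.charge_model import default_pka_table

        before = default_pka_table().n_terminus
        default_pka_table().override(n_terminus=1.0)
        assert default_pka_table().n_terminus == before


class TestPipeline:
    def test_fixture_replay_counts(self, tmp_path):
        cfg = dataclasses.replace(RunConfig(), min_replicates=1,
                                  output_dir=tmp_path / "out")
        obs = fixture_observations("acidic_shift_C")
        bundle = run_pipeline(cfg, obs)
        assert bundle["summary"]["n_pairs"] == 11
        assert bundle["summary"]["counts_per_group"] == {"acidic_C": 11}
        summary = json.loads((tmp_path / "out" / "run_summary.json").read_text())
        assert summary["counts_per_group"] == {"acidic_C": 11}
        assert (tmp_path / "out" / "classification.tsv").exists()

    def test_replayed_fixture_pair_totals(self):
        cfg = dataclasses.replace(RunConfig(), min_replicates=1)
        for name, count in FIXTURE_ROW_COUNTS.items():
            bundle = run_pipeline(cfg, fixture_observations(name))
            assert bundle["summary"]["n_pairs"] == count

    def test_empty_input_runs_clean(self):
        bundle = run_pipeline(RunConfig(), [])
        assert bundle["summary"]["n_pairs"] == 0
        assert bundle["summary"]["counts_per_group"] == {}

    def test_two_runs_write_identical_outputs(self, tmp_path):
        obs = fixture_observations("acidic_shift_C")
        texts = []
        for sub in ("a", "b"):
            cfg = dataclasses.replace(RunConfig(), min_replicates=1,
                                      output_dir=tmp_path / sub)
            run_pipeline(cfg, obs)
            texts.append((tmp_path / sub / "classification.tsv").read_text())
        assert texts[0] == texts[1]


class TestCli:
    def test_mass_subcommand(self):
        result = CliRunner().invoke(cli_main, ["mass", "ECADLWPR"])
        assert result.exit_code == 0
        assert "1190.57" in result.output

    def test_pi_subcommand_reports_acidic_shift(self):
        result = CliRunner().invoke(cli_main, ["pi", "ASALIQHEWRPK"])
        assert result.exit_code == 0
        assert "-" in result.output.splitlines()[1].split("\t")[-1]

    def test_simulate_then_classify(self, tmp_path):
        runner = CliRunner()
        obs_path = tmp_path / "sim.tsv"
        truth_path = tmp_path / "truth.tsv"
        result = runner.invoke(cli_main, [
            "simulate", "--seed", "4", "--n-proteins", "3",
            "--out", str(obs_path), "--truth-out", str(truth_path)])
        assert result.exit_code == 0, result.output
        result = runner.invoke(cli_main, [
            "classify", str(obs_path), "--out", str(tmp_path / "res")])
        assert result.exit_code == 0, result.output
        counts = json.loads(result.output)
        truth = pd.read_csv(truth_path, sep="\t")
        assert sum(counts.values()) == len(truth)

    def test_fixtures_listing(self):
        result = CliRunner().invoke(cli_main, ["fixtures"])
        assert result.exit_code == 0
        assert "acidic_shift_C" in result.output
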