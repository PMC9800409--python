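"""Network spec parsing, synthetic generation, and the command line."""

import json

import pytest
from click.testing import CliRunner

from beqbn import (
    NetworkSpecError,
    TwoStageNetwork,
    generate_random_networks,
    parse_network_spec,
    write_network_spec,
)
from beqbn.cli import main
from beqbn.simulate import EDGE_PRIORS


class TestNetworkSpecIO:
    def test_parse_valid_yaml_spec(self, tmp_path):
        path = tmp_path / "net.yaml"
        path.write_text("prior_a1: 0.5\np_b1_given_a1: 0.97\np_b1_given_a2: 0.84\n")
        net = parse_network_spec(path)
        assert (net.p_a1, net.p_b1_given_a1, net.p_b1_given_a2) == (0.5, 0.97, 0.84)

    def test_missing_key_has_distinct_message(self, tmp_path):
        path = tmp_path / "net.yaml"
        path.write_text("prior_a1: 0.5\np_b1_given_a1: 0.97\n")
        with pytest.raises(NetworkSpecError, match="missing required key.*p_b1_given_a2"):
            parse_network_spec(path)

    def test_out_of_range_probability_has_distinct_message(self, tmp_path):
        path = tmp_path / "net.yaml"
        path.write_text("prior_a1: 1.2\np_b1_given_a1: 0.9\np_b1_given_a2: 0.8\n")
        with pytest.raises(NetworkSpecError, match="invalid probability"):
            parse_network_spec(path)

    def test_malformed_file_has_distinct_message(self, tmp_path):
        path = tmp_path / "net.yaml"
        path.write_text("{prior_a1: [unclosed\n")
        with pytest.raises(NetworkSpecError, match="malformed"):
            parse_network_spec(path)

    def test_round_trip_is_identity(self, tmp_path):
        net = TwoStageNetwork(
            0.37, 0.61, 0.05, labels=(("defect", "cooperate"), ("defect", "cooperate"))
        )
        path = tmp_path / "net.yaml"
        write_network_spec(net, path)
        assert parse_network_spec(path) == net


class TestSyntheticNetworks:
    def test_fixed_seed_is_reproducible(self):
        assert generate_random_networks(10, seed=7) == generate_random_networks(10, seed=7)

    def test_different_seeds_differ(self):
        assert generate_random_networks(10, seed=7) != generate_random_networks(10, seed=8)

    def test_every_batch_contains_the_edge_priors(self):
        nets = generate_random_networks(50, seed=1)
        priors = {n.p_a1 for n in nets}
        assert set(EDGE_PRIORS) <= priors

    def test_count_validated(self):
        with pytest.raises(ValueError):
            generate_random_networks(0, seed=1)


class TestCLI:
    runner = CliRunner()

    def test_predict_emits_breakdown_json(self, tmp_path):
        spec = tmp_path / "net.yaml"
        spec.write_text("prior_a1: 0.5\np_b1_given_a1: 0.97\np_b1_given_a2: 0.84\n")
        result = self.runner.invoke(main, ["predict", "--network", str(spec)])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert payload["probability"] == pytest.approx(0.6368509055297983, abs=1e-9)
        assert payload["classical_tpl"] == pytest.approx(0.905, abs=1e-12)
        assert payload["config"]["normalization"] == "clamp"

    def test_reproduce_writes_csv_and_provenance(self, tmp_path):
        out = tmp_path / "out"
        result = self.runner.invoke(main, ["reproduce", "--benchmark", "pd", "--out", str(out)])
        assert result.exit_code == 0, result.output
        csv_text = (out / "pd_errors.csv").read_text()
        assert csv_text.startswith("dataset,predictor,empirical,predicted,error,rmse")
        prov = json.loads((out / "pd_provenance.json").read_text())
        assert prov["config"]["interference_magnitude"] == "born_cross_term"
        assert len(prov["calibration"]["candidates"]) == 8

    def test_reproduce_is_bit_identical_across_runs(self, tmp_path):
        outputs = []
        for name in ("a", "b"):
            out = tmp_path / name
            self.runner.invoke(main, ["reproduce", "--benchmark", "faces", "--out", str(out)])
            outputs.append(
                (out / "faces_errors.csv").read_bytes()
                + (out / "faces_provenance.json").read_bytes()
            )
        assert outputs[0] == outputs[1]

    def test_calibrate_reports_grid_and_is_deterministic(self, tmp_path):
        runs = [
            self.runner.invoke(main, ["calibrate", "--out", str(tmp_path / f"{i}.json")])
            for i in range(2)
        ]
        assert all(r.exit_code == 0 for r in runs)
        assert (tmp_path / "0.json").read_bytes() == (tmp_path / "1.json").read_bytes()
        report = json.loads(runs[0].output)
        assert report["discrepancy"] in (True, False)
        assert {"pd_rmse", "faces_rmse"} <= set(report["candidates"][0])

    def test_simulate_is_bit_identical_for_a_fixed_seed(self):
        a = self.runner.invoke(main, ["simulate", "--count", "20", "--seed", "5"])
        b = self.runner.invoke(main, ["simulate", "--count", "20", "--seed", "5"])
        assert a.exit_code == 0 and a.output == b.output
        assert a.output.splitlines()[0].startswith("prior_a1,")
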