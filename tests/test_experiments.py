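"""Tests for the runner, convergence detection, truth tables, condition
classification, persistence and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from paingate import (
    Epoch,
    GateCircuit,
    InputPair,
    Phase,
    RunConfig,
    Scenario,
    scenario_standard,
    shift_from_threshold,
    standard_epoch,
)
from paingate.cli import main as cli_main
from paingate.experiments import (
    PARAM_COLUMNS,
    Trajectory,
    TruthTable,
    classify_condition,
    detect_convergence,
    load_trajectory,
    phase_sweep,
    run_scenario,
    save_trajectory,
    truth_table,
)


def synthetic_trajectory(values: np.ndarray) -> Trajectory:
    """Trajectory whose six parameter columns all follow ``values``."""
    n = len(values)
    data = pd.DataFrame({c: values for c in PARAM_COLUMNS})
    data.insert(0, "iteration", np.arange(1, n + 1))
    circuit = GateCircuit.from_values([0.5] * 4, [0.5, 0.5])
    return Trajectory(data, {"scenario": "synthetic"}, circuit, standard_epoch())


def table_from_o2(o2, intensities=(0.6, 0.3)) -> TruthTable:
    s, n = intensities
    return TruthTable(
        pd.DataFrame(
            {
                "I1": [0.0, s, 0.0, s],
                "I2": [0.0, 0.0, n, n],
                "net1": 0.0, "o1": 0.0, "net2": 0.0,
                "o2": list(o2),
            }
        )
    )


class TestDetectConvergence:
    def test_constant_trajectory_converges_to_the_constant(self):
        traj = synthetic_trajectory(np.full(300, 0.42))
        res = detect_convergence(traj)
        assert res.converged
        assert res.setpoint["w1"] == pytest.approx(0.42)
        assert res.setpoint["t1"] == pytest.approx(2 * 0.42 - 0.5)

    def test_square_wave_does_not_converge(self):
        wave = 0.5 + 0.05 * (-1.0) ** np.arange(300)
        assert not detect_convergence(synthetic_trajectory(wave)).converged

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="exceed window"):
            detect_convergence(synthetic_trajectory(np.ones(50)), window=100)


class TestTruthTable:
    def test_standard_setpoint_rows(self, standard_circuit):
        tt = truth_table(standard_circuit, standard_epoch())
        assert np.allclose(tt.table["net1"], [0.0, 0.6, 0.15, 0.75])
        # the sensory-only row's inhibition is the sigmoid rate O1 = 0.989,
        # not the thresholded bit 1: at k = 50 the saturation gap 0.09 above
        # threshold is e^(-4.5) ~ 0.011
        assert np.allclose(tt.table["net2"], [0.0, -1.0, 0.15, -0.85], atol=0.012)
        assert tt.binarized() == (0, 0, 1, 0)

    def test_pure_and_repeatable(self, standard_circuit):
        a = truth_table(standard_circuit, standard_epoch())
        b = truth_table(standard_circuit, standard_epoch())
        pd.testing.assert_frame_equal(a.table, b.table)


class TestClassifyCondition:
    @pytest.mark.parametrize(
        "o2, intensities, label",
        [
            ((0.1, 0.0, 0.9, 0.0), (0.6, 0.3), "normal"),
            ((0.1, 0.8, 0.9, 0.0), (0.3, 0.5), "dysesthesia"),
            ((0.9, 0.0, 0.9, 0.0), (0.6, 0.3), "wind_up"),
            ((0.9, 0.1, 0.8, 0.0), (0.1, 0.1), "phantom"),
            ((0.1, 0.2, 0.3, 0.1), (0.6, 0.3), "wind_down"),
            ((0.1, 0.0, 0.9, 0.9), (0.6, 0.3), "mixed"),
        ],
    )
    def test_rule_based_labels(self, o2, intensities, label):
        assert classify_condition(table_from_o2(o2, intensities)) == label

    def test_requires_four_rows(self):
        tt = TruthTable(pd.DataFrame({"I1": [0], "I2": [0], "o2": [0.0],
                                      "net1": [0.0], "o1": [0.0], "net2": [0.0]}))
        with pytest.raises(ValueError, match="four-row"):
            classify_condition(tt)


class TestRunScenario:
    def test_identical_seed_gives_bit_identical_trajectory(self):
        scen = scenario_standard(120)
        a = run_scenario(scen, 5)
        b = run_scenario(scen, 5)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert np.array_equal(
            a.final_circuit.parameter_vector(), b.final_circuit.parameter_vector()
        )

    def test_one_record_per_iteration_with_monotone_index(self):
        scen = scenario_standard(75)
        traj = run_scenario(scen, 1)
        assert len(traj) == 75
        assert (np.diff(traj.data["iteration"]) == 1).all()

    def test_frozen_phase_leaves_parameters_untouched(self):
        frozen = Scenario(
            "frozen-tail",
            (
                Phase(standard_epoch(), 30),
                Phase(standard_epoch(), 30, synaptic_plasticity=False,
                      intrinsic_plasticity=False),
            ),
        )
        traj = run_scenario(frozen, 3)
        tail = traj.data.tail(30)[PARAM_COLUMNS].to_numpy()
        assert np.ptp(tail, axis=0).max() == 0.0

    def test_nociceptive_only_response_rises_during_standard_training(self):
        # the nociceptive-only CT response climbs toward 1 within ~20 iterations
        traj = run_scenario(scenario_standard(150), 2)
        ribbon = traj.data["o2_nociceptive_only"]
        assert ribbon.tail(100).mean() > 0.9
        assert ribbon.iloc[:20].max() > 0.5


class TestPersistence:
    def test_csv_round_trip(self, tmp_path):
        traj = run_scenario(scenario_standard(60), 9, RunConfig(upsilon=0.07))
        path = save_trajectory(traj, tmp_path / "run.csv")
        loaded = load_trajectory(path)
        pd.testing.assert_frame_equal(loaded.data, traj.data)
        assert loaded.metadata["upsilon"] == 0.07
        assert loaded.metadata["seed"] == 9
        assert np.allclose(
            loaded.final_circuit.parameter_vector(),
            traj.final_circuit.parameter_vector(),
        )


class TestPhaseSweep:
    def test_standard_point_trains_to_normal_gating(self):
        labels = phase_sweep([0.6], [0.3], n_iterations=250, seed=0)
        assert labels.loc[0.3, 0.6] == "normal"

    def test_weak_sensory_only_point_trains_to_wind_up(self):
        labels = phase_sweep([0.1], [0.0], n_iterations=300, seed=0)
        assert labels.loc[0.0, 0.1] in {"wind_up", "phantom"}


class TestCli:
    def test_run_and_report(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "traj.csv"
        res = runner.invoke(
            cli_main,
            ["run", "--scenario", "standard", "--iterations", "200",
             "--seed", "3", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert "condition: normal" in res.output
        res = runner.invoke(cli_main, ["report", str(out), "--tol", "0.05"])
        assert res.exit_code == 0, res.output
        assert "converged" in res.output

    def test_run_accepts_scenario_file(self, tmp_path):
        scen_file = tmp_path / "scen.yaml"
        scen_file.write_text(scenario_standard(80).to_yaml())
        res = CliRunner().invoke(cli_main, ["run", "--scenario", str(scen_file)])
        assert res.exit_code == 0, res.output

    def test_sweep_prints_label_matrix(self, tmp_path):
        out = tmp_path / "labels.csv"
        res = CliRunner().invoke(
            cli_main,
            ["sweep", "--grid-step", "0.5", "--iterations", "120", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        assert out.exists()
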