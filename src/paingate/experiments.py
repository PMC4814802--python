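"""Simulation runner and analyses: trajectories, convergence detection,
truth tables, multi-initialisation studies, condition classification and the
input-intensity phase sweep.

A *trajectory* records the circuit's parameters once per iteration together
with the CT-neuron response to a fixed probe epoch, evaluated purely (the
probe never feeds plasticity).  A *truth table* is the circuit's pure
forward response to each pair of an epoch at a frozen parameter set, with an
optional 0.5 binarisation: "pain present" means the CT output rate exceeds
the sigmoid midpoint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .activation import DEFAULT_SLOPE_FACTOR
from .circuit import GateCircuit, InputPair, forward, run_epoch
from .plasticity import DEFAULT_DECAY, DEFAULT_UPSILON
from .protocols import Epoch, Phase, Scenario, combination_epoch

__all__ = [
    "RunConfig",
    "Trajectory",
    "TruthTable",
    "ConvergenceResult",
    "MultiInitResult",
    "run_scenario",
    "detect_convergence",
    "truth_table",
    "multi_init_study",
    "classify_condition",
    "phase_sweep",
    "save_trajectory",
    "load_trajectory",
]

PARAM_COLUMNS = ["w1", "w2", "w3", "w4", "s1", "s2"]
PROBE_COLUMNS = ["o2_null", "o2_sensory_only", "o2_nociceptive_only", "o2_both"]

#: CT output rate above which a response counts as "pain present".
PAIN_CUT = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Tunable simulation parameters shared by all runs."""

    upsilon: float = DEFAULT_UPSILON
    slope_factor: float = DEFAULT_SLOPE_FACTOR
    decay: float = DEFAULT_DECAY
    order: str = "fixed"
    inhibition: str = "rate"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthTable:
    """Pure forward response of a frozen circuit to each pair of an epoch."""

    table: pd.DataFrame  # columns: I1, I2, net1, o1, net2, o2

    @property
    def o2(self) -> np.ndarray:
        return self.table["o2"].to_numpy()

    def binarized(self, cut: float = PAIN_CUT) -> tuple[int, ...]:
        """Pain-present bits per row at the given CT-rate cut."""
        return tuple(int(v > cut) for v in self.o2)

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v: .4f}")


@dataclass
class Trajectory:
    """Per-iteration record of one scenario run plus its final state."""

    data: pd.DataFrame
    metadata: dict
    final_circuit: GateCircuit
    probe_epoch: Epoch

    def __len__(self) -> int:
        return len(self.data)

    def final_truth_table(self) -> TruthTable:
        return truth_table(self.final_circuit, self.probe_epoch)

    def setpoint(self, window: int = 100) -> dict[str, float]:
        """Trailing-window mean of every tracked parameter."""
        tail = self.data.tail(window)
        out = {c: float(tail[c].mean()) for c in PARAM_COLUMNS}
        out["t1"] = 2.0 * out["s1"] - 0.5
        out["t2"] = 2.0 * out["s2"] - 0.5
        return out

    def setpoint_circuit(self, window: int = 100) -> GateCircuit:
        """Frozen circuit at the trailing-window mean parameters."""
        sp = self.setpoint(window)
        return GateCircuit.from_values(
            [sp["w1"], sp["w2"], sp["w3"], sp["w4"]],
            [sp["s1"], sp["s2"]],
            slope_factor=self.metadata.get("slope_factor", DEFAULT_SLOPE_FACTOR),
            synaptic_plasticity_on=False,
            intrinsic_plasticity_on=False,
        )


@dataclass(frozen=True)
class ConvergenceResult:
    converged: bool
    setpoint: dict[str, float]
    max_change: float


@dataclass
class MultiInitResult:
    trajectories: list[Trajectory]
    setpoints: np.ndarray  # (n_runs, 6) in PARAM_COLUMNS order
    max_pairwise_distance: float
    truth_tables: list[TruthTable]
    patterns: list[tuple[int, ...]]


def _probe_o2(circuit: GateCircuit, probe: Epoch) -> list[float]:
    return [forward(circuit, pair).o2 for pair in probe]


def run_scenario(
    scenario: Scenario,
    seed: int,
    config: RunConfig | None = None,
    init: GateCircuit | None = None,
) -> Trajectory:
    """Execute a scenario's phases on one circuit, logging every iteration.

    The circuit starts from ``init`` or from Uniform(0, 1) weights and
    shifts drawn from the seeded generator.  Identical (scenario, seed,
    config) always yield a bit-identical trajectory.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(seed)
    circuit = (
        init.copy()
        if init is not None
        else GateCircuit.random_init(
            rng,
            slope_factor=cfg.slope_factor,
            upsilon=cfg.upsilon,
            decay=cfg.decay,
            inhibition=cfg.inhibition,
        )
    )
    probe = scenario.resolve_probe()
    records: list[list[float]] = []
    iteration = 0
    for phase in scenario.phases:
        circuit.synaptic_plasticity_on = phase.synaptic_plasticity
        circuit.intrinsic_plasticity_on = phase.intrinsic_plasticity
        for _ in range(phase.n_iterations):
            run_epoch(circuit, phase.epoch, rng, order=cfg.order)
            iteration += 1
            t1, t2 = circuit.thresholds
            records.append(
                [iteration, *circuit.weights, *circuit.shifts, t1, t2]
                + _probe_o2(circuit, probe)
            )
    columns = ["iteration", *PARAM_COLUMNS, "t1", "t2", *PROBE_COLUMNS[: len(probe)]]
    data = pd.DataFrame(records, columns=columns)
    metadata = {
        "scenario": scenario.name,
        "seed": int(seed),
        **cfg.to_dict(),
        "initial": None if init is None else list(init.parameter_vector()),
    }
    return Trajectory(data=data, metadata=metadata, final_circuit=circuit, probe_epoch=probe)


def detect_convergence(
    trajectory: Trajectory, window: int = 100, tol: float = 1e-3
) -> ConvergenceResult:
    """Trailing-window convergence test on every tracked parameter.

    Converged iff the max absolute change of each of w1..w4, s1, s2 over the
    last ``window`` iterations is below ``tol``.  The reported setpoint is
    the trailing-window mean, so novel attractors are detected without
    knowing them in advance.
    """
    if len(trajectory) <= window:
        raise ValueError(
            f"trajectory length {len(trajectory)} must exceed window {window}"
        )
    tail = trajectory.data.tail(window)[PARAM_COLUMNS].to_numpy()
    max_change = float(np.max(tail.max(axis=0) - tail.min(axis=0)))
    return ConvergenceResult(
        converged=max_change < tol,
        setpoint=trajectory.setpoint(window),
        max_change=max_change,
    )


def truth_table(circuit: GateCircuit, epoch: Epoch | Sequence[InputPair]) -> TruthTable:
    """Pure forward evaluation of the circuit on each pair of an epoch."""
    rows = []
    for pair in epoch:
        res = forward(circuit, pair)
        rows.append(
            {
                "I1": pair.sensory,
                "I2": pair.nociceptive,
                "net1": res.net1,
                "o1": res.o1,
                "net2": res.net2,
                "o2": res.o2,
            }
        )
    return TruthTable(pd.DataFrame(rows))


def multi_init_study(
    scenario: Scenario,
    n_runs: int = 5,
    seed: int = 0,
    config: RunConfig | None = None,
    setpoint_window: int = 100,
) -> MultiInitResult:
    """Run a scenario from independent random initialisations.

    Child seeds are spawned deterministically from ``seed``.  Reports the
    per-run trailing-window setpoints, the maximum pairwise distance between
    them (max-norm over w1..w4, s1, s2) and each run's final truth table.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    trajectories = [run_scenario(scenario, int(s), config) for s in child_seeds]
    setpoints = np.array(
        [[t.setpoint(setpoint_window)[c] for c in PARAM_COLUMNS] for t in trajectories]
    )
    dists = [
        np.max(np.abs(setpoints[i] - setpoints[j]))
        for i in range(n_runs)
        for j in range(i + 1, n_runs)
    ]
    tables = [
        truth_table(t.setpoint_circuit(setpoint_window), t.probe_epoch)
        for t in trajectories
    ]
    return MultiInitResult(
        trajectories=trajectories,
        setpoints=setpoints,
        max_pairwise_distance=float(max(dists)),
        truth_tables=tables,
        patterns=[tt.binarized() for tt in tables],
    )


def classify_condition(
    source: Trajectory | TruthTable, pain_cut: float = PAIN_CUT
) -> str:
    """Rule-based pain-condition label from a final test truth table.

    Expects the four-row combination order (null, sensory-only,
    nociceptive-only, both).  Labels:

    - ``wind_down``: every response below the cut (globally hyporesponsive);
    - ``phantom`` / ``wind_up``: pain at null input (phantom when the probe
      stimuli themselves are at most very weak, <= 0.2);
    - ``dysesthesia``: pain for the sensory-only input (allodynia-like);
    - ``normal``: pain for the nociceptive-only input and nowhere else;
    - ``mixed``: any other pattern.
    """
    tt = source.final_truth_table() if isinstance(source, Trajectory) else source
    if len(tt.table) != 4:
        raise ValueError("classification expects a four-row combination truth table")
    bits = tt.binarized(pain_cut)
    b_null, b_sens, b_noci, b_both = bits
    if not any(bits):
        return "wind_down"
    if b_null:
        max_input = float(tt.table[["I1", "I2"]].to_numpy().max())
        return "phantom" if max_input <= 0.2 else "wind_up"
    if b_sens:
        return "dysesthesia"
    if bits == (0, 0, 1, 0):
        return "normal"
    return "mixed"


def phase_sweep(
    sensory_grid: Sequence[float],
    nociceptive_grid: Sequence[float],
    n_iterations: int = 400,
    seed: int = 0,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Train a fresh circuit per (sensory, nociceptive) intensity pair and
    classify the resulting condition.

    Each grid point uses a combination epoch at those intensities for
    ``n_iterations`` iterations, then classifies the setpoint truth table.
    Returns a label matrix indexed by nociceptive intensity (rows) with
    sensory intensity columns.  Qualitatively, points below the diagonal
    (sensory > nociceptive) should train to ``normal``; above it, to
    dysesthesia-like conditions; very weak corners to wind-up/phantom.
    """
    labels = np.empty((len(nociceptive_grid), len(sensory_grid)), dtype=object)
    for i, noci in enumerate(nociceptive_grid):
        for j, sens in enumerate(sensory_grid):
            sub_seed = np.random.SeedSequence([seed, i, j]).generate_state(1)[0]
            scen = Scenario(
                name=f"sweep[{sens:.2f},{noci:.2f}]",
                phases=(Phase(combination_epoch(sens, noci), n_iterations),),
            )
            traj = run_scenario(scen, int(sub_seed), config)
            table = truth_table(traj.setpoint_circuit(), traj.probe_epoch)
            labels[i, j] = classify_condition(table)
    return pd.DataFrame(
        labels,
        index=pd.Index([round(v, 4) for v in nociceptive_grid], name="nociceptive"),
        columns=pd.Index([round(v, 4) for v in sensory_grid], name="sensory"),
    )


def save_trajectory(trajectory: Trajectory, csv_path: str | Path) -> Path:
    """Write a trajectory as CSV with a JSON metadata sidecar."""
    path = Path(csv_path)
    trajectory.data.to_csv(path, index=False)
    sidecar = path.with_suffix(".meta.json")
    meta = dict(trajectory.metadata)
    meta["final_parameters"] = {
        c: v for c, v in zip(PARAM_COLUMNS, trajectory.final_circuit.parameter_vector())
    }
    meta["probe"] = trajectory.probe_epoch.to_dict()
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_trajectory(csv_path: str | Path) -> Trajectory:
    """Reload a saved trajectory (final circuit rebuilt from the sidecar)."""
    path = Path(csv_path)
    data = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    fin = meta["final_parameters"]
    circuit = GateCircuit.from_values(
        [fin["w1"], fin["w2"], fin["w3"], fin["w4"]],
        [fin["s1"], fin["s2"]],
        slope_factor=meta.get("slope_factor", DEFAULT_SLOPE_FACTOR),
        synaptic_plasticity_on=False,
        intrinsic_plasticity_on=False,
    )
    probe = Epoch.from_dict(meta["probe"])
    return Trajectory(data=data, metadata=meta, final_circuit=circuit, probe_epoch=probe)
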