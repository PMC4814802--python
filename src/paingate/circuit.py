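"""The gate circuit: wiring, forward evaluation, and one plasticity step.

Two neurons implement the spinal gate.  The substantia gelatinosa (SG)
interneuron and the central transmission (CT) neuron each receive both
afferents through plastic excitatory synapses:

    w1: sensory -> SG      w2: sensory -> CT
    w3: nociceptive -> SG  w4: nociceptive -> CT

The SG neuron inhibits the CT neuron through a fixed, non-plastic synapse of
magnitude 1, so the forward pass is

    Net1 = w1*I1 + w3*I2          O1 = sigmoid(Net1; s1)
    Net2 = w2*I1 + w4*I2 - O1     O2 = sigmoid(Net2; s2)

with I1 the sensory (mechanoreceptor) and I2 the nociceptive firing
probability.  O2 is the pain signal relayed toward the brain.  By default
the inhibitory term uses the SG *rate* O1 (the expected-value view, which is
also how truth tables are computed); with the near-step sigmoid the rate
saturates to ~0/1 in the trained regimes, where this coincides with the
realized SG spike.  A ``"spike"`` inhibition mode, in which the plasticity
step gates the CT neuron with the sampled SG bit instead, is available as a
model variant; the two modes diverge only in regimes where the SG neuron
sits away from saturation (sustained sole-stimulus protocols).

A plasticity step samples fictitious spikes and applies both adaptation
rules.  Stochastic draws consume one shared generator in a fixed order per
presentation -- input bits i1, i2, then SG output bit, then CT output bit --
so runs are exactly reproducible from a seed.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .activation import DEFAULT_SLOPE_FACTOR, NeuronState, activate, net_input, sample_spike
from .plasticity import (
    DEFAULT_DECAY,
    DEFAULT_UPSILON,
    IntrinsicState,
    SynapseState,
    update_shift,
    update_weight,
)

__all__ = ["InputPair", "ForwardResult", "GateCircuit", "forward", "step", "run_epoch"]


@dataclass(frozen=True)
class InputPair:
    """One (sensory, nociceptive) pair of afferent firing probabilities."""

    sensory: float
    nociceptive: float

    def __post_init__(self) -> None:
        for name in ("sensory", "nociceptive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} firing probability must lie in [0, 1], got {v}")


class ForwardResult(NamedTuple):
    o1: float
    o2: float
    net1: float
    net2: float


@dataclass
class GateCircuit:
    """Wired SG/CT pair with four plastic weights and two plastic shifts."""

    w1: SynapseState
    w2: SynapseState
    w3: SynapseState
    w4: SynapseState
    sg: IntrinsicState
    ct: IntrinsicState
    slope_factor: float = DEFAULT_SLOPE_FACTOR
    synaptic_plasticity_on: bool = True
    intrinsic_plasticity_on: bool = True
    #: how the SG->CT inhibition enters the plasticity step: "spike" gates the
    #: CT neuron with the sampled SG spike (the realized inhibitory event),
    #: "rate" with the SG output rate O1.  Pure forward evaluation always uses
    #: the rate (the expected-value view, which truth tables report); the two
    #: coincide wherever the near-step sigmoid saturates.
    inhibition: str = "rate"

    @classmethod
    def from_values(
        cls,
        weights: Sequence[float],
        shifts: Sequence[float],
        *,
        slope_factor: float = DEFAULT_SLOPE_FACTOR,
        upsilon: float = DEFAULT_UPSILON,
        decay: float = DEFAULT_DECAY,
        synaptic_plasticity_on: bool = True,
        intrinsic_plasticity_on: bool = True,
        inhibition: str = "rate",
    ) -> "GateCircuit":
        """Build a circuit from plain weight and shift values."""
        if len(weights) != 4:
            raise ValueError("expected 4 weights (w1..w4)")
        if len(shifts) != 2:
            raise ValueError("expected 2 shifts (s1, s2)")
        syn = [SynapseState(weight=float(w), decay=decay) for w in weights]
        return cls(
            w1=syn[0],
            w2=syn[1],
            w3=syn[2],
            w4=syn[3],
            sg=IntrinsicState(shift=float(shifts[0]), rate=upsilon),
            ct=IntrinsicState(shift=float(shifts[1]), rate=upsilon),
            slope_factor=slope_factor,
            synaptic_plasticity_on=synaptic_plasticity_on,
            intrinsic_plasticity_on=intrinsic_plasticity_on,
            inhibition=inhibition,
        )

    @classmethod
    def random_init(
        cls,
        rng: np.random.Generator,
        *,
        slope_factor: float = DEFAULT_SLOPE_FACTOR,
        upsilon: float = DEFAULT_UPSILON,
        decay: float = DEFAULT_DECAY,
        inhibition: str = "rate",
    ) -> "GateCircuit":
        """Circuit with weights and shifts drawn Uniform(0, 1)."""
        return cls.from_values(
            rng.uniform(0.0, 1.0, size=4),
            rng.uniform(0.0, 1.0, size=2),
            slope_factor=slope_factor,
            upsilon=upsilon,
            decay=decay,
            inhibition=inhibition,
        )

    # -- convenience views ------------------------------------------------

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.w1.weight, self.w2.weight, self.w3.weight, self.w4.weight)

    @property
    def shifts(self) -> tuple[float, float]:
        return (self.sg.shift, self.ct.shift)

    @property
    def thresholds(self) -> tuple[float, float]:
        return (2.0 * self.sg.shift - 0.5, 2.0 * self.ct.shift - 0.5)

    def sg_neuron(self) -> NeuronState:
        return NeuronState(self.sg.shift, self.slope_factor, "SG")

    def ct_neuron(self) -> NeuronState:
        return NeuronState(self.ct.shift, self.slope_factor, "CT")

    def copy(self) -> "GateCircuit":
        return deepcopy(self)

    def parameter_vector(self) -> np.ndarray:
        """(w1, w2, w3, w4, s1, s2) as an array, for convergence tracking."""
        return np.array([*self.weights, *self.shifts])


def forward(circuit: GateCircuit, pair: InputPair) -> ForwardResult:
    """Pure forward evaluation of the gate on one input pair."""
    inputs = (pair.sensory, pair.nociceptive)
    net1 = net_input((circuit.w1.weight, circuit.w3.weight), inputs)
    o1 = activate(net1, circuit.sg_neuron())
    net2 = net_input((circuit.w2.weight, circuit.w4.weight), inputs, inhibitory_term=o1)
    o2 = activate(net2, circuit.ct_neuron())
    return ForwardResult(o1=o1, o2=o2, net1=net1, net2=net2)


def step(circuit: GateCircuit, pair: InputPair, rng: np.random.Generator) -> GateCircuit:
    """One presentation: forward pass plus both plasticity updates (in place).

    Fictitious spikes are drawn in fixed order (i1, i2, o1, o2).  Weight
    updates share the neuron's single postsynaptic bit across its two
    synapses; each afferent contributes one presynaptic bit.  Shifts then
    move toward this presentation's output rates.  With both plasticity
    flags off the circuit is returned untouched.
    """
    res = forward(circuit, pair)
    if circuit.synaptic_plasticity_on or circuit.intrinsic_plasticity_on:
        i1 = sample_spike(pair.sensory, rng)
        i2 = sample_spike(pair.nociceptive, rng)
        o1 = sample_spike(res.o1, rng)
        if circuit.inhibition == "spike":
            # CT sees the realized SG spike this presentation, so its output
            # rate is conditional on whether inhibition actually arrived.
            net2 = net_input(
                (circuit.w2.weight, circuit.w4.weight),
                (pair.sensory, pair.nociceptive),
                inhibitory_term=float(o1),
            )
            o2_rate = activate(net2, circuit.ct_neuron())
        elif circuit.inhibition == "rate":
            o2_rate = res.o2
        else:
            raise ValueError(f"inhibition must be 'spike' or 'rate', got {circuit.inhibition!r}")
        o2 = sample_spike(o2_rate, rng)
        if circuit.synaptic_plasticity_on:
            circuit.w1 = update_weight(circuit.w1, i1, o1)
            circuit.w3 = update_weight(circuit.w3, i2, o1)
            circuit.w2 = update_weight(circuit.w2, i1, o2)
            circuit.w4 = update_weight(circuit.w4, i2, o2)
        if circuit.intrinsic_plasticity_on:
            circuit.sg = update_shift(circuit.sg, res.o1)
            circuit.ct = update_shift(circuit.ct, o2_rate)
    return circuit


def run_epoch(
    circuit: GateCircuit,
    epoch: "Sequence[InputPair]",
    rng: np.random.Generator,
    order: str = "fixed",
) -> GateCircuit:
    """One iteration: present every pair of the epoch once.

    ``order`` is ``"fixed"`` (epoch order as given) or ``"shuffled"``
    (a fresh seeded permutation per iteration).
    """
    pairs = list(epoch)
    if not pairs:
        raise ValueError("epoch must contain at least one input pair")
    if order == "shuffled":
        pairs = [pairs[k] for k in rng.permutation(len(pairs))]
    elif order != "fixed":
        raise ValueError(f"order must be 'fixed' or 'shuffled', got {order!r}")
    for pair in pairs:
        step(circuit, pair, rng)
    return circuit
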