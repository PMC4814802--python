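"""The two adaptation rules: probabilistic synaptic plasticity and intrinsic
(threshold) plasticity.

Synaptic weights follow the presynaptic rule: a weight is the conditional
probability that the postsynaptic neuron spikes given a presynaptic spike,

    w = P(o | i) = n(o AND i) / n(i),

estimated from fictitious binary spikes sampled from the pre- and
postsynaptic rates.  Left alone this rule is self-reinforcing (more
correlation -> larger weight -> more correlation) and drives weights toward
saturation at 1.

Intrinsic plasticity counterbalances it by dragging the activation-function
shift toward the neuron's recent output,

    s_t = (v * O_{t-1} + s_{t-1}) / (v + 1),

so a chronically active neuron raises its threshold and a silent one lowers
it.  The interplay of the two rules is what lets the gate circuit's
parameters stabilise at a finite setpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "DEFAULT_UPSILON",
    "DEFAULT_DECAY",
    "SynapseState",
    "IntrinsicState",
    "update_weight",
    "update_shift",
]

#: Default adaptation rate of intrinsic plasticity ("small arbitrary factor").
#: 0.05 re-adapts within a few tens of iterations without oscillating hard
#: against the near-step sigmoid.
DEFAULT_UPSILON = 0.05

#: Default forgetting factor of the spike-count tallies used in scenario runs.
#: 1.0 is exact lifetime counting; 0.99 keeps an effective memory of ~100
#: presentations so the circuit can re-converge after a regime change.
DEFAULT_DECAY = 0.99


@dataclass
class SynapseState:
    """One plastic excitatory synapse.

    ``weight`` is the conditional probability P(post-spike | pre-spike);
    ``joint_count`` and ``pre_count`` are the (optionally decayed) tallies of
    coincident spikes n(o AND i) and presynaptic spikes n(i) that estimate it.
    While ``pre_count`` is zero the weight keeps its initialisation value:
    the conditional probability is undefined and never divided through zero.
    """

    weight: float
    joint_count: float = 0.0
    pre_count: float = 0.0
    decay: float = 1.0
    plastic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")
        if self.joint_count < 0 or self.pre_count < 0:
            raise ValueError("spike counts must be nonnegative")
        if self.joint_count > self.pre_count + 1e-12:
            raise ValueError("joint_count cannot exceed pre_count")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay must lie in (0, 1], got {self.decay}")


@dataclass
class IntrinsicState:
    """Intrinsic-plasticity state of one neuron: shift ``s`` and rate ``v``."""

    shift: float
    rate: float = DEFAULT_UPSILON
    plastic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 1.0:
            raise ValueError(f"shift must lie in [0, 1], got {self.shift}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def _check_bit(value: int, name: str) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")
    return int(value)


def update_weight(state: SynapseState, pre_bit: int, post_bit: int) -> SynapseState:
    """One presentation's update of the conditional-probability weight.

    Tallies are decayed then incremented; the weight is re-estimated as
    joint/pre whenever a presynaptic spike has ever been seen.  With
    ``decay = 1`` this is exact cumulative counting n(o AND i)/n(i).
    Returns a new state; the input is not mutated.  Non-plastic synapses
    pass through unchanged.
    """
    if not state.plastic:
        return state
    i = _check_bit(pre_bit, "pre_bit")
    o = _check_bit(post_bit, "post_bit")
    joint = state.decay * state.joint_count + i * o
    pre = state.decay * state.pre_count + i
    weight = joint / pre if pre > 0 else state.weight
    return replace(state, joint_count=joint, pre_count=pre, weight=weight)


def update_shift(state: IntrinsicState, prev_output: float) -> IntrinsicState:
    """One presentation's update of the activation-function shift.

    ``s <- (v * O + s) / (v + 1)`` with ``O`` the neuron's output rate at the
    previous presentation.  The update is a convex combination of ``s`` and
    ``O``, so the shift stays in [0, 1] and moves strictly toward ``O``
    (geometric approach with ratio 1/(1 + v) under a constant output).
    """
    if not state.plastic:
        return state
    if not 0.0 <= prev_output <= 1.0:
        raise ValueError(f"prev_output must lie in [0, 1], got {prev_output}")
    shift = (state.rate * prev_output + state.shift) / (state.rate + 1.0)
    return replace(state, shift=shift)
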