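"""Rate-code neuron primitives.

The circuit's two neurons are phenomenological rate-code units: inputs and
outputs are firing probabilities in [0, 1].  The activation function is a
steep sigmoid whose horizontal position is set by a shift parameter ``s``:

    O = 1 / (1 + exp(-k * (net + 0.5 - 2 s)))

``s`` determines the firing threshold ``t = 2 s - 0.5``, defined as the net
input at which the neuron fires with probability 0.5.  With ``s = 0`` the
sigmoid sits fully leftward (a zero net input already fires the neuron,
O ~ 1); with ``s = 1`` it sits fully rightward (even a net input of 1 leaves
O ~ 0).  The slope factor ``k`` (default 50) makes the sigmoid nearly a step
so rate outputs saturate at 0 or 1 except in a narrow band around threshold.

The exponent -k*(net + 0.5 - 2s) is the unique reading of the activation
formula consistent with both limit cases above and with t = 2s - 0.5; other
parenthesisations put the midpoint elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_SLOPE_FACTOR",
    "NeuronState",
    "net_input",
    "activate",
    "threshold_from_shift",
    "shift_from_threshold",
    "sample_spike",
]

#: Curve-compressing factor of the sigmoid; 50 gives a near-step transition.
DEFAULT_SLOPE_FACTOR = 50.0


@dataclass
class NeuronState:
    """Intrinsic parameters of one rate-code neuron.

    Parameters
    ----------
    shift : float
        Position parameter ``s`` of the activation sigmoid, in [0, 1].
    slope_factor : float
        Steepness ``k`` of the sigmoid (positive).
    label : str
        Identifier, conventionally ``"SG"`` (substantia gelatinosa
        interneuron) or ``"CT"`` (central transmission neuron).
    """

    shift: float
    slope_factor: float = DEFAULT_SLOPE_FACTOR
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift <= 1.0:
            raise ValueError(f"shift must lie in [0, 1], got {self.shift}")
        if self.slope_factor <= 0:
            raise ValueError("slope_factor must be positive")

    @property
    def threshold(self) -> float:
        """Firing threshold ``t = 2 s - 0.5`` (net input giving O = 0.5)."""
        return threshold_from_shift(self.shift)


def net_input(
    weights: Sequence[float],
    inputs: Sequence[float],
    inhibitory_term: float = 0.0,
) -> float:
    """Weighted sum of excitatory inputs minus an inhibitory contribution.

    ``net = sum_j w_j I_j - inhibitory_term``.  All afferent synapses are
    excitatory; the only inhibition in the circuit is the fixed SG -> CT
    projection, passed here as ``inhibitory_term`` (0 for the SG neuron, the
    SG output rate for the CT neuron).
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(inputs, dtype=float)
    if w.shape != x.shape:
        raise ValueError(
            f"weights and inputs must have equal length, got {w.shape} vs {x.shape}"
        )
    if w.size and (w.min() < 0 or w.max() > 1):
        raise ValueError("weights must lie in [0, 1]")
    if x.size and (x.min() < 0 or x.max() > 1):
        raise ValueError("inputs must lie in [0, 1]")
    if inhibitory_term < 0:
        raise ValueError("inhibitory_term must be nonnegative")
    return float(np.dot(w, x) - inhibitory_term)


def activate(net: float, state: NeuronState) -> float:
    """Firing probability of a neuron with net input ``net``.

    Strictly increasing in ``net``, strictly decreasing in the shift, and
    exactly 0.5 at ``net = threshold(shift)``.
    """
    z = state.slope_factor * (net + 0.5 - 2.0 * state.shift)
    # Guard against overflow in exp for strongly negative arguments.
    if z >= 0:
        return float(1.0 / (1.0 + np.exp(-z)))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


def threshold_from_shift(shift: float) -> float:
    """Firing threshold ``t = 2 s - 0.5`` for a shift ``s`` in [0, 1]."""
    if not 0.0 <= shift <= 1.0:
        raise ValueError(f"shift must lie in [0, 1], got {shift}")
    return 2.0 * shift - 0.5


def shift_from_threshold(threshold: float) -> float:
    """Inverse of :func:`threshold_from_shift`: ``s = (t + 0.5) / 2``."""
    shift = (threshold + 0.5) / 2.0
    if not 0.0 <= shift <= 1.0:
        raise ValueError(f"threshold must lie in [-0.5, 1.5], got {threshold}")
    return shift


def sample_spike(probability: float, rng: np.random.Generator) -> int:
    """Bernoulli draw of a binary spike from a firing probability."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {probability}")
    return int(rng.random() < probability)
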