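"""Stimulation protocols: epochs, the verbal-intensity scale, and the
scenario scripts for the pain conditions studied with the model.

An *epoch* is the set of input combinations presented within one iteration;
the standard epoch covers the four presence/absence combinations with a
medium-intense sensory input (0.6) and a weak nociceptive one (0.3) -- the
physiological asymmetry between myelinated mechanoreceptor afferents and
unmyelinated nociceptors.  A *scenario* is a sequence of phases, each an
epoch presented for a span of iterations with the plasticity rules switched
on or off, modelling how a pain condition develops out of a normally trained
gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import yaml

from .circuit import InputPair

__all__ = [
    "Epoch",
    "Scenario",
    "Phase",
    "INTENSITY_SCALE",
    "intensity",
    "intensity_interval",
    "standard_epoch",
    "combination_epoch",
    "single_epoch",
    "scenario_standard",
    "scenario_phantom",
    "scenario_demyelinating",
    "scenario_breakthrough",
    "scenario_wind_down",
    "scenario_wind_up",
    "scenario_dual_intense",
    "SCENARIO_BUILDERS",
    "get_scenario",
]

# Standard stimulation intensities: mechanoreceptor afferents fire at a
# higher rate than unmyelinated nociceptive ones.
STANDARD_SENSORY = 0.6
STANDARD_NOCICEPTIVE = 0.3

#: Verbal intensity -> (half-open probability interval, representative value).
INTENSITY_SCALE: Mapping[str, tuple[tuple[float, float], float]] = {
    "very intense": ((0.8, 1.0), 0.9),
    "intense": ((0.6, 0.8), 0.7),
    "medium": ((0.4, 0.6), 0.5),
    "weak": ((0.25, 0.4), 0.3),
    "very weak": ((0.0, 0.20), 0.1),
}


def intensity(label: str) -> float:
    """Representative firing probability for a verbal intensity label."""
    key = label.strip().lower().replace("_", " ")
    try:
        return INTENSITY_SCALE[key][1]
    except KeyError:
        raise ValueError(
            f"unknown intensity label {label!r}; known: {sorted(INTENSITY_SCALE)}"
        ) from None


def intensity_interval(label: str) -> tuple[float, float]:
    """The probability interval associated with a verbal intensity label."""
    key = label.strip().lower().replace("_", " ")
    try:
        return INTENSITY_SCALE[key][0]
    except KeyError:
        raise ValueError(f"unknown intensity label {label!r}") from None


@dataclass(frozen=True)
class Epoch:
    """Ordered set of input pairs presented within one iteration."""

    pairs: tuple[InputPair, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("an epoch needs at least one input pair")

    def __iter__(self) -> Iterator[InputPair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_dict(self) -> list[dict[str, float]]:
        return [{"sensory": p.sensory, "nociceptive": p.nociceptive} for p in self.pairs]

    @classmethod
    def from_dict(cls, data: Sequence[Mapping[str, float]]) -> "Epoch":
        return cls(tuple(InputPair(d["sensory"], d["nociceptive"]) for d in data))


def combination_epoch(sensory: float, nociceptive: float) -> Epoch:
    """The four presence/absence combinations at given intensities.

    Order: (0,0), (S,0), (0,N), (S,N) -- null, sensory-only,
    nociceptive-only, both.
    """
    return Epoch(
        (
            InputPair(0.0, 0.0),
            InputPair(sensory, 0.0),
            InputPair(0.0, nociceptive),
            InputPair(sensory, nociceptive),
        )
    )


def standard_epoch() -> Epoch:
    """Standard training epoch: sensory 0.6 (medium-intense), nociceptive 0.3 (weak)."""
    return combination_epoch(STANDARD_SENSORY, STANDARD_NOCICEPTIVE)


def single_epoch(sensory: float, nociceptive: float) -> Epoch:
    """Degenerate epoch of one pair (sole-stimulus phases)."""
    return Epoch((InputPair(sensory, nociceptive),))


@dataclass(frozen=True)
class Phase:
    """One scenario phase: an epoch for a span of iterations with flags."""

    epoch: Epoch
    n_iterations: int
    synaptic_plasticity: bool = True
    intrinsic_plasticity: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "pairs": self.epoch.to_dict(),
            "iterations": self.n_iterations,
            "synaptic_plasticity": self.synaptic_plasticity,
            "intrinsic_plasticity": self.intrinsic_plasticity,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Phase":
        return cls(
            epoch=Epoch.from_dict(data["pairs"]),
            n_iterations=int(data["iterations"]),
            synaptic_plasticity=bool(data.get("synaptic_plasticity", True)),
            intrinsic_plasticity=bool(data.get("intrinsic_plasticity", True)),
        )


@dataclass(frozen=True)
class Scenario:
    """A named phase sequence modelling one pain condition.

    ``probe_epoch`` is the epoch used for read-out: trajectory logging and
    the final truth table evaluate the circuit on it without perturbing the
    dynamics.  It defaults to the last four-pair epoch of the scenario, or
    the standard epoch if none exists.
    """

    name: str
    phases: tuple[Phase, ...]
    probe_epoch: Epoch | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("a scenario needs at least one phase")

    @property
    def total_iterations(self) -> int:
        return sum(p.n_iterations for p in self.phases)

    def resolve_probe(self) -> Epoch:
        if self.probe_epoch is not None:
            return self.probe_epoch
        for phase in reversed(self.phases):
            if len(phase.epoch) == 4:
                return phase.epoch
        return standard_epoch()

    def to_dict(self) -> dict:
        out = {"name": self.name, "phases": [p.to_dict() for p in self.phases]}
        if self.probe_epoch is not None:
            out["probe"] = self.probe_epoch.to_dict()
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "Scenario":
        probe = data.get("probe")
        return cls(
            name=data["name"],
            phases=tuple(Phase.from_dict(p) for p in data["phases"]),
            probe_epoch=Epoch.from_dict(probe) if probe is not None else None,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


def _standard_phase(n: int = 50) -> Phase:
    return Phase(standard_epoch(), n)


def scenario_standard(n: int = 150) -> Scenario:
    """Standard stimulation only: the healthy gate training regime."""
    return Scenario("standard", (_standard_phase(n),))


def scenario_phantom() -> Scenario:
    """Amputation model: standard training, then silence, then weak neuroma
    firing.  Plasticity stays on throughout."""
    vw = intensity("very weak")
    return Scenario(
        "phantom",
        (
            _standard_phase(),
            Phase(combination_epoch(0.0, 0.0), 50),
            Phase(combination_epoch(vw, vw), 50),
        ),
        probe_epoch=combination_epoch(vw, vw),
    )


def scenario_demyelinating(weakened_sensory: float = 0.3, raised_nociceptive: float = 0.5) -> Scenario:
    """Demyelination weakens the sensory afferent to nociceptive-like rates;
    a later event raises nociceptive intensity to medium."""
    return Scenario(
        "demyelinating",
        (
            _standard_phase(),
            Phase(combination_epoch(weakened_sensory, STANDARD_NOCICEPTIVE), 50),
            Phase(combination_epoch(weakened_sensory, raised_nociceptive), 50),
        ),
    )


def scenario_breakthrough(intense_nociceptive: float | None = None) -> Scenario:
    """Sustained intense nociception on top of normal touch."""
    noc = intensity("intense") if intense_nociceptive is None else intense_nociceptive
    return Scenario(
        "breakthrough",
        (
            _standard_phase(),
            Phase(combination_epoch(STANDARD_SENSORY, noc), 100),
        ),
    )


def scenario_wind_down() -> Scenario:
    """Constant maximal nociceptive input, then a frozen-plasticity test on
    the standard combinations."""
    return Scenario(
        "wind_down",
        (
            _standard_phase(),
            Phase(single_epoch(0.0, 1.0), 50),
            Phase(standard_epoch(), 50, synaptic_plasticity=False, intrinsic_plasticity=False),
        ),
        probe_epoch=standard_epoch(),
    )


def scenario_wind_up() -> Scenario:
    """Repetitive weak sensory stimulation alone, then a frozen test."""
    return Scenario(
        "wind_up",
        (
            _standard_phase(),
            Phase(single_epoch(intensity("very weak"), 0.0), 50),
            Phase(standard_epoch(), 50, synaptic_plasticity=False, intrinsic_plasticity=False),
        ),
        probe_epoch=standard_epoch(),
    )


def scenario_dual_intense() -> Scenario:
    """Both afferents very intense simultaneously, then a frozen test on the
    very-intense combinations."""
    vi = intensity("very intense")
    return Scenario(
        "dual_intense",
        (
            _standard_phase(),
            Phase(single_epoch(vi, vi), 50),
            Phase(combination_epoch(vi, vi), 50, synaptic_plasticity=False, intrinsic_plasticity=False),
        ),
        probe_epoch=combination_epoch(vi, vi),
    )


SCENARIO_BUILDERS = {
    "standard": scenario_standard,
    "phantom": scenario_phantom,
    "demyelinating": scenario_demyelinating,
    "breakthrough": scenario_breakthrough,
    "wind_down": scenario_wind_down,
    "wind_up": scenario_wind_up,
    "dual_intense": scenario_dual_intense,
}


def get_scenario(name: str, **kwargs) -> Scenario:
    """Look up a built-in scenario by name."""
    try:
        return SCENARIO_BUILDERS[name](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; known: {sorted(SCENARIO_BUILDERS)}"
        ) from None
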