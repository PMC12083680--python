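"""Parameter containers for the closed-loop left-heart circuit.

Units follow clinical hemodynamics convention throughout the package:
pressure mmHg, volume mL, flow mL/s, time s, resistance mmHg*s/mL,
compliance mL/mmHg, elastance mmHg/mL.

The circuit topology is fixed:

    PV -> LA -> MV -> LV -> AoV -> SA -> SV -> RA -> TV -> RV -> PuV -> PA -> PV

with four elastance chambers (LA, LV, RA, RV), four linear RC vascular
compartments (SA, SV, PA, PV: systemic/pulmonary arterial and venous),
and four ideal unidirectional valves (MV, AoV, TV, PuV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

CHAMBER_LABELS: Tuple[str, ...] = ("LA", "LV", "RA", "RV")
COMPARTMENT_LABELS: Tuple[str, ...] = ("SA", "SV", "PA", "PV")
VALVE_LABELS: Tuple[str, ...] = ("MV", "AoV", "TV", "PuV")
ATRIAL_LABELS: Tuple[str, ...] = ("LA", "RA")

#: State-vector ordering used by the simulation engine (topology order).
ELEMENT_ORDER: Tuple[str, ...] = ("LA", "LV", "SA", "SV", "RA", "RV", "PA", "PV")


class ParameterError(ValueError):
    """Raised when a parameter value violates its physical constraints."""


def _require(cond: bool, key: str, constraint: str) -> None:
    if not cond:
        raise ParameterError(f"{key}: {constraint}")


@dataclass(frozen=True)
class ElastanceParams:
    """Blended time-varying elastance law for one chamber.

    Active (end-systolic) limb: ``ees * (v - v0)``.
    Passive (end-diastolic) limb: ``a_res * (exp(b_res * (v - v0)) - 1)``,
    the exponential reservoir curve.

    Parameters
    ----------
    ees : float
        End-systolic elastance, mmHg/mL.
    v0 : float
        Unstressed (zero-pressure) volume, mL.
    a_res : float
        Passive-stiffness amplitude, mmHg.
    b_res : float
        Passive-stiffness exponent, 1/mL.
    """

    ees: float
    v0: float
    a_res: float
    b_res: float

    def __post_init__(self) -> None:
        _require(self.ees >= 0, "ees", "must be >= 0")
        _require(self.v0 >= 0, "v0", "must be >= 0")
        _require(self.a_res >= 0, "a_res", "must be >= 0")
        _require(self.b_res > 0, "b_res", "must be > 0")


@dataclass(frozen=True)
class ChamberParams:
    """One cardiac chamber: constitutive law plus an activation window.

    ``activation_onset`` and ``activation_duration`` are fractions of the
    current cycle length; the window may wrap across the cycle boundary
    (interpreted modulo 1). Activation rises from 0 at the window edges
    to exactly 1 at its midpoint.

    ``wall_resistance`` (mmHg*s/mL) is the viscoelastic wall term used
    by the simulation engine: the chamber node pressure is the elastic
    pressure plus ``wall_resistance * dV/dt``, which gives the
    pressure-volume trajectory its reservoir-phase hysteresis.

    ``activation_amplitude`` scales the activation peak in [0, 1]; it is
    the 0D analogue of the actuation-pressure knob on a benchtop
    actuator (1 = full contraction, 0 = no contraction).
    """

    label: str
    constitutive: ElastanceParams
    activation_onset: float
    activation_duration: float
    wall_resistance: float = 0.0
    activation_amplitude: float = 1.0

    def __post_init__(self) -> None:
        _require(self.label in CHAMBER_LABELS, "label",
                 f"must be one of {CHAMBER_LABELS}")
        _require(self.wall_resistance >= 0, "wall_resistance",
                 "must be >= 0")
        _require(0.0 <= self.activation_amplitude <= 1.0,
                 "activation_amplitude", "must lie in [0, 1]")
        _require(0.0 <= self.activation_onset < 1.0, "activation_onset",
                 "must lie in [0, 1)")
        _require(0.0 < self.activation_duration <= 1.0, "activation_duration",
                 "must lie in (0, 1]")

    @property
    def is_atrial(self) -> bool:
        return self.label in ATRIAL_LABELS


@dataclass(frozen=True)
class ValveParams:
    """Ideal unidirectional valve: linear conductance, zero backflow."""

    label: str
    resistance: float

    def __post_init__(self) -> None:
        _require(self.label in VALVE_LABELS, "label",
                 f"must be one of {VALVE_LABELS}")
        _require(self.resistance > 0, "resistance", "must be > 0")


@dataclass(frozen=True)
class VascularCompartmentParams:
    """Linear capacitor with a resistive outflow path (RC windkessel node)."""

    label: str
    compliance: float
    outflow_resistance: float
    unstressed_volume: float

    def __post_init__(self) -> None:
        _require(self.label in COMPARTMENT_LABELS, "label",
                 f"must be one of {COMPARTMENT_LABELS}")
        _require(self.compliance > 0, "compliance", "must be > 0")
        _require(self.outflow_resistance > 0, "outflow_resistance",
                 "must be > 0")
        _require(self.unstressed_volume >= 0, "unstressed_volume",
                 "must be >= 0")


@dataclass(frozen=True)
class RhythmSchedule:
    """Cycle-length schedule, repeated cyclically.

    A uniform rhythm has one entry (60/bpm seconds). The irregular AF
    schedule cycles through its entries in order. ``atrial_active`` turns
    atrial contraction on or off globally (off for flutter/AF).
    ``av_delay`` is the interval by which the atrial activation peak
    precedes ventricular activation onset, in seconds; it is consumed by
    the circuit builders when placing the atrial activation window.
    """

    cycle_lengths: Tuple[float, ...]
    atrial_active: bool = True
    av_delay: float = 0.16

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycle_lengths",
                           tuple(float(c) for c in self.cycle_lengths))
        _require(len(self.cycle_lengths) > 0, "cycle_lengths",
                 "must be non-empty")
        _require(all(c > 0 for c in self.cycle_lengths), "cycle_lengths",
                 "every cycle length must be > 0")
        _require(0.0 <= self.av_delay < min(self.cycle_lengths), "av_delay",
                 "must be >= 0 and < the shortest cycle length")

    @property
    def period(self) -> float:
        """Length of one full schedule repetition, s."""
        return float(sum(self.cycle_lengths))

    @property
    def mean_rate_bpm(self) -> float:
        return 60.0 * len(self.cycle_lengths) / self.period


@dataclass(frozen=True)
class CircuitParams:
    """Complete closed-loop circuit: chambers, compartments, valves,
    rhythm and total blood volume."""

    chambers: Mapping[str, ChamberParams]
    compartments: Mapping[str, VascularCompartmentParams]
    valves: Mapping[str, ValveParams]
    rhythm: RhythmSchedule
    total_volume: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "chambers", dict(self.chambers))
        object.__setattr__(self, "compartments", dict(self.compartments))
        object.__setattr__(self, "valves", dict(self.valves))
        _require(set(self.chambers) == set(CHAMBER_LABELS), "chambers",
                 f"labels must be exactly {set(CHAMBER_LABELS)}")
        _require(set(self.compartments) == set(COMPARTMENT_LABELS),
                 "compartments",
                 f"labels must be exactly {set(COMPARTMENT_LABELS)}")
        _require(set(self.valves) == set(VALVE_LABELS), "valves",
                 f"labels must be exactly {set(VALVE_LABELS)}")
        for name, group in (("chambers", self.chambers),
                            ("compartments", self.compartments),
                            ("valves", self.valves)):
            for label, obj in group.items():
                _require(obj.label == label, name,
                         f"key {label!r} does not match element label "
                         f"{obj.label!r}")
        _require(self.total_volume > self.unstressed_volume, "total_volume",
                 "must exceed the sum of unstressed volumes "
                 f"({self.unstressed_volume:.1f} mL)")

    @property
    def unstressed_volume(self) -> float:
        """Sum of all unstressed volumes, mL."""
        return (sum(c.constitutive.v0 for c in self.chambers.values())
                + sum(c.unstressed_volume
                      for c in self.compartments.values()))

    @property
    def stressed_volume(self) -> float:
        return self.total_volume - self.unstressed_volume

    # -- functional update helpers (scenario constructors are pure) ------

    def with_la_constitutive(self, **changes: float) -> "CircuitParams":
        """Return a copy with updated LA constitutive parameters."""
        la = self.chambers["LA"]
        new = replace(la, constitutive=replace(la.constitutive, **changes))
        chambers = dict(self.chambers)
        chambers["LA"] = new
        return replace(self, chambers=chambers)

    def with_rhythm(self, rhythm: RhythmSchedule) -> "CircuitParams":
        return replace(self, rhythm=rhythm)


# -- dotted-path access used by calibration and the JSON config layer ----

def get_param(circuit: CircuitParams, path: str) -> float:
    """Read a scalar parameter by dotted path.

    Examples: ``"total_volume"``, ``"chambers.LV.constitutive.ees"``,
    ``"compartments.SA.outflow_resistance"``, ``"valves.MV.resistance"``.
    """
    obj: object = circuit
    for part in path.split("."):
        if isinstance(obj, Mapping):
            if part not in obj:
                raise ParameterError(f"{path}: unknown label {part!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"{path}: unknown field {part!r}")
            obj = getattr(obj, part)
    if not isinstance(obj, (int, float)):
        raise ParameterError(f"{path}: not a scalar parameter")
    return float(obj)


def set_param(circuit: CircuitParams, path: str, value: float) -> CircuitParams:
    """Return a copy of ``circuit`` with the parameter at ``path`` set."""
    parts = path.split(".")

    def _set(obj: object, parts: Sequence[str]) -> object:
        head, rest = parts[0], parts[1:]
        if isinstance(obj, Mapping):
            if head not in obj:
                raise ParameterError(f"{path}: unknown label {head!r}")
            new = dict(obj)
            new[head] = _set(obj[head], rest)
            return new
        if not hasattr(obj, head):
            raise ParameterError(f"{path}: unknown field {head!r}")
        if not rest:
            return replace(obj, **{head: float(value)})  # type: ignore[arg-type]
        return replace(obj, **{head: _set(getattr(obj, head), rest)})  # type: ignore[arg-type]

    if len(parts) == 1:
        return replace(circuit, **{parts[0]: float(value)})
    return replace(circuit, **{parts[0]: _set(getattr(circuit, parts[0]),
                                              parts[1:])})
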