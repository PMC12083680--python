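"""Configuration and waveform I/O.

Circuit configurations are JSON objects with one section per element.
The LA block uses the model's published symbol names (``la_ees``,
``la_v0``, ``la_a_res``, ``la_b_res``); every other element is
namespaced the same way (``lv_ees``, ..., ``mv_resistance``). Unknown
keys are rejected, and constraint violations name the offending key.

Waveforms travel as tidy CSV: a mandatory ``time_s`` column followed by
``p_<element>``, ``v_<element>`` and ``q_<edge>`` columns (mmHg, mL,
mL/s), comma-separated, ``.`` decimal, UTF-8, header mandatory. Partial
traces are allowed on read: a file with only ``time_s, p_la, v_la``
supports mean-LAP and PV-loop analysis.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .engine import FLOW_EDGES, SimulationResult, beat_boundaries
from .params import (
    CHAMBER_LABELS,
    COMPARTMENT_LABELS,
    ELEMENT_ORDER,
    VALVE_LABELS,
    ChamberParams,
    CircuitParams,
    ElastanceParams,
    ParameterError,
    RhythmSchedule,
    ValveParams,
    VascularCompartmentParams,
)


class ConfigError(ValueError):
    """Raised for a malformed configuration file."""


_CHAMBER_KEYS = ("ees", "v0", "a_res", "b_res",
                 "activation_onset", "activation_duration",
                 "wall_resistance", "activation_amplitude")
_COMPARTMENT_KEYS = ("compliance", "outflow_resistance", "unstressed_volume")
_RHYTHM_KEYS = ("cycle_lengths", "atrial_active", "av_delay")
_TOP_KEYS = tuple(l.lower() for l in CHAMBER_LABELS) + \
    tuple(l.lower() for l in COMPARTMENT_LABELS) + ("valves", "rhythm",
                                                    "total_volume")


def circuit_to_dict(circuit: CircuitParams) -> Dict[str, object]:
    out: Dict[str, object] = {}
    for label in CHAMBER_LABELS:
        ch = circuit.chambers[label]
        lx = label.lower()
        out[lx] = {
            f"{lx}_ees": ch.constitutive.ees,
            f"{lx}_v0": ch.constitutive.v0,
            f"{lx}_a_res": ch.constitutive.a_res,
            f"{lx}_b_res": ch.constitutive.b_res,
            "activation_onset": ch.activation_onset,
            "activation_duration": ch.activation_duration,
            "wall_resistance": ch.wall_resistance,
            "activation_amplitude": ch.activation_amplitude,
        }
    for label in COMPARTMENT_LABELS:
        co = circuit.compartments[label]
        out[label.lower()] = {
            "compliance": co.compliance,
            "outflow_resistance": co.outflow_resistance,
            "unstressed_volume": co.unstressed_volume,
        }
    out["valves"] = {f"{l.lower()}_resistance": circuit.valves[l].resistance
                     for l in VALVE_LABELS}
    out["rhythm"] = {
        "cycle_lengths": list(circuit.rhythm.cycle_lengths),
        "atrial_active": circuit.rhythm.atrial_active,
        "av_delay": circuit.rhythm.av_delay,
    }
    out["total_volume"] = circuit.total_volume
    return out


def _section(data: Dict[str, object], name: str) -> Dict[str, object]:
    if name not in data:
        raise ConfigError(f"missing section {name!r}")
    sec = data[name]
    if not isinstance(sec, dict):
        raise ConfigError(f"section {name!r} must be a JSON object")
    return sec


def _num(sec: Dict[str, object], section: str, key: str) -> float:
    if key not in sec:
        raise ConfigError(f"{section}.{key}: missing")
    v = sec[key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        raise ConfigError(f"{section}.{key}: must be a number")
    return float(v)


def circuit_from_dict(data: Dict[str, object]) -> CircuitParams:
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a JSON object")
    unknown = set(data) - set(_TOP_KEYS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    chambers = {}
    for label in CHAMBER_LABELS:
        lx = label.lower()
        sec = _section(data, lx)
        allowed = {f"{lx}_{k}" for k in ("ees", "v0", "a_res", "b_res")} | \
            {"activation_onset", "activation_duration", "wall_resistance",
             "activation_amplitude"}
        extra = set(sec) - allowed
        if extra:
            raise ConfigError(f"{lx}: unknown key(s) {sorted(extra)}")
        try:
            constitutive = ElastanceParams(
                ees=_num(sec, lx, f"{lx}_ees"),
                v0=_num(sec, lx, f"{lx}_v0"),
                a_res=_num(sec, lx, f"{lx}_a_res"),
                b_res=_num(sec, lx, f"{lx}_b_res"))
            chambers[label] = ChamberParams(
                label=label, constitutive=constitutive,
                activation_onset=_num(sec, lx, "activation_onset"),
                activation_duration=_num(sec, lx, "activation_duration"),
                wall_resistance=(_num(sec, lx, "wall_resistance")
                                 if "wall_resistance" in sec else 0.0),
                activation_amplitude=(_num(sec, lx, "activation_amplitude")
                                      if "activation_amplitude" in sec
                                      else 1.0))
        except ParameterError as err:
            msg = str(err)
            prefix = f"{lx}." if msg.startswith("activation") else f"{lx}.{lx}_"
            raise ConfigError(prefix + msg) from err

    compartments = {}
    for label in COMPARTMENT_LABELS:
        lx = label.lower()
        sec = _section(data, lx)
        extra = set(sec) - set(_COMPARTMENT_KEYS)
        if extra:
            raise ConfigError(f"{lx}: unknown key(s) {sorted(extra)}")
        try:
            compartments[label] = VascularCompartmentParams(
                label=label,
                compliance=_num(sec, lx, "compliance"),
                outflow_resistance=_num(sec, lx, "outflow_resistance"),
                unstressed_volume=_num(sec, lx, "unstressed_volume"))
        except ParameterError as err:
            raise ConfigError(f"{lx}.{err}") from err

    vsec = _section(data, "valves")
    allowed_v = {f"{l.lower()}_resistance" for l in VALVE_LABELS}
    extra = set(vsec) - allowed_v
    if extra:
        raise ConfigError(f"valves: unknown key(s) {sorted(extra)}")
    try:
        valves = {l: ValveParams(l, _num(vsec, "valves",
                                         f"{l.lower()}_resistance"))
                  for l in VALVE_LABELS}
    except ParameterError as err:
        raise ConfigError(f"valves.{err}") from err

    rsec = _section(data, "rhythm")
    extra = set(rsec) - set(_RHYTHM_KEYS)
    if extra:
        raise ConfigError(f"rhythm: unknown key(s) {sorted(extra)}")
    cls = rsec.get("cycle_lengths")
    if (not isinstance(cls, list) or not cls
            or not all(isinstance(c, (int, float)) and not isinstance(c, bool)
                       for c in cls)):
        raise ConfigError("rhythm.cycle_lengths: must be a non-empty "
                          "list of numbers")
    active = rsec.get("atrial_active", True)
    if not isinstance(active, bool):
        raise ConfigError("rhythm.atrial_active: must be a boolean")
    try:
        rhythm = RhythmSchedule(cycle_lengths=tuple(float(c) for c in cls),
                                atrial_active=active,
                                av_delay=_num(rsec, "rhythm", "av_delay"))
    except ParameterError as err:
        raise ConfigError(f"rhythm.{err}") from err

    tv = data.get("total_volume")
    if not isinstance(tv, (int, float)) or isinstance(tv, bool):
        raise ConfigError("total_volume: missing or not a number")
    try:
        return CircuitParams(chambers=chambers, compartments=compartments,
                             valves=valves, rhythm=rhythm,
                             total_volume=float(tv))
    except ParameterError as err:
        raise ConfigError(str(err)) from err


def load_config(path) -> CircuitParams:
    """Load and validate a circuit configuration JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as err:
            raise ConfigError(f"{path}: invalid JSON ({err})") from err
    return circuit_from_dict(data)


def save_config(circuit: CircuitParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(circuit_to_dict(circuit), fh, indent=2, sort_keys=True)
        fh.write("\n")


def packaged_config(name: str) -> Path:
    """Path to a packaged reference configuration (``baseline_sinus``
    or ``laao``)."""
    p = Path(__file__).parent / "data" / f"{name}.json"
    if not p.exists():
        raise ConfigError(f"no packaged config named {name!r}")
    return p


# ---------------------------------------------------------------------
# waveform CSV

def waveform_frame(result: SimulationResult) -> pd.DataFrame:
    cols: Dict[str, np.ndarray] = {"time_s": result.time}
    for label in ELEMENT_ORDER:
        if label in result.pressures:
            cols[f"p_{label.lower()}"] = result.pressures[label]
    for label in ELEMENT_ORDER:
        if label in result.volumes:
            cols[f"v_{label.lower()}"] = result.volumes[label]
    for edge in FLOW_EDGES:
        if edge in result.flows:
            cols[f"q_{edge.lower()}"] = result.flows[edge]
    return pd.DataFrame(cols)


def write_waveforms(result: SimulationResult, path) -> None:
    """Write traces to CSV at full double precision."""
    waveform_frame(result).to_csv(path, index=False, float_format="%.17g")


def read_waveforms(path, *, rhythm: Optional[RhythmSchedule] = None,
                   cycle_length: Optional[float] = None) -> SimulationResult:
    """Read a waveform CSV back into a :class:`SimulationResult`.

    Beat boundaries are reconstructed from ``rhythm`` or a uniform
    ``cycle_length`` when given; otherwise the whole span is treated as
    a single analysis interval.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ConfigError(f"{path}: missing mandatory column 'time_s'")
    known_p = {f"p_{l.lower()}": l for l in ELEMENT_ORDER}
    known_v = {f"v_{l.lower()}": l for l in ELEMENT_ORDER}
    known_q = {f"q_{e.lower()}": e for e in FLOW_EDGES}
    bad = [c for c in df.columns
           if c != "time_s" and c not in known_p
           and c not in known_v and c not in known_q]
    if bad:
        raise ConfigError(f"{path}: unrecognized column(s) {bad}; expected "
                          "time_s, p_<element>, v_<element>, q_<edge>")
    t = df["time_s"].to_numpy(dtype=float)
    pressures = {known_p[c]: df[c].to_numpy(dtype=float)
                 for c in df.columns if c in known_p}
    volumes = {known_v[c]: df[c].to_numpy(dtype=float)
               for c in df.columns if c in known_v}
    flows = {known_q[c]: df[c].to_numpy(dtype=float)
             for c in df.columns if c in known_q}
    if rhythm is not None:
        beats = beat_boundaries(rhythm, float(t[-1]))
    elif cycle_length is not None:
        beats = beat_boundaries(RhythmSchedule((float(cycle_length),),
                                               av_delay=0.0),
                                float(t[-1]))
        beats = beats + t[0]
    else:
        beats = np.array([t[0], t[-1]])
    return SimulationResult(time=t, pressures=pressures, volumes=volumes,
                            flows=flows, beat_times=beats, circuit=None,
                            diagnostics={"source": str(path)})
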