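"""Constitutive laws of the circuit elements.

Chamber pressure is the standard blended time-varying elastance
(Suga-Sagawa convention):

    P(v, e) = e * Ees * (v - V0) + (1 - e) * A_res * (exp(B_res*(v - V0)) - 1)

so that the active end-systolic line is recovered at e = 1 and the
exponential passive (reservoir) curve at e = 0. Valves are ideal linear
diodes; vascular compartments are linear capacitors.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .params import (
    ChamberParams,
    ElastanceParams,
    RhythmSchedule,
    ValveParams,
    VascularCompartmentParams,
)


class ActivationError(ValueError):
    """Raised for an activation value outside [0, 1]."""


def chamber_pressure(v, e, params: ElastanceParams):
    """Chamber pressure (mmHg) at volume ``v`` (mL) and activation ``e``.

    Accepts scalars or numpy arrays for ``v`` and ``e``.
    """
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < 0.0) or np.any(e_arr > 1.0):
        raise ActivationError(f"activation must lie in [0, 1], got {e!r}")
    dv = np.asarray(v, dtype=float) - params.v0
    active = params.ees * dv
    passive = params.a_res * np.expm1(params.b_res * dv)
    out = e_arr * active + (1.0 - e_arr) * passive
    return float(out) if out.ndim == 0 else out


def passive_chamber_pressure(v, params: ElastanceParams):
    """End-diastolic (e = 0) limb of :func:`chamber_pressure`."""
    return chamber_pressure(v, 0.0, params)


def cycle_at(t: float, rhythm: RhythmSchedule) -> Tuple[float, float]:
    """Return ``(cycle_start, cycle_length)`` for time ``t`` (s).

    Cycle boundaries coincide with ventricular activation onsets; the
    schedule repeats cyclically from t = 0.
    """
    period = rhythm.period
    n_reps = math.floor(t / period)
    tm = t - n_reps * period
    start = n_reps * period
    for cl in rhythm.cycle_lengths:
        if tm < cl:
            return start, cl
        tm -= cl
        start += cl
    # roundoff can land tm exactly on the repetition boundary
    return start, rhythm.cycle_lengths[0]


def activation(t: float, chamber: ChamberParams,
               rhythm: RhythmSchedule) -> float:
    """Normalized activation e(t) in [0, 1] for one chamber.

    Squared half-sine within the chamber's activation window (a fraction
    of the current cycle, interpreted modulo 1 so the window may wrap
    across the cycle boundary): zero at the window edges, peaking at the
    chamber's ``activation_amplitude`` (exactly 1 for a full-strength
    chamber) at the midpoint, zero outside. Atrial chambers return
    identically 0 when ``rhythm.atrial_active`` is false.
    """
    if chamber.is_atrial and not rhythm.atrial_active:
        return 0.0
    if t < 0:
        raise ValueError("t must be >= 0")
    start, cl = cycle_at(t, rhythm)
    phase = (t - start) / cl
    phi = (phase - chamber.activation_onset) % 1.0
    if phi >= chamber.activation_duration:
        return 0.0
    return (chamber.activation_amplitude
            * math.sin(math.pi * phi / chamber.activation_duration) ** 2)


def valve_flow(p_up: float, p_down: float, valve: ValveParams) -> float:
    """Flow (mL/s) through an ideal diode valve; never negative."""
    return max(0.0, p_up - p_down) / valve.resistance


def compartment_pressure(v, comp: VascularCompartmentParams):
    """Pressure (mmHg) of a linear vascular capacitor at volume ``v``."""
    out = (np.asarray(v, dtype=float) - comp.unstressed_volume) / comp.compliance
    return float(out) if out.ndim == 0 else out
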