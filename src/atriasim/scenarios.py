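"""Scenario builders: pure transformations of a base circuit.

Each condition studied with the model is a parameter variant of the
baseline closed loop:

* ``apply_laao`` -- the published post-occlusion LA parameter set
  (stiffer reservoir, reduced reservoir amplitude, higher Ees);
* ``make_flutter`` -- uniform (typically rapid) rhythm with atrial
  contraction disabled;
* ``make_af`` -- irregular cycle-length schedule with atrial
  contraction disabled;
* ``scale_atrial_contractility`` -- multiplicative factor on the LA
  activation amplitude, the 0D analogue of turning down atrial
  actuation pressure;
* ``set_heart_rate`` -- uniform rate change with rate-corrected
  activation timing.

Rate correction: the systolic actuation time is held constant in
absolute terms (0.3 s, emulating a fixed-duration pneumatic actuation
and the near-rate-invariance of systole), so at rapid rates diastole
collapses and ventricular filling time shrinks -- the mechanism behind
the reduced cardiac output of a rapid ventricular response. Window
*fractions* are rescaled accordingly (identity at the 1 s reference
cycle), and the AV delay shortens as sqrt(T). Activation amplitude
derates as (T / 1 s)^0.5 for cycles shorter than 1 s: pneumatic
actuators lose stroke at rapid pacing, and the muscle force-frequency
response flattens -- the second mechanism (with the shrinking filling
window) behind the diminished output and elevated diastolic
ventricular pressure of a rapid ventricular response.

Constructors never mutate the base circuit, and variants acting on
independent parameter sets compose in any order.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

from .params import (
    ChamberParams,
    CircuitParams,
    ParameterError,
    RhythmSchedule,
)

HR_MIN, HR_MAX = 40.0, 150.0

#: Irregular cycle-length schedule representing AF (s).
AF_CYCLE_LENGTHS = (0.375, 0.4, 0.5)

#: Systolic-duration law t_sys = SYS_INTERCEPT + SYS_SLOPE * T (seconds):
#: constant absolute systolic time across rates.
SYS_INTERCEPT = 0.30
SYS_SLOPE = 0.0

#: Exponent of the rapid-pacing amplitude derating (T/1s)^AMP_EXPONENT.
AMP_EXPONENT = 0.5


def _check_rate(bpm: float) -> None:
    if not HR_MIN <= bpm <= HR_MAX:
        raise ParameterError(
            f"heart rate {bpm} bpm outside supported range "
            f"[{HR_MIN:.0f}, {HR_MAX:.0f}]")


def _fraction_scale(T: float) -> float:
    """Ratio of an activation-window fraction at cycle length ``T`` to
    its value at the 1 s reference cycle."""
    return (SYS_INTERCEPT + SYS_SLOPE * T) / ((SYS_INTERCEPT + SYS_SLOPE) * T)


def _retime(base: CircuitParams, rhythm: RhythmSchedule) -> CircuitParams:
    """Return a copy of ``base`` on ``rhythm`` with activation windows
    rescaled by the systolic-duration law.

    Window fractions are mapped through their 1 s reference values, so
    retiming is idempotent and independent of the rate the base
    circuit happens to be at. Atrial windows are re-anchored so the
    activation peak precedes the cycle end by the (sqrt-shortened) AV
    delay.
    """
    t_old = base.rhythm.period / len(base.rhythm.cycle_lengths)
    t_new = rhythm.period / len(rhythm.cycle_lengths)
    scale = _fraction_scale(t_new) / _fraction_scale(t_old)
    amp_scale = (min(1.0, t_new ** AMP_EXPONENT)
                 / min(1.0, t_old ** AMP_EXPONENT))
    av_ref = base.rhythm.av_delay / (t_old ** 0.5)
    av_new = min(av_ref * t_new ** 0.5, 0.45 * min(rhythm.cycle_lengths))
    chambers: Mapping[str, ChamberParams] = {}
    for label, ch in base.chambers.items():
        dur = min(0.9, ch.activation_duration * scale)
        amp = min(1.0, ch.activation_amplitude * amp_scale)
        if ch.is_atrial:
            onset = (1.0 - av_new / t_new - dur / 2.0) % 1.0
        else:
            onset = ch.activation_onset
        chambers[label] = replace(ch, activation_onset=onset,
                                  activation_duration=dur,
                                  activation_amplitude=amp)
    return replace(base, chambers=chambers,
                   rhythm=replace(rhythm, av_delay=av_new))


def apply_laao(base: CircuitParams) -> CircuitParams:
    """Apply the post-appendage-occlusion LA parameter changes.

    Loss of the appendage's reservoir contribution is modelled purely
    through the LA constitutive law: a_res -> 0.35, b_res -> 0.07
    (stiffer, lower-amplitude passive curve) and ees -> 0.7 mmHg/mL
    (reduced compliance). Absolute overwrites, hence idempotent.
    """
    return base.with_la_constitutive(a_res=0.35, b_res=0.07, ees=0.7)


def make_flutter(base: CircuitParams, rate: float = 150.0) -> CircuitParams:
    """Atrial flutter: uniform rhythm at ``rate`` bpm, no atrial kick.

    Ventricular activation keeps its rate-corrected timing; atrial
    activation is identically zero, reducing the LA to its passive
    reservoir curve.
    """
    _check_rate(rate)
    rhythm = RhythmSchedule(cycle_lengths=(60.0 / rate,),
                            atrial_active=False,
                            av_delay=0.0)
    return _retime(base, rhythm)


def make_af(base: CircuitParams,
            cycle_lengths: Sequence[float] = AF_CYCLE_LENGTHS
            ) -> CircuitParams:
    """Irregular-cycle atrial fibrillation.

    The rhythm cycles repeatedly through ``cycle_lengths`` (default
    0.375, 0.4, 0.5 s -- mean rate ~141 bpm) with atrial contraction
    disabled. A single-entry list reduces to a uniform rhythm.
    """
    if len(cycle_lengths) == 0:
        raise ParameterError("cycle_lengths: must be non-empty")
    cl = tuple(float(c) for c in cycle_lengths)
    rhythm = RhythmSchedule(cycle_lengths=cl, atrial_active=False,
                            av_delay=0.0)
    return _retime(base, rhythm)


def scale_atrial_contractility(base: CircuitParams,
                               k: float) -> CircuitParams:
    """Scale the LA activation amplitude by ``k`` in [0, 1].

    The active pressure term scales by ``k`` at every instant, so k = 0
    restores the passive reservoir curve (flutter-like loss of atrial
    kick) and k = 1 is the identity. Passive (reservoir) parameters are
    untouched.
    """
    if not 0.0 <= k <= 1.0:
        raise ParameterError(f"contractility scale {k} outside [0, 1]")
    la = base.chambers["LA"]
    chambers = dict(base.chambers)
    chambers["LA"] = replace(
        la, activation_amplitude=k * la.activation_amplitude)
    return replace(base, chambers=chambers)


def set_heart_rate(base: CircuitParams, bpm: float) -> CircuitParams:
    """Uniform rhythm at ``bpm`` with rate-corrected activation timing."""
    _check_rate(bpm)
    rhythm = replace(base.rhythm, cycle_lengths=(60.0 / bpm,))
    return _retime(base, rhythm)
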