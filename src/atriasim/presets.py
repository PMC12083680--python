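"""Reference circuits.

The left-atrial constitutive parameters are the published values of the
model this package implements (Ees 0.45 mmHg/mL, V0 0 mL, A_res 0.5,
B_res 0.049; see :func:`atriasim.scenarios.apply_laao` for the
post-occlusion set). All other parameters are a calibrated stand-in:
they were fitted once, with the calibration module, so that the 60 bpm
baseline reproduces the operating points of the benchtop loop the model
mirrors (aortic pressure ~115/60 mmHg, left-ventricular ~120/6 mmHg,
cardiac output > 5 L/min, mean left-atrial pressure 17.1 mmHg).
Compliances are compact, mock-loop-scale values rather than textbook
whole-body ones: the loop emulates a benchtop circuit with small
acrylic compliance chambers.
"""

from __future__ import annotations

from .params import (
    ChamberParams,
    CircuitParams,
    ElastanceParams,
    RhythmSchedule,
    ValveParams,
    VascularCompartmentParams,
)

#: Published left-atrial constitutive parameters (baseline, pre-occlusion).
LA_BASELINE = ElastanceParams(ees=0.45, v0=0.0, a_res=0.5, b_res=0.049)

#: Published left-atrial parameter changes after appendage occlusion.
LA_POST_LAAO = ElastanceParams(ees=0.7, v0=0.0, a_res=0.35, b_res=0.07)

#: Ventricular systole occupies the first 30% of each cycle; atrial
#: systole is a 20%-wide window whose peak precedes the next ventricular
#: onset by the AV delay (0.16 s at 60 bpm -> peak at phase 0.84).
VENTRICULAR_ONSET = 0.0
VENTRICULAR_DURATION = 0.30
ATRIAL_DURATION = 0.20


def _atrial_onset(av_delay: float, cycle_length: float) -> float:
    """Window onset placing the atrial activation peak ``av_delay``
    seconds before the next ventricular onset (cycle end)."""
    peak = 1.0 - av_delay / cycle_length
    return (peak - ATRIAL_DURATION / 2.0) % 1.0


def baseline_sinus(heart_rate_bpm: float = 60.0,
                   av_delay: float = 0.16) -> CircuitParams:
    """Calibrated baseline circuit in sinus rhythm.

    Parameters
    ----------
    heart_rate_bpm : float
        Uniform heart rate, beats per minute (40-150).
    av_delay : float
        Atrial-peak to ventricular-onset interval, s.
    """
    cl = 60.0 / heart_rate_bpm
    rhythm = RhythmSchedule(cycle_lengths=(cl,), atrial_active=True,
                            av_delay=av_delay)
    a_onset = _atrial_onset(av_delay, cl)
    chambers = {
        "LA": ChamberParams("LA", LA_BASELINE,
                            activation_onset=a_onset,
                            activation_duration=ATRIAL_DURATION,
                            wall_resistance=0.008),
        "RA": ChamberParams("RA",
                            ElastanceParams(ees=0.25, v0=5.0,
                                            a_res=0.40, b_res=0.12),
                            activation_onset=a_onset,
                            activation_duration=ATRIAL_DURATION,
                            wall_resistance=0.004),
        "LV": ChamberParams("LV",
                            ElastanceParams(ees=1.8818, v0=10.0,
                                            a_res=0.80, b_res=0.020),
                            activation_onset=VENTRICULAR_ONSET,
                            activation_duration=VENTRICULAR_DURATION,
                            wall_resistance=0.002),
        "RV": ChamberParams("RV",
                            ElastanceParams(ees=0.65, v0=10.0,
                                            a_res=0.30, b_res=0.045),
                            activation_onset=VENTRICULAR_ONSET,
                            activation_duration=VENTRICULAR_DURATION,
                            wall_resistance=0.002),
    }
    compartments = {
        "SA": VascularCompartmentParams("SA", compliance=1.3708,
                                        outflow_resistance=0.4823,
                                        unstressed_volume=100.0),
        "SV": VascularCompartmentParams("SV", compliance=0.8,
                                        outflow_resistance=0.1342,
                                        unstressed_volume=300.0),
        "PA": VascularCompartmentParams("PA", compliance=0.8,
                                        outflow_resistance=0.08,
                                        unstressed_volume=50.0),
        "PV": VascularCompartmentParams("PV", compliance=0.25,
                                        outflow_resistance=0.03,
                                        unstressed_volume=80.0),
    }
    valves = {
        "MV": ValveParams("MV", resistance=0.05),
        "AoV": ValveParams("AoV", resistance=0.014),
        "TV": ValveParams("TV", resistance=0.05),
        "PuV": ValveParams("PuV", resistance=0.02),
    }
    return CircuitParams(chambers=chambers, compartments=compartments,
                         valves=valves, rhythm=rhythm, total_volume=1041.3402)
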