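"""Constitutive laws: blended elastance, activation, valves, capacitors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriasim.circuit import (
    ActivationError,
    activation,
    chamber_pressure,
    compartment_pressure,
    passive_chamber_pressure,
    valve_flow,
)
from atriasim.params import (
    ChamberParams,
    ElastanceParams,
    RhythmSchedule,
    ValveParams,
    VascularCompartmentParams,
)
from atriasim.presets import LA_BASELINE, LA_POST_LAAO


class TestChamberPressure:
    @pytest.mark.parametrize("e", [0.0, 0.3, 1.0])
    def test_zero_at_unstressed_volume(self, e):
        p = ElastanceParams(ees=0.45, v0=12.0, a_res=0.5, b_res=0.049)
        assert chamber_pressure(12.0, e, p) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("params, v, e, expected", [
        # passive reservoir curve at 50 mL of stretch, pre vs post occlusion
        (LA_BASELINE, 50.0, 0.0, 0.5 * (math.exp(0.049 * 50) - 1)),   # ~5.29
        (LA_POST_LAAO, 50.0, 0.0, 0.35 * (math.exp(0.07 * 50) - 1)),  # ~11.24
        # fully activated end-systolic line
        (LA_BASELINE, 10.0, 1.0, 4.5),
    ])
    def test_printed_constitutive_values(self, params, v, e, expected):
        assert chamber_pressure(v, e, params) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_hand_evaluated_magnitudes(self):
        assert chamber_pressure(50.0, 0.0, LA_BASELINE) == pytest.approx(
            5.29, abs=0.01)
        assert chamber_pressure(50.0, 0.0, LA_POST_LAAO) == pytest.approx(
            11.24, abs=0.01)

    @pytest.mark.parametrize("e", [-0.1, 1.5])
    def test_invalid_activation_rejected(self, e):
        with pytest.raises(ActivationError):
            chamber_pressure(30.0, e, LA_BASELINE)

    @given(e=st.floats(0.0, 1.0),
           v1=st.floats(0.0, 150.0), v2=st.floats(0.0, 150.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_volume(self, e, v1, v2):
        lo, hi = sorted([v1, v2])
        if hi - lo < 1e-6:
            return
        p1 = chamber_pressure(LA_BASELINE.v0 + lo, e, LA_BASELINE)
        p2 = chamber_pressure(LA_BASELINE.v0 + hi, e, LA_BASELINE)
        assert p2 > p1

    def test_blend_is_linear_in_activation(self):
        v = 60.0
        pes = chamber_pressure(v, 1.0, LA_BASELINE)
        ped = chamber_pressure(v, 0.0, LA_BASELINE)
        for e in np.linspace(0, 1, 11):
            assert chamber_pressure(v, e, LA_BASELINE) == pytest.approx(
                e * pes + (1 - e) * ped, rel=1e-12)

    def test_initial_passive_slope_invariant_pre_and_post(self):
        # dP/dv at v0, e=0 equals a_res*b_res = 0.0245 for both sets
        h = 1e-7
        for params in (LA_BASELINE, LA_POST_LAAO):
            slope = passive_chamber_pressure(params.v0 + h, params) / h
            assert slope == pytest.approx(0.0245, rel=1e-5)
        assert LA_BASELINE.a_res * LA_BASELINE.b_res == pytest.approx(
            LA_POST_LAAO.a_res * LA_POST_LAAO.b_res, rel=1e-12)

    def test_post_occlusion_passive_curve_dominates(self):
        v = np.linspace(0.0, 80.0, 400)
        pre = passive_chamber_pressure(v, LA_BASELINE)
        post = passive_chamber_pressure(v, LA_POST_LAAO)
        assert np.all(post >= pre - 1e-12)


class TestActivation:
    def chamber(self, onset=0.0, duration=0.3, label="LV", amp=1.0):
        return ChamberParams(label, LA_BASELINE, activation_onset=onset,
                             activation_duration=duration,
                             activation_amplitude=amp)

    def rhythm(self, atrial_active=True):
        return RhythmSchedule((1.0,), atrial_active=atrial_active)

    def test_zero_outside_window_and_peak_at_midpoint(self):
        ch = self.chamber(onset=0.1, duration=0.4)
        r = self.rhythm()
        assert activation(0.05, ch, r) == 0.0
        assert activation(0.6, ch, r) == 0.0
        assert activation(0.3, ch, r) == pytest.approx(1.0)

    def test_disabled_atrial_contraction_is_identically_zero(self):
        ch = self.chamber(onset=0.74, duration=0.2, label="LA")
        r = self.rhythm(atrial_active=False)
        assert all(activation(t, ch, r) == 0.0
                   for t in np.linspace(0, 3, 301))

    def test_wrapped_window_crosses_cycle_boundary(self):
        ch = self.chamber(onset=0.9, duration=0.2)
        r = self.rhythm()
        assert activation(1.0, ch, r) == pytest.approx(1.0)   # peak at wrap
        assert activation(0.05, ch, r) > 0.0
        assert activation(0.5, ch, r) == 0.0

    def test_amplitude_scales_peak(self):
        ch = self.chamber(onset=0.0, duration=0.4, amp=0.6)
        assert activation(0.2, ch, self.rhythm()) == pytest.approx(0.6)

    def test_continuity_at_window_edges(self):
        ch = self.chamber(onset=0.2, duration=0.3)
        r = self.rhythm()
        eps = 1e-8
        assert activation(0.2 + eps, ch, r) < 1e-10
        assert activation(0.5 - eps, ch, r) < 1e-10

    def test_integral_positive_when_active_zero_when_disabled(self):
        t = np.linspace(0, 1, 2001)
        ch = self.chamber(onset=0.74, duration=0.2, label="LA")
        on = np.trapezoid([activation(x, ch, self.rhythm()) for x in t], t)
        off = np.trapezoid(
            [activation(x, ch, self.rhythm(atrial_active=False))
             for x in t], t)
        assert on > 0.05
        assert off == 0.0

    def test_irregular_schedule_uses_per_cycle_phase(self):
        r = RhythmSchedule((0.375, 0.4, 0.5), atrial_active=False,
                           av_delay=0.0)
        ch = self.chamber(onset=0.0, duration=0.5)
        # midpoint of each cycle's window peaks at 1
        for start, cl in [(0.0, 0.375), (0.375, 0.4), (0.775, 0.5)]:
            assert activation(start + 0.25 * cl, ch, r) == pytest.approx(1.0)


class TestValveAndCompartment:
    def test_valve_closed_under_adverse_gradient(self):
        v = ValveParams("MV", resistance=0.05)
        assert valve_flow(5.0, 9.0, v) == 0.0
        assert valve_flow(5.0, 5.0, v) == 0.0

    def test_valve_linear_conductance(self):
        v = ValveParams("MV", resistance=0.05)
        assert valve_flow(10.0, 5.0, v) == pytest.approx(100.0)

    def test_valve_flow_nondecreasing_in_gradient(self):
        v = ValveParams("AoV", resistance=0.02)
        grads = np.linspace(-10, 30, 100)
        flows = [valve_flow(g, 0.0, v) for g in grads]
        assert all(b >= a for a, b in zip(flows, flows[1:]))

    def test_compartment_pressure_linear(self):
        c = VascularCompartmentParams("SA", compliance=1.0,
                                      outflow_resistance=1.0,
                                      unstressed_volume=100.0)
        assert compartment_pressure(100.0, c) == 0.0
        assert compartment_pressure(200.0, c) == pytest.approx(100.0)
        c2 = VascularCompartmentParams("SA", compliance=2.0,
                                       outflow_resistance=1.0,
                                       unstressed_volume=100.0)
        assert compartment_pressure(200.0, c2) == pytest.approx(50.0)
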