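"""ODE assembly and integration of the closed loop to periodic steady state.

The state vector holds the eight storage volumes in topology order
(LA, LV, SA, SV, RA, RV, PA, PV). Each element's dV/dt is inflow minus
outflow, so total blood volume is conserved by construction. The system
is stiff (valve opening/closing produces fast transients), so an
implicit integrator (BDF by default) is used; valve switching is handled
by the smooth max(0, .) conductance rather than event detection.

Chamber node pressure includes a small viscoelastic wall term,

    P = P_elastic(V, e) + eta * dV/dt,

with ``eta`` the chamber's wall resistance (mmHg*s/mL). The term
separates the filling and emptying limbs of the atrial pressure-volume
trajectory (hysteresis of the reservoir phase); with a pure elastance
both limbs would retrace one passive curve. Because dV/dt depends on
the node pressures, each heart side is a small linear system in its two
chamber pressures, solved in closed form with the valve (diode) states
iterated to consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    CHAMBER_LABELS,
    COMPARTMENT_LABELS,
    ELEMENT_ORDER,
    VALVE_LABELS,
    CircuitParams,
    RhythmSchedule,
)

#: Flow edges in topology order: ``q_<edge>`` is the flow leaving the
#: element named by the edge (valves keep their valve label).
FLOW_EDGES: Tuple[str, ...] = ("MV", "AoV", "SA", "SV", "TV", "PuV", "PA", "PV")


class SimulationError(RuntimeError):
    """Raised when the integrator fails to produce a valid trajectory."""


@dataclass
class SimulationResult:
    """Time-gridded traces of the full circuit plus beat boundaries.

    ``pressures``/``volumes`` are keyed by element label; ``flows`` by
    edge name (see :data:`FLOW_EDGES`). All traces share ``time``.
    """

    time: np.ndarray
    pressures: Dict[str, np.ndarray]
    volumes: Dict[str, np.ndarray]
    flows: Dict[str, np.ndarray]
    beat_times: np.ndarray
    circuit: Optional[CircuitParams] = None
    diagnostics: Dict[str, object] = field(default_factory=dict)

    @property
    def total_volume_trace(self) -> np.ndarray:
        return np.sum([self.volumes[k] for k in self.volumes], axis=0)

    def beats(self) -> List[Tuple[float, float]]:
        """Complete beat intervals covered by the trajectory."""
        b = self.beat_times
        return [(float(b[i]), float(b[i + 1])) for i in range(len(b) - 1)]


class _Compiled:
    """Scalar- and array-compiled circuit for fast RHS evaluation."""

    def __init__(self, circuit: CircuitParams):
        ch = [circuit.chambers[l] for l in CHAMBER_LABELS]  # LA LV RA RV
        self.ees = [c.constitutive.ees for c in ch]
        self.v0 = [c.constitutive.v0 for c in ch]
        self.a_res = [c.constitutive.a_res for c in ch]
        self.b_res = [c.constitutive.b_res for c in ch]
        self.eta = [c.wall_resistance for c in ch]
        self.onset = [c.activation_onset for c in ch]
        self.dur = [c.activation_duration for c in ch]
        self.amp = [c.activation_amplitude for c in ch]

        co = [circuit.compartments[l] for l in COMPARTMENT_LABELS]
        self.C = [c.compliance for c in co]              # SA SV PA PV
        self.Vu = [c.unstressed_volume for c in co]
        self.Rout = [c.outflow_resistance for c in co]

        self.Rv = [circuit.valves[l].resistance
                   for l in VALVE_LABELS]                # MV AoV TV PuV

        r = circuit.rhythm
        self.cl = [float(c) for c in r.cycle_lengths]
        self.cum = [0.0]
        for c in self.cl:
            self.cum.append(self.cum[-1] + c)
        self.period = self.cum[-1]
        self.atrial_active = r.atrial_active

    # -- scalar path (hot loop) ---------------------------------------

    def _act4(self, t: float) -> Tuple[float, float, float, float]:
        tm = math.fmod(t, self.period)
        tau = tm
        T = self.cl[-1]
        for k, cl in enumerate(self.cl):
            if tau < cl:
                T = cl
                break
            tau -= cl
        ph = tau / T
        out = []
        for i in range(4):
            if not self.atrial_active and i in (0, 2):   # LA, RA
                out.append(0.0)
                continue
            phi = (ph - self.onset[i]) % 1.0
            if phi < self.dur[i]:
                s = math.sin(math.pi * phi / self.dur[i])
                out.append(self.amp[i] * s * s)
            else:
                out.append(0.0)
        return out[0], out[1], out[2], out[3]

    def _pel(self, i: int, v: float, e: float) -> float:
        dv = v - self.v0[i]
        return (e * self.ees[i] * dv
                + (1.0 - e) * self.a_res[i] * math.expm1(self.b_res[i] * dv))

    @staticmethod
    def _side(E1: float, eta1: float, Pu: float, Rin: float,
              E2: float, eta2: float, Rv12: float, Rv2d: float,
              Pd: float) -> Tuple[float, float, float, float, float]:
        """Solve one heart side for (P1, P2, q_in, q_12, q_out).

        Chamber 1 receives from node pressure ``Pu`` through ``Rin``,
        ejects into chamber 2 through valve ``Rv12``; chamber 2 ejects
        into node pressure ``Pd`` through valve ``Rv2d``. Node pressure
        P_i = E_i + eta_i * dV_i/dt; with fixed diode states this is a
        linear 2x2 system, iterated until the states are consistent.
        """
        s1 = 1.0 if E1 > E2 else 0.0
        s2 = 1.0 if E2 > Pd else 0.0
        P1, P2 = E1, E2
        for _ in range(4):
            a1 = eta1 / Rin
            b1 = s1 * eta1 / Rv12
            b2 = s1 * eta2 / Rv12
            c2 = s2 * eta2 / Rv2d
            A11 = 1.0 + a1 + b1
            A22 = 1.0 + b2 + c2
            r1 = E1 + a1 * Pu
            r2 = E2 + c2 * Pd
            det = A11 * A22 - b1 * b2
            P1 = (r1 * A22 + b1 * r2) / det
            P2 = (A11 * r2 + b2 * r1) / det
            ns1 = 1.0 if P1 > P2 else 0.0
            ns2 = 1.0 if P2 > Pd else 0.0
            if ns1 == s1 and ns2 == s2:
                break
            s1, s2 = ns1, ns2
        q_in = (Pu - P1) / Rin
        q_12 = max(0.0, P1 - P2) / Rv12
        q_out = max(0.0, P2 - Pd) / Rv2d
        return P1, P2, q_in, q_12, q_out

    def rhs(self, t, y):
        eLA, eLV, eRA, eRV = self._act4(t)
        vLA, vLV, vSA, vSV, vRA, vRV, vPA, vPV = y
        pSA = (vSA - self.Vu[0]) / self.C[0]
        pSV = (vSV - self.Vu[1]) / self.C[1]
        pPA = (vPA - self.Vu[2]) / self.C[2]
        pPV = (vPV - self.Vu[3]) / self.C[3]
        ELA = self._pel(0, vLA, eLA)
        ELV = self._pel(1, vLV, eLV)
        ERA = self._pel(2, vRA, eRA)
        ERV = self._pel(3, vRV, eRV)
        pLA, pLV, q_pv, q_mv, q_ao = self._side(
            ELA, self.eta[0], pPV, self.Rout[3],
            ELV, self.eta[1], self.Rv[0], self.Rv[1], pSA)
        pRA, pRV, q_sv, q_tv, q_pu = self._side(
            ERA, self.eta[2], pSV, self.Rout[1],
            ERV, self.eta[3], self.Rv[2], self.Rv[3], pPA)
        if not (pLA == pLA and pLV == pLV and pRA == pRA and pRV == pRV):
            raise SimulationError(f"non-finite pressure at t={t:.4f} s")
        q_sa = (pSA - pSV) / self.Rout[0]
        q_pa = (pPA - pPV) / self.Rout[2]
        return (q_pv - q_mv, q_mv - q_ao, q_ao - q_sa, q_sa - q_sv,
                q_sv - q_tv, q_tv - q_pu, q_pu - q_pa, q_pa - q_pv)

    # -- vectorized path (trace output) -------------------------------

    def activations(self, t):
        """Chamber activations in (LA, LV, RA, RV) order, shape (4, n)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cl = np.asarray(self.cl)
        cum = np.asarray(self.cum)
        tm = np.mod(t, self.period)
        k = np.clip(np.searchsorted(cum, tm, side="right") - 1,
                    0, len(cl) - 1)
        ph = (tm - cum[k]) / cl[k]
        onset = np.asarray(self.onset)[:, None]
        dur = np.asarray(self.dur)[:, None]
        phi = (ph[None, :] - onset) % 1.0
        amp = np.asarray(self.amp)[:, None]
        e = amp * np.where(phi < dur, np.sin(np.pi * phi / dur) ** 2, 0.0)
        if not self.atrial_active:
            e[[0, 2], :] = 0.0
        return e

    @staticmethod
    def _side_vec(E1, eta1, Pu, Rin, E2, eta2, Rv12, Rv2d, Pd):
        s1 = (E1 > E2).astype(float)
        s2 = (E2 > Pd).astype(float)
        P1, P2 = E1, E2
        for _ in range(4):
            a1 = eta1 / Rin
            b1 = s1 * eta1 / Rv12
            b2 = s1 * eta2 / Rv12
            c2 = s2 * eta2 / Rv2d
            A11 = 1.0 + a1 + b1
            A22 = 1.0 + b2 + c2
            r1 = E1 + a1 * Pu
            r2 = E2 + c2 * Pd
            det = A11 * A22 - b1 * b2
            P1 = (r1 * A22 + b1 * r2) / det
            P2 = (A11 * r2 + b2 * r1) / det
            s1 = (P1 > P2).astype(float)
            s2 = (P2 > Pd).astype(float)
        q_in = (Pu - P1) / Rin
        q_12 = np.maximum(0.0, P1 - P2) / Rv12
        q_out = np.maximum(0.0, P2 - Pd) / Rv2d
        return P1, P2, q_in, q_12, q_out

    def traces(self, t, y):
        """Pressures and flows at sample times; y shape (8, n).

        Returns ``(p, q)`` with p rows in :data:`ELEMENT_ORDER` and q
        rows in :data:`FLOW_EDGES` order.
        """
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        e = self.activations(t)
        v0 = np.asarray(self.v0)[:, None]
        ees = np.asarray(self.ees)[:, None]
        a_res = np.asarray(self.a_res)[:, None]
        b_res = np.asarray(self.b_res)[:, None]
        dv = y[[0, 1, 4, 5]] - v0          # LA LV RA RV
        Eel = e * ees * dv + (1.0 - e) * a_res * np.expm1(b_res * dv)
        C = np.asarray(self.C)[:, None]
        Vu = np.asarray(self.Vu)[:, None]
        pco = (y[[2, 3, 6, 7]] - Vu) / C   # SA SV PA PV
        pSA, pSV, pPA, pPV = pco
        pLA, pLV, q_pv, q_mv, q_ao = self._side_vec(
            Eel[0], self.eta[0], pPV, self.Rout[3],
            Eel[1], self.eta[1], self.Rv[0], self.Rv[1], pSA)
        pRA, pRV, q_sv, q_tv, q_pu = self._side_vec(
            Eel[2], self.eta[2], pSV, self.Rout[1],
            Eel[3], self.eta[3], self.Rv[2], self.Rv[3], pPA)
        q_sa = (pSA - pSV) / self.Rout[0]
        q_pa = (pPA - pPV) / self.Rout[2]
        p = np.vstack([pLA, pLV, pSA, pSV, pRA, pRV, pPA, pPV])
        q = np.vstack([q_mv, q_ao, q_sa, q_sv, q_tv, q_pu, q_pa, q_pv])
        return p, q


def derivatives(t: float, state, circuit: CircuitParams) -> np.ndarray:
    """dV/dt (mL/s) of the eight storage elements in topology order.

    The component sum is exactly zero: the loop is closed.
    """
    return np.array(_Compiled(circuit).rhs(t, np.asarray(state, dtype=float)))


def initial_state(circuit: CircuitParams) -> np.ndarray:
    """Distribute stressed volume over the elements.

    Weights are each element's small-signal compliance about its
    unstressed volume (1/(a_res*b_res) for chambers, capped to avoid a
    floppy ventricle swallowing the loop; C for compartments). Metrics
    are computed on final beats only, so the start point just needs to
    lie in the basin of the periodic attractor.
    """
    comp = _Compiled(circuit)
    C = np.asarray(comp.C)
    ch_w = np.minimum(1.0 / (np.asarray(comp.a_res) * np.asarray(comp.b_res)),
                      10.0 * np.max(C))
    w = np.empty(8)
    w[[0, 1, 4, 5]] = ch_w
    w[[2, 3, 6, 7]] = C
    y0 = np.empty(8)
    y0[[0, 1, 4, 5]] = comp.v0
    y0[[2, 3, 6, 7]] = comp.Vu
    return y0 + circuit.stressed_volume * w / w.sum()


def beat_boundaries(rhythm: RhythmSchedule, duration: float) -> np.ndarray:
    """Cycle-onset times in [0, duration], starting at 0."""
    times = [0.0]
    i = 0
    n = len(rhythm.cycle_lengths)
    while True:
        t_next = times[-1] + rhythm.cycle_lengths[i % n]
        if t_next > duration + 1e-9:
            break
        times.append(t_next)
        i += 1
    return np.asarray(times)


def simulate(circuit: CircuitParams, duration: float = 30.0, *,
             method: str = "BDF", rtol: float = 1e-6, atol: float = 1e-6,
             points_per_cycle: int = 240,
             y0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate the closed loop for ``duration`` seconds.

    A stiff implicit solver integrates the eight volume ODEs; traces
    are sampled on a dense grid of ``points_per_cycle`` points per
    cardiac cycle. Identical inputs produce bitwise-identical results.
    """
    comp = _Compiled(circuit)
    bounds = beat_boundaries(circuit.rhythm, duration)
    grids = [np.linspace(bounds[i], bounds[i + 1], points_per_cycle,
                         endpoint=False)
             for i in range(len(bounds) - 1)]
    tail_start = float(bounds[-1])
    if duration - tail_start > 1e-9:
        next_cl = comp.cl[(len(bounds) - 1) % len(comp.cl)]
        n_tail = max(2, int(points_per_cycle
                            * (duration - tail_start) / next_cl))
        grids.append(np.linspace(tail_start, duration, n_tail,
                                 endpoint=False))
    t_eval = np.unique(np.concatenate(grids + [[duration]]))

    if y0 is None:
        y0 = initial_state(circuit)
    sol = solve_ivp(comp.rhs, (0.0, duration), np.asarray(y0, dtype=float),
                    method=method, t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"integration failed at t="
            f"{sol.t[-1] if len(sol.t) else 0.0:.3f} s: {sol.message}")

    p, q = comp.traces(sol.t, sol.y)
    volumes = {lab: sol.y[i] for i, lab in enumerate(ELEMENT_ORDER)}
    pressures = {lab: p[i] for i, lab in enumerate(ELEMENT_ORDER)}
    flows = {edge: q[i] for i, edge in enumerate(FLOW_EDGES)}
    diagnostics = {"method": method, "rtol": rtol, "atol": atol,
                   "points_per_cycle": points_per_cycle,
                   "nfev": int(sol.nfev), "njev": int(sol.njev),
                   "nlu": int(sol.nlu), "n_samples": int(len(sol.t)),
                   "message": str(sol.message)}
    return SimulationResult(time=sol.t, pressures=pressures, volumes=volumes,
                            flows=flows, beat_times=bounds, circuit=circuit,
                            diagnostics=diagnostics)


def segment_beats(result: SimulationResult,
                  rhythm: Optional[RhythmSchedule] = None
                  ) -> List[Tuple[float, float]]:
    """Beat intervals tiling the trajectory (complete cycles only)."""
    if rhythm is None:
        bounds = result.beat_times
    else:
        bounds = beat_boundaries(rhythm, float(result.time[-1]))
    return [(float(bounds[i]), float(bounds[i + 1]))
            for i in range(len(bounds) - 1)]


def periodicity_drift(result: SimulationResult, n_windows: int = 3) -> float:
    """Max change (mL) of end-of-repetition element volumes over the
    final ``n_windows`` schedule repetitions.

    For an irregular rhythm the comparison is across full schedule
    repetitions rather than single beats. Values below ~0.5 mL certify
    periodic steady state.
    """
    circuit = result.circuit
    if circuit is None:
        raise ValueError("result lacks circuit metadata")
    period = circuit.rhythm.period
    t_end = float(result.time[-1])
    n_reps = int(math.floor(t_end / period + 1e-9))
    if n_reps < n_windows + 1:
        raise ValueError(
            f"need >= {n_windows + 1} schedule repetitions, have {n_reps}")
    sample_times = [n_reps * period - k * period
                    for k in range(n_windows, -1, -1)]
    drift = 0.0
    for trace in result.volumes.values():
        vals = np.interp(sample_times, result.time, trace)
        drift = max(drift, float(np.max(np.abs(np.diff(vals)))))
    return drift
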