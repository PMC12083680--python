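"""Hemodynamic analysis of simulated (or imported) waveform traces.

Quantities computed per steady-state beat: mean left-atrial pressure,
the a/c/v pressure waves (pump, reservoir and conduit phases of the LA
cycle), mitral E/A inflow peaks, stroke volume and cardiac output, and
the LA pressure-volume loop with its figure-eight decomposition into
counter-rotating a- and v-subloops.

Wave classification uses timing windows expressed as fractions of the
beat (beats are delimited by ventricular activation onsets):

* a-wave: the atrial activation window (late diastole);
* c-wave: early ventricular systole, the first half of the ventricular
  activation window;
* v-wave: late systole up to mitral opening, from mid-systole to just
  past the end of the ventricular window;
* E-wave: early diastole, from late ventricular relaxation (mitral
  opening precedes the end of the activation window) through the first
  half of the diastolic interval;
* A-wave (flow): the atrial activation window.

With the default 30%-of-cycle ventricular window this gives c in
[0, 0.15), v in [0.15, 0.40), E in [0.21, 0.65).

Any window may report absence — a flutter or AF beat has no a-wave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .engine import SimulationResult

__all__ = [
    "WavePeak", "ACVWaves", "EAWaves", "BeatMetrics", "SubLoop", "PVLoop",
    "mean_lap", "detect_acv_waves", "mitral_ea", "cardiac_output",
    "stroke_volume", "beat_metrics", "pv_loop", "shoelace_area",
    "laa_ejection_fraction", "default_wave_windows",
]


@dataclass(frozen=True)
class WavePeak:
    time: float        # s, absolute
    value: float       # mmHg for pressure waves, mL/s for flow waves


@dataclass(frozen=True)
class ACVWaves:
    a: Optional[WavePeak]
    c: Optional[WavePeak]
    v: Optional[WavePeak]


@dataclass(frozen=True)
class EAWaves:
    e: Optional[WavePeak]
    a: Optional[WavePeak]

    @property
    def ea_ratio(self) -> Optional[float]:
        if self.e is None or self.a is None or self.a.value == 0:
            return None
        return self.e.value / self.a.value


@dataclass(frozen=True)
class BeatMetrics:
    """Per-beat summary of LA and systemic hemodynamics."""

    mean_lap: float                      # mmHg
    a_peak: Optional[WavePeak]           # LAP a-wave
    c_peak: Optional[WavePeak]
    v_peak: Optional[WavePeak]
    e_peak: Optional[WavePeak]           # mitral E (mL/s)
    a_flow_peak: Optional[WavePeak]      # mitral A (mL/s)
    stroke_volume: float                 # mL
    cardiac_output: float                # L/min


@dataclass(frozen=True)
class SubLoop:
    points: np.ndarray                   # closed (n, 2) (volume, pressure)
    area: float                          # signed, mmHg*mL (ccw positive)

    @property
    def orientation(self) -> str:
        return "ccw" if self.area >= 0 else "cw"


@dataclass(frozen=True)
class PVLoop:
    """Ordered (volume, pressure) trajectory over one beat with its
    decomposition at self-intersections."""

    points: np.ndarray                   # closed (n, 2)
    subloops: List[SubLoop]
    n_intersections: int

    @property
    def figure_eight(self) -> bool:
        """True iff two or more significant subloops of opposite
        orientation exist (tiny slivers below 1% of the total swept
        area are ignored)."""
        total = sum(abs(s.area) for s in self.subloops)
        if total == 0:
            return False
        orients = {s.orientation for s in self.subloops
                   if abs(s.area) >= 0.01 * total}
        return orients == {"ccw", "cw"}

    @property
    def multiple_intersections(self) -> bool:
        return self.n_intersections > 1


# ---------------------------------------------------------------------
# window helpers

def default_wave_windows(circuit=None) -> Dict[str, Tuple[float, float]]:
    """Phase windows (fractions of the beat) for wave classification.

    The a-windows follow the circuit's LA activation window when a
    circuit is given; otherwise the package's default atrial timing
    (window [0.74, 0.94], peak at 0.84) is assumed.
    """
    if circuit is not None:
        la = circuit.chambers["LA"]
        a_win = (la.activation_onset,
                 la.activation_onset + la.activation_duration)
        vd = circuit.chambers["LV"].activation_duration
    else:
        a_win = (0.74, 0.94)
        vd = 0.30
    return {
        "a": a_win,
        "c": (0.0, 0.5 * vd),
        "v": (0.5 * vd, min(vd + 0.10, 0.95)),
        # mitral opening slightly precedes the end of the ventricular
        # activation window (relaxation tail), so open the E window early
        "e": (0.7 * vd, vd + (1.0 - vd) / 2.0),
        "a_flow": a_win,
    }


def _window_mask(phase: np.ndarray, win: Tuple[float, float]) -> np.ndarray:
    """Boolean mask for phases inside ``win``; handles wrap-around."""
    lo, hi = win
    if hi <= 1.0 and lo <= hi:
        return (phase >= lo) & (phase < hi)
    # wrapped window, e.g. (0.9, 1.1) meaning [0.9, 1) U [0, 0.1)
    return (phase >= lo) | (phase < hi % 1.0)


def _beat_slice(t: np.ndarray, beat: Tuple[float, float]) -> slice:
    t0, t1 = beat
    i0 = int(np.searchsorted(t, t0 - 1e-12))
    i1 = int(np.searchsorted(t, t1 + 1e-12))
    if i1 - i0 < 4:
        raise ValueError(f"beat [{t0}, {t1}] covers too few samples")
    return slice(i0, i1)


# ---------------------------------------------------------------------
# scalar metrics

def mean_lap(result: SimulationResult, beats: int = 5) -> float:
    """Time-weighted mean LA pressure over the final ``beats`` complete
    beats (mmHg)."""
    if beats < 1:
        raise ValueError("window must cover at least one complete beat")
    intervals = result.beats()
    if len(intervals) < beats:
        raise ValueError(
            f"trajectory holds {len(intervals)} complete beats, "
            f"need {beats}")
    t0 = intervals[-beats][0]
    t1 = intervals[-1][1]
    sl = _beat_slice(result.time, (t0, t1))
    t = result.time[sl]
    p = result.pressures["LA"][sl]
    return float(np.trapezoid(p, t) / (t[-1] - t[0]))


def stroke_volume(result: SimulationResult,
                  beat: Tuple[float, float]) -> float:
    """Aortic-valve ejected volume over one beat (mL)."""
    sl = _beat_slice(result.time, beat)
    return float(np.trapezoid(result.flows["AoV"][sl], result.time[sl]))


def cardiac_output(t: np.ndarray, aortic_flow: np.ndarray,
                   window: Optional[Tuple[float, float]] = None) -> float:
    """Mean aortic flow over an integer-beat window, as L/min."""
    t = np.asarray(t, dtype=float)
    q = np.asarray(aortic_flow, dtype=float)
    if window is not None:
        sl = _beat_slice(t, window)
        t, q = t[sl], q[sl]
    mean_flow = np.trapezoid(q, t) / (t[-1] - t[0])   # mL/s
    return float(mean_flow * 60.0 / 1000.0)


# ---------------------------------------------------------------------
# wave detection

def _classified_peak(t: np.ndarray, x: np.ndarray, phase: np.ndarray,
                     win: Tuple[float, float],
                     min_prominence: float) -> Optional[WavePeak]:
    idx, _ = find_peaks(x, prominence=min_prominence)
    if len(idx) == 0:
        return None
    idx = idx[_window_mask(phase[idx], win)]
    if len(idx) == 0:
        return None
    best = idx[np.argmax(x[idx])]
    return WavePeak(time=float(t[best]), value=float(x[best]))


def detect_acv_waves(t: np.ndarray, lap: np.ndarray,
                     beat: Tuple[float, float], *,
                     circuit=None,
                     windows: Optional[Dict[str, Tuple[float, float]]] = None,
                     atrial_active: Optional[bool] = None,
                     min_prominence: float = 0.02) -> ACVWaves:
    """Locate the a-, c- and v-waves of one LA pressure beat.

    Local maxima (scipy ``find_peaks``) are classified by the timing
    windows documented in the module docstring; each wave may be
    absent. When ``circuit`` carries an inactive atrial rhythm the
    a-wave is reported absent without looking for a peak.
    """
    win = dict(default_wave_windows(circuit))
    if windows:
        win.update(windows)
    if atrial_active is None:
        atrial_active = (circuit.rhythm.atrial_active
                         if circuit is not None else True)
    sl = _beat_slice(np.asarray(t, float), beat)
    ts = np.asarray(t, float)[sl]
    ps = np.asarray(lap, float)[sl]
    phase = (ts - beat[0]) / (beat[1] - beat[0])
    a = (None if not atrial_active
         else _classified_peak(ts, ps, phase, win["a"], min_prominence))
    c = _classified_peak(ts, ps, phase, win["c"], min_prominence)
    v = _classified_peak(ts, ps, phase, win["v"], min_prominence)
    return ACVWaves(a=a, c=c, v=v)


def mitral_ea(t: np.ndarray, mv_flow: np.ndarray,
              beat: Tuple[float, float], *,
              circuit=None,
              windows: Optional[Dict[str, Tuple[float, float]]] = None,
              atrial_active: Optional[bool] = None,
              min_prominence: float = 1.0) -> EAWaves:
    """E and A peaks of the mitral inflow over one beat.

    E is the largest flow peak in early diastole (first half of the
    diastolic interval); A the largest within the atrial activation
    window. A is absent when atrial contraction is disabled.
    """
    win = dict(default_wave_windows(circuit))
    if windows:
        win.update(windows)
    if atrial_active is None:
        atrial_active = (circuit.rhythm.atrial_active
                         if circuit is not None else True)
    sl = _beat_slice(np.asarray(t, float), beat)
    ts = np.asarray(t, float)[sl]
    qs = np.asarray(mv_flow, float)[sl]
    phase = (ts - beat[0]) / (beat[1] - beat[0])
    e = _classified_peak(ts, qs, phase, win["e"], min_prominence)
    a = (None if not atrial_active
         else _classified_peak(ts, qs, phase, win["a_flow"], min_prominence))
    return EAWaves(e=e, a=a)


def beat_metrics(result: SimulationResult,
                 beat: Optional[Tuple[float, float]] = None) -> BeatMetrics:
    """Full per-beat metric set for one (default: last complete) beat."""
    if beat is None:
        beat = result.beats()[-1]
    acv = detect_acv_waves(result.time, result.pressures["LA"], beat,
                           circuit=result.circuit)
    ea = mitral_ea(result.time, result.flows["MV"], beat,
                   circuit=result.circuit)
    sv = stroke_volume(result, beat)
    co = cardiac_output(result.time, result.flows["AoV"], beat)
    sl = _beat_slice(result.time, beat)
    ml = float(np.trapezoid(result.pressures["LA"][sl], result.time[sl])
               / (result.time[sl][-1] - result.time[sl][0]))
    return BeatMetrics(mean_lap=ml, a_peak=acv.a, c_peak=acv.c,
                       v_peak=acv.v, e_peak=ea.e, a_flow_peak=ea.a,
                       stroke_volume=sv, cardiac_output=co)


# ---------------------------------------------------------------------
# pressure-volume loop geometry

def shoelace_area(points: np.ndarray) -> float:
    """Signed area of a closed polyline (ccw positive).

    The polyline need not repeat its first point; closure is implicit.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _close(points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    if not np.allclose(p[0], p[-1]):
        p = np.vstack([p, p[0]])
    return p


def _self_intersections(pts: np.ndarray):
    """Interior crossings between non-adjacent segments of a closed
    polyline ``pts`` (first point repeated at the end).

    Returns a list of ``(i, j, s, u, point)`` sorted by earliest
    parameter along the path. Exact-collinear overlaps are ignored
    (degenerate for sampled trajectories); near-endpoint ties resolve
    to the earlier parameter by the sort order.
    """
    a = pts[:-1]
    d = pts[1:] - a
    m = len(a)
    hits = []
    for i in range(m - 2):
        j0 = i + 2
        j1 = m - 1 if i == 0 else m  # skip the closure-adjacent pair
        if j1 <= j0:
            continue
        diff = a[j0:j1] - a[i]
        dj = d[j0:j1]
        denom = d[i, 0] * dj[:, 1] - d[i, 1] * dj[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (diff[:, 0] * dj[:, 1] - diff[:, 1] * dj[:, 0]) / denom
            u = (diff[:, 0] * d[i, 1] - diff[:, 1] * d[i, 0]) / denom
        eps = 1e-12
        ok = (np.isfinite(s) & np.isfinite(u)
              & (s > eps) & (s < 1 - eps) & (u > eps) & (u < 1 - eps))
        for k in np.nonzero(ok)[0]:
            x = a[i] + s[k] * d[i]
            hits.append((i, j0 + k, float(s[k]), float(u[k]), x))
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def _decompose(pts: np.ndarray, depth: int = 8):
    """Split a closed polyline at its self-intersections.

    Splits at the earliest crossing along the path, then recurses into
    both halves. Returns ``(subloop point arrays, crossing count)``.
    """
    hits = _self_intersections(pts)
    if not hits or depth == 0:
        return [pts], 0
    i, j, s, u, x = hits[0]
    loop1 = np.vstack([x, pts[i + 1:j + 1], x])
    loop2 = np.vstack([x, pts[j + 1:], pts[1:i + 1], x])
    out = []
    count = 1
    for loop in (loop1, loop2):
        subs, c = _decompose(loop, depth - 1)
        out.extend(subs)
        count += c
    return out, count


def pv_loop(result: SimulationResult,
            beat: Optional[Tuple[float, float]] = None,
            *, volume: Optional[np.ndarray] = None,
            pressure: Optional[np.ndarray] = None) -> PVLoop:
    """LA pressure-volume loop for one beat, decomposed at its
    self-intersection(s).

    In sinus rhythm the trajectory crosses itself once, yielding the
    counter-rotating a- and v-subloops (figure-eight); without atrial
    contraction it is a single loop. Signed areas use the shoelace
    formula (ccw positive in the (volume, pressure) plane).

    Raw ``volume``/``pressure`` arrays may be supplied instead of a
    simulation result (e.g. fixture or imported trajectories).
    """
    if volume is None or pressure is None:
        if beat is None:
            beat = result.beats()[-1]
        sl = _beat_slice(result.time, beat)
        volume = result.volumes["LA"][sl]
        pressure = result.pressures["LA"][sl]
    pts = _close(np.column_stack([np.asarray(volume, float),
                                  np.asarray(pressure, float)]))
    sub_pts, n_inter = _decompose(pts)
    subloops = [SubLoop(points=p, area=shoelace_area(p[:-1]))
                for p in sub_pts]
    return PVLoop(points=pts, subloops=subloops, n_intersections=n_inter)


def laa_ejection_fraction(max_area: float, min_area: float) -> float:
    """Appendage ejection fraction, percent: (max - min) / max * 100.

    Areas may be in any single consistent unit (cm^2 or mL).
    """
    if max_area <= 0:
        raise ValueError("max_area must be > 0")
    if min_area < 0 or min_area > max_area:
        raise ValueError("require 0 <= min_area <= max_area")
    return (max_area - min_area) / max_area * 100.0
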