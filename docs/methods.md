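# Methods

## Model structure

The circulation is closed and volume-conserving: eight storage
elements in fixed topology order (LA, LV, SA, SV, RA, RV, PA, PV),
where SA/SV are the systemic arterial/venous compartments and PA/PV the
pulmonary ones. The state vector is the eight element volumes; every
edge flow appears once as an outflow and once as an inflow, so
`sum(dV/dt) = 0` identically and total blood volume is conserved to
solver precision (asserted at < 0.1 mL on every run in the test suite,
observed ~1e-12 mL).

**Chambers.** Pressure follows the blended time-varying elastance
(Suga–Sagawa) convention: with activation `e(t)`,

    P_el(V, e) = e · Ees (V − V0) + (1 − e) · A_res (exp(B_res (V − V0)) − 1).

At `e = 1` this is the end-systolic line, at `e = 0` the exponential
end-diastolic (reservoir) curve. The two limbs are published for the LA
only; the same template with package-calibrated coefficients serves the
other three chambers. The blend (rather than an unconditional sum) was
chosen because it reduces exactly to each printed limb at the
activation extremes; whether the original implementation blends or sums
is not stated, and at physiological operating points the two differ
only modestly in the active window.

**Activation.** A squared half-sine on a window given as a fraction of
the current cycle: zero at the window edges, exactly
`activation_amplitude` (default 1) at the midpoint; the window may wrap
across the cycle boundary. Ventricular systole occupies the first 30%
of a 1 s cycle; the atrial window is 20% wide with its peak `av_delay`
(default 0.16 s) before the next ventricular onset. No activation
function is published; the squared half-sine is smooth, has compact
support, and integrates to half the window length.

**Viscoelastic wall term.** Chamber node pressure is
`P = P_el + η dV/dt` with `η` a small wall resistance (LA 0.008,
RA 0.004, ventricles 0.002 mmHg·s/mL). Without it, LA pressure is a
single-valued function of (V, e): the filling and emptying limbs of the
PV trajectory retrace the same passive curve, the reservoir (v-) loop
has zero area, and the coincident limbs generate spurious
micro-intersections. The wall term is the standard 0D viscoelastic
chamber element; it separates the limbs (clockwise v-loop, i.e. work
absorbed during reservoir filling) and leaves time-averaged pressures
essentially unchanged. Because `dV/dt` depends on node pressures, each
heart side is a 2×2 linear system in its two chamber pressures, solved
in closed form with the valve diode states iterated to consistency
(≤ 4 iterations; the iteration is a fixed-point on a two-state
lattice and terminates deterministically).

**Valves and vessels.** Valves are ideal linear diodes
(`q = max(0, ΔP)/R`, no inertance, no regurgitation — the emulated
bench uses unidirectional mechanical valves); vascular compartments are
linear capacitors with a resistive outflow. Valve switching is handled
by the smooth `max(0, ·)` conductance rather than event location, which
a stiff implicit integrator handles robustly and keeps the trajectory
deterministic.

**Integration.** `scipy.integrate.solve_ivp` with BDF, rtol = atol =
1e-6, dense sampling at 240 points per cycle, 30 s horizon. Metrics use
the final five complete beats (final full schedule repetitions for
irregular rhythms); the discarded transient is ample — beat-to-beat
drift of end-cycle volumes over the last three repetitions is ~1e-3 mL
against an acceptance threshold of 0.5 mL. The initial condition
distributes stressed volume proportionally to each element's
small-signal compliance (chamber weights capped at ten times the
largest vascular compliance so a floppy ventricle cannot swallow the
loop); steady state does not depend on it. A tenfold tolerance
refinement moves final-beat mean LA pressure by < 0.01 mmHg
(asserted < 0.1).

## Published parameters and the calibrated stand-in

The LA constitutive set is fixed input: Ees 0.45 mmHg/mL, V0 0 mL,
A_res 0.5, B_res 0.049; appendage occlusion is applied purely as
A_res → 0.35, B_res → 0.07, Ees → 0.7 (absolute overwrites, hence
idempotent). Note A_res·B_res = 0.0245 mmHg/mL in both states: the
passive curves share their initial slope at V0 and the post-occlusion
curve dominates everywhere above it.

Every other parameter is unpublished and ships as a calibrated
stand-in. The calibration module fitted {LV Ees, systemic resistance,
systemic arterial compliance, venous return resistance, total volume}
once so the 60 bpm baseline reproduces aortic 115/60 mmHg, CO
5.3 L/min and pre-occlusion mLAP 17.1 mmHg (all four achieved to
< 0.1%). The structural choices behind the fit:

* **Compact, mock-loop-scale compliances** (C_SA 1.37, C_SV 0.8,
  C_PA 0.8, C_PV 0.25 mL/mmHg) rather than whole-body textbook values:
  the loop emulates a benchtop circuit with small acrylic compliance
  chambers. Baseline pressures and flows do not identify the loop's
  volume-stiffness; the reported post-occlusion mLAP rise does (a soft
  loop buffers the ~15 mL the stiffened LA displaces and the rise all
  but vanishes), so loop stiffness was set as part of the stand-in
  calibration, to the reported pre/post response. With it the model
  predicts mLAP 17.1 → 18.7 mmHg post-occlusion.
* **Mitral/tricuspid resistances of mechanical-valve scale**
  (0.05 mmHg·s/mL, mean diastolic gradient ~4 mmHg at rest), which
  keeps early filling velocities physiologic and makes filling
  genuinely time-limited at short diastoles.

## Rate and contractility scenarios

Scenario builders are pure functions of a base circuit and compose
order-independently.

* **Rate changes** rescale the activation windows through a
  systolic-duration law: absolute ventricular systole is held at 0.3 s
  across rates (window *fractions* grow as the cycle shrinks),
  emulating fixed-duration pneumatic actuation and the weak rate
  dependence of systole. The AV delay shortens as √T. Activation
  amplitude derates as (T/1 s)^0.5 for cycles below 1 s — pneumatic
  actuators lose stroke at rapid pacing and the force–frequency
  response flattens — leaving 60 bpm untouched, 80 bpm at ~93% and
  150 bpm at ~63%. Together the two laws produce the expected
  rate–output curve: reduced output at 40 bpm, a plateau through the
  controlled range, and declining output with rising filling pressures
  at rapid rates. Retiming maps through the 1 s reference values, so
  it is idempotent and round-trips exactly.
* **Flutter** is a uniform (default 150 bpm) rhythm with
  `atrial_active = False`: atrial activation identically zero, the LA
  reduced to its passive reservoir curve.
* **Irregular AF** cycles through the cycle-length schedule
  (0.375, 0.4, 0.5 s; mean rate ≈ 141 bpm) with atria disabled. No
  stochastic RR-interval generation is attempted.
* **Contractility** scales the LA activation *amplitude* by
  k ∈ [0, 1]. Scaling Ees alone was rejected: under the blended law a
  zero-force activation still un-weights the passive term, so pressure
  paradoxically dips below the reservoir curve during "contraction"
  and the sweep is non-monotone. Amplitude scaling multiplies the
  active term by k at every instant, restores the passive curve at
  k = 0 (identical to flutter, as required), and is the direct
  analogue of an actuation-pressure knob.

## Waveform analysis

Beats are delimited by ventricular activation onsets. Peaks are local
maxima (scipy `find_peaks`, small prominence floor) classified by phase
windows tied to the activation schedule — published material names the
waves but no detection rule, so the windows are this package's
operationalization: a-wave inside the atrial activation window; c-wave
in the first half of ventricular systole; v-wave from mid-systole to
just past the end of the ventricular window (mitral opening); E in
early diastole (opened slightly before the activation window ends,
since mitral opening precedes full relaxation); A-flow inside the
atrial window. Any window may report absence — that is the expected
result for a/A in flutter and AF. The model's c-wave is usually absent:
it arises from mitral annular bulging, which a single-node LA does not
represent.

The LA PV loop for one beat is closed and decomposed at
self-intersections found by exact segment-pair predicates; signed areas
use the shoelace formula (counter-clockwise positive), and the loop is
a figure-eight when two opposite-orientation subloops each hold ≥ 1% of
the total swept area (the threshold discards degenerate slivers).
Splitting recurses on the earliest crossing along the path; collinear
ties resolve to the earlier parameter. Areas are reported in mmHg·mL.
On exact geometry the subloop areas partition the total signed area to
1e-12; on simulated sinus loops the crossing is near-tangent and the
partition holds to ~1e-8 relative (conditioning of the intersection
point, not round-off). The model reports volumetric flow (mL/s); users
converting to Doppler velocities supply their own effective orifice
area.

Mean LA pressure is the time-weighted (trapezoidal) mean over an
integer number of steady-state beats; cardiac output is mean aortic
valve flow × 60/1000, consistent with stroke volume × rate to < 1% on
uniform rhythms. The appendage ejection fraction helper implements
(max − min)/max × 100 on areas in any consistent unit.

## Calibration

Objective: Σ wᵢ ((simᵢ − targetᵢ)/targetᵢ)² over the requested features
(aortic systolic/diastolic, CO, mLAP, E/A ratio) — relative errors make
mmHg and L/min commensurable. Search: Nelder–Mead with box bounds,
initialized at the base circuit's current values with a simplex
spanning 15% of each bound interval; every evaluation is a full stiff
solve, so derivative-free search is the right tool against valve
non-smoothness. A failed simulation penalizes the candidate (objective
1e6) instead of aborting. The best-so-far iterate is returned on budget
exhaustion, the reported trajectory is monotone by construction, and
the whole procedure is deterministic. Search evaluations default to
30 s runs; the shipped workflows shorten them (12–16 s, 3–4 analysis
beats, rtol 1e-5) and always recompute the achieved features from a
fresh simulation of the fitted circuit. The four published LA
constitutive parameters are rejected as free parameters by
construction. Parameter-recovery: with targets generated from a known
circuit and {systemic resistance, systemic arterial compliance, LV Ees}
perturbed ±30%, the search recovers each within 10% (typically ≪ 1%)
with objective < 1e-3.

## What the synthetic fixtures do and do not show

The fixture generator produces analysis inputs with embedded ground
truth: Gaussian bumps centred in the classification windows (three-bump
LAP, two-lobe mitral flow) and the bowtie path with known signed areas
±1. They verify that the detectors and the loop decomposition recover
injected answers to one sample / round-off; they do not exercise noise
robustness (the default traces are noise-free; a noise option exists),
baseline wander, or morphologies outside the window convention — real
catheter or Doppler traces bring all three, so window offsets may need
adjustment there. Simulator-level tests likewise certify the model's
internal consistency and its reproduction of the documented systems
behavior, not patient-level predictive accuracy: the stand-in
calibration above is one circuit consistent with the reported operating
points, not a fitted population.

## Known limitations

* Post-occlusion mLAP is predicted at +1.6 mmHg against a reported
  +2.4; the residual reflects the unidentifiability of the unpublished
  non-atrial parameters from the printed operating points.
* No inertances, no regurgitation, no atrial-septal shunt, no
  autonomic reflexes; flutter/AF disable atrial mechanics entirely
  rather than modelling residual fibrillatory contraction (a residual
  fraction can be emulated via the contractility scale).
* The LAA is not a separate compartment: occlusion acts only through
  the published LA constitutive changes, so intra-appendage flow and
  stasis are out of scope.
* The amplitude-derating and systolic-duration laws are scenario-level
  device/physiology emulations with one exponent and one duration each;
  they are not fitted to rate-response data.
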