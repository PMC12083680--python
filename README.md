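# atriasim

A closed-loop lumped-parameter (0D) model of left-atrial hemodynamics,
built to study how the left atrium's three functions — reservoir,
conduit and pump — respond to atrial arrhythmias and to left-atrial-
appendage occlusion (LAAO).

Atrial fibrillation predisposes the left atrial appendage (LAA) to
thrombus formation, and device-based appendage occlusion is a standard
stroke-prevention intervention for patients who cannot take
anticoagulants. Occluding the appendage, however, removes part of the
atrium's reservoir capacity and measurably raises mean left-atrial
pressure (mLAP). `atriasim` is for researchers and device engineers who
want a fast, systems-level simulator of those effects: it reproduces
sinus rhythm, atrial flutter, irregular-cycle AF, heart-rate sweeps,
contractility sweeps and the LAAO intervention as parameter variants of
a single closed circuit, together with the waveform analysis used to
quantify them (a/c/v waves, mitral E/A peaks, cardiac output, and the
figure-eight decomposition of the LA pressure–volume loop).

## The model

The circulation is a fixed-topology network of eight storage elements

```
PV → LA → MV → LV → AoV → SA → SV → RA → TV → RV → PuV → PA → PV
```

with four time-varying-elastance chambers (LA, LV, RA, RV), four linear
RC vascular compartments (systemic/pulmonary arterial and venous) and
four ideal diode valves. Chamber pressure follows the blended elastance
convention

```
P(V, t) = e(t) · Ees (V − V0)  +  (1 − e(t)) · A_res (exp(B_res (V − V0)) − 1)
```

— the activation e(t) ∈ [0, 1] interpolates between an end-systolic
line of slope `Ees` and an exponential end-diastolic (reservoir) curve
with amplitude `A_res` and stiffness exponent `B_res`. The left-atrial
coefficients are the published set (Ees 0.45 mmHg/mL, V0 0 mL,
A_res 0.5, B_res 0.049); occlusion is modelled purely as the published
parameter changes A_res → 0.35, B_res → 0.07, Ees → 0.7. A small
viscoelastic wall term (`P += η dV/dt`) gives the PV trajectory its
reservoir-phase hysteresis. The eight volume ODEs conserve total blood
volume exactly and are integrated with a stiff implicit solver (BDF)
over 30 s runs, with metrics computed on the final five steady-state
beats.

Everything the published LA block does not pin down — ventricular and
right-heart elastances, vascular resistances and compliances, total
volume — is a calibrated stand-in fitted once, with the package's own
calibration module, to the loop's documented operating points at
60 bpm (aortic pressure 115/60 mmHg, cardiac output 5.3 L/min,
pre-occlusion mLAP 17.1 mmHg); see `docs/methods.md`.

## Worked example

```python
from atriasim import mean_lap, simulate
from atriasim.presets import baseline_sinus
from atriasim.scenarios import apply_laao

base = baseline_sinus()                    # calibrated 60 bpm circuit
pre = simulate(base, duration=30.0)
post = simulate(apply_laao(base), duration=30.0)
print(f"mLAP pre {mean_lap(pre):.2f} -> post {mean_lap(post):.2f} mmHg")
```

prints

```
mLAP pre 17.10 -> post 18.69 mmHg
```

— occluding the appendage (stiffer, lower-amplitude reservoir curve and
higher atrial elastance) raises the steady-state mean left-atrial
pressure by about 1.6 mmHg in this calibration, the systems-level
signature of lost reservoir function. The `examples/` directory has one
short script per capability: the baseline hemodynamic summary
(`sinus_baseline.py`), the occlusion comparison including pulmonary-vein
backflow (`laao_comparison.py`), figure-eight PV-loop decomposition in
sinus vs flutter vs AF (`arrhythmia_pv_loops.py`), heart-rate and
contractility sweeps (`rate_and_contractility_sweeps.py`) and
parameter-estimation recovery (`calibrate_and_recover.py`). For
example, `arrhythmia_pv_loops.py` prints

```
sinus 60 bpm     mLAP 17.10 mmHg | figure-eight: True  | subloops: cw -37 mmHg*mL, ccw +159 mmHg*mL | a-wave: present
flutter 150 bpm  mLAP 21.08 mmHg | figure-eight: False | subloops: cw -27 mmHg*mL | a-wave: absent
```

— the sinus loop splits at its self-intersection into a
counter-clockwise a-loop (atrial pump work) and a clockwise v-loop
(reservoir filling); flutter retains only the v-loop.

A thin CLI mirrors the library (`atriasim simulate|sweep|metrics|
calibrate|fixtures`); waveforms travel as tidy CSV (`time_s`,
`p_<element>`, `v_<element>`, `q_<edge>`) so externally recorded traces
can be pushed through the same metrics.

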