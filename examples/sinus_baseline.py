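"""Baseline sinus rhythm: simulate the calibrated closed loop at 60 bpm
and print the standard left-heart hemodynamic summary."""

from atriasim import beat_metrics, mean_lap, simulate
from atriasim.presets import baseline_sinus

circuit = baseline_sinus()
result = simulate(circuit, duration=30.0)

bm = beat_metrics(result)
p_sa = result.pressures["SA"][result.time > 25.0]
p_lv = result.pressures["LV"][result.time > 25.0]

print(f"mean LA pressure      {mean_lap(result):6.2f} mmHg")
print(f"cardiac output        {bm.cardiac_output:6.2f} L/min")
print(f"stroke volume         {bm.stroke_volume:6.1f} mL")
print(f"aortic pressure       {p_sa.max():5.1f}/{p_sa.min():.1f} mmHg")
print(f"LV pressure           {p_lv.max():5.1f}/{p_lv.min():.1f} mmHg")
print(f"LAP a-wave peak       {bm.a_peak.value:6.2f} mmHg")
print(f"LAP v-wave peak       {bm.v_peak.value:6.2f} mmHg")
print(f"mitral E peak         {bm.e_peak.value:6.0f} mL/s")
print(f"mitral A peak         {bm.a_flow_peak.value:6.0f} mL/s")
print()
print("The a-wave is the atrial kick (pump phase), the v-wave passive "
      "atrial filling (reservoir phase); E and A are early-diastolic "
      "and atrial-driven mitral inflow. Values sit in the elevated-LAP "
      "regime of an occlusion candidate.")
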