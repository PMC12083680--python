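"""Parameter estimation: recover a perturbed systemic resistance from
hemodynamic targets generated by the unperturbed circuit."""

from atriasim import (
    CalibrationSpec,
    TargetFeatures,
    calibrate,
    feature_vector,
    get_param,
    set_param,
    simulate,
)
from atriasim.presets import baseline_sinus

base = baseline_sinus()
path = "compartments.SA.outflow_resistance"
truth = get_param(base, path)

ref = feature_vector(simulate(base, 12.0, rtol=1e-5), beats=3)
targets = TargetFeatures(aortic_systolic=ref.aortic_systolic,
                         aortic_diastolic=ref.aortic_diastolic,
                         cardiac_output=ref.cardiac_output,
                         mean_lap=ref.mean_lap)

start = set_param(base, path, 1.3 * truth)   # +30% perturbation
spec = CalibrationSpec(free={path: (0.5 * truth, 2.0 * truth)},
                       max_evaluations=50, sim_duration=12.0,
                       analysis_beats=3, rtol=1e-5)
result = calibrate(start, spec, targets)

fitted = get_param(result.circuit, path)
print(f"true SVR      {truth:.4f} mmHg*s/mL")
print(f"perturbed     {1.3 * truth:.4f}")
print(f"recovered     {fitted:.4f}  ({100 * (fitted / truth - 1):+.1f}%)")
print(f"objective     {result.objective:.2e} after "
      f"{result.n_evaluations} evaluations")
print()
print("The bounded simplex search drives the weighted relative error "
      "between simulated and target features to ~0, recovering the "
      "perturbed resistance; the same machinery fits the baseline "
      "circuit to bench or literature operating points.")
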