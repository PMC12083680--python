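"""Parameter estimation: fit free circuit parameters to hemodynamic
targets.

The objective is a weighted sum of squared *relative* errors between
simulated and target features, which makes pressures (mmHg) and flows
(L/min) commensurable. The search is a bounded Nelder-Mead simplex
(derivative-free): every objective evaluation is a full stiff ODE
solve with non-smooth valve switching, so gradient methods are a poor
fit. Given identical inputs the whole procedure is deterministic.

The four published LA constitutive parameters are treated as fixed
model inputs and are excluded from the free set by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from . import metrics as _metrics
from .engine import SimulationError, SimulationResult, simulate
from .params import CircuitParams, get_param, set_param

_LA_PREFIX = "chambers.LA.constitutive"

#: Feature names understood by :func:`feature_vector`.
FEATURE_NAMES = ("aortic_systolic", "aortic_diastolic", "cardiac_output",
                 "mean_lap", "ea_ratio")


@dataclass(frozen=True)
class TargetFeatures:
    """Hemodynamic targets; any subset may be present.

    Units: pressures mmHg, cardiac_output L/min, ea_ratio dimensionless.
    ``weights`` default to 1 for each present feature.
    """

    aortic_systolic: Optional[float] = None
    aortic_diastolic: Optional[float] = None
    cardiac_output: Optional[float] = None
    mean_lap: Optional[float] = None
    ea_ratio: Optional[float] = None
    weights: Dict[str, float] = field(default_factory=dict)

    def present(self) -> Dict[str, float]:
        out = {k: getattr(self, k) for k in FEATURE_NAMES
               if getattr(self, k) is not None}
        if not out:
            raise ValueError("at least one target feature must be set")
        return out

    def weight(self, name: str) -> float:
        w = self.weights.get(name, 1.0)
        if w <= 0:
            raise ValueError(f"weight for {name} must be > 0")
        return w


@dataclass(frozen=True)
class CalibrationSpec:
    """Free-parameter declaration and optimizer budget.

    ``free`` maps dotted parameter paths (see
    :func:`atriasim.params.set_param`) to finite (lower, upper) bounds.
    ``sim_duration``/``analysis_beats`` control the per-evaluation
    simulation; shorter settings trade steady-state margin for speed.
    """

    free: Dict[str, Tuple[float, float]]
    max_evaluations: int = 200
    seed: int = 0
    sim_duration: float = 30.0
    analysis_beats: int = 5
    rtol: float = 1e-6

    def __post_init__(self) -> None:
        for path, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{path}: bounds must be finite, lo < hi")
            if path.startswith(_LA_PREFIX):
                raise ValueError(
                    f"{path}: LA constitutive parameters are fixed model "
                    "inputs and cannot be calibrated")


@dataclass
class CalibrationResult:
    circuit: CircuitParams
    objective: float
    objective_trajectory: List[float]      # best-so-far per evaluation
    achieved: TargetFeatures
    converged: bool
    n_evaluations: int


def feature_vector(result: SimulationResult,
                   beats: int = 5) -> TargetFeatures:
    """Extract the calibration features from a steady-state run."""
    intervals = result.beats()
    if len(intervals) < beats:
        raise ValueError("run too short for the analysis window")
    t0, t1 = intervals[-beats][0], intervals[-1][1]
    sl = slice(int(np.searchsorted(result.time, t0)),
               int(np.searchsorted(result.time, t1)) + 1)
    if "SA" not in result.pressures or "AoV" not in result.flows:
        raise ValueError("run lacks systemic-arterial traces")
    p_sa = result.pressures["SA"][sl]
    co = _metrics.cardiac_output(result.time[sl], result.flows["AoV"][sl])
    ml = _metrics.mean_lap(result, beats=beats)
    ea = _metrics.mitral_ea(result.time, result.flows["MV"],
                            intervals[-1], circuit=result.circuit)
    return TargetFeatures(
        aortic_systolic=float(np.max(p_sa)),
        aortic_diastolic=float(np.min(p_sa)),
        cardiac_output=co,
        mean_lap=ml,
        ea_ratio=ea.ea_ratio,
    )


def _objective(sim: TargetFeatures, targets: TargetFeatures) -> float:
    total = 0.0
    for name, tgt in targets.present().items():
        val = getattr(sim, name)
        if val is None:
            return 1e6
        total += targets.weight(name) * ((val - tgt) / tgt) ** 2
    return total


def calibrate(base: CircuitParams, spec: CalibrationSpec,
              targets: TargetFeatures) -> CalibrationResult:
    """Fit the free parameters of ``base`` to ``targets``.

    Starts from the base circuit's current values (which must lie
    within the declared bounds) with the initial simplex scaled to the
    bounds; returns the best candidate found when the evaluation budget
    is exhausted. A failing simulation penalizes the candidate rather
    than aborting the search.
    """
    targets.present()   # validate early
    paths = list(spec.free)
    lo = np.array([spec.free[p][0] for p in paths])
    hi = np.array([spec.free[p][1] for p in paths])
    x0 = np.array([get_param(base, p) for p in paths])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("free parameters must start within bounds")

    trajectory: List[float] = []
    best = {"x": x0.copy(), "f": np.inf}

    def build(x: np.ndarray) -> CircuitParams:
        circuit = base
        for p, v in zip(paths, np.clip(x, lo, hi)):
            circuit = set_param(circuit, p, float(v))
        return circuit

    def evaluate(x: np.ndarray) -> float:
        try:
            res = simulate(build(x), duration=spec.sim_duration,
                           rtol=spec.rtol)
            f = _objective(feature_vector(res, beats=spec.analysis_beats),
                           targets)
        except (SimulationError, ValueError):
            f = 1e6
        if f < best["f"]:
            best["f"] = f
            best["x"] = np.clip(np.asarray(x, float), lo, hi)
        trajectory.append(min(f, best["f"]))
        return f

    converged = False
    if spec.max_evaluations > 0:
        opt = minimize(evaluate, x0, method="Nelder-Mead",
                       bounds=list(zip(lo, hi)),
                       options={"maxfev": spec.max_evaluations,
                                "xatol": 1e-4 * float(np.mean(hi - lo)),
                                "fatol": 1e-8,
                                "initial_simplex": _initial_simplex(
                                    x0, lo, hi)})
        converged = bool(opt.success)
    else:
        evaluate(x0)

    fitted = build(best["x"])
    final = simulate(fitted, duration=spec.sim_duration, rtol=spec.rtol)
    achieved = feature_vector(final, beats=spec.analysis_beats)
    return CalibrationResult(circuit=fitted, objective=float(best["f"]),
                             objective_trajectory=trajectory,
                             achieved=achieved, converged=converged,
                             n_evaluations=len(trajectory))


def _initial_simplex(x0: np.ndarray, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    """Simplex spanning ~15% of each bound interval around x0."""
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        step = 0.15 * (hi[i] - lo[i])
        xi = x0[i] + step if x0[i] + step <= hi[i] else x0[i] - step
        simplex[i + 1, i] = xi
    return simplex
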