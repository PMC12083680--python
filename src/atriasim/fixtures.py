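"""Deterministic synthetic fixtures for the analysis pipeline.

Every fixture regenerates bit-identically from its seed, and each
synthetic trace carries its analytically known answers alongside the
data, so detector output can be checked against ground truth without a
simulation in the loop:

* a three-bump LA pressure beat with Gaussian peaks centred in the
  a-, c- and v-wave classification windows;
* a two-lobe mitral inflow beat (E and A lobes);
* the "bowtie" self-intersecting PV path (two unit triangles crossing
  at the origin, signed areas -1 and +1);
* the reference circuits (baseline sinus, post-LAAO, flutter at
  150 bpm, irregular AF).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from .params import CircuitParams
from .presets import baseline_sinus
from .scenarios import apply_laao, make_af, make_flutter

#: (center, amplitude, width) of the synthetic LAP bumps, phases of a
#: 1 s beat; centers sit inside the a/c/v classification windows.
LAP_BUMPS: Dict[str, Tuple[float, float, float]] = {
    "a": (0.84, 5.0, 0.030),
    "c": (0.075, 2.0, 0.020),
    "v": (0.30, 4.0, 0.040),
}
LAP_BASELINE_MMHG = 10.0

#: (center, amplitude, width) of the synthetic mitral-flow lobes.
MITRAL_LOBES: Dict[str, Tuple[float, float, float]] = {
    "e": (0.45, 300.0, 0.050),
    "a": (0.84, 200.0, 0.040),
}


@dataclass(frozen=True)
class SyntheticTrace:
    """A generated trace with its analytically known peak answers."""

    time: np.ndarray
    values: np.ndarray
    answers: Dict[str, Tuple[float, float]]   # name -> (time, value)


@dataclass(frozen=True)
class FixtureSet:
    seed: int
    circuits: Dict[str, CircuitParams]
    lap_three_bump: SyntheticTrace
    mitral_two_lobe: SyntheticTrace
    bowtie: np.ndarray                        # closed (n, 2) path
    bowtie_areas: Tuple[float, float]         # signed subloop areas

    def write(self, directory) -> None:
        """Dump traces as CSV and answers as JSON (deterministic bytes)."""
        import json

        from .io import save_config

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        answers = {"seed": self.seed,
                   "lap_three_bump": self.lap_three_bump.answers,
                   "mitral_two_lobe": self.mitral_two_lobe.answers,
                   "bowtie_areas": list(self.bowtie_areas)}
        for name, trace, col in (
                ("lap_three_bump", self.lap_three_bump, "p_la"),
                ("mitral_two_lobe", self.mitral_two_lobe, "q_mv")):
            with open(d / f"{name}.csv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write(f"time_s,{col}\n")
                for t, v in zip(trace.time, trace.values):
                    fh.write(f"{t:.17g},{v:.17g}\n")
        with open(d / "bowtie.csv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("v_la,p_la\n")
            for x, y in self.bowtie:
                fh.write(f"{x:.17g},{y:.17g}\n")
        with open(d / "answers.json", "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(answers, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for name, circ in self.circuits.items():
            save_config(circ, d / f"{name}.json")


def _bump_trace(bumps: Dict[str, Tuple[float, float, float]],
                baseline: float, n: int, noise_sd: float,
                rng: np.random.Generator) -> SyntheticTrace:
    t = np.arange(n) / n                      # one 1 s beat, [0, 1)
    x = np.full(n, baseline)
    answers = {}
    for name, (center, amp, width) in bumps.items():
        x = x + amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        answers[name] = (center, baseline + amp)
    x = x + noise_sd * rng.standard_normal(n)
    return SyntheticTrace(time=t, values=x, answers=answers)


def bowtie_path() -> np.ndarray:
    """Closed self-intersecting path: two unit triangles crossing at
    the origin, with signed areas -1 (cw) and +1 (ccw)."""
    return np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0],
                     [1.0, 1.0], [-1.0, -1.0]])


def generate_fixtures(seed: int = 0, *, n_samples: int = 500,
                      noise_sd: float = 0.0) -> FixtureSet:
    """Build the full fixture set for ``seed``.

    ``noise_sd`` adds Gaussian noise to the synthetic traces (zero by
    default so peak answers are exact to the sample).
    """
    rng = np.random.default_rng(seed)
    lap = _bump_trace(LAP_BUMPS, LAP_BASELINE_MMHG, n_samples,
                      noise_sd, rng)
    mitral = _bump_trace(MITRAL_LOBES, 0.0, n_samples, noise_sd, rng)
    base = baseline_sinus()
    circuits = {
        "baseline_sinus": base,
        "laao": apply_laao(base),
        "flutter_150": make_flutter(base, 150.0),
        "af_irregular": make_af(base),
    }
    return FixtureSet(seed=seed, circuits=circuits, lap_three_bump=lap,
                      mitral_two_lobe=mitral, bowtie=bowtie_path(),
                      bowtie_areas=(-1.0, 1.0))
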