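"""Synthetic stress–strain curves with known ground truth.

Forward-evaluates any of the constitutive models on a strain grid and adds a
controlled noise model, so every fitter can be validated by parameter
recovery without external data.  Reference parameter sets for the two
specimens the models were built around — a bovine Achilles tendon and a
rabbit medial collateral ligament — are provided as module constants.

Noise is applied to stress only; strain is treated as exact, the standard
tensile-test convention that keeps ordinary least squares appropriate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .models import (
    BilinearParams,
    CombinedParams,
    PiecewiseParams,
    StressStrainCurve,
    eval_bilinear,
    eval_combined,
    eval_piecewise,
)

__all__ = [
    "NoiseSpec",
    "strain_grid",
    "generate_curve",
    "TENDON_PIECEWISE",
    "TENDON_COMBINED",
    "LIGAMENT_PIECEWISE",
    "LIGAMENT_COMBINED",
    "TENDON_EPS_MAX",
    "LIGAMENT_EPS_MAX",
]

# Identified parameters for the two reference specimens.
TENDON_PIECEWISE = PiecewiseParams(k1=22820.0, n=1.58, eps_c=0.028, eps_th=0.022, E=377.2)
TENDON_COMBINED = CombinedParams(k1=2330.0, n=1.02, eps_c=0.025, E=194.8)
LIGAMENT_PIECEWISE = PiecewiseParams(k1=1718.0, n=1.02, eps_c=0.048, eps_th=0.040, E=492.1)
LIGAMENT_COMBINED = CombinedParams(k1=1149.0, n=1.01, eps_c=0.044, E=330.4)

# Default strain spans covering both regions with a wide margin on each side:
# the ligament's linear region extends to higher strain than the tendon's.
TENDON_EPS_MAX = 0.06
LIGAMENT_EPS_MAX = 0.08

_EVALUATORS = {
    "piecewise": (PiecewiseParams, eval_piecewise),
    "combined": (CombinedParams, eval_combined),
    "bilinear": (BilinearParams, eval_bilinear),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian stress noise.

    kind : "none", "gaussian_absolute" (sd in MPa) or
        "gaussian_relative_to_max" (sd as a fraction of the max noiseless
        stress).
    sd : noise scale in the units `kind` implies; >= 0.
    seed : PRNG seed; a fixed seed reproduces the curve exactly.
    """

    kind: str = "none"
    sd: float = 0.0
    seed: int = 0

    _KINDS = ("none", "gaussian_absolute", "gaussian_relative_to_max")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"noise kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")


def strain_grid(eps_max: float, n_points: int, spacing: str = "uniform") -> np.ndarray:
    """Strictly increasing strain grid on (0, eps_max].

    Uniform spacing gives ``(eps_max/n, 2*eps_max/n, ..., eps_max)``; log
    spacing is geometric with ratio ``10**(2/(n-1))`` ending at eps_max,
    concentrating points in the heel region (two decades of strain).
    """
    if eps_max <= 0:
        raise ValueError(f"eps_max must be positive, got {eps_max}")
    if n_points < 2:
        raise ValueError(f"need at least 2 grid points, got {n_points}")
    if spacing == "uniform":
        return np.linspace(eps_max / n_points, eps_max, n_points)
    if spacing == "log":
        return np.geomspace(eps_max / 100.0, eps_max, n_points)
    raise ValueError(f"spacing must be 'uniform' or 'log', got {spacing!r}")


def generate_curve(model: str, params, grid, noise: NoiseSpec = NoiseSpec()) -> StressStrainCurve:
    """Forward-simulate a stress–strain curve with known ground truth.

    With ``noise.kind == "none"`` the stresses are exactly the evaluator's
    values.  The generating model and parameters are recorded in the curve's
    label as a JSON string, so ground truth travels with the curve.
    """
    try:
        params_cls, evaluator = _EVALUATORS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(_EVALUATORS)}")
    if not isinstance(params, params_cls):
        raise TypeError(
            f"model {model!r} needs {params_cls.__name__}, got {type(params).__name__}"
        )
    grid = np.asarray(grid, dtype=float)
    stress = np.asarray(evaluator(params, grid), dtype=float)
    if noise.kind != "none" and noise.sd > 0:
        sd = noise.sd
        if noise.kind == "gaussian_relative_to_max":
            sd = noise.sd * float(np.max(np.abs(stress)))
        rng = np.random.default_rng(noise.seed)
        stress = stress + rng.normal(0.0, sd, size=stress.size)
    label = json.dumps({"model": model, "params": asdict(params)})
    return StressStrainCurve(grid, stress, label=label)
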