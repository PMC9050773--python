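"""Constitutive relations for collagen-fiber tissues.

The stress–strain response of tendon and ligament shows a concave-up *heel*
(toe) region, attributed to straightening of crimped collagen, followed by a
near-linear region where the collagen backbones are stretched.  Three
closed-form descriptions of that response are provided here:

piecewise
    ``sigma = k1 * eps**(n+1)`` for ``eps < eps_c`` and
    ``sigma = E * (eps - eps_th)`` for ``eps >= eps_c``.  The transition
    strain ``eps_c`` separates the two regimes; ``eps_th`` is the strain-axis
    intercept of the extrapolated linear region, so ``E`` is exactly the
    linear-region tangent modulus.

combined
    ``sigma = k1 * eps**(n+1) + H(eps - eps_c) * E * (eps - eps_c)``.  The
    power-law term stays active at all strains, so the tangent modulus above
    ``eps_c`` is ``k1*(n+1)*eps**n + E`` and the fitted ``E`` *understates*
    the linear-region modulus.

bilinear
    Two straight lines switching at their intersection strain.

All stresses are in MPa and strains are dimensionless engineering strains;
there is no unit-conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "StressStrainCurve",
    "PiecewiseParams",
    "CombinedParams",
    "BilinearParams",
    "heaviside",
    "eval_piecewise",
    "eval_combined",
    "eval_combined_slope",
    "eval_bilinear",
    "continuity_gap",
    "critical_strain_from_ratio",
]

FloatArray = npt.NDArray[np.float64]


def _as_strain_array(strain) -> FloatArray:
    eps = np.atleast_1d(np.asarray(strain, dtype=float))
    if not np.all(np.isfinite(eps)):
        raise ValueError("strain values must be finite")
    if np.any(eps < 0):
        raise ValueError("strain values must be non-negative")
    return eps


def _scalar_like(strain, values: FloatArray):
    # preserve scalar-in / scalar-out while evaluators work on arrays
    if np.ndim(strain) == 0:
        return float(values[0])
    return values


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired strain/stress samples from a tensile test or simulator.

    Parameters
    ----------
    strain : array-like
        Dimensionless engineering strains, strictly increasing, >= 0.
    stress : array-like
        Stresses in MPa, same length as `strain`, finite.
    label : str
        Free-text specimen tag (the synthetic generator stores ground-truth
        parameters here).
    """

    strain: FloatArray
    stress: FloatArray
    label: str = ""

    def __post_init__(self):
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if strain.ndim != 1 or stress.ndim != 1:
            raise ValueError("strain and stress must be one-dimensional")
        if strain.size != stress.size:
            raise ValueError(
                f"strain ({strain.size}) and stress ({stress.size}) lengths differ"
            )
        if strain.size < 2:
            raise ValueError("a curve needs at least 2 points")
        if not np.all(np.isfinite(strain)) or not np.all(np.isfinite(stress)):
            raise ValueError("strain and stress must be finite")
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative")
        if np.any(np.diff(strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        strain.setflags(write=False)
        stress.setflags(write=False)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return int(self.strain.size)

    def scaled(self, c: float) -> "StressStrainCurve":
        """Return a copy with all stresses multiplied by `c`."""
        return StressStrainCurve(self.strain, self.stress * float(c), self.label)


@dataclass(frozen=True)
class PiecewiseParams:
    """Parameters of the piecewise heel/linear constitutive relation.

    k1 : MPa, heel-region power-law coefficient (> 0)
    n : dimensionless heel exponent offset; the evaluator raises strain to
        ``n + 1`` (> 0)
    eps_c : dimensionless transition strain (> 0)
    eps_th : dimensionless threshold (intercept) strain of the linear
        region, 0 < eps_th <= eps_c
    E : MPa, linear-region modulus (> 0)
    """

    k1: float
    n: float
    eps_c: float
    eps_th: float
    E: float

    def __post_init__(self):
        if not (self.k1 > 0):
            raise ValueError(f"k1 must be positive, got {self.k1}")
        if not (self.n > 0):
            raise ValueError(f"n must be positive, got {self.n}")
        if not (0 < self.eps_th <= self.eps_c):
            raise ValueError(
                f"need 0 < eps_th <= eps_c, got eps_th={self.eps_th}, eps_c={self.eps_c}"
            )
        if not (self.E > 0):
            raise ValueError(f"E must be positive, got {self.E}")

    @classmethod
    def continuous(cls, k1: float, n: float, eps_c: float, E: float) -> "PiecewiseParams":
        """Construct with eps_th chosen so the relation is exactly continuous.

        Eliminates eps_th via ``eps_th = eps_c - k1 * eps_c**(n+1) / E``, the
        unique value at which the heel and linear branches meet at eps_c.
        """
        eps_th = eps_c - k1 * eps_c ** (n + 1.0) / E
        return cls(k1=k1, n=n, eps_c=eps_c, eps_th=eps_th, E=E)


@dataclass(frozen=True)
class CombinedParams:
    """Parameters of the combined (always-on power law + switched line) model."""

    k1: float
    n: float
    eps_c: float
    E: float

    def __post_init__(self):
        for name in ("k1", "n", "eps_c"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.E < 0:
            raise ValueError(f"E must be non-negative, got {self.E}")


@dataclass(frozen=True)
class BilinearParams:
    """Two line segments switching at their intersection strain.

    The intersection ``eps_c = (b_heel - b_lin) / (E - E_heel)`` is computed
    at construction; passing it explicitly is allowed only if consistent.
    """

    E_heel: float
    b_heel: float
    E: float
    b_lin: float
    eps_c: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.E == self.E_heel:
            raise ValueError("parallel lines: E must differ from E_heel")
        eps_c = (self.b_heel - self.b_lin) / (self.E - self.E_heel)
        if self.eps_c is None:
            object.__setattr__(self, "eps_c", eps_c)
        elif not np.isclose(self.eps_c, eps_c, rtol=1e-9, atol=1e-12):
            raise ValueError(
                f"eps_c={self.eps_c} inconsistent with line intersection {eps_c}"
            )


def heaviside(x: float) -> int:
    """Unit step function with the strict convention H(0) = 0.

    Note the piecewise evaluator does *not* rely on this primitive at the
    transition strain: under the strict convention both switching factors
    vanish at ``eps == eps_c``, which would zero the stress there, so the
    boundary sample is assigned to the linear branch by explicit logic in
    :func:`eval_piecewise`.
    """
    x = float(x)
    if not np.isfinite(x):
        raise ValueError("heaviside requires a finite argument")
    return 1 if x > 0 else 0


def eval_piecewise(params: PiecewiseParams, strain):
    """Evaluate the piecewise relation; heel on [0, eps_c), linear on [eps_c, inf).

    ``eps**(n+1)`` at ``eps = 0`` is defined as 0 (its limit), so the curve
    always starts at the origin.
    """
    eps = _as_strain_array(strain)
    linear = eps >= params.eps_c
    sigma = np.where(
        linear,
        params.E * (eps - params.eps_th),
        params.k1 * np.power(eps, params.n + 1.0),
    )
    return _scalar_like(strain, sigma)


def eval_combined(params: CombinedParams, strain):
    """Evaluate the combined model: power law everywhere + line above eps_c."""
    eps = _as_strain_array(strain)
    term1 = params.k1 * np.power(eps, params.n + 1.0)
    term2 = np.where(eps > params.eps_c, params.E * (eps - params.eps_c), 0.0)
    return _scalar_like(strain, term1 + term2)


def eval_combined_slope(params: CombinedParams, strain: float) -> float:
    """Tangent modulus of the combined model above the transition strain.

    Returns ``k1*(n+1)*eps**n + E``.  Because the power-law term never
    switches off, this exceeds ``E`` for every positive strain: the fitted
    ``E`` of the combined model is not the linear-region modulus.
    Only defined for ``strain > eps_c``, the regime where the stated slope
    applies.
    """
    eps = float(strain)
    if not np.isfinite(eps):
        raise ValueError("strain must be finite")
    if eps <= params.eps_c:
        raise ValueError(
            f"slope formula applies above the transition strain: {eps} <= {params.eps_c}"
        )
    return params.k1 * (params.n + 1.0) * eps**params.n + params.E


def eval_bilinear(params: BilinearParams, strain):
    """Evaluate the bilinear model; low-strain line below eps_c, high-strain at/above."""
    eps = _as_strain_array(strain)
    sigma = np.where(
        eps >= params.eps_c,
        params.E * eps + params.b_lin,
        params.E_heel * eps + params.b_heel,
    )
    return _scalar_like(strain, sigma)


def continuity_gap(params: PiecewiseParams) -> float:
    """Stress jump of the piecewise relation at the transition strain, in MPa.

    Returns ``k1*eps_c**(n+1) - E*(eps_c - eps_th)`` (heel branch minus linear
    branch, both evaluated at eps_c).  Zero means exactly continuous.  The
    threshold strain eps_th exists to close this gap, but freely fitted (or
    rounded) parameter sets are typically only approximately continuous.
    """
    heel = params.k1 * params.eps_c ** (params.n + 1.0)
    linear = params.E * (params.eps_c - params.eps_th)
    return heel - linear


def critical_strain_from_ratio(numerator: float, denominator: float) -> float:
    """Transition strain from a ratio of two moduli: ``numerator/denominator - 1``.

    Utility for the helical-spring estimate of the critical strain, which is
    obtained from the ratio of the fully-stretched to the linear-region
    modulus (e.g. 437/426 - 1 = 0.026 for bovine Achilles tendon).
    """
    numerator = float(numerator)
    denominator = float(denominator)
    if not (numerator > 0 and denominator > 0):
        raise ValueError("both moduli must be positive")
    return numerator / denominator - 1.0
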