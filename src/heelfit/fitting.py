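"""Least-squares identification of constitutive parameters from a curve.

All three fitters share a *profiled-breakpoint* strategy: the transition
strain eps_c is profiled over a deterministic candidate grid, each candidate
splits the curve into a heel and a linear subset, closed-form or log-linear
sub-fits identify the branch parameters, and the candidate with the smallest
total squared residual wins.  A bounded trust-region refinement then polishes
the smooth parameters from that starting point.  No random starts are used,
so a fit is a deterministic function of (curve, options).

For the piecewise model the sum of squared residuals is constant in eps_c
between two adjacent strain samples (eps_c only assigns points to branches),
so eps_c is identifiable only up to that interval; the reported eps_c is the
interval midpoint.  When continuity is enforced, eps_th is eliminated via
``eps_th = eps_c - k1*eps_c**(n+1)/E`` and eps_c becomes a smooth, genuinely
identified parameter that is refined continuously within the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar, nnls

from .models import (
    BilinearParams,
    CombinedParams,
    PiecewiseParams,
    StressStrainCurve,
    continuity_gap,
    eval_bilinear,
    eval_combined,
    eval_piecewise,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "FitError",
    "r_squared",
    "fit_linear_region",
    "fit_heel_region",
    "fit_piecewise",
    "fit_combined",
    "fit_bilinear",
]

# physically motivated parameter bounds, wide enough for tendon/ligament data
K1_BOUNDS = (1e-12, 1e7)  # MPa
N_BOUNDS = (1e-6, 10.0)  # dimensionless
E_BOUNDS = (1e-12, 1e5)  # MPa


class FitError(ValueError):
    """Raised when a curve cannot be fitted (too short, degenerate, ...)."""


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the profiled-breakpoint fit.

    eps_c_grid : number of candidate transition strains in the profile stage.
    eps_c_range : (lo, hi) strain range for the candidates; None means the
        5th–95th percentile of the observed strains.
    enforce_continuity : if True, fit the 4-parameter constrained piecewise
        model (eps_th eliminated) instead of the 5-parameter free one.
    min_points_per_branch : minimum samples required on each side of a
        candidate eps_c.
    refine_tol : relative convergence tolerance on the refinement objective.
    seed : reserved for stochastic multi-start; the default fit is
        deterministic and never consumes it.
    """

    eps_c_grid: int = 101
    eps_c_range: Optional[tuple] = None
    enforce_continuity: bool = False
    min_points_per_branch: int = 3
    refine_tol: float = 1e-10
    seed: Optional[int] = None

    def __post_init__(self):
        if self.eps_c_grid < 3:
            raise ValueError("eps_c_grid needs at least 3 candidates")
        if self.min_points_per_branch < 2:
            raise ValueError("each branch needs at least 2 points for its 2 parameters")
        if self.eps_c_range is not None:
            lo, hi = self.eps_c_range
            if not (0 <= lo < hi):
                raise ValueError(f"invalid eps_c_range {self.eps_c_range}")


ParamsT = Union[PiecewiseParams, CombinedParams, BilinearParams]


@dataclass(frozen=True)
class FitResult:
    """Identified parameters plus goodness-of-fit and convergence diagnostics."""

    model: str
    params: ParamsT
    r_squared: float
    residuals: np.ndarray
    objective: float  # sum of squared residuals, MPa^2
    converged: bool
    n_evals: int
    continuity_gap: Optional[float] = None  # MPa, piecewise only
    profile_objective: Optional[float] = None  # SSR of the pre-refinement stage
    options: Optional[FitOptions] = None

    def to_dict(self) -> dict:
        """JSON-ready report with a fixed schema."""
        return {
            "model": self.model,
            "params": asdict(self.params),
            "r_squared": self.r_squared,
            "continuity_gap_MPa": self.continuity_gap,
            "objective": self.objective,
            "converged": self.converged,
            "options": asdict(self.options) if self.options is not None else None,
        }


def r_squared(observed, predicted, kind: str = "standard") -> float:
    """Coefficient of determination of a fit.

    ``kind="standard"`` returns ``1 - SS_res/SS_tot`` (default; can be
    negative for a fit worse than the mean).  ``kind="regression"`` returns
    the regression-sum-of-squares variant ``SS_reg/SS_tot``; the two coincide
    for ordinary linear least squares with an intercept but not in general.
    """
    y = np.asarray(observed, dtype=float)
    d = np.asarray(predicted, dtype=float)
    if y.size != d.size or y.size == 0:
        raise ValueError("observed and predicted must have equal nonzero lengths")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero total variance: R^2 undefined for constant data")
    if kind == "standard":
        return 1.0 - float(np.sum((y - d) ** 2)) / ss_tot
    if kind == "regression":
        return float(np.sum((d - y.mean()) ** 2)) / ss_tot
    raise ValueError(f"unknown R^2 kind: {kind!r}")


# ---------------------------------------------------------------------------
# branch sub-fits


def fit_linear_region(curve: StressStrainCurve) -> tuple:
    """OLS fit of the linear region as ``sigma = E * (eps - eps_th)``.

    Returns ``(E, eps_th)`` where eps_th is the strain-axis intercept,
    ``-intercept/E`` of the fitted line.  Exact normal-equation solution.
    """
    E, b = _ols_line(curve.strain, curve.stress)
    if E == 0.0:
        raise FitError("linear region has zero slope: eps_th undefined")
    return float(E), float(-b / E)


def _ols_line(eps: np.ndarray, sig: np.ndarray) -> tuple:
    if eps.size < 2:
        raise FitError("need at least 2 points for a line fit")
    if np.ptp(eps) == 0:
        raise FitError("singular design: all strains equal")
    A = np.column_stack([eps, np.ones_like(eps)])
    (slope, intercept), *_ = np.linalg.lstsq(A, sig, rcond=None)
    return float(slope), float(intercept)


def fit_heel_region(curve: StressStrainCurve, refine_tol: float = 1e-10) -> tuple:
    """Fit the heel region as ``sigma = k1 * eps**(n+1)``; returns ``(k1, n)``.

    A log–log least-squares line (slope = n+1, intercept = log k1) over the
    points with positive strain and stress initializes a bounded nonlinear
    refinement that minimizes squared residuals in stress space, so the
    returned pair is a stress-space optimum, not the log-space one.
    """
    k1, n, _, nfev, _ = _fit_heel(curve.strain, curve.stress, refine_tol)
    return k1, n


def _fit_heel(eps, sig, refine_tol: float = 1e-10):
    """Internal heel fit returning (k1, n, ssr, nfev, converged)."""
    pos = (eps > 0) & (sig > 0)
    if np.count_nonzero(pos) < 2:
        raise FitError("heel fit needs >= 2 points with positive strain and stress")
    slope, intercept = _ols_line(np.log(eps[pos]), np.log(sig[pos]))
    n0 = np.clip(slope - 1.0, N_BOUNDS[0], N_BOUNDS[1])
    k10 = np.clip(np.exp(intercept), K1_BOUNDS[0], K1_BOUNDS[1])

    def resid(x):
        k1, n = x
        return k1 * np.power(eps, n + 1.0) - sig

    sol = least_squares(
        resid,
        x0=[k10, n0],
        bounds=([K1_BOUNDS[0], N_BOUNDS[0]], [K1_BOUNDS[1], N_BOUNDS[1]]),
        method="trf",
        x_scale="jac",
        ftol=refine_tol,
        xtol=refine_tol,
        gtol=refine_tol,
    )
    ssr = float(np.sum(sol.fun**2))
    return float(sol.x[0]), float(sol.x[1]), ssr, int(sol.nfev), bool(sol.success)


# ---------------------------------------------------------------------------
# profile machinery

def _candidate_splits(strain: np.ndarray, options: FitOptions) -> list:
    """Map the eps_c candidate grid onto unique admissible split indices.

    Split index i assigns points [0, i) to the heel branch and [i, n) to the
    linear branch.
    """
    n = strain.size
    if options.eps_c_range is not None:
        lo, hi = options.eps_c_range
    else:
        lo, hi = np.percentile(strain, [5.0, 95.0])
    candidates = np.linspace(lo, hi, options.eps_c_grid)
    splits = np.unique(np.searchsorted(strain, candidates, side="left"))
    mpb = options.min_points_per_branch
    admissible = [int(i) for i in splits if mpb <= i <= n - mpb]
    if not admissible:
        raise FitError(
            "no candidate transition strain leaves "
            f"{mpb} points on both branches (curve has {n} points)"
        )
    return admissible


def _profile_splits(strain, stress, options, split_objective):
    """Evaluate `split_objective` over the candidate splits, then hill-climb.

    The local search over neighbouring split indices makes the result
    independent of the candidate-grid resolution: whenever the grid visits the
    basin of the best split, the exact best split is found, matching an
    exhaustive search.
    """
    n = strain.size
    mpb = options.min_points_per_branch
    cache: dict = {}

    last_error = None

    def obj(i):
        nonlocal last_error
        if i not in cache:
            try:
                cache[i] = split_objective(i)
            except FitError as exc:
                last_error = exc
                cache[i] = (np.inf, None)
        return cache[i][0]

    for i in _candidate_splits(strain, options):
        obj(i)
    # ties broken toward the smaller split index hence the smaller eps_c
    best = min(cache, key=lambda i: (cache[i][0], i))
    improved = True
    while improved:
        improved = False
        for j in (best - 1, best + 1):
            if mpb <= j <= n - mpb and obj(j) < obj(best):
                best = j
                improved = True
    if not np.isfinite(obj(best)):
        raise FitError(f"every candidate split failed to fit (last error: {last_error})")
    return best, cache[best]


# ---------------------------------------------------------------------------
# full-model fitters

def fit_piecewise(curve: StressStrainCurve, options: FitOptions = FitOptions()) -> FitResult:
    """Identify the five piecewise parameters (four when continuity is enforced).

    Profile stage: for each candidate eps_c, the heel points get a power-law
    fit and the linear points an OLS line; the split with the smallest total
    squared residual wins.  Refinement stage: bounded trust-region least
    squares over the smooth parameters started from the profile solution.
    Deterministic given (curve, options).
    """
    eps, sig = curve.strain, curve.stress
    tol = options.refine_tol
    nfev_total = 0

    def split_objective(i):
        k1, n, ssr_h, nfev, _ = _fit_heel(eps[:i], sig[:i], tol)
        E, eps_th = fit_linear_region(StressStrainCurve(eps[i:], sig[i:]))
        if E <= 0:
            raise FitError("non-positive linear-region slope")
        lin_resid = sig[i:] - E * (eps[i:] - eps_th)
        ssr = ssr_h + float(np.sum(lin_resid**2))
        return ssr, (k1, n, E, eps_th, nfev)

    best, (profile_ssr, (k1, n, E, eps_th, nfev)) = _profile_splits(
        eps, sig, options, split_objective
    )
    nfev_total += nfev
    # eps_c is flat between samples: report the split-interval midpoint,
    # then refine the smooth parameters (incl. eps_c itself if constrained)
    lo, hi = eps[best - 1], eps[best]
    eps_c0 = 0.5 * (lo + hi)
    heel_mask = np.arange(eps.size) < best

    if options.enforce_continuity:
        def resid(x):
            k1_, n_, ec_, E_ = x
            eth_ = ec_ - k1_ * ec_ ** (n_ + 1.0) / E_
            pred = np.where(heel_mask, k1_ * np.power(eps, n_ + 1.0), E_ * (eps - eth_))
            return pred - sig

        x0 = [k1, n, eps_c0, E]
        lb = [K1_BOUNDS[0], N_BOUNDS[0], np.nextafter(lo, np.inf), E_BOUNDS[0]]
        ub = [K1_BOUNDS[1], N_BOUNDS[1], hi, E_BOUNDS[1]]
    else:
        def resid(x):
            k1_, n_, eth_, E_ = x
            pred = np.where(heel_mask, k1_ * np.power(eps, n_ + 1.0), E_ * (eps - eth_))
            return pred - sig

        x0 = [k1, n, np.clip(eps_th, 0.0, eps_c0), E]
        lb = [K1_BOUNDS[0], N_BOUNDS[0], 0.0, E_BOUNDS[0]]
        ub = [K1_BOUNDS[1], N_BOUNDS[1], eps_c0, E_BOUNDS[1]]

    sol = least_squares(
        resid, x0=np.clip(x0, lb, ub), bounds=(lb, ub), method="trf",
        x_scale="jac", ftol=tol, xtol=tol, gtol=tol,
    )
    nfev_total += int(sol.nfev)
    refined_ssr = float(np.sum(sol.fun**2))
    if refined_ssr <= profile_ssr:
        if options.enforce_continuity:
            params = PiecewiseParams.continuous(sol.x[0], sol.x[1], sol.x[2], sol.x[3])
        else:
            params = PiecewiseParams(sol.x[0], sol.x[1], eps_c0, max(sol.x[2], np.finfo(float).tiny), sol.x[3])
        converged = bool(sol.success)
    else:  # refinement failed to improve: keep the profile solution
        if options.enforce_continuity:
            params = PiecewiseParams.continuous(k1, n, eps_c0, E)
        else:
            params = PiecewiseParams(k1, n, eps_c0, max(eps_th, np.finfo(float).tiny), E)
        converged = False

    pred = eval_piecewise(params, eps)
    residuals = sig - pred
    return FitResult(
        model="piecewise",
        params=params,
        r_squared=r_squared(sig, pred),
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        converged=converged,
        n_evals=nfev_total,
        continuity_gap=continuity_gap(params),
        profile_objective=profile_ssr,
        options=options,
    )


def _combined_varpro(eps, sig, eps_c, n):
    """Best (k1, E) >= 0 for fixed (eps_c, n) by non-negative least squares."""
    A = np.column_stack([np.power(eps, n + 1.0), np.clip(eps - eps_c, 0.0, None)])
    coef, rnorm = nnls(A, sig)
    return coef[0], coef[1], rnorm**2


def fit_combined(curve: StressStrainCurve, options: FitOptions = FitOptions()) -> FitResult:
    """Identify (k1, n, eps_c, E) of the combined model.

    The power-law term is fitted against all points and the switched linear
    term against the points above the candidate eps_c.  For each candidate,
    (k1, E) are profiled out exactly by non-negative least squares and n by a
    bounded scalar search; the best candidate seeds a joint bounded
    refinement of all four parameters (eps_c is smoothly identified here,
    unlike in the piecewise model).  Deterministic given (curve, options).
    """
    eps, sig = curve.strain, curve.stress
    tol = options.refine_tol
    n = eps.size
    mpb = options.min_points_per_branch
    if options.eps_c_range is not None:
        lo, hi = options.eps_c_range
    else:
        lo, hi = np.percentile(eps, [5.0, 95.0])
    # keep candidates admissible: >= mpb points on each side
    lo = max(lo, eps[mpb - 1] + 1e-12)
    hi = min(hi, eps[n - mpb])
    if not lo < hi:
        raise FitError("curve too short for the requested points-per-branch")
    candidates = np.linspace(lo, hi, options.eps_c_grid)

    best = None
    for ec in candidates:
        res = minimize_scalar(
            lambda nn: _combined_varpro(eps, sig, ec, nn)[2],
            bounds=N_BOUNDS, method="bounded",
        )
        if best is None or res.fun < best[0]:
            k1c, Ec, ssr = _combined_varpro(eps, sig, ec, res.x)
            best = (ssr, k1c, float(res.x), float(ec), Ec)
    profile_ssr, k1, n_exp, eps_c0, E = best

    def resid(x):
        k1_, n_, ec_, E_ = x
        return (
            k1_ * np.power(eps, n_ + 1.0)
            + np.where(eps > ec_, E_ * (eps - ec_), 0.0)
            - sig
        )

    lb = [K1_BOUNDS[0], N_BOUNDS[0], eps[0], 0.0]
    ub = [K1_BOUNDS[1], N_BOUNDS[1], eps[-1], E_BOUNDS[1]]
    x0 = np.clip([max(k1, K1_BOUNDS[0]), n_exp, eps_c0, max(E, 0.0)], lb, ub)
    sol = least_squares(
        resid, x0=x0, bounds=(lb, ub), method="trf",
        x_scale="jac", ftol=tol, xtol=tol, gtol=tol,
    )
    refined_ssr = float(np.sum(sol.fun**2))
    if refined_ssr <= profile_ssr:
        params = CombinedParams(k1=sol.x[0], n=sol.x[1], eps_c=sol.x[2], E=sol.x[3])
        converged = bool(sol.success)
    else:
        params = CombinedParams(k1=max(k1, K1_BOUNDS[0]), n=n_exp, eps_c=eps_c0, E=E)
        converged = False

    pred = eval_combined(params, eps)
    residuals = sig - pred
    return FitResult(
        model="combined",
        params=params,
        r_squared=r_squared(sig, pred),
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        converged=converged,
        n_evals=int(sol.nfev),
        profile_objective=profile_ssr,
        options=options,
    )


def fit_bilinear(curve: StressStrainCurve, options: FitOptions = FitOptions()) -> FitResult:
    """Fit two lines by OLS on each side of a profiled split.

    The transition strain is *recomputed* as the intersection of the two
    fitted lines (the classical construction), so it need not lie between the
    last heel sample and the first linear one.
    """
    eps, sig = curve.strain, curve.stress

    def split_objective(i):
        s1, b1 = _ols_line(eps[:i], sig[:i])
        s2, b2 = _ols_line(eps[i:], sig[i:])
        # relative tolerance: data on one global line yields branch slopes
        # equal only to floating-point error, and eps_c would blow up
        if abs(s1 - s2) <= 1e-8 * max(1.0, abs(s1), abs(s2)):
            raise FitError("parallel branch lines: intersection strain undefined")
        r1 = sig[:i] - (s1 * eps[:i] + b1)
        r2 = sig[i:] - (s2 * eps[i:] + b2)
        ssr = float(np.sum(r1**2) + np.sum(r2**2))
        return ssr, (s1, b1, s2, b2)

    try:
        best, (ssr, (s1, b1, s2, b2)) = _profile_splits(eps, sig, options, split_objective)
    except FitError as exc:
        raise FitError(f"bilinear fit failed: {exc}") from exc
    params = BilinearParams(E_heel=s1, b_heel=b1, E=s2, b_lin=b2)
    pred = eval_bilinear(params, eps)
    residuals = sig - pred
    return FitResult(
        model="bilinear",
        params=params,
        r_squared=r_squared(sig, pred),
        residuals=residuals,
        objective=float(np.sum(residuals**2)),
        converged=True,
        n_evals=0,
        profile_objective=ssr,
        options=options,
    )
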